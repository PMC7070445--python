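"""Sliding-window regularized LDA decoding of motion direction from EEG.

The classifier slides a 92 ms window (46 ms step) over the epoch; per
window the activity of every electrode is averaged over time and a
shrinkage-regularized linear discriminant is trained to separate
leftward from rightward motion.  Performance is the cross-validated
ROC AUC, averaged over repeated class-balanced subsamples of the
trials.  Each window's projection vector w defines a one-dimensional
discriminant component whose forward-model topography is the
channel-wise correlation between the component and the data; a fixed
component can be projected onto all trials and time points to obtain
single-trial evidence time courses, which carry the congruency
contrasts and the latency bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import stats as cstats
from .containers import EpochArray, LDAComponent

__all__ = [
    "SlidingWindowLDA", "EvidenceTimecourse",
    "shrinkage_lda", "forward_model", "project_component",
    "congruency_evidence", "congruency_effect", "latency_bootstrap",
]


# ---------------------------------------------------------------------------
# core linear algebra
# ---------------------------------------------------------------------------

def shrinkage_lda(X: np.ndarray, y: np.ndarray, gamma: float = 0.1):
    """Two-class LDA with shrinkage-regularized pooled covariance.

    The pooled within-class covariance is shrunk toward a scaled
    identity, ``(1 - gamma) * S + gamma * (trace(S)/C) * I``, and the
    projection is ``w = S_gamma^-1 (mu+ - mu-)`` with the bias placing
    the decision boundary midway between the class means.  Positive
    class is y = +1 (rightward motion).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required to train the LDA")
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    Xc = np.vstack([pos - mu_p, neg - mu_n])
    n, C = Xc.shape
    S = Xc.T @ Xc / max(n - 2, 1)
    if gamma == 0:
        if np.linalg.matrix_rank(S) < C:
            raise np.linalg.LinAlgError(
                "singular pooled covariance; use gamma > 0 (shrinkage)")
        S_g = S
    else:
        nu = np.trace(S) / C
        S_g = (1 - gamma) * S + gamma * nu * np.eye(C)
    w = np.linalg.solve(S_g, mu_p - mu_n)
    bias = -float(w @ (mu_p + mu_n) / 2)
    return w, bias


def _window_starts(times: np.ndarray, window: float, step: float) -> np.ndarray:
    """Start times of half-open [t, t + window) sliding windows."""
    t0, t1 = times[0], times[-1]
    dt = times[1] - times[0]
    starts = []
    t = t0
    while t + window <= t1 + dt / 2:
        starts.append(t)
        t += step
    return np.asarray(starts)


def _window_average(data: np.ndarray, times: np.ndarray, start: float,
                    window: float) -> np.ndarray:
    mask = (times >= start - 1e-9) & (times < start + window - 1e-9)
    if not mask.any():
        raise ValueError(f"no samples inside window starting at {start:.3f} s")
    return data[:, :, mask].mean(axis=-1)


def _as_array(epochs, times=None):
    if isinstance(epochs, EpochArray):
        return epochs.data[:, epochs.eeg_picks, :], epochs.times
    if times is None:
        raise ValueError("times axis required for plain-array input")
    return np.asarray(epochs, dtype=float), np.asarray(times, dtype=float)


# ---------------------------------------------------------------------------
# sliding-window estimator
# ---------------------------------------------------------------------------

class SlidingWindowLDA(BaseEstimator):
    """Sliding-window shrinkage-LDA decoder of motion direction.

    Parameters
    ----------
    window : float
        Window duration in seconds (default 0.092).  Results are
        reported at the first time point within each window.
    step : float
        Window step in seconds (default 0.046).
    gamma : float
        Covariance shrinkage parameter (default 0.1).
    folds : int
        Cross-validation folds for the AUC (default 6).
    reps : int
        Repetitions of the analysis on random class-balanced subsamples
        of the trials (default 100); AUC and w are averaged over reps.
    subsample_frac : float
        Fraction of per-class trials drawn per repetition (default 0.8).
    random_state : int or None
        Seed for subsampling and fold shuffling.

    Attributes (after :meth:`fit`)
    ------------------------------
    window_starts_ : ndarray of window start times (s)
    auc_ : ndarray, cross-validated AUC per window
    auc_sd_ : ndarray, SD of the AUC over subsample repetitions
    components_ : list of :class:`LDAComponent` per window
    """

    def __init__(self, window: float = 0.092, step: float = 0.046,
                 gamma: float = 0.1, folds: int = 6, reps: int = 100,
                 subsample_frac: float = 0.8, random_state=None):
        self.window = window
        self.step = step
        self.gamma = gamma
        self.folds = folds
        self.reps = reps
        self.subsample_frac = subsample_frac
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y, times=None):
        """Train per-window discriminants and estimate their AUC.

        ``X`` is an :class:`EpochArray` or a (trials, channels, time)
        array with ``times`` given; ``y`` are signed labels (+1 right,
        -1 left).
        """
        data, t = _as_array(X, times)
        y = np.asarray(y)
        if set(np.unique(y)) - {-1, 1}:
            raise ValueError("labels must be +1 / -1")
        if data.shape[0] != len(y):
            raise ValueError("label count does not match trial count")
        if self.window > t[-1] - t[0]:
            raise ValueError("window longer than the epoch")
        n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == -1))
        if min(n_pos, n_neg) < self.folds:
            raise ValueError(f"need at least {self.folds} trials per class")
        rng = np.random.default_rng(self.random_state)

        starts = _window_starts(t, self.window, self.step)
        pos_idx, neg_idx = np.flatnonzero(y == 1), np.flatnonzero(y == -1)
        n_draw = max(int(round(self.subsample_frac * min(n_pos, n_neg))),
                     self.folds)

        auc = np.empty(len(starts))
        auc_sd = np.empty(len(starts))
        comps: list[LDAComponent] = []
        for wi, start in enumerate(starts):
            Xw = _window_average(data, t, start, self.window)
            rep_auc = np.empty(self.reps)
            rep_w = np.empty((self.reps, Xw.shape[1]))
            rep_b = np.empty(self.reps)
            for r in range(self.reps):
                if self.reps == 1 and self.subsample_frac >= 1.0:
                    idx = np.concatenate([pos_idx, neg_idx])
                else:
                    idx = np.concatenate([
                        rng.choice(pos_idx, n_draw, replace=False),
                        rng.choice(neg_idx, n_draw, replace=False)])
                rep_auc[r] = self._cv_auc(Xw[idx], y[idx], rng)
                rep_w[r], rep_b[r] = shrinkage_lda(Xw[idx], y[idx], self.gamma)
            # sign-align reps to the first before averaging to prevent
            # cancellation of the mean projection vector
            signs = np.sign(rep_w @ rep_w[0])
            signs[signs == 0] = 1
            w_mean = (rep_w * signs[:, None]).mean(axis=0)
            b_mean = float((rep_b * signs).mean())
            auc[wi] = rep_auc.mean()
            auc_sd[wi] = rep_auc.std(ddof=1) if self.reps > 1 else 0.0
            comps.append(LDAComponent(w=w_mean, bias=b_mean,
                                      window_start=float(start),
                                      window_len=self.window,
                                      gamma=self.gamma))
        self.window_starts_ = starts
        self.auc_ = auc
        self.auc_sd_ = auc_sd
        self.components_ = comps
        self.times_ = t
        return self

    def _cv_auc(self, Xw, y, rng):
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        scores = np.empty(len(y))
        for train, test in skf.split(Xw, y):
            assert not np.intersect1d(train, test).size
            w, b = shrinkage_lda(Xw[train], y[train], self.gamma)
            scores[test] = Xw[test] @ w + b
        return roc_auc_score((y == 1).astype(int), scores)

    # ------------------------------------------------------------------
    def peak(self):
        """(start time, AUC) of the best-decoding window."""
        i = int(np.argmax(self.auc_))
        return float(self.window_starts_[i]), float(self.auc_[i])

    def component_at(self, time: float) -> LDAComponent:
        """Component whose window start is closest to ``time``."""
        i = int(np.argmin(np.abs(self.window_starts_ - time)))
        return self.components_[i]

    def transform(self, X, times=None) -> "EvidenceTimecourse":
        """Project the peak-window component onto all trials/time points."""
        return project_component(self.component_at(self.peak()[0]), X, times)


# ---------------------------------------------------------------------------
# forward model and projections
# ---------------------------------------------------------------------------

def forward_model(component: LDAComponent, epochs, times=None) -> np.ndarray:
    """Forward-model topography of a discriminant component.

    The pattern is the normalized correlation between the discriminant
    component and the window-averaged activity: per channel, the
    covariance over trials with the unit-variance discriminant score,
    ``a_ch = cov(x_ch, y) / std(y)`` — the interpretable scalp map of
    the decoded source.  For data generated by a single source
    ``x = s * m`` this recovers the mixing pattern ``m`` exactly, and
    it is invariant to rescaling of ``w``.  Zero-variance channels map
    to 0 with a warning.
    """
    data, t = _as_array(epochs, times)
    if data.shape[1] != len(component.w):
        raise ValueError("channel count does not match component weights")
    Xw = _window_average(data, t, component.window_start, component.window_len)
    yc = Xw @ component.w
    yc = yc - yc.mean()
    Xc = Xw - Xw.mean(axis=0)
    sy = np.sqrt(np.sum(yc**2))
    if sy == 0:
        raise ValueError("discriminant component has zero variance")
    sx = np.sum(Xc**2, axis=0)
    if not np.all(sx > 0):
        warnings.warn(f"{np.sum(sx == 0)} zero-variance channel(s); "
                      "pattern set to 0")
    a = (Xc.T @ yc) / sy
    component.pattern = a
    return a


@dataclass
class EvidenceTimecourse:
    """Single-trial discriminant evidence from a fixed component."""

    y: np.ndarray               # (trials, n_windows)
    window_starts: np.ndarray
    component: LDAComponent = field(repr=False, default=None)


def project_component(component: LDAComponent, epochs, times=None,
                      window=None, step: float = 0.046,
                      include_bias: bool = True) -> EvidenceTimecourse:
    """Apply a fixed component's weights to all trials and time points.

    ``y(trial, t) = w @ x_window(t) (+ bias)`` on the same sliding-window
    grid used for training.  Linear in the data.
    """
    data, t = _as_array(epochs, times)
    if data.shape[1] != len(component.w):
        raise ValueError("channel count does not match component weights")
    window = component.window_len if window is None else window
    starts = _window_starts(t, window, step)
    y = np.empty((data.shape[0], len(starts)))
    for i, s in enumerate(starts):
        y[:, i] = _window_average(data, t, s, window) @ component.w
    if include_bias:
        y += component.bias
    return EvidenceTimecourse(y=y, window_starts=starts, component=component)


# ---------------------------------------------------------------------------
# congruency contrast
# ---------------------------------------------------------------------------

def congruency_evidence(epochs, labels, congruent, train_window_start: float,
                        window: float = 0.092, step: float = 0.046,
                        gamma: float = 0.1, folds: int = 6, seed=None,
                        times=None) -> np.ndarray:
    """Per-participant congruency contrast of direction-aligned evidence.

    Uses fold-wise cross-validation: the LDA weights at the window of
    interest are computed on the training folds and the evidence is
    quantified on the held-out trials, so the contrast is unbiased by
    the classifier fit.  Evidence is aligned by the true direction
    (y * label, removing the sign difference between the two motion
    directions; the bias is excluded as it carries no class
    information once aligned).  Returns the mean aligned evidence on
    congruent minus incongruent trials, per window start.
    """
    data, t = _as_array(epochs, times)
    labels = np.asarray(labels)
    congruent = np.asarray(congruent, dtype=bool)
    if not (congruent.any() and (~congruent).any()):
        raise ValueError("participant lacks one congruency class")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    starts = _window_starts(t, window, step)
    aligned = np.full((len(labels), len(starts)), np.nan)
    for train, test in skf.split(data[:, :, 0], labels):
        Xw = _window_average(data[train], t, train_window_start, window)
        w, b = shrinkage_lda(Xw, labels[train], gamma)
        comp = LDAComponent(w=w, bias=b, window_start=train_window_start,
                            window_len=window, gamma=gamma)
        ev = project_component(comp, data[test], t, step=step,
                               include_bias=False)
        aligned[test] = ev.y * labels[test, None]
    return aligned[congruent].mean(axis=0) - aligned[~congruent].mean(axis=0)


def congruency_effect(contrasts: np.ndarray, n_perm: int = 2000,
                      seed=None, **cluster_kwargs):
    """Group-level test of the congruency contrast time courses.

    ``contrasts`` is (participants x windows) of per-participant
    congruent-minus-incongruent aligned evidence.  Returns per-window
    one-sample t values and the sign-flip cluster-mass permutation
    result.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    result = cstats.cluster_permutation(contrasts, n_perm=n_perm, seed=seed,
                                        **cluster_kwargs)
    return result.t_map, result


# ---------------------------------------------------------------------------
# latency bootstrap
# ---------------------------------------------------------------------------

@dataclass
class LatencyBootstrap:
    latency_a: float            # original-sample onset latencies (s)
    latency_b: float
    mean_difference: float      # bootstrap mean of (A - B), the effect size
    p_value: float
    distribution: np.ndarray = field(repr=False, default=None)
    dropped_fraction: float = 0.0
    unreliable: bool = False


def _first_cluster_latency(courses, window_starts, n_perm, seed, alpha=0.05,
                           **kw):
    res = cstats.cluster_permutation(courses, n_perm=n_perm, seed=seed, **kw)
    sig = res.significant(alpha)
    if not sig:
        return None
    onset_bins = [c.bins.min() for c in sig]
    return float(window_starts[min(onset_bins)])


def latency_bootstrap(contrasts_a: np.ndarray, contrasts_b: np.ndarray,
                      window_starts: np.ndarray, n_boot: int = 2000,
                      n_perm_inner: int = 500, seed=None, alpha: float = 0.05,
                      **cluster_kwargs) -> LatencyBootstrap:
    """Percentile bootstrap of the onset-latency difference of two effects.

    The onset latency of a condition is the first time bin of its
    earliest significant cluster.  Participants are resampled with
    replacement; per resample both cluster tests are recomputed and the
    latency difference (A - B) collected.  Resamples in which either
    condition shows no significant effect are dropped and counted;
    more than 50% drops flags the estimate as unreliable.
    """
    a = np.asarray(contrasts_a, dtype=float)
    b = np.asarray(contrasts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must have paired participant courses")
    rng = np.random.default_rng(seed)
    lat_a = _first_cluster_latency(a, window_starts, n_perm_inner,
                                   rng.integers(2**31 - 1), alpha, **cluster_kwargs)
    lat_b = _first_cluster_latency(b, window_starts, n_perm_inner,
                                   rng.integers(2**31 - 1), alpha, **cluster_kwargs)
    if lat_a is None or lat_b is None:
        raise ValueError("no significant effect in the original sample for "
                         "at least one condition")
    n = a.shape[0]
    diffs = []
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        la = _first_cluster_latency(a[idx], window_starts, n_perm_inner,
                                    rng.integers(2**31 - 1), alpha, **cluster_kwargs)
        lb = _first_cluster_latency(b[idx], window_starts, n_perm_inner,
                                    rng.integers(2**31 - 1), alpha, **cluster_kwargs)
        if la is None or lb is None:
            dropped += 1
            continue
        diffs.append(la - lb)
    diffs = np.asarray(diffs)
    if diffs.size == 0:
        raise ValueError("all bootstrap resamples lacked a significant effect")
    p_lo = (1 + np.sum(diffs <= 0)) / (diffs.size + 1)
    p_hi = (1 + np.sum(diffs >= 0)) / (diffs.size + 1)
    frac_dropped = dropped / n_boot
    return LatencyBootstrap(latency_a=lat_a, latency_b=lat_b,
                            mean_difference=float(diffs.mean()),
                            p_value=float(min(1.0, 2 * min(p_lo, p_hi))),
                            distribution=diffs,
                            dropped_fraction=frac_dropped,
                            unreliable=frac_dropped > 0.5)
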