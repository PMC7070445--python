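"""Prestimulus time-frequency analysis and power-behaviour GLMs.

Morlet-wavelet time-frequency decomposition of the one-dimensional
discriminant component (the LDA "virtual channel"), with the
poststimulus period zeroed before the transform so that power
estimates cannot be contaminated by stimulus-evoked responses, and
power z-scored across trials per time-frequency bin.  Single-trial
logistic GLMs then link prestimulus power to choice (stimulus, cue,
their interaction, and power interactions) or to accuracy
(congruency, power, power x congruency), with group-level sign-flip
cluster-mass tests over the time-frequency plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from mne.time_frequency import tfr_array_morlet
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression

from . import stats as cstats
from .containers import EpochArray, LDAComponent, TFPower

__all__ = [
    "default_grid", "MorletTF", "component_signal", "wavelet_tf",
    "GLMBetaMap", "choice_glm", "accuracy_glm",
    "median_split_analysis", "cue_power_contrast",
]


def default_grid(fmin: float = 2.0, fmax: float = 50.0):
    """The analysis frequency grid and per-frequency wavelet widths.

    Frequencies run from 2 to 50 Hz in 1 Hz steps below 16 Hz and 2 Hz
    steps above; the wavelet width rises linearly from 3 cycles at
    2 Hz to 9 cycles at 35 Hz and stays at 9 above.
    """
    freqs = np.concatenate([np.arange(2.0, 16.0, 1.0),
                            np.arange(16.0, 51.0, 2.0)])
    freqs = freqs[(freqs >= fmin) & (freqs <= fmax)]
    cycles = np.clip(3 + (freqs - 2) * (9 - 3) / (35 - 2), 3, 9)
    return freqs, cycles


def component_signal(component: LDAComponent, epochs: EpochArray) -> np.ndarray:
    """Sample-wise virtual-channel signal y(t) = w @ x(t) per trial.

    Unlike the sliding-window evidence projection, no temporal
    averaging is applied: this is the input for the time-frequency
    transform.
    """
    data = epochs.data[:, epochs.eeg_picks, :]
    if data.shape[1] != len(component.w):
        raise ValueError("channel count does not match component weights")
    return np.einsum("tcs,c->ts", data, component.w)


def wavelet_tf(signals: np.ndarray, times: np.ndarray, fs: float,
               fmin: float = 2.0, fmax: float = 50.0,
               prestim: tuple = (-0.5, 0.0), decim: int = 5,
               zero_poststim: bool = True) -> TFPower:
    """Morlet time-frequency power of single-trial signals, z-scored.

    Poststimulus samples (t >= 0) are zeroed before the transform so
    the prestimulus estimates are invariant to whatever the evoked
    response contains.  Power is computed on the grid of
    :func:`default_grid`, restricted to the ``prestim`` window
    (decimated by ``decim``), and z-scored across trials within each
    (frequency, time) bin.

    Frequencies whose full wavelet support does not fit into the
    prestimulus span are kept but flagged with a warning (their
    low-frequency estimates lean on the zeroed region).
    """
    signals = np.asarray(signals, dtype=float)
    times = np.asarray(times, dtype=float)
    if signals.ndim != 2 or signals.shape[1] != len(times):
        raise ValueError("signals must be (trials, n_times) matching times")
    freqs, cycles = default_grid(fmin, fmax)
    if freqs[-1] >= fs / 2:
        raise ValueError(f"frequency grid exceeds Nyquist ({fs / 2} Hz)")
    x = signals.copy()
    if zero_poststim:
        x[:, times >= 0] = 0.0
    # zero-pad so the widest wavelet fits; the pad is trimmed afterwards
    pad = int(np.ceil(5 * (cycles / (2 * np.pi * freqs)).max() * fs)) + 1
    x = np.pad(x, ((0, 0), (pad, pad)))
    power = tfr_array_morlet(x[:, None, :], sfreq=fs, freqs=freqs,
                             n_cycles=cycles, output="power")[:, 0]
    power = power[:, :, pad:-pad]
    keep = (times >= prestim[0]) & (times < prestim[1])
    idx = np.flatnonzero(keep)[::decim]
    power = power[:, :, idx]
    t_out = times[idx]

    span = prestim[1] - prestim[0]
    flagged = freqs[cycles / freqs > span]
    if flagged.size:
        warnings.warn(f"wavelet support exceeds the prestimulus span for "
                      f"{flagged.size} low frequencies (<= {flagged.max():.0f} Hz)")

    mu = power.mean(axis=0, keepdims=True)
    sd = power.std(axis=0, keepdims=True)
    z = (power - mu) / np.maximum(sd, np.finfo(float).tiny)
    return TFPower(power_z=z, freqs=freqs, times=t_out, cycles=cycles)


class MorletTF(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`wavelet_tf` for pipeline use."""

    def __init__(self, fmin: float = 2.0, fmax: float = 50.0,
                 prestim: tuple = (-0.5, 0.0), decim: int = 5):
        self.fmin = fmin
        self.fmax = fmax
        self.prestim = prestim
        self.decim = decim

    def fit(self, X=None, y=None):
        self.freqs_, self.cycles_ = default_grid(self.fmin, self.fmax)
        return self

    def transform(self, X, times=None, fs=None) -> TFPower:
        if isinstance(X, tuple):
            X, times, fs = X
        return wavelet_tf(X, times, fs, self.fmin, self.fmax,
                          self.prestim, self.decim)


# ---------------------------------------------------------------------------
# single-trial GLMs
# ---------------------------------------------------------------------------

CHOICE_PREDICTORS = ("stim", "cue", "stim_x_cue", "power",
                     "power_x_stim", "power_x_cue")
ACCURACY_PREDICTORS = ("congruency", "power", "power_x_congruency")


@dataclass
class GLMBetaMap:
    """Per-participant regression betas over the time-frequency plane."""

    betas: np.ndarray            # (participants, predictors, freqs, times)
    predictors: tuple
    freqs: np.ndarray
    times: np.ndarray
    cluster_results: dict = field(default_factory=dict)

    def group_t(self, predictor: str) -> np.ndarray:
        i = self.predictors.index(predictor)
        b = self.betas[:, i]
        return sps.ttest_1samp(b, 0, axis=0).statistic

    def cluster_test(self, predictor: str, n_perm: int = 2000, seed=None,
                     **kw):
        i = self.predictors.index(predictor)
        res = cstats.cluster_permutation(self.betas[:, i], n_perm=n_perm,
                                         seed=seed, **kw)
        self.cluster_results[predictor] = res
        return res


def _fit_logistic(X: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Logistic fit with intercept; ridge fallback on separation."""
    Xd = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y01, Xd).fit(disp=0, maxiter=200)
        if res.mle_retvals.get("converged", False) and \
                np.all(np.isfinite(res.params)) and \
                np.max(np.abs(res.params)) < 50:
            return np.asarray(res.params[1:])
    except Exception:
        pass
    # (quasi-)separation or ill-conditioning: weak-ridge fallback
    clf = LogisticRegression(C=1.0, max_iter=1000)
    clf.fit(X, y01)
    return clf.coef_[0]


def _glm_participant(design: np.ndarray, power_z: np.ndarray, y01: np.ndarray,
                     power_cols: list) -> np.ndarray:
    """Fit the per-bin logistic GLM for one participant.

    ``design`` is (trials, predictors) with np.nan placeholders in the
    power-dependent columns listed in ``power_cols``; those columns are
    filled per (f, t) bin with power_z (times the interacting trial
    variable already stored as the column's multiplier).
    """
    n_pred = design.shape[1]
    nf, nt = power_z.shape[1:]
    betas = np.empty((n_pred, nf, nt))
    X = design.copy()
    for fi in range(nf):
        for ti in range(nt):
            pz = power_z[:, fi, ti]
            for col, mult in power_cols:
                X[:, col] = pz * mult
            betas[:, fi, ti] = _fit_logistic(X, y01)
    return betas


def choice_glm(tables: list[pd.DataFrame], tf_list: list[TFPower],
               n_perm: int = 2000, seed=None,
               run_cluster_tests: bool = True) -> GLMBetaMap:
    """Logistic GLM of single-trial choice on stimulus, cue, and power.

    Per participant and time-frequency bin, choice (right = 1) is
    regressed on the visual motion direction, the cue direction, their
    interaction, prestimulus power, and the power x stimulus and
    power x cue interactions (all stimulus codes +-1, power z-scored
    per bin).  Group-level inference is a one-sample cluster-mass
    permutation test on the betas, per predictor, with 2-D
    (frequency x time) adjacency.
    """
    if len(tables) != len(tf_list):
        raise ValueError("one TFPower per participant table required")
    betas = []
    for table, tf in zip(tables, tf_list):
        if len(table) != tf.power_z.shape[0]:
            raise ValueError("trials misaligned between table and TF power")
        stim = table["direction"].to_numpy(dtype=float)
        cue = table["cue"].to_numpy(dtype=float)
        y01 = (table["choice"].to_numpy() == 1).astype(float)
        design = np.column_stack([stim, cue, stim * cue,
                                  np.zeros_like(stim), np.zeros_like(stim),
                                  np.zeros_like(stim)])
        power_cols = [(3, np.ones_like(stim)), (4, stim), (5, cue)]
        betas.append(_glm_participant(design, tf.power_z, y01, power_cols))
    tf0 = tf_list[0]
    out = GLMBetaMap(betas=np.stack(betas), predictors=CHOICE_PREDICTORS,
                     freqs=tf0.freqs, times=tf0.times)
    if run_cluster_tests:
        rng = np.random.default_rng(seed)
        for pred in CHOICE_PREDICTORS:
            out.cluster_test(pred, n_perm=n_perm,
                             seed=rng.integers(2**31 - 1))
    return out


def accuracy_glm(tables: list[pd.DataFrame], tf_list: list[TFPower],
                 n_perm: int = 2000, seed=None,
                 run_cluster_tests: bool = True) -> GLMBetaMap:
    """Logistic GLM of accuracy on congruency, power, and their interaction."""
    if len(tables) != len(tf_list):
        raise ValueError("one TFPower per participant table required")
    betas = []
    for table, tf in zip(tables, tf_list):
        if len(table) != tf.power_z.shape[0]:
            raise ValueError("trials misaligned between table and TF power")
        cong = np.where(table["congruent"].to_numpy(dtype=bool), 1.0, -1.0)
        y01 = table["correct"].to_numpy(dtype=float)
        design = np.column_stack([cong, np.zeros_like(cong),
                                  np.zeros_like(cong)])
        power_cols = [(1, np.ones_like(cong)), (2, cong)]
        betas.append(_glm_participant(design, tf.power_z, y01, power_cols))
    tf0 = tf_list[0]
    out = GLMBetaMap(betas=np.stack(betas), predictors=ACCURACY_PREDICTORS,
                     freqs=tf0.freqs, times=tf0.times)
    if run_cluster_tests:
        rng = np.random.default_rng(seed)
        for pred in ACCURACY_PREDICTORS:
            out.cluster_test(pred, n_perm=n_perm,
                             seed=rng.integers(2**31 - 1))
    return out


# ---------------------------------------------------------------------------
# follow-up analyses
# ---------------------------------------------------------------------------

def median_split_analysis(tables: list[pd.DataFrame], tf_list: list[TFPower],
                          cluster_mask: np.ndarray):
    """Accuracy in low- vs high-power trials, per congruency, BH-adjusted.

    ``cluster_mask`` is a boolean (freqs x times) map (e.g. the
    bin-wise intersection of two alpha clusters); per trial the power
    is averaged over the masked bins, trials are median-split within
    participant, and the accuracy difference (high minus low power) is
    tested per congruency class with paired t tests, FDR-adjusted over
    the two tests (Benjamini-Hochberg).
    """
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("empty cluster mask")
    acc = {True: [], False: []}       # congruency -> (n_subj, 2) low/high
    for table, tf in zip(tables, tf_list):
        trial_power = tf.power_z[:, cluster_mask].mean(axis=1)
        median = np.median(trial_power)
        high = trial_power > median
        for cong in (True, False):
            sel = table["congruent"].to_numpy(dtype=bool) == cong
            lo, hi = sel & ~high, sel & high
            if not (lo.any() and hi.any()):
                warnings.warn("participant with empty congruency cell after "
                              "median split excluded")
                acc[cong].append((np.nan, np.nan))
                continue
            acc[cong].append((table.loc[lo, "correct"].mean(),
                              table.loc[hi, "correct"].mean()))
    out = {}
    pvals = []
    for cong in (True, False):
        arr = np.asarray(acc[cong], dtype=float)
        arr = arr[~np.isnan(arr).any(axis=1)]
        t, p = sps.ttest_rel(arr[:, 1], arr[:, 0])
        out["congruent" if cong else "incongruent"] = {
            "acc_low": float(arr[:, 0].mean()), "acc_high": float(arr[:, 1].mean()),
            "t": float(t), "p": float(p),
            "d": cstats.cohens_d(arr[:, 1], arr[:, 0])}
        pvals.append(p)
    adj = cstats.bh_fdr(pvals)
    out["congruent"]["p_adjusted"] = float(adj[0])
    out["incongruent"]["p_adjusted"] = float(adj[1])
    return out


def cue_power_contrast(tables: list[pd.DataFrame], tf_list: list[TFPower],
                       band_mask: np.ndarray, condition: str = "precue"):
    """Group t-test of prestimulus power between the two cue directions.

    Per participant, the band/window-averaged power is contrasted
    between cue-left and cue-right trials of the given condition
    (the check that a preceding symbolic cue does not itself shift
    alpha power).
    """
    band_mask = np.asarray(band_mask, dtype=bool)
    diffs = []
    for table, tf in zip(tables, tf_list):
        sel = table["condition"] == condition
        if not sel.any():
            raise ValueError(f"no trials of condition {condition!r}")
        power = tf.power_z[:, band_mask].mean(axis=1)
        cue = table["cue"].to_numpy()
        right = sel & (cue == 1)
        left = sel & (cue == -1)
        diffs.append(power[right.to_numpy() if hasattr(right, "to_numpy") else right].mean()
                     - power[left.to_numpy() if hasattr(left, "to_numpy") else left].mean())
    diffs = np.asarray(diffs)
    t, p = sps.ttest_1samp(diffs, 0)
    return {"mean_difference": float(diffs.mean()), "t": float(t),
            "p": float(p), "d": cstats.cohens_d(diffs)}
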