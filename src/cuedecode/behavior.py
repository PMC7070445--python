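"""Behavioral analysis of the cued motion-discrimination task.

Accuracy/RT cell summaries with a fully within-subject cue x congruency
ANOVA, signal-detection measures computed relative to leftward motion
with the per-cue-side bias combination, the 2-down/1-up adaptive
staircase used to titrate motion coherence, opponent motion-energy
extraction from the random-dot movies, and reverse-correlation
perceptual templates with shuffle-based z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sig
from scipy import stats as sps

from . import stats as cstats
from .containers import CONDITIONS
from .synthetic import DotMovie

__all__ = [
    "SDTResult", "PerceptualTemplate", "Staircase", "StaircaseResult",
    "summarize_behavior", "sdt_measures", "run_staircase", "weibull_observer",
    "motion_energy", "per_epoch_evidence", "perceptual_template",
    "template_congruency_contrast",
]


# ---------------------------------------------------------------------------
# accuracy / RT summaries
# ---------------------------------------------------------------------------

def _cell_means(table: pd.DataFrame, value: str) -> np.ndarray:
    """condition x congruency cell means for one participant (3 x 2)."""
    out = np.full((len(CONDITIONS), 2), np.nan)
    for i, cond in enumerate(CONDITIONS):
        for j, cong in enumerate((True, False)):
            cell = table[(table["condition"] == cond)
                         & (table["congruent"] == cong)]
            if cell.empty:
                raise ValueError(f"empty cell: condition={cond}, congruent={cong}")
            out[i, j] = cell[value].mean()
    return out


def summarize_behavior(tables: list[pd.DataFrame], value: str = "correct"):
    """Group summary of accuracy (or RT) over cue condition x congruency.

    Parameters
    ----------
    tables : list of per-participant trial tables (choices filled in).
    value : column to summarise ('correct' or 'rt').

    Returns a dict with the participant x condition x congruency cell
    means, the repeated-measures ANOVA (cue, congruency, interaction;
    F, conventional dfs, p, partial eta squared), and post hoc paired
    t tests of congruent vs incongruent per condition with Cohen's d.
    """
    if len(tables) < 2:
        raise ValueError("group tests need at least 2 participants")
    cells = np.stack([_cell_means(t, value) for t in tables])  # (n, 3, 2)
    anova = cstats.two_way_rm_anova(cells)
    anova = {"cue": anova["A"], "congruency": anova["B"],
             "cue_x_congruency": anova["AxB"]}
    posthoc = {}
    for i, cond in enumerate(CONDITIONS):
        c, ic = cells[:, i, 0], cells[:, i, 1]
        t, p = sps.ttest_rel(c, ic)
        posthoc[cond] = {"t": float(t), "p": float(p),
                         "d": cstats.cohens_d(c, ic),
                         "mean_congruent": float(c.mean()),
                         "mean_incongruent": float(ic.mean())}
    return {"cells": cells, "anova": anova, "posthoc": posthoc,
            "conditions": list(CONDITIONS)}


# ---------------------------------------------------------------------------
# signal detection theory
# ---------------------------------------------------------------------------

@dataclass
class SDTResult:
    """Signal-detection measures with leftward motion as the signal."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: dict          # per cue side (-1 left, +1 right)
    combined_bias: float       # magnitude after sign alignment
    cue_following_bias: float  # signed; positive = responses drawn toward the cue


def _rates(n_hit, n_sig, n_fa, n_noise):
    """Log-linear corrected rates: add 0.5 to each count cell."""
    return (n_hit + 0.5) / (n_sig + 1.0), (n_fa + 0.5) / (n_noise + 1.0)


def _d_c(h, fa):
    zh, zfa = sps.norm.ppf(h), sps.norm.ppf(fa)
    return zh - zfa, -(zh + zfa) / 2


def sdt_measures(table: pd.DataFrame) -> SDTResult:
    """d-prime and criterion relative to leftward motion.

    A hit is a 'left' response to leftward motion; a false alarm a
    'left' response to rightward motion.  The criterion c is computed
    separately for trials cued left and cued right, and the two bias
    measures are combined after converting both sides to the same sign
    (the per-side signs cancel for an observer drawn toward the cue).
    Extreme rates are handled by the log-linear correction (0.5 added
    to every count cell).
    """
    left = table["direction"] == -1
    right = table["direction"] == 1
    if not (left.any() and right.any()):
        raise ValueError("both motion directions required for SDT measures")
    resp_left = table["choice"] == -1

    h, fa = _rates((left & resp_left).sum(), left.sum(),
                   (right & resp_left).sum(), right.sum())
    d_prime, _ = _d_c(h, fa)

    criterion = {}
    for side in (-1, 1):
        sub = table[table["cue"] == side]
        if sub.empty:
            raise ValueError(f"no trials with cue side {side}")
        s_left = sub["direction"] == -1
        s_resp = sub["choice"] == -1
        hs, fas = _rates((s_left & s_resp).sum(), s_left.sum(),
                         ((~s_left) & s_resp).sum(), (~s_left).sum())
        criterion[side] = _d_c(hs, fas)[1]

    signed = (criterion[1] - criterion[-1]) / 2
    return SDTResult(hit_rate=float(h), fa_rate=float(fa),
                     d_prime=float(d_prime),
                     criterion_c={k: float(v) for k, v in criterion.items()},
                     combined_bias=float(abs(signed)),
                     cue_following_bias=float(signed))


# ---------------------------------------------------------------------------
# adaptive staircase
# ---------------------------------------------------------------------------

@dataclass
class Staircase:
    """A 2-down/1-up transformed staircase on motion coherence (%).

    Difficulty increases (coherence decreases) after ``n_down``
    consecutive correct responses and decreases after every error,
    converging on the ~70.7%-correct point of the psychometric
    function.  The step halves from ``step_initial`` to ``step_final``
    after the second reversal.
    """

    start: float = 40.0
    step_initial: float = 4.0
    step_final: float = 2.0
    n_down: int = 2
    n_up: int = 1
    switch_after: int = 2       # reversals before the step shrinks
    level: float = field(init=False)
    reversals: list = field(init=False, default_factory=list)
    _correct_streak: int = field(init=False, default=0)
    _last_move: int = field(init=False, default=0)

    def __post_init__(self):
        self.level = float(self.start)

    @property
    def step(self) -> float:
        return self.step_initial if len(self.reversals) < self.switch_after \
            else self.step_final

    def update(self, correct: bool) -> None:
        move = 0
        if correct:
            self._correct_streak += 1
            if self._correct_streak >= self.n_down:
                move = -1
                self._correct_streak = 0
        else:
            self._correct_streak = 0
            move = +1
        if move:
            if self._last_move and move != self._last_move:
                self.reversals.append(self.level)
            self._last_move = move
            self.level = float(np.clip(self.level + move * self.step, 0.0, 100.0))

    def threshold(self, n_last: int = 6) -> float:
        if len(self.reversals) < n_last:
            raise RuntimeError("staircase has not produced enough reversals")
        return float(np.mean(self.reversals[-n_last:]))


@dataclass
class StaircaseResult:
    threshold: float
    track_thresholds: np.ndarray
    converged: bool
    tracks: list = field(repr=False, default_factory=list)


def weibull_observer(threshold: float = 20.0, slope: float = 3.0,
                     lapse: float = 0.02, guess: float = 0.5,
                     p_at_threshold: float = 0.75):
    """Two-alternative Weibull psychometric function of coherence (%).

    Returns a callable ``level -> P(correct)`` with
    ``P = guess + (1 - guess - lapse) * (1 - exp(-(x/alpha)^slope))``
    where ``alpha`` is scaled so that P(threshold) = ``p_at_threshold``.
    """
    # solve alpha from the stated percent correct at threshold
    q = (p_at_threshold - guess) / (1 - guess - lapse)
    if not 0 < q < 1:
        raise ValueError("p_at_threshold incompatible with guess/lapse")
    alpha = threshold / (-np.log(1 - q)) ** (1 / slope)

    def psychometric(level):
        level = np.maximum(np.asarray(level, dtype=float), 0.0)
        return guess + (1 - guess - lapse) * (1 - np.exp(-(level / alpha) ** slope))

    psychometric.alpha = alpha
    return psychometric


def run_staircase(observer, n_trials: int = 400, n_tracks: int = 3,
                  seed=None, n_reversals_avg: int = 6,
                  min_reversals: int = 10, **staircase_kwargs) -> StaircaseResult:
    """Run interleaved 2-down/1-up staircases against a simulated observer.

    ``observer`` maps a coherence level (%) to P(correct); ``n_trials``
    trials are simulated per track, interleaved round-robin.  Each
    track's threshold is the mean of its last ``n_reversals_avg``
    reversal levels; the overall estimate averages the tracks.  The
    result is flagged non-converged if any track yields fewer than
    ``min_reversals`` reversals.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tracks = [Staircase(**staircase_kwargs) for _ in range(n_tracks)]
    for _ in range(n_trials):
        for tr in tracks:
            tr.update(bool(rng.uniform() < observer(tr.level)))
    converged = all(len(tr.reversals) >= max(min_reversals, n_reversals_avg)
                    for tr in tracks)
    thr = np.array([np.mean(tr.reversals[-n_reversals_avg:])
                    if len(tr.reversals) >= n_reversals_avg else np.nan
                    for tr in tracks])
    return StaircaseResult(threshold=float(np.nanmean(thr)),
                           track_thresholds=thr, converged=converged,
                           tracks=tracks)


# ---------------------------------------------------------------------------
# motion energy
# ---------------------------------------------------------------------------

def per_epoch_evidence(table: pd.DataFrame) -> np.ndarray:
    """Ground-truth backend: signed per-epoch coherence evidence.

    Returns (n_trials, n_epochs) with rightward motion positive, in
    coherence fraction units (direction * coherence / 100).
    """
    cols = [c for c in table.columns if c.startswith("coh_e")]
    coh = table[cols].to_numpy(dtype=float) / 100.0
    return table["direction"].to_numpy(dtype=float)[:, None] * coh


def motion_energy(movie: DotMovie, n_bins: int = 100, sf: float = 0.8,
                  sigma_x: float = 0.7, sigma_t: float = 0.05) -> np.ndarray:
    """Opponent spatiotemporal motion energy per coherence epoch.

    The dot movie is projected onto the horizontal axis (per-frame dot
    histogram over x), then filtered with a pair of complex space-time
    Gabors tuned to leftward and rightward motion at the dot speed
    (temporal frequency = ``sf`` * speed).  The signed evidence is the
    rightward minus leftward energy, summed over space and averaged
    within each 12-frame epoch; rightward motion is positive.
    """
    n_frames = movie.n_frames
    fpe = movie.frames_per_epoch
    if n_frames < fpe:
        raise ValueError("movie shorter than one coherence epoch")
    R = movie.aperture_radius
    edges = np.linspace(-R, R, n_bins + 1)
    dx = edges[1] - edges[0]
    img = np.stack([np.histogram(movie.positions[f, :, 0], bins=edges)[0]
                    for f in range(n_frames)]).astype(float)
    img -= img.mean(axis=1, keepdims=True)

    dt = 1.0 / movie.frame_rate
    tf = sf * movie.speed                      # Hz, matched to dot speed
    # space-time Gabor support
    xs = (np.arange(-int(3 * sigma_x / dx), int(3 * sigma_x / dx) + 1)) * dx
    ts = (np.arange(-int(3 * sigma_t / dt), int(3 * sigma_t / dt) + 1)) * dt
    T, X = np.meshgrid(ts, xs, indexing="ij")
    env = np.exp(-X**2 / (2 * sigma_x**2) - T**2 / (2 * sigma_t**2))
    g_right = env * np.exp(1j * 2 * np.pi * (sf * X - tf * T))
    e_r = np.abs(sig.fftconvolve(img, g_right.real, mode="same")) ** 2 + \
        np.abs(sig.fftconvolve(img, g_right.imag, mode="same")) ** 2
    g_left = env * np.exp(1j * 2 * np.pi * (sf * X + tf * T))
    e_l = np.abs(sig.fftconvolve(img, g_left.real, mode="same")) ** 2 + \
        np.abs(sig.fftconvolve(img, g_left.imag, mode="same")) ** 2

    net = (e_r - e_l).sum(axis=1)              # per frame
    n_epochs = n_frames // fpe
    per_epoch = net[:n_epochs * fpe].reshape(n_epochs, fpe).mean(axis=1)
    # scale-free normalisation so evidence is comparable across movies
    denom = (e_r + e_l).sum()
    return per_epoch / denom * n_frames if denom > 0 else per_epoch


# ---------------------------------------------------------------------------
# reverse correlation
# ---------------------------------------------------------------------------

@dataclass
class PerceptualTemplate:
    """Choice-conditioned stimulus weights, z-scored against a shuffle null."""

    weights_z: np.ndarray
    raw_weights: np.ndarray
    n_shuffles: int
    shuffle_mean: np.ndarray = field(repr=False, default=None)
    shuffle_sd: np.ndarray = field(repr=False, default=None)


def perceptual_template(evidence: np.ndarray, choices: np.ndarray,
                        n_shuffles: int = 1000, seed=None) -> PerceptualTemplate:
    """Reverse-correlation perceptual weights per stimulus epoch.

    The raw weight of an epoch is the mean evidence on rightward-choice
    trials minus the mean on leftward-choice trials.  Weights are
    normalised to z-scores against a null obtained by shuffling the
    choice labels over trials (``n_shuffles`` permutations), which
    makes them invariant to affine rescaling of the evidence.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for a stable null")
    evidence = np.asarray(evidence, dtype=float)
    choices = np.asarray(choices)
    right = choices == 1
    if right.all() or not right.any():
        raise ValueError("both choice options required for reverse correlation")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def contrast(mask):
        return evidence[mask].mean(axis=0) - evidence[~mask].mean(axis=0)

    raw = contrast(right)
    null = np.empty((n_shuffles, evidence.shape[1]))
    for s in range(n_shuffles):
        null[s] = contrast(rng.permutation(right))
    mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
    z = (raw - mu) / np.maximum(sd, np.finfo(float).tiny)
    return PerceptualTemplate(weights_z=z, raw_weights=raw,
                              n_shuffles=n_shuffles, shuffle_mean=mu,
                              shuffle_sd=sd)


def template_congruency_contrast(templates_congruent: np.ndarray,
                                 templates_incongruent: np.ndarray,
                                 n_boot: int = 2000, seed=None):
    """Congruent minus incongruent template difference with bootstrap CI.

    Inputs are paired per-participant template arrays (participants x
    epochs).  Returns the group difference curve with a two-sided
    percentile bootstrap CI and p-value per epoch.
    """
    a = np.asarray(templates_congruent, dtype=float)
    b = np.asarray(templates_incongruent, dtype=float)
    if a.shape != b.shape:
        raise ValueError("congruent/incongruent templates must be paired "
                         f"(got {a.shape} vs {b.shape})")
    return cstats.percentile_bootstrap(a - b, n_boot=n_boot, seed=seed)
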