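"""Synthetic cued motion-discrimination experiments with known ground truth.

Generates every ingredient of a session of the cued visual-motion
discrimination task: the balanced three-condition design (acoustic
motion cue, visual symbolic precue, visual symbolic postcue; 66%-valid
cues), the random-dot stimuli whose motion coherence is redrawn every
12 frames around the observer's threshold, choices from a logistic
observer that weights the momentary motion evidence, the cue, and the
trial's prestimulus alpha state, and multichannel EEG epochs containing
a spatially mixed direction-discriminative component whose amplitude is
boosted on cue-congruent trials, on top of 1/f background noise and a
trial-varying prestimulus alpha oscillation.

Every generator is deterministic under a fixed seed, so downstream
analyses (reverse correlation, sliding-window LDA, prestimulus
time-frequency GLMs) can be tested as recovery problems against the
planted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (CONDITIONS, EpochArray, N_EPOCHS, coherence_columns)

__all__ = [
    "DesignSpec", "ObserverParams", "EEGSimParams", "DotMovie",
    "generate_design", "draw_coherence_profile", "render_dot_movie",
    "simulate_choices", "simulate_eeg", "simulate_session",
    "simulate_participants", "sensor_layout",
]

MINIBLOCK = 78  # trials per mini-block of a single condition


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Session design: conditions x directions x trials, cue validity."""

    conditions: tuple = CONDITIONS
    trials_per_cell: int = 156
    cue_validity: float = 0.66
    threshold: float = 18.2      # mean motion coherence (%), observer threshold
    coherence_sd: float = 10.0   # SD of the per-epoch coherence draw (%)
    n_epochs: int = N_EPOCHS

    def __post_init__(self):
        if not (isinstance(self.trials_per_cell, (int, np.integer))
                and self.trials_per_cell > 0):
            raise ValueError("trials_per_cell must be a positive integer")
        if not 0 <= self.cue_validity <= 1:
            raise ValueError("cue_validity must lie in [0, 1]")
        if self.coherence_sd < 0:
            raise ValueError("coherence_sd must be non-negative")
        if not 0 <= self.threshold <= 100:
            raise ValueError("threshold must lie in [0, 100] %")


def generate_design(spec: DesignSpec = DesignSpec(), seed=None) -> pd.DataFrame:
    """Generate a balanced trial table for one session.

    Per condition x direction cell, ``round(validity * trials_per_cell)``
    trials carry a congruent cue (with the default 156 trials and 66%
    validity: 103 congruent, 66.0%).  Trials are ordered in mini-blocks
    of 78 trials of a single condition, with conditions appearing in
    pseudorandom order within each experimental block, as in the task.
    Per-trial coherence profiles (8 epochs of 12 frames each) are drawn
    from a clipped normal around the observer threshold.
    """
    rng = np.random.default_rng(seed)
    n_cong = int(round(spec.cue_validity * spec.trials_per_cell))
    rows = []
    for cond in spec.conditions:
        cond_rows = []
        for direction in (-1, 1):
            for i in range(spec.trials_per_cell):
                congruent = i < n_cong
                cond_rows.append({"condition": cond, "direction": direction,
                                  "cue": direction if congruent else -direction,
                                  "congruent": congruent})
        order = rng.permutation(len(cond_rows))
        rows.append([cond_rows[i] for i in order])

    # split each condition into mini-blocks, then interleave conditions
    # in random order within each experimental block
    n_trials_cond = 2 * spec.trials_per_cell
    if n_trials_cond % MINIBLOCK == 0:
        n_mini = n_trials_cond // MINIBLOCK
        blocks = []
        for b in range(n_mini):
            for ci in rng.permutation(len(spec.conditions)):
                blocks.append(rows[ci][b * MINIBLOCK:(b + 1) * MINIBLOCK])
        ordered = [t for blk in blocks for t in blk]
    else:  # non-standard cell counts: simple condition interleave
        ordered = [t for cond_rows in rows for t in cond_rows]

    table = pd.DataFrame(ordered)
    table.insert(0, "trial", np.arange(len(table)))
    table["choice"] = np.nan
    table["correct"] = np.nan
    table["rt"] = np.nan
    coh = np.stack([draw_coherence_profile(spec.threshold, spec.coherence_sd,
                                           rng, n_epochs=spec.n_epochs)
                    for _ in range(len(table))])
    for j, col in enumerate(coherence_columns(spec.n_epochs)):
        table[col] = coh[:, j]
    return table


def draw_coherence_profile(threshold: float, sd: float = 10.0, seed=None,
                           n_epochs: int = N_EPOCHS) -> np.ndarray:
    """Per-epoch motion coherence (%): normal draws clipped to [0, 100].

    One independent draw per 12-frame epoch, centred on the observer's
    discrimination threshold.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must lie in [0, 100] %")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return np.clip(rng.normal(threshold, sd, size=n_epochs), 0.0, 100.0)


# ---------------------------------------------------------------------------
# random-dot stimulus
# ---------------------------------------------------------------------------

@dataclass
class DotMovie:
    """A limited-lifetime random-dot motion stimulus.

    ``positions`` holds per-frame dot coordinates in degrees of visual
    angle (aperture diameter 10 deg, central 0.8 deg devoid of dots);
    ``ages`` the per-frame dot ages in frames. Coherently moving dots
    displace by ``speed / frame_rate`` degrees per frame along the
    signed horizontal direction.
    """

    positions: np.ndarray          # (n_frames, n_dots, 2)
    ages: np.ndarray               # (n_frames, n_dots)
    coherent: np.ndarray           # (n_frames, n_dots) bool, True = signal dot
    direction: int                 # +1 right, -1 left
    coherence: np.ndarray          # per-epoch coherence (%)
    frame_rate: float = 120.0
    speed: float = 4.0             # deg/s
    lifetime: int = 9              # frames
    aperture_radius: float = 5.0
    inner_radius: float = 0.4
    frames_per_epoch: int = 12

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dots(self) -> int:
        return self.positions.shape[1]


def _random_positions(rng, n, r_out, r_in):
    """Uniform positions in the annular aperture."""
    r = np.sqrt(rng.uniform(r_in**2, r_out**2, size=n))
    phi = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def render_dot_movie(coherence: np.ndarray, direction: int, seed=None,
                     n_dots: int = 1300, n_frames: int = 96,
                     frame_rate: float = 120.0, speed: float = 4.0,
                     lifetime: int = 9, aperture_radius: float = 5.0,
                     inner_radius: float = 0.4,
                     frames_per_epoch: int = 12) -> DotMovie:
    """Render a limited-lifetime random-dot movie for one trial.

    Per frame, a fraction ``coherence(epoch)/100`` of the dots is moved
    coherently in the signed direction at ``speed`` deg/s; the remaining
    noise dots are reborn at random positions.  Dots that reach their
    lifetime or exit the aperture are redrawn at random positions with
    age reset.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    coherence = np.asarray(coherence, dtype=float)
    if np.any((coherence < 0) | (coherence > 100)):
        raise ValueError("coherence values must lie in [0, 100] %")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dx = direction * speed / frame_rate

    pos = np.empty((n_frames, n_dots, 2))
    ages = np.empty((n_frames, n_dots), dtype=int)
    coh_mask = np.zeros((n_frames, n_dots), dtype=bool)

    pos[0] = _random_positions(rng, n_dots, aperture_radius, inner_radius)
    ages[0] = rng.integers(0, lifetime, size=n_dots)  # staggered births

    for f in range(1, n_frames):
        epoch = min((f // frames_per_epoch), len(coherence) - 1)
        frac = coherence[epoch] / 100.0
        n_coh = int(round(frac * n_dots))
        signal = np.zeros(n_dots, dtype=bool)
        signal[rng.choice(n_dots, size=n_coh, replace=False)] = True
        coh_mask[f] = signal

        p = pos[f - 1].copy()
        a = ages[f - 1] + 1
        p[signal, 0] += dx
        # noise dots are reborn at random positions
        n_noise = int(np.sum(~signal))
        p[~signal] = _random_positions(rng, n_noise, aperture_radius, inner_radius)
        a[~signal] = 0
        # expire old dots and dots that left the aperture / entered the hole
        r = np.hypot(p[:, 0], p[:, 1])
        dead = (a >= lifetime) | (r > aperture_radius) | (r < inner_radius)
        n_dead = int(np.sum(dead))
        if n_dead:
            p[dead] = _random_positions(rng, n_dead, aperture_radius, inner_radius)
            a[dead] = 0
        pos[f] = p
        ages[f] = a

    return DotMovie(positions=pos, ages=ages, coherent=coh_mask,
                    direction=direction, coherence=coherence,
                    frame_rate=frame_rate, speed=speed, lifetime=lifetime,
                    aperture_radius=aperture_radius, inner_radius=inner_radius,
                    frames_per_epoch=frames_per_epoch)


# ---------------------------------------------------------------------------
# observer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverParams:
    """Logistic observer weighting motion evidence, cue, and alpha state.

    P(choice = right) = lapse/2 + (1 - lapse) *
        sigmoid(beta_motion * (kernel . evidence) + beta_cue * cue
                + beta_alpha_motion * alpha * (kernel . evidence)
                + beta_alpha_cue * alpha * cue)

    with per-epoch signed evidence ``direction * coherence / 100`` and
    ``alpha`` the trial's z-scored log alpha power.  ``temporal_kernel``
    weights the 8 coherence epochs (default: uniform averaging).
    """

    beta_motion: float = 5.0
    beta_cue: float = 0.4
    beta_alpha_motion: float = 0.25
    beta_alpha_cue: float = -0.25
    lapse: float = 0.02
    temporal_kernel: tuple = tuple(np.full(N_EPOCHS, 1.0 / N_EPOCHS))

    def __post_init__(self):
        if not 0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")


def trial_evidence(table: pd.DataFrame, kernel=None) -> np.ndarray:
    """Kernel-weighted signed motion evidence per trial (rightward +)."""
    cols = [c for c in table.columns if c.startswith("coh_e")]
    coh = table[cols].to_numpy(dtype=float) / 100.0
    if kernel is None:
        kernel = np.full(coh.shape[1], 1.0 / coh.shape[1])
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape[0] != coh.shape[1]:
        raise ValueError(f"kernel length {kernel.shape[0]} does not match "
                         f"{coh.shape[1]} coherence epochs")
    return table["direction"].to_numpy(dtype=float) * (coh @ kernel)


def simulate_choices(table: pd.DataFrame, obs: ObserverParams = ObserverParams(),
                     alpha_state=None, seed=None) -> pd.DataFrame:
    """Draw observer choices for every trial of ``table``.

    ``alpha_state`` is the per-trial z-scored (log) alpha power entering
    the interaction terms; if None, zeros (no prestimulus influence).
    Returns a copy of the table with ``choice``/``correct``/``rt``
    filled in.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    table = table.copy()
    ev = trial_evidence(table, np.asarray(obs.temporal_kernel))
    cue = table["cue"].to_numpy(dtype=float)
    alpha = np.zeros(len(table)) if alpha_state is None else np.asarray(alpha_state, dtype=float)
    if alpha.shape[0] != len(table):
        raise ValueError("alpha_state length does not match trial count")
    lin = (obs.beta_motion * ev + obs.beta_cue * cue
           + obs.beta_alpha_motion * alpha * ev
           + obs.beta_alpha_cue * alpha * cue)
    p_right = obs.lapse / 2 + (1 - obs.lapse) / (1 + np.exp(-lin))
    choice = np.where(rng.uniform(size=len(table)) < p_right, 1, -1)
    table["choice"] = choice
    table["correct"] = (choice == table["direction"]).astype(int)
    table["rt"] = rng.lognormal(mean=np.log(0.5), sigma=0.25, size=len(table))
    return table


def choice_probability_right(evidence, cue, alpha, obs: ObserverParams):
    """Closed-form P(choice = right) of the logistic observer."""
    lin = (obs.beta_motion * np.asarray(evidence)
           + obs.beta_cue * np.asarray(cue)
           + obs.beta_alpha_motion * np.asarray(alpha) * np.asarray(evidence)
           + obs.beta_alpha_cue * np.asarray(alpha) * np.asarray(cue))
    return obs.lapse / 2 + (1 - obs.lapse) / (1 + np.exp(-lin))


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EEGSimParams:
    """Parameters of the synthetic EEG epochs (amplitudes in microvolt).

    The direction-discriminative component is a Gaussian-windowed bump
    at ``signal_latency`` whose signed amplitude follows the motion
    direction, multiplied by ``congruency_gain`` on cue-congruent
    trials, and spatially mixed through a smooth occipital-like
    topography.  Background activity is 1/f noise plus a prestimulus
    alpha oscillation with log-normal trial-to-trial power that
    desynchronises after stimulus onset.
    """

    n_channels: int = 128
    fs: float = 150.0
    tmin: float = -0.5
    tmax: float = 1.0
    signal_latency: float = 0.32
    signal_width: float = 0.05      # s, Gaussian SD of the evoked bump
    signal_gain: float = 4.0        # uV, per-direction amplitude
    congruency_gain: float = 1.3    # multiplicative boost on congruent trials
    alpha_freq: float = 8.0         # Hz
    alpha_log_mu: float = float(np.log(8.0))   # log-normal amplitude params
    alpha_log_sd: float = 0.4
    noise_scale: float = 10.0       # uV RMS of the 1/f background
    noise_exponent: float = 1.0     # 1/f slope
    eog_artifact_rate: float = 0.0  # probability of a blink-like trial
    n_eog: int = 2

    def __post_init__(self):
        if not self.tmin <= self.signal_latency <= self.tmax:
            raise ValueError("signal_latency must lie within the epoch window")
        if self.congruency_gain < 0:
            raise ValueError("congruency_gain must be non-negative")
        if self.fs <= 2 * self.alpha_freq:
            raise ValueError("fs must exceed twice the alpha frequency")


def sensor_layout(n_channels: int, n_eog: int = 2):
    """Deterministic 2-D sensor coordinates: sunflower layout on a disk.

    EOG channels are placed outside the scalp disk, near the front.
    """
    k = np.arange(n_channels) + 0.5
    r = np.sqrt(k / n_channels)
    theta = k * (np.pi * (3 - np.sqrt(5)))
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    eog = np.column_stack([np.linspace(-0.4, 0.4, max(n_eog, 1))[:n_eog],
                           np.full(n_eog, 1.25)])
    names = [f"ch{i + 1:03d}" for i in range(n_channels)] + \
            [f"EOG{i + 1}" for i in range(n_eog)]
    return np.vstack([pos, eog]), names


def _smooth_topography(pos, centre, spread=0.45):
    d = np.linalg.norm(pos - np.asarray(centre), axis=1)
    topo = np.exp(-(d / spread) ** 2)
    return topo / np.linalg.norm(topo)


def _one_over_f_noise(rng, shape, n_times, fs, exponent, scale):
    """1/f^exponent noise, unit-free RMS `scale`, along the last axis."""
    freqs = np.fft.rfftfreq(n_times, d=1 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2)
    spec = (rng.standard_normal(shape + (len(freqs),))
            + 1j * rng.standard_normal(shape + (len(freqs),))) * gain
    x = np.fft.irfft(spec, n=n_times, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return scale * x / np.maximum(rms, np.finfo(float).tiny)


def simulate_eeg(table: pd.DataFrame, params: EEGSimParams = EEGSimParams(),
                 seed=None):
    """Simulate epoched EEG for every trial of ``table``.

    Returns
    -------
    epochs : EpochArray
        trials x (EEG + EOG) channels x time, in microvolt.
    alpha_state : ndarray
        Ground-truth z-scored log alpha power per trial (the quantity
        the observer model consumes).
    info : dict
        Planted ground truth: signal/alpha topographies, artifact trial
        indices, raw alpha amplitudes.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = params
    n_trials = len(table)
    n_times = int(round((p.tmax - p.tmin) * p.fs))
    times = np.arange(n_times) / p.fs + p.tmin
    pos, names = sensor_layout(p.n_channels, p.n_eog)
    n_total = p.n_channels + p.n_eog

    signal_topo = _smooth_topography(pos[:p.n_channels], (0.1, -0.75))
    alpha_topo = _smooth_topography(pos[:p.n_channels], (-0.15, -0.55), spread=0.6)

    data = _one_over_f_noise(rng, (n_trials, n_total), n_times, p.fs,
                             p.noise_exponent, p.noise_scale)

    # prestimulus alpha with trial-varying log-normal power, desynchronising
    # after stimulus onset
    alpha_amp = np.exp(rng.normal(p.alpha_log_mu, p.alpha_log_sd, size=n_trials))
    phase = rng.uniform(0, 2 * np.pi, size=n_trials)
    envelope = np.where(times < 0, 1.0, np.exp(-times / 0.15))
    osc = np.sin(2 * np.pi * p.alpha_freq * times[None, :] + phase[:, None])
    alpha_sig = alpha_amp[:, None] * envelope[None, :] * osc       # (trials, time)
    data[:, :p.n_channels, :] += alpha_topo[None, :, None] * alpha_sig[:, None, :]

    # direction-discriminative evoked component, boosted on congruent trials
    bump = np.exp(-0.5 * ((times - p.signal_latency) / p.signal_width) ** 2)
    amp = (table["direction"].to_numpy(dtype=float) * p.signal_gain
           * np.where(table["congruent"].to_numpy(dtype=bool), p.congruency_gain, 1.0))
    data[:, :p.n_channels, :] += (amp[:, None, None] * signal_topo[None, :, None]
                                  * bump[None, None, :])

    # blink-like EOG artifacts on a random subset of trials
    artifact_trials = np.array([], dtype=int)
    if p.eog_artifact_rate > 0 and p.n_eog > 0:
        artifact_trials = np.flatnonzero(rng.uniform(size=n_trials)
                                         < p.eog_artifact_rate)
        for t in artifact_trials:
            t0 = rng.uniform(p.tmin + 0.1, p.tmax - 0.1)
            blink = 300.0 * np.exp(-0.5 * ((times - t0) / 0.08) ** 2)
            data[t, p.n_channels:, :] += blink[None, :]
            # volume conduction to frontal EEG channels
            frontal = pos[:p.n_channels, 1] > 0.5
            data[t, :p.n_channels, :][frontal] += 0.3 * blink[None, :]

    log_power = 2 * np.log(alpha_amp)
    alpha_state = (log_power - log_power.mean()) / log_power.std()
    epochs = EpochArray(data, times, p.fs, names, pos)
    info = {"signal_topography": signal_topo, "alpha_topography": alpha_topo,
            "artifact_trials": artifact_trials, "alpha_amplitude": alpha_amp}
    return epochs, alpha_state, info


# ---------------------------------------------------------------------------
# whole sessions / cohorts
# ---------------------------------------------------------------------------

def simulate_session(spec: DesignSpec = DesignSpec(),
                     obs: ObserverParams = ObserverParams(),
                     eeg: EEGSimParams | None = EEGSimParams(),
                     seed=None):
    """Simulate one participant's full session.

    The EEG is generated first so its ground-truth alpha state can
    drive the observer's choices, closing the loop between prestimulus
    power and behaviour.

    Returns ``(table, epochs, alpha_state, info)``; ``epochs`` and
    ``info`` are None when ``eeg`` is None (behaviour-only simulation).
    """
    rng = np.random.default_rng(seed)
    table = generate_design(spec, rng)
    if eeg is None:
        table = simulate_choices(table, obs, None, rng)
        return table, None, None, None
    epochs, alpha_state, info = simulate_eeg(table, eeg, rng)
    table = simulate_choices(table, obs, alpha_state, rng)
    return table, epochs, alpha_state, info


def simulate_participants(n_participants: int = 20,
                          spec: DesignSpec = DesignSpec(),
                          obs: ObserverParams = ObserverParams(),
                          eeg: EEGSimParams | None = EEGSimParams(),
                          seed=None, threshold_sd: float = 1.9):
    """Yield per-participant sessions with individual thresholds.

    Thresholds vary across participants as a normal around the group
    mean with SD ``threshold_sd`` (percentage points of coherence).
    """
    rng = np.random.default_rng(seed)
    for _ in range(n_participants):
        thr = float(np.clip(rng.normal(spec.threshold, threshold_sd), 1, 99))
        p_spec = replace(spec, threshold=thr)
        yield simulate_session(p_spec, obs, eeg,
                               rng.integers(0, 2**31 - 1))
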