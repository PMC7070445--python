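"""Shared synthetic constructions for the test suite."""

import numpy as np

import cuedecode as cd
from cuedecode.containers import TFPower
from cuedecode.synthetic import DesignSpec, ObserverParams, simulate_choices


def cohort_with_alpha_behaviour(n_subj=10, n_trials=240, beta_alpha_cue=-0.8,
                                beta_alpha_motion=0.0, seed=0, nf=8, nt=6):
    """Trial tables plus synthetic TF power whose alpha bins carry the
    trial's true alpha state (a controlled stand-in for the measured
    component power)."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(4, 4 + 2 * nf, 2.0)   # includes 8 Hz
    times = np.linspace(-0.4, -0.05, nt)
    alpha_rows = np.abs(freqs - 8) <= 1
    tables, tfs = [], []
    for _ in range(n_subj):
        spec = DesignSpec(trials_per_cell=max(n_trials // 6, 10))
        table = cd.generate_design(spec, seed=rng.integers(2**31 - 1))
        alpha = rng.standard_normal(len(table))
        obs = ObserverParams(beta_alpha_cue=beta_alpha_cue,
                             beta_alpha_motion=beta_alpha_motion)
        table = simulate_choices(table, obs, alpha,
                                 seed=rng.integers(2**31 - 1))
        power = rng.standard_normal((len(table), nf, nt))
        power[:, alpha_rows, :] += 0.8 * alpha[:, None, None]
        power = (power - power.mean(0)) / power.std(0)
        tables.append(table)
        tfs.append(TFPower(power, freqs, times))
    return tables, tfs, alpha_rows
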