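"""Group-level inference shared by all analysis stages.

Implements the study's statistical toolbox: one-sample sign-flip
cluster-mass permutation tests on 1-D (time) and 2-D (time-frequency)
grids, the participant-level percentile bootstrap, Benjamini-Hochberg
FDR adjustment, and the reported effect sizes (paired Cohen's d,
partial eta squared from a fully within-subject two-way ANOVA).

Conventions
-----------
* Cluster tests are one-sample tests across participants: the input is
  an array of shape ``(n_participants, *grid)`` where grid is 1-D or
  2-D.  Under the null hypothesis of zero mean, each participant's map
  may have its sign flipped, which generates the permutation
  distribution of the maximal absolute cluster mass (max-statistic
  correction, two-sided at the requested level).
* Permutation and bootstrap p-values use the +1 correction so that
  p = 0 is impossible; the smallest attainable value is
  ``1 / (n_perm + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps

__all__ = [
    "Cluster",
    "ClusterResult",
    "cluster_permutation",
    "percentile_bootstrap",
    "BootstrapResult",
    "bh_fdr",
    "cohens_d",
    "partial_eta_squared",
    "two_way_rm_anova",
]


# ---------------------------------------------------------------------------
# cluster-mass permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    """A contiguous supra-threshold set of grid bins."""

    bins: np.ndarray          # (k, ndim) integer bin coordinates
    mass: float               # summed t-values (signed)
    p_value: float            # two-sided permutation p
    sign: int                 # +1 / -1

    @property
    def extent(self) -> int:
        return len(self.bins)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    t_threshold: float
    n_perm: int
    alpha1: float = 0.05
    min_size: int = 3
    null_max_mass: np.ndarray = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def mask(self, alpha: float = 0.05) -> np.ndarray:
        """Boolean grid marking bins inside significant clusters."""
        m = np.zeros(self.t_map.shape, dtype=bool)
        for c in self.significant(alpha):
            m[tuple(c.bins.T)] = True
        return m


def _t_maps(flips: np.ndarray, data2d: np.ndarray, sumsq: np.ndarray) -> np.ndarray:
    """One-sample t-maps for many sign-flip patterns at once.

    ``x**2`` is invariant to sign flips, so only the mean changes per
    permutation; the second moment is shared.
    """
    n = data2d.shape[0]
    means = flips @ data2d / n
    var = (sumsq / n - means**2) * (n / (n - 1))
    var = np.maximum(var, np.finfo(float).tiny)
    return means / np.sqrt(var / n)


def _label_clusters(supra: np.ndarray, structure: np.ndarray):
    labels, n_lab = ndimage.label(supra, structure=structure)
    return labels, n_lab


def _max_abs_mass(t_map: np.ndarray, thresh: float, min_size: int,
                  structure: np.ndarray) -> float:
    best = 0.0
    for sign in (1, -1):
        supra = sign * t_map > thresh
        labels, n_lab = _label_clusters(supra, structure)
        if n_lab == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(t_map), labels,
                                   index=np.arange(1, n_lab + 1))
        masses = ndimage.sum_labels(np.abs(t_map), labels,
                                    index=np.arange(1, n_lab + 1))
        masses = masses[sizes >= min_size]
        if masses.size:
            best = max(best, float(masses.max()))
    return best


def cluster_permutation(data: np.ndarray, n_perm: int = 2000,
                        alpha1: float = 0.05, min_size: int = 3,
                        seed=None, alpha: float = 0.05) -> ClusterResult:
    """Sign-flip cluster-mass permutation test across participants.

    Parameters
    ----------
    data : ndarray, shape (n_participants, n_bins) or (n_participants, n_f, n_t)
        Per-participant effect maps (e.g. regression betas, evidence
        differences).  The test is one-sample against zero.
    n_perm : int
        Number of random sign-flip permutations.  If all ``2**n``
        distinct flips are fewer than ``n_perm``, exact enumeration is
        used instead.
    alpha1 : float
        Two-sided first-level (bin-wise) threshold on the t statistic.
    min_size : int
        Minimal cluster extent in bins; smaller supra-threshold islets
        are discarded.
    seed : int, Generator or None
        Randomness for the sign flips.
    alpha : float
        Cluster-level two-sided significance level used by
        :meth:`ClusterResult.significant`.

    Notes
    -----
    Adjacency is consecutive bins in 1-D and 4-connectivity in 2-D.
    The null distribution collects, per permutation, the single maximal
    absolute cluster mass over both signs, which controls the
    family-wise error rate of the two-sided test.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim not in (2, 3):
        raise ValueError("data must be (participants, bins) or (participants, f, t)")
    n = data.shape[0]
    if n < 6:
        raise ValueError(f"need at least 6 participants, got {n}")
    grid_shape = data.shape[1:]
    ndim = len(grid_shape)
    # 1-D: consecutive neighbours; 2-D: 4-connectivity (no diagonals)
    structure = np.ones(3) if ndim == 1 else ndimage.generate_binary_structure(2, 1)

    t_thresh = float(sps.t.ppf(1 - alpha1 / 2, df=n - 1))
    data2d = data.reshape(n, -1)
    sumsq = (data2d**2).sum(axis=0)

    t_obs = _t_maps(np.ones((1, n)), data2d, sumsq)[0].reshape(grid_shape)

    # observed clusters, both signs
    observed: list[tuple[np.ndarray, float, int]] = []
    for sign in (1, -1):
        supra = sign * t_obs > t_thresh
        labels, n_lab = _label_clusters(supra, structure)
        for lab in range(1, n_lab + 1):
            bins = np.argwhere(labels == lab)
            if len(bins) < min_size:
                continue
            mass = float(t_obs[tuple(bins.T)].sum())
            observed.append((bins, mass, sign))

    # permutation null of the maximal |mass|
    if 2**n <= n_perm:
        flips = np.array([[1 if (i >> b) & 1 else -1 for b in range(n)]
                          for i in range(2**n)], dtype=float)
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = _t_maps(flips, data2d, sumsq)
    null_max = np.empty(len(flips))
    for i, row in enumerate(t_null):
        null_max[i] = _max_abs_mass(row.reshape(grid_shape), t_thresh,
                                    min_size, structure)

    n_eff = len(flips)
    clusters = []
    for bins, mass, sign in observed:
        p = (1 + np.sum(null_max >= abs(mass))) / (n_eff + 1)
        clusters.append(Cluster(bins=bins, mass=mass, p_value=float(p), sign=sign))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(clusters=clusters, t_map=t_obs, t_threshold=t_thresh,
                         n_perm=n_eff, alpha1=alpha1, min_size=min_size,
                         null_max_mass=null_max)


# ---------------------------------------------------------------------------
# percentile bootstrap across participants
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    estimate: np.ndarray      # statistic on the original sample
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: np.ndarray       # two-sided, against zero
    distribution: np.ndarray = field(repr=False, default=None)


def percentile_bootstrap(values: np.ndarray, statistic=None, n_boot: int = 2000,
                         ci: float = 0.95, seed=None) -> BootstrapResult:
    """Percentile bootstrap over participants (resampled with replacement).

    ``values`` has participants along axis 0; any trailing shape is
    carried through.  ``statistic`` maps a resampled (n, ...) array to
    the group statistic (default: mean over axis 0).  The two-sided p
    is ``2 * min(P(stat <= 0), P(stat >= 0))`` over the bootstrap
    distribution, floored at ``1/(n_boot+1)``.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 participants, got {n}")
    if statistic is None:
        statistic = lambda v: np.mean(v, axis=0)
    rng = np.random.default_rng(seed)
    est = np.asarray(statistic(values), dtype=float)
    dist = np.empty((n_boot,) + est.shape)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        dist[b] = statistic(values[idx])
    lo = np.percentile(dist, 100 * (1 - ci) / 2, axis=0)
    hi = np.percentile(dist, 100 * (1 + ci) / 2, axis=0)
    p_lo = (1 + np.sum(dist <= 0, axis=0)) / (n_boot + 1)
    p_hi = (1 + np.sum(dist >= 0, axis=0)) / (n_boot + 1)
    p = np.minimum(1.0, 2 * np.minimum(p_lo, p_hi))
    return BootstrapResult(estimate=est, ci_low=np.asarray(lo),
                           ci_high=np.asarray(hi), p_value=np.asarray(p),
                           distribution=dist)


# ---------------------------------------------------------------------------
# multiple comparisons and effect sizes
# ---------------------------------------------------------------------------

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Equivalent to ``min_{k >= i} (m * p_(k) / k)`` on the sorted values,
    with monotonicity enforced and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    shape = p.shape
    p = p.ravel()
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out.reshape(shape)


def cohens_d(x, y=None) -> float:
    """Paired Cohen's d: mean(diff) / SD(diff) (SD with ddof=1)."""
    x = np.asarray(x, dtype=float)
    diff = x if y is None else x - np.asarray(y, dtype=float)
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
    return float(diff.mean() / sd)


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """eta_p^2 = SS_effect / (SS_effect + SS_error)."""
    denom = ss_effect + ss_error
    return 0.0 if denom == 0 else float(ss_effect / denom)


def two_way_rm_anova(cells: np.ndarray):
    """Fully within-subject two-way ANOVA from a cell-mean array.

    Parameters
    ----------
    cells : ndarray, shape (n_subjects, a, b)
        Per-subject cell means for factor A (a levels) and B (b levels).

    Returns
    -------
    dict mapping effect name ('A', 'B', 'AxB') to
    ``{'F', 'df1', 'df2', 'p', 'eta_p2', 'ss_effect', 'ss_error'}``.

    Each effect is tested against its own subject-by-effect interaction
    error term, the standard univariate repeated-measures partition.
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 3:
        raise ValueError("cells must be (subjects, a_levels, b_levels)")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = y.mean()
    m_a = y.mean(axis=(0, 2))            # (a,)
    m_b = y.mean(axis=(0, 1))            # (b,)
    m_s = y.mean(axis=(1, 2))            # (n,)
    m_ab = y.mean(axis=0)                # (a, b)
    m_as = y.mean(axis=2)                # (n, a)
    m_bs = y.mean(axis=1)                # (n, b)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    ss_abs = np.sum((y - m_as[:, :, None] - m_bs[:, None, :]
                     - m_ab[None, :, :] + m_a[None, :, None]
                     + m_b[None, None, :] + m_s[:, None, None] - grand) ** 2)

    out = {}
    for name, ss_eff, df1, ss_err, df2 in (
            ("A", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
            ("B", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
            ("AxB", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1))):
        if ss_err <= 0:
            warnings.warn(f"zero error variance for effect {name}")
            F = np.inf if ss_eff > 0 else 0.0
            p = 0.0 if ss_eff > 0 else 1.0
        else:
            F = (ss_eff / df1) / (ss_err / df2)
            p = float(sps.f.sf(F, df1, df2))
        out[name] = {"F": float(F), "df1": df1, "df2": df2, "p": p,
                     "eta_p2": partial_eta_squared(ss_eff, ss_err),
                     "ss_effect": float(ss_eff), "ss_error": float(ss_err)}
    return out
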