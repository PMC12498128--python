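"""Cluster-based permutation t tests with max-|Tsum| family-wise control.

Per bin (electrode, or electrode x frequency) a two-sided t statistic is
computed — unpaired across groups, or paired across conditions.  Bins with
uncorrected p < 0.001 are clustered over an adjacency graph, separately by
t sign; each cluster's statistic is the sum of its member t values (Tsum).
Significance comes from the permutation distribution of the largest |Tsum|
over all clusters under random relabelings (group labels for the unpaired
design; within-subject condition flips for the paired design), with the
add-one convention p = (1 + #{surrogate >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.stats as st

DEFAULT_FORMING_P = 0.001
DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 1000


@dataclass
class Cluster:
    members: np.ndarray  # bin indices
    tsum: float
    p: float = np.nan

    @property
    def sign(self) -> int:
        return 1 if self.tsum > 0 else -1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    df: float
    threshold_p: float
    n_permutations: int
    design: str
    max_null: np.ndarray | None = None
    excluded_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    exhaustive: bool = False

    def significant(self, alpha: float = DEFAULT_ALPHA) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "df": self.df,
            "threshold_p": self.threshold_p,
            "n_permutations": self.n_permutations,
            "exhaustive": self.exhaustive,
            "clusters": [
                {"members": c.members.tolist(), "tsum": float(c.tsum), "p": float(c.p)}
                for c in self.clusters
            ],
        }


def _unpaired_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Student (pooled-variance) two-sample t per column."""
    n1, n2 = x.shape[0], y.shape[0]
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    v1 = x.var(axis=0, ddof=1)
    v2 = y.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def _paired_t(d: np.ndarray) -> np.ndarray:
    """One-sample t of paired differences per column."""
    n = d.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        return d.mean(axis=0) / np.sqrt(d.var(axis=0, ddof=1) / n)


def bin_t_map(
    values: np.ndarray, design: str, group_labels: np.ndarray | None = None
) -> tuple[np.ndarray, float, np.ndarray]:
    """Per-bin t statistics.

    ``design='unpaired'``: ``values`` is subjects x bins with boolean/binary
    ``group_labels`` (True = first group); pooled-variance two-sample t,
    df = n1 + n2 - 2.  ``design='paired'``: ``values`` is the subjects x bins
    array of condition differences; one-sample t, df = n - 1.

    Returns ``(t, df, excluded)`` where ``excluded`` indexes zero-variance
    bins whose t is undefined (set to 0 and barred from cluster forming).
    """
    v = np.asarray(values, dtype=float)
    if design == "unpaired":
        g = np.asarray(group_labels, dtype=bool)
        if g.sum() < 2 or (~g).sum() < 2:
            raise ValueError("need at least two subjects per group")
        t = _unpaired_t(v[g], v[~g])
        dof = v.shape[0] - 2
    elif design == "paired":
        if v.shape[0] < 2:
            raise ValueError("need at least two subjects")
        t = _paired_t(v)
        dof = v.shape[0] - 1
    else:
        raise ValueError(f"unknown design {design!r}")
    excluded = np.flatnonzero(~np.isfinite(t))
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    return t, float(dof), excluded


def form_clusters(
    t_map: np.ndarray,
    df: float,
    graph: sp.spmatrix,
    threshold_p: float = DEFAULT_FORMING_P,
    excluded: np.ndarray | None = None,
) -> list[Cluster]:
    """Connected components of supra-threshold bins, split by t sign.

    The forming threshold is the two-sided t critical value at
    ``threshold_p`` for ``df`` degrees of freedom.
    """
    t = np.asarray(t_map, dtype=float)
    if graph.shape[0] != t.size:
        raise ValueError("adjacency graph does not cover all bins")
    t_crit = st.t.isf(threshold_p / 2, df)
    supra = np.abs(t) > t_crit
    if excluded is not None and excluded.size:
        supra[excluded] = False
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = supra & ((t > 0) if sign > 0 else (t < 0))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = graph[np.ix_(idx, idx)]
        n_comp, labels = csgraph.connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            clusters.append(Cluster(members=members, tsum=float(t[members].sum())))
    clusters.sort(key=lambda c: -abs(c.tsum))
    return clusters


def _max_abs_tsum(
    t: np.ndarray, df: float, graph: sp.spmatrix, threshold_p: float,
    excluded: np.ndarray | None,
) -> float:
    cl = form_clusters(t, df, graph, threshold_p, excluded)
    return max((abs(c.tsum) for c in cl), default=0.0)


def permutation_p(
    values: np.ndarray,
    design: str,
    graph: sp.spmatrix,
    group_labels: np.ndarray | None = None,
    threshold_p: float = DEFAULT_FORMING_P,
    n_permutations: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Cluster permutation test.

    For the unpaired design ``values`` is subjects x bins and group labels
    are shuffled across subjects; for the paired design ``values`` is the
    subjects x bins condition-difference array and each subject's difference
    sign is flipped at random.  When the permutation space is no larger than
    ``n_permutations`` all distinct relabelings are enumerated exactly.
    """
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    t_obs, df, excluded = bin_t_map(v, design, group_labels)
    clusters = form_clusters(t_obs, df, graph, threshold_p, excluded)

    exhaustive = False
    max_null = []
    if design == "unpaired":
        g = np.asarray(group_labels, dtype=bool)
        n, n1 = g.size, int(g.sum())
        from math import comb

        if comb(n, n1) <= n_permutations:
            exhaustive = True
            for chosen in combinations(range(n), n1):
                gp = np.zeros(n, dtype=bool)
                gp[list(chosen)] = True
                t, _, exc = bin_t_map(v, design, gp)
                max_null.append(_max_abs_tsum(t, df, graph, threshold_p, exc))
        else:
            for _ in range(n_permutations):
                gp = np.zeros(n, dtype=bool)
                gp[rng.choice(n, n1, replace=False)] = True
                t, _, exc = bin_t_map(v, design, gp)
                max_null.append(_max_abs_tsum(t, df, graph, threshold_p, exc))
    else:
        n = v.shape[0]
        if 2**n <= n_permutations:
            exhaustive = True
            for code in range(2**n):
                signs = np.where((code >> np.arange(n)) & 1, -1.0, 1.0)
                t, _, exc = bin_t_map(v * signs[:, None], design)
                max_null.append(_max_abs_tsum(t, df, graph, threshold_p, exc))
        else:
            for _ in range(n_permutations):
                signs = rng.choice([-1.0, 1.0], size=n)
                t, _, exc = bin_t_map(v * signs[:, None], design)
                max_null.append(_max_abs_tsum(t, df, graph, threshold_p, exc))

    max_null = np.asarray(max_null)
    n_eff = max_null.size
    for c in clusters:
        if exhaustive:
            c.p = float((max_null >= abs(c.tsum)).sum() / n_eff)
        else:
            c.p = float((1 + (max_null >= abs(c.tsum)).sum()) / (1 + n_eff))

    return ClusterResult(
        clusters=clusters,
        t_map=t_obs,
        df=df,
        threshold_p=threshold_p,
        n_permutations=n_eff,
        design=design,
        max_null=max_null,
        excluded_bins=excluded,
        exhaustive=exhaustive,
    )
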