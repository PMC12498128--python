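"""Monte-Carlo calibration studies for the cluster permutation test.

These drive the family-wise error rate (FWER) and power/localization checks:
null datasets are drawn as spatially smoothed Gaussian noise on the
electrode x frequency grid (smoothing makes neighbouring bins correlated,
the regime cluster tests exist for), with no group effect; power datasets
add a fixed-amplitude patch to one group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .cluster import permutation_p
from .montage import spatio_spectral_adjacency


def _smoothing_operator(graph: sp.spmatrix, neighbor_weight: float = 0.5) -> sp.csr_matrix:
    """Row-normalized (I + w*A) smoothing over the adjacency graph."""
    n = graph.shape[0]
    op = (sp.identity(n, format="csr") + neighbor_weight * graph.astype(float)).tocsr()
    row_sums = np.asarray(op.sum(axis=1)).ravel()
    return sp.diags(1.0 / row_sums) @ op


def smoothed_null_data(
    rng: np.random.Generator,
    n_subjects: int,
    graph: sp.spmatrix,
    neighbor_weight: float = 0.5,
) -> np.ndarray:
    """Subjects x bins Gaussian noise smoothed over the bin adjacency.

    Rescaled per bin to unit variance, so planted effect sizes are in exact
    per-bin SD units while neighbouring bins stay positively correlated.
    """
    op = _smoothing_operator(graph, neighbor_weight)
    raw = rng.standard_normal((n_subjects, graph.shape[0]))
    smoothed = (op @ raw.T).T
    bin_sd = np.sqrt(np.asarray(op.multiply(op).sum(axis=1)).ravel())
    return smoothed / bin_sd


@dataclass
class FwerResult:
    n_runs: int
    n_rejections: int

    @property
    def rate(self) -> float:
        return self.n_rejections / self.n_runs

    def binomial_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Wilson score interval for the rejection probability."""
        from scipy.stats import norm

        z = norm.isf((1 - level) / 2)
        n, p = self.n_runs, self.rate
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        return max(0.0, centre - half), min(1.0, centre + half)


def fwer_null_study(
    n_runs: int = 200,
    n_per_group: int = 20,
    n_freqs: int = 97,
    n_permutations: int = 500,
    alpha: float = 0.05,
    forming_p: float = 0.001,
    seed: int = 0,
) -> FwerResult:
    """Empirical FWER of the unpaired cluster test on null electrode x
    frequency data: the fraction of runs declaring any cluster significant."""
    graph = spatio_spectral_adjacency(n_freqs)
    rejections = 0
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        values = smoothed_null_data(rng, 2 * n_per_group, graph)
        labels = np.arange(2 * n_per_group) < n_per_group
        res = permutation_p(
            values, "unpaired", graph, labels,
            threshold_p=forming_p, n_permutations=n_permutations,
            seed=np.random.default_rng([seed, run, 1]),
        )
        if res.significant(alpha):
            rejections += 1
    return FwerResult(n_runs=n_runs, n_rejections=rejections)


@dataclass
class PowerResult:
    n_runs: int
    n_detected: int
    coverages: list[float]

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_runs


def planted_patch_study(
    n_runs: int = 50,
    n_per_group: int = 30,
    n_freqs: int = 30,
    effect_sd: float = 1.5,
    patch_channels: tuple[int, ...] = (2, 3, 16, 17),  # F3, F4, Fz, Cz
    patch_freqs: tuple[int, int] = (10, 20),
    n_permutations: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerResult:
    """Detection and localization of a planted patch effect.

    One group receives a +effect_sd shift on a channels x frequency-bin
    patch; a run counts as detected when a significant cluster exists, and
    its coverage is the fraction of planted bins inside the best-overlapping
    significant cluster.
    """
    graph = spatio_spectral_adjacency(n_freqs)
    planted = np.array([
        c * n_freqs + f for c in patch_channels for f in range(*patch_freqs)
    ])
    detected, coverages = 0, []
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        values = smoothed_null_data(rng, 2 * n_per_group, graph)
        values[:n_per_group, planted] += effect_sd
        labels = np.arange(2 * n_per_group) < n_per_group
        res = permutation_p(
            values, "unpaired", graph, labels,
            n_permutations=n_permutations,
            seed=np.random.default_rng([seed, run, 1]),
        )
        sig = res.significant(alpha)
        if sig:
            detected += 1
            best = max(
                sig, key=lambda c: np.intersect1d(c.members, planted).size
            )
            coverages.append(
                np.intersect1d(best.members, planted).size / planted.size
            )
        else:
            coverages.append(0.0)
    return PowerResult(n_runs=n_runs, n_detected=detected, coverages=coverages)
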