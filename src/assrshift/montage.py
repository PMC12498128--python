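"""The 19-channel 10-20 montage and its spatial / spatio-spectral adjacency.

Cluster-based permutation tests need an explicit neighbourhood structure over
the scalp.  Rather than recomputing it from electrode coordinates on every
run, the neighbour table below is frozen in source: it is the Delaunay
triangulation of the idealized standard 10-20 positions of the 19 electrodes
(as produced by ``mne.channels.find_ch_adjacency`` on the ``standard_1020``
montage), version-controlled so results are reproducible independent of any
library's montage files.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

#: Electrode order used throughout the package (rows of every channel axis).
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz",
)

#: Frozen scalp neighbour table (symmetric; Delaunay on standard 10-20 positions).
NEIGHBORS: dict[str, tuple[str, ...]] = {
    "Fp1": ("F3", "F7", "Fp2", "Fz"),
    "Fp2": ("F4", "F8", "Fp1", "Fz"),
    "F3": ("C3", "Cz", "F7", "Fp1", "Fz"),
    "F4": ("C4", "Cz", "F8", "Fp2", "Fz"),
    "C3": ("Cz", "F3", "F7", "P3", "P7", "T7"),
    "C4": ("Cz", "F4", "F8", "P4", "P8", "T8"),
    "P3": ("C3", "Cz", "O1", "P7", "Pz"),
    "P4": ("C4", "Cz", "O2", "P8", "Pz"),
    "O1": ("O2", "P3", "P7", "Pz"),
    "O2": ("O1", "P4", "P8", "Pz"),
    "F7": ("C3", "F3", "Fp1", "T7"),
    "F8": ("C4", "F4", "Fp2", "T8"),
    "T7": ("C3", "F7", "P7"),
    "T8": ("C4", "F8", "P8"),
    "P7": ("C3", "O1", "P3", "T7"),
    "P8": ("C4", "O2", "P4", "T8"),
    "Fz": ("Cz", "F3", "F4", "Fp1", "Fp2"),
    "Cz": ("C3", "C4", "F3", "F4", "Fz", "P3", "P4", "Pz"),
    "Pz": ("Cz", "O1", "O2", "P3", "P4"),
}


def channel_index(names: list[str] | tuple[str, ...] | None = None) -> dict[str, int]:
    names = CHANNELS if names is None else tuple(names)
    return {name: i for i, name in enumerate(names)}


def spatial_adjacency(channel_names: list[str] | tuple[str, ...] | None = None) -> sp.csr_matrix:
    """Boolean electrode adjacency matrix (no self-edges) in channel order."""
    names = CHANNELS if channel_names is None else tuple(channel_names)
    unknown = set(names) - set(NEIGHBORS)
    if unknown:
        raise ValueError(f"channels without a frozen neighbour entry: {sorted(unknown)}")
    idx = channel_index(names)
    n = len(names)
    mat = np.zeros((n, n), dtype=bool)
    for ch in names:
        for nb in NEIGHBORS[ch]:
            if nb in idx:
                mat[idx[ch], idx[nb]] = True
    if not np.array_equal(mat, mat.T):
        raise AssertionError("frozen neighbour table is not symmetric")
    return sp.csr_matrix(mat)


def spatio_spectral_adjacency(
    n_freqs: int, channel_names: list[str] | tuple[str, ...] | None = None
) -> sp.csr_matrix:
    """Tensor-product adjacency over (channel, frequency-bin) nodes.

    Two bins are neighbours iff they are spatial neighbours at the same
    frequency, or the same electrode at an adjacent (+-1) frequency bin.
    Diagonal (neighbour electrode AND neighbour frequency) links are excluded.
    Node order is channel-major: node = channel * n_freqs + freq_bin.
    """
    if n_freqs < 1:
        raise ValueError("n_freqs must be positive")
    spatial = spatial_adjacency(channel_names)
    eye_f = sp.identity(n_freqs, dtype=bool, format="csr")
    spectral = sp.diags([True] * (n_freqs - 1), 1, shape=(n_freqs, n_freqs), dtype=bool)
    spectral = (spectral + spectral.T).tocsr()
    eye_c = sp.identity(spatial.shape[0], dtype=bool, format="csr")
    adj = sp.kron(spatial, eye_f, format="csr") + sp.kron(eye_c, spectral, format="csr")
    return adj.astype(bool)


def head_positions_2d(channel_names: list[str] | tuple[str, ...] | None = None) -> np.ndarray:
    """Approximate 2-D scalp layout (unit head circle) for topography plots."""
    # Idealized 10-20 layout on a unit disc; y points to the nose.
    layout = {
        "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
        "F7": (-0.81, 0.59), "F3": (-0.41, 0.52), "Fz": (0.0, 0.50),
        "F4": (0.41, 0.52), "F8": (0.81, 0.59),
        "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
        "C4": (0.50, 0.0), "T8": (1.0, 0.0),
        "P7": (-0.81, -0.59), "P3": (-0.41, -0.52), "Pz": (0.0, -0.50),
        "P4": (0.41, -0.52), "P8": (0.81, -0.59),
        "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
    }
    names = CHANNELS if channel_names is None else tuple(channel_names)
    return np.array([layout[ch] for ch in names], dtype=float)
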