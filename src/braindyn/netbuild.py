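"""Construction of windowed intralayer networks and the coupled multilayer form.

A subject's region x time signal matrix is cut into overlapping sliding
windows; within each window the pairwise Pearson correlation between
regions forms one intralayer adjacency matrix (one *layer* of the temporal
multilayer network).  Layers are coupled ordinally: each node is linked to
itself in the adjacent layers with a uniform weight ``omega``, which in
supra-adjacency form places ``omega * I`` on the first off-diagonal blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SubjectSeries",
    "LayerStack",
    "SupraAdjacency",
    "sliding_windows",
    "trim_initial_samples",
    "windowed_correlation",
    "build_supra",
]

NEGATIVE_POLICIES = ("zero", "abs", "keep")


@dataclass
class SubjectSeries:
    """One subject's region x time signal matrix with group membership.

    Parameters
    ----------
    data : ndarray, shape (n_regions, n_samples)
        Signal matrix; rows are regions, columns are time samples.
    region_ids : sequence of str
        Unique region labels, one per row.
    group : str
        Group label, e.g. ``"control"`` or ``"case"``.
    score : float, optional
        Symptom severity score (cases only in the emulated design).
    subject_id : str, optional
    """

    data: np.ndarray
    region_ids: Sequence[str]
    group: str
    score: float | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x samples)")
        if np.isnan(self.data).any():
            raise ValueError("data contains missing values")
        ids = list(self.region_ids)
        if len(ids) != self.data.shape[0]:
            raise ValueError("region_ids length must match number of rows")
        if len(set(ids)) != len(ids):
            raise ValueError("region_ids must be unique")
        self.region_ids = ids

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class LayerStack:
    """Ordered stack of per-window N x N intralayer adjacency matrices.

    Every layer is symmetric with zero diagonal; after negative-weight
    handling with the default policy all entries lie in [0, 1].
    """

    layers: list[np.ndarray]
    window_starts: list[int]
    window_length_samples: int
    step_samples: int
    region_ids: list[str] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_nodes(self) -> int:
        return self.layers[0].shape[0]

    def layer_strengths(self) -> np.ndarray:
        """Intralayer node strengths k_il, shape (n_nodes, n_layers)."""
        return np.stack([A.sum(axis=1) for A in self.layers], axis=1)


@dataclass
class SupraAdjacency:
    """Explicit L*N x L*N supra-adjacency matrix.

    Diagonal blocks hold the intralayer matrices A_l; off-diagonal blocks
    are ``omega * I`` for adjacent layers (|l - r| = 1) and zero otherwise.
    """

    matrix: np.ndarray
    n_nodes: int
    n_layers: int
    omega: float
    coupling: str = "ordinal"


def sliding_windows(n_samples: int, window_samples: int, step_samples: int = 1) -> list[range]:
    """Half-open sample ranges [s, s + window) advancing by ``step_samples``.

    The number of windows is ``floor((n_samples - window) / step) + 1``;
    190 samples with a 50-sample window and unit step give 141 windows.
    """
    if window_samples > n_samples:
        raise ValueError(
            f"window ({window_samples}) longer than series ({n_samples})")
    if window_samples < 1 or step_samples < 1:
        raise ValueError("window and step must be positive")
    return [range(s, s + window_samples)
            for s in range(0, n_samples - window_samples + 1, step_samples)]


def trim_initial_samples(data: np.ndarray, n_drop: int = 10) -> np.ndarray:
    """Drop the first ``n_drop`` time samples (signal-stabilisation discard).

    Scanner series need the first volumes removed before analysis; 200
    acquired samples with the default drop leave 190.
    """
    data = np.asarray(data)
    if n_drop < 0 or n_drop >= data.shape[-1]:
        raise ValueError("n_drop must be in [0, n_samples)")
    return data[..., n_drop:]


def _apply_negative_policy(A: np.ndarray, policy: str) -> np.ndarray:
    if policy == "zero":
        return np.clip(A, 0.0, None)
    if policy == "abs":
        return np.abs(A)
    if policy == "keep":
        return A
    raise ValueError(f"unknown negative policy {policy!r}; choose from {NEGATIVE_POLICIES}")


def windowed_correlation(subject: SubjectSeries,
                         windows: Sequence[range],
                         negative_policy: str = "zero") -> LayerStack:
    """Pearson-correlation intralayer network per sliding window.

    For each window the N x N pairwise Pearson correlation of the regional
    signals is computed, the diagonal zeroed, and negative entries handled
    by ``negative_policy`` (``zero`` clips to 0, ``abs`` takes magnitudes,
    ``keep`` leaves them).

    Raises
    ------
    ValueError
        If a region is constant within a window (undefined correlation);
        the message names the region and window.
    """
    if negative_policy not in NEGATIVE_POLICIES:
        raise ValueError(f"unknown negative policy {negative_policy!r}")
    layers = []
    starts = []
    for w_idx, win in enumerate(windows):
        if len(win) < 3:
            raise ValueError(f"window {w_idx} has fewer than 3 samples")
        seg = subject.data[:, win.start:win.stop]
        sd = seg.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"region {subject.region_ids[bad[0]]} is constant in window "
                f"{w_idx} (samples {win.start}..{win.stop - 1})")
        A = np.corrcoef(seg)
        np.fill_diagonal(A, 0.0)
        A = _apply_negative_policy(A, negative_policy)
        A = (A + A.T) / 2.0  # enforce exact symmetry against fp asymmetry
        layers.append(A)
        starts.append(win.start)
    if not layers:
        raise ValueError("no windows supplied")
    step = starts[1] - starts[0] if len(starts) > 1 else 1
    return LayerStack(layers=layers, window_starts=starts,
                      window_length_samples=len(windows[0]),
                      step_samples=step, region_ids=list(subject.region_ids))


def build_supra(stack: LayerStack, omega: float) -> SupraAdjacency:
    """Assemble the explicit supra-adjacency matrix with ordinal coupling.

    Node-layer (i, l) occupies row ``l * N + i``.  Adjacent layers are
    coupled by ``omega`` on the identity; non-adjacent blocks are zero, so
    with ``omega = 0`` the matrix is block diagonal.
    """
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    if stack.n_layers < 1:
        raise ValueError("need at least one layer")
    N, L = stack.n_nodes, stack.n_layers
    M = np.zeros((N * L, N * L))
    for l, A in enumerate(stack.layers):
        M[l * N:(l + 1) * N, l * N:(l + 1) * N] = A
    eye = omega * np.eye(N)
    for l in range(L - 1):
        M[l * N:(l + 1) * N, (l + 1) * N:(l + 2) * N] = eye
        M[(l + 1) * N:(l + 2) * N, l * N:(l + 1) * N] = eye
    return SupraAdjacency(matrix=M, n_nodes=N, n_layers=L, omega=float(omega))
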