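"""Dynamic community metrics: allegiance, recruitment, integration,
flexibility, promiscuity, system aggregates, and core-periphery division.

All metrics are functions of the community labels only, so they are
invariant under any relabeling of communities.  Allegiance is accumulated
jointly over optimizer runs and temporal layers; recruitment and
integration then read off within- and between-system co-assignment
probabilities from the allegiance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import MultilayerAssignment

__all__ = [
    "AllegianceMatrix",
    "CorePeriphery",
    "module_allegiance",
    "recruitment",
    "integration",
    "flexibility",
    "promiscuity",
    "node_metrics_table",
    "aggregate_to_network",
    "core_periphery",
    "compare_core_periphery",
]


@dataclass
class AllegianceMatrix:
    """N x N co-assignment frequency matrix P over runs and layers.

    P_ij is the fraction of (run, layer) pairs in which nodes i and j
    share a community; P is symmetric with unit diagonal.
    """

    P: np.ndarray
    n_runs: int
    n_layers: int


@dataclass
class CorePeriphery:
    """Flexibility-ranked division into core (stable) and periphery (labile)."""

    core: list[int]       # region indices, k lowest mean flexibility
    periphery: list[int]  # region indices, k highest mean flexibility
    k: int
    mean_flexibility: np.ndarray


def module_allegiance(runs: Sequence[MultilayerAssignment]) -> AllegianceMatrix:
    """Co-assignment frequency of every node pair over all runs and layers."""
    if not runs:
        raise ValueError("need at least one run")
    N, L = runs[0].n_nodes, runs[0].n_layers
    P = np.zeros((N, N))
    for run in runs:
        if run.labels.shape != (N, L):
            raise ValueError("inconsistent assignment shapes across runs")
        for l in range(L):
            g = run.labels[:, l]
            P += g[:, None] == g[None, :]
    P /= len(runs) * L
    np.fill_diagonal(P, 1.0)
    return AllegianceMatrix(P=P, n_runs=len(runs), n_layers=L)


def _system_indices(system_map: Sequence, n_nodes: int) -> dict:
    systems = np.asarray(list(system_map))
    if systems.size != n_nodes:
        raise ValueError("system_map must assign every node a system")
    return {s: np.flatnonzero(systems == s) for s in np.unique(systems)}


def recruitment(alleg: AllegianceMatrix, system_map: Sequence) -> np.ndarray:
    """Mean allegiance of each node to the nodes of its own system.

    The self-term is included (P_ii = 1), so a node alone in its system
    has recruitment exactly 1.
    """
    P = alleg.P
    out = np.empty(P.shape[0])
    for members in _system_indices(system_map, P.shape[0]).values():
        out[members] = P[np.ix_(members, members)].mean(axis=1)
    return out


def integration(alleg: AllegianceMatrix, system_map: Sequence,
                as_printed: bool = False) -> np.ndarray:
    """Mean allegiance of each node to nodes outside its own system.

    I_iS = (1 / (N - n_S)) * sum_{j not in S} P_ij.  ``as_printed=True``
    switches the summation to j in S while keeping the 1/(N - n_S)
    normaliser, for auditing against a variant definition that sums within
    the system.
    """
    P = alleg.P
    N = P.shape[0]
    groups = _system_indices(system_map, N)
    out = np.empty(N)
    for members in groups.values():
        n_s = members.size
        if n_s == N:
            raise ValueError("a system containing all nodes leaves no "
                             "between-system pairs (division by zero)")
        if as_printed:
            out[members] = P[np.ix_(members, members)].sum(axis=1) / (N - n_s)
        else:
            outside = np.setdiff1d(np.arange(N), members)
            out[members] = P[np.ix_(members, outside)].sum(axis=1) / (N - n_s)
    return out


def flexibility(run: MultilayerAssignment) -> np.ndarray:
    """Fraction of adjacent-layer transitions where a node changes community.

    F_i = g_i / (L - 1) with g_i the number of layers l where the node's
    label differs between l and l+1.  Undefined for a single layer.
    """
    if run.n_layers < 2:
        raise ValueError("flexibility needs at least 2 layers")
    changes = np.count_nonzero(run.labels[:, :-1] != run.labels[:, 1:], axis=1)
    return changes / (run.n_layers - 1)


def promiscuity(run: MultilayerAssignment) -> np.ndarray:
    """Fraction of all communities (beyond the first) a node ever joins.

    Psi_i = (M_i - 1) / (Com - 1), M_i the number of distinct communities
    node i holds across layers and Com the assignment's total community
    count.  Psi = 0 for a node that stays in one community and Psi = 1 for
    a node that visits every community; a single-community assignment
    yields 0 for every node (the one-community limit).
    """
    com = np.unique(run.labels).size
    m_i = np.array([np.unique(row).size for row in run.labels])
    if com == 1:
        return np.zeros(run.n_nodes)
    return (m_i - 1) / (com - 1)


def node_metrics_table(runs: Sequence[MultilayerAssignment],
                       system_map: Sequence,
                       region_ids: Sequence[str] | None = None,
                       integration_as_printed: bool = False) -> pd.DataFrame:
    """Per-node metric table with run-averaged flexibility and promiscuity.

    Recruitment and integration come from the joint allegiance matrix;
    flexibility and promiscuity are computed per run and averaged
    (mean of ratios) across the ensemble.
    """
    alleg = module_allegiance(runs)
    flex = np.mean([flexibility(r) for r in runs], axis=0)
    prom = np.mean([promiscuity(r) for r in runs], axis=0)
    n = alleg.P.shape[0]
    if region_ids is None:
        region_ids = [f"ROI_{i + 1:03d}" for i in range(n)]
    return pd.DataFrame({
        "region": list(region_ids),
        "system": list(system_map),
        "recruitment": recruitment(alleg, system_map),
        "integration": integration(alleg, system_map,
                                   as_printed=integration_as_printed),
        "flexibility": flex,
        "promiscuity": prom,
    })


def aggregate_to_network(values: np.ndarray, system_map: Sequence) -> dict:
    """Unweighted per-system means of a per-node metric."""
    values = np.asarray(values, dtype=float)
    groups = _system_indices(system_map, values.size)
    return {s: float(values[m].mean()) for s, m in groups.items()}


def core_periphery(mean_flex: np.ndarray, k: int = 10) -> CorePeriphery:
    """Rank nodes by group-mean flexibility; k lowest = core, k highest = periphery.

    Ties are broken by region index (stable argsort), with a warning when
    the cut falls inside a tie.
    """
    mean_flex = np.asarray(mean_flex, dtype=float)
    n = mean_flex.size
    if k > n // 2:
        raise ValueError(f"k = {k} exceeds half the node count ({n})")
    order = np.argsort(mean_flex, kind="stable")
    core = order[:k]
    periphery = order[-k:][::-1]
    if n > 2 * k and (mean_flex[order[k - 1]] == mean_flex[order[k]]
                      or mean_flex[order[-k]] == mean_flex[order[-k - 1]]):
        warnings.warn("flexibility ties at the core/periphery cut; "
                      "broken by region index", RuntimeWarning, stacklevel=2)
    return CorePeriphery(core=sorted(core.tolist()),
                         periphery=sorted(periphery.tolist()),
                         k=k, mean_flexibility=mean_flex)


def compare_core_periphery(a: CorePeriphery, b: CorePeriphery) -> dict:
    """Common and group-specific core/periphery node sets for two groups."""
    return {
        "core_common": sorted(set(a.core) & set(b.core)),
        "core_only_a": sorted(set(a.core) - set(b.core)),
        "core_only_b": sorted(set(b.core) - set(a.core)),
        "periphery_common": sorted(set(a.periphery) & set(b.periphery)),
        "periphery_only_a": sorted(set(a.periphery) - set(b.periphery)),
        "periphery_only_b": sorted(set(b.periphery) - set(a.periphery)),
    }
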