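"""Synthetic cohorts of ROI time series with planted, time-varying modules.

Each subject's signal is a piecewise-stationary Gaussian process: a hidden
state sequence (memoryless Bernoulli switching at a group-specific rate)
selects one of a small set of planted partitions of the regions, and within
each stationary segment samples are drawn with a block-constant correlation
matrix — ``within_block_corr`` inside planted communities,
``between_block_corr`` across them, unit variances — plus independent
additive noise.  The planted partitions, state sequence, and the resulting
per-node planted flexibility (fraction of adjacent samples at which a
node's planted community changes) form the ground truth that downstream
community detection is checked against.

State 0 is aligned with the emitted region -> system map (contiguous
blocks); later states perturb it by reassigning a fraction of regions
(always including the symptom-linked region, so its planted flexibility
carries the switching signal) to other communities.  Case-group symptom
scores are an affine function of the subject's planted flexibility at the
symptom-linked region plus Gaussian noise, clipped to the 1-23 range of a
clinical severity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .netbuild import SubjectSeries

__all__ = [
    "CohortSpec",
    "PlantedTruth",
    "planted_partitions",
    "generate_subject",
    "generate_cohort",
    "system_names",
]

GROUPS = ("control", "case")

#: canonical functional-system names for the 5-system parcellation
FIVE_SYSTEMS = ("sensorimotor", "visual", "attention", "default_mode",
                "subcortical")

#: symptom score = SCORE_INTERCEPT + SCORE_SLOPE * planted_flexibility + noise
SCORE_INTERCEPT = 1.0
SCORE_SLOPE = 150.0
SCORE_RANGE = (1.0, 23.0)


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    ``n_subjects_per_group`` may be a single count (both groups equal) or a
    ``(n_control, n_case)`` pair.  Switch rates are expected partition
    switches per 100 samples.  ``reassign_fraction`` controls how many
    regions change community between planted states.
    """

    n_subjects_per_group: int | tuple[int, int] = 35
    n_regions: int = 90
    n_samples: int = 190
    n_systems: int = 5
    n_states: int = 3
    switch_rate_control: float = 2.0
    switch_rate_case: float = 6.0
    within_block_corr: float = 0.8
    between_block_corr: float = 0.1
    noise_sd: float = 0.5
    symptom_link_node: int = 10
    symptom_noise_sd: float = 2.0
    reassign_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        n = self.n_subjects_per_group
        self._n_control, self._n_case = (n, n) if isinstance(n, int) else tuple(n)
        for name in ("_n_control", "_n_case", "n_regions", "n_samples",
                     "n_systems"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name.lstrip('_')} must be positive")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.switch_rate_control < 0 or self.switch_rate_case < 0:
            raise ValueError("switch rates must be >= 0")
        if not (0 <= self.between_block_corr <= self.within_block_corr <= 1):
            raise ValueError("need 0 <= between_block_corr <= "
                             "within_block_corr <= 1")
        if not 0 <= self.symptom_link_node < self.n_regions:
            raise ValueError("symptom_link_node out of range")
        if self.n_systems > self.n_regions:
            raise ValueError("more systems than regions")
        if not 0 <= self.reassign_fraction <= 1:
            raise ValueError("reassign_fraction must be in [0, 1]")

    @property
    def n_control(self) -> int:
        return self._n_control

    @property
    def n_case(self) -> int:
        return self._n_case


@dataclass
class PlantedTruth:
    """Ground truth of one generated subject."""

    state_sequence: np.ndarray      # (n_samples,) planted partition ids
    partitions: np.ndarray          # (n_states, n_regions) community ids
    planted_flexibility: np.ndarray  # (n_regions,) adjacent-sample change rate


def system_names(n_systems: int) -> list[str]:
    if n_systems == len(FIVE_SYSTEMS):
        return list(FIVE_SYSTEMS)
    return [f"system_{i + 1}" for i in range(n_systems)]


def _base_partition(spec: CohortSpec) -> np.ndarray:
    labels = np.empty(spec.n_regions, dtype=int)
    for s, block in enumerate(np.array_split(np.arange(spec.n_regions),
                                             spec.n_systems)):
        labels[block] = s
    return labels


def planted_partitions(spec: CohortSpec) -> np.ndarray:
    """The cohort's shared planted partitions, (n_states, n_regions).

    Deterministic in ``spec.seed``.  State 0 equals the system blocks;
    each later state reassigns a random subset of regions (always
    containing the symptom-linked region) to other communities.
    """
    rng = np.random.default_rng(np.uint32(spec.seed) ^ np.uint32(0x5EED))
    base = _base_partition(spec)
    parts = [base]
    n_move = max(1, round(spec.reassign_fraction * spec.n_regions))
    communities = np.unique(base)
    for _ in range(spec.n_states - 1):
        p = base.copy()
        others = np.setdiff1d(np.arange(spec.n_regions), [spec.symptom_link_node])
        moved = rng.choice(others, size=min(max(n_move - 1, 0), others.size),
                           replace=False)
        moved = np.append(moved, spec.symptom_link_node)
        for i in moved:
            choices = communities[communities != base[i]]
            if choices.size:
                p[i] = rng.choice(choices)
        parts.append(p)
    return np.stack(parts)


def _block_correlation(labels: np.ndarray, within: float, between: float) -> np.ndarray:
    R = np.full((labels.size, labels.size), between)
    same = labels[:, None] == labels[None, :]
    R[same] = within
    np.fill_diagonal(R, 1.0)
    return R


def _nearest_pd_cholesky(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Cholesky factor, with eigenvalue-clipping repair for semidefinite R.

    Block-constant correlation with 0 <= between <= within <= 1 is always
    positive semidefinite; the repair only activates at the singular
    boundary (e.g. within = 1).
    """
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((R + R.T) / 2)
        if w.min() < -1e-6:
            raise ValueError(
                "target correlation matrix is not positive semidefinite: "
                "infeasible within/between correlation pair") from None
        R2 = (V * np.clip(w, tol, None)) @ V.T
        d = np.sqrt(np.diag(R2))
        R2 = R2 / np.outer(d, d)
        return np.linalg.cholesky(R2 + tol * np.eye(R.shape[0]))


def _switch_rate(spec: CohortSpec, group: str) -> float:
    if group == "control":
        return spec.switch_rate_control
    if group == "case":
        return spec.switch_rate_case
    raise ValueError(f"group must be one of {GROUPS}, got {group!r}")


def generate_subject(spec: CohortSpec, group: str, seed: int,
                     subject_id: str = "") -> tuple[SubjectSeries, PlantedTruth]:
    """One subject's piecewise-stationary series and its planted truth.

    The state sequence starts in state 0 and switches each sample with
    probability ``rate / 100`` to a uniformly drawn different state.
    Within a segment, samples have the state's block-constant correlation
    (unit variances); independent ``noise_sd`` Gaussian noise is added on
    top.  Identical ``spec`` and ``seed`` give bit-identical output.
    """
    rate = _switch_rate(spec, group)
    parts = planted_partitions(spec)
    rng = np.random.default_rng(seed)

    T, N = spec.n_samples, spec.n_regions
    p_switch = rate / 100.0
    states = np.zeros(T, dtype=int)
    for t in range(1, T):
        if rng.random() < p_switch:
            others = [s for s in range(spec.n_states) if s != states[t - 1]]
            states[t] = others[rng.integers(len(others))]
        else:
            states[t] = states[t - 1]

    chol = {s: _nearest_pd_cholesky(_block_correlation(
        parts[s], spec.within_block_corr, spec.between_block_corr))
        for s in np.unique(states)}
    Z = rng.standard_normal((N, T))
    X = np.empty((N, T))
    start = 0
    for t in range(1, T + 1):
        if t == T or states[t] != states[start]:
            X[:, start:t] = chol[states[start]] @ Z[:, start:t]
            start = t
    X += spec.noise_sd * rng.standard_normal((N, T))

    node_parts = parts[states]  # (T, N)
    changes = np.count_nonzero(node_parts[:-1] != node_parts[1:], axis=0)
    flex = changes / (T - 1) if T > 1 else np.zeros(N)

    series = SubjectSeries(
        data=X, region_ids=[f"ROI_{i + 1:03d}" for i in range(N)],
        group=group, subject_id=subject_id or f"{group}_{seed}")
    truth = PlantedTruth(state_sequence=states, partitions=parts,
                         planted_flexibility=flex)
    return series, truth


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectSeries],
                                               list[PlantedTruth],
                                               list[str], np.ndarray]:
    """Full two-group cohort with system map and case-group symptom scores.

    Per-subject seeds are ``spec.seed + subject_index`` (controls first),
    so the cohort is reproducible and subjects are independent.  Scores
    exist only for the case group (controls get NaN): an affine function of
    planted flexibility at the symptom-linked region plus
    ``symptom_noise_sd`` Gaussian noise, clipped to [1, 23].

    Returns (subjects, truths, system_map, scores) where ``system_map`` is
    the per-region system name list shared by all subjects.
    """
    names = system_names(spec.n_systems)
    sys_map = [names[s] for s in _base_partition(spec)]

    subjects: list[SubjectSeries] = []
    truths: list[PlantedTruth] = []
    idx = 0
    for group, n in (("control", spec.n_control), ("case", spec.n_case)):
        for j in range(n):
            sid = f"{group}_{j + 1:02d}"
            s, t = generate_subject(spec, group, seed=spec.seed + idx,
                                    subject_id=sid)
            subjects.append(s)
            truths.append(t)
            idx += 1

    score_rng = np.random.default_rng(np.uint32(spec.seed) ^ np.uint32(0x5C0E))
    scores = np.full(len(subjects), np.nan)
    for i, (s, t) in enumerate(zip(subjects, truths)):
        if s.group == "case":
            raw = (SCORE_INTERCEPT
                   + SCORE_SLOPE * t.planted_flexibility[spec.symptom_link_node]
                   + spec.symptom_noise_sd * score_rng.standard_normal())
            scores[i] = np.clip(raw, *SCORE_RANGE)
            s.score = float(scores[i])
    return subjects, truths, sys_map, scores
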