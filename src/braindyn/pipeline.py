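"""End-to-end orchestration: simulate/load -> build -> detect -> measure -> compare.

`run_pipeline` takes either a `CohortSpec` (synthetic cohort) or an
already-loaded list of subjects with a system map, runs the sliding-window
network construction, the seeded multilayer community-detection ensemble,
the dynamic metrics, and the group-statistics layer, and returns (and
optionally writes) the full results bundle.  All randomness derives from
``config.base_seed`` via per-subject seed blocks, so re-running with the
same configuration is numerically identical regardless of any future
parallelisation over subjects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as bio
from .community import community_quantity, run_ensemble
from .dynmetrics import (aggregate_to_network, compare_core_periphery,
                         core_periphery, node_metrics_table)
from .netbuild import SubjectSeries, sliding_windows, windowed_correlation
from .stats import fdr_adjust, symptom_correlation, two_sample_t
from .synthdata import CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "SubjectResult", "run_pipeline"]

METRICS = ("recruitment", "integration", "flexibility", "promiscuity")


@dataclass
class PipelineConfig:
    """Operating point of the pipeline.

    Defaults reproduce the reference analysis: 50-sample windows with unit
    step, structural and temporal resolutions gamma = omega = 1, a 50-run
    optimizer ensemble, negative correlations zeroed, 10-node core and
    periphery, alpha 0.05 with per-family Benjamini-Hochberg correction.
    """

    window_samples: int = 50
    step_samples: int = 1
    gamma: float = 1.0
    omega: float = 1.0
    n_runs: int = 50
    negative_policy: str = "zero"
    core_k: int = 10
    alpha: float = 0.05
    fdr_method: str = "BH"
    base_seed: int = 0
    integration_as_printed: bool = False


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    score: float | None
    mean_Q: float
    mean_quantity: float
    node_metrics: pd.DataFrame  # columns region, system, and METRICS


def _analyze_subject(subject: SubjectSeries, system_map: Sequence[str],
                     config: PipelineConfig, base_seed: int) -> SubjectResult:
    windows = sliding_windows(subject.n_samples, config.window_samples,
                              config.step_samples)
    stack = windowed_correlation(subject, windows, config.negative_policy)
    ens = run_ensemble(stack, gamma=config.gamma, omega=config.omega,
                       n_runs=config.n_runs, base_seed=base_seed)
    table = node_metrics_table(
        ens.runs, system_map, region_ids=subject.region_ids,
        integration_as_printed=config.integration_as_printed)
    return SubjectResult(subject_id=subject.subject_id, group=subject.group,
                         score=subject.score, mean_Q=ens.mean_Q,
                         mean_quantity=ens.mean_quantity, node_metrics=table)


def _compare(values_a, values_b, metric, level, unit) -> dict:
    try:
        cmp = two_sample_t(values_a, values_b, metric=metric, level=level)
    except ValueError:
        # degenerate comparison (zero pooled variance): no evidence either
        # way when the constant groups coincide, certain otherwise
        a = np.asarray(values_a, float)
        b = np.asarray(values_b, float)
        equal = a.mean() == b.mean()
        return {"metric": metric, "level": level, "unit": unit,
                "t": 0.0 if equal else np.inf * np.sign(a.mean() - b.mean()),
                "df": a.size + b.size - 2, "p": 1.0 if equal else 0.0,
                "mean_case": float(a.mean()), "mean_control": float(b.mean()),
                "sd_case": float(a.std(ddof=1)), "sd_control": float(b.std(ddof=1)),
                "n_case": int(a.size), "n_control": int(b.size)}
    return {"metric": metric, "level": level, "unit": unit, "t": cmp.t,
            "df": cmp.df, "p": cmp.p,
            "mean_case": cmp.mean_a, "mean_control": cmp.mean_b,
            "sd_case": cmp.sd_a, "sd_control": cmp.sd_b,
            "n_case": cmp.n_a, "n_control": cmp.n_b}


def _group_frames(results: list[SubjectResult], metric: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node metric values stacked by group: (case_df, control_df)."""
    case = pd.DataFrame([r.node_metrics[metric].to_numpy()
                         for r in results if r.group == "case"])
    ctrl = pd.DataFrame([r.node_metrics[metric].to_numpy()
                         for r in results if r.group == "control"])
    return case, ctrl


def run_pipeline(config: PipelineConfig,
                 spec: CohortSpec | None = None,
                 subjects: list[SubjectSeries] | None = None,
                 system_map: Sequence[str] | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run the full analysis and return the results bundle.

    Exactly one of ``spec`` (synthetic cohort, generated here) or
    ``subjects`` + ``system_map`` (pre-loaded cohort) must be given.  The
    bundle holds per-subject results, community-, system- and node-level
    group comparisons (each an FDR family), the two groups' core-periphery
    divisions and their overlap, and case-group symptom correlations for
    the significant comparisons.
    """
    if (spec is None) == (subjects is None):
        raise ValueError("give either a CohortSpec or subjects, not both")
    truths = None
    if spec is not None:
        spec = dataclasses.replace(spec, seed=config.base_seed)
        subjects, truths, system_map, _ = generate_cohort(spec)
    if system_map is None:
        raise ValueError("system_map required with pre-loaded subjects")

    results = [
        _analyze_subject(s, system_map, config,
                         base_seed=config.base_seed + 1 + i * config.n_runs)
        for i, s in enumerate(subjects)
    ]
    case = [r for r in results if r.group == "case"]
    ctrl = [r for r in results if r.group == "control"]
    if not case or not ctrl:
        raise ValueError("need subjects in both groups")

    # community level: quality (Q) and quantity, one FDR family
    comm = pd.DataFrame([
        _compare([r.mean_Q for r in case], [r.mean_Q for r in ctrl],
                 "community_quality", "community", "Q"),
        _compare([r.mean_quantity for r in case], [r.mean_quantity for r in ctrl],
                 "community_quantity", "community", "count"),
    ])
    comm["p_fdr"] = fdr_adjust(comm["p"])

    systems = list(dict.fromkeys(system_map))
    sys_rows, node_rows = [], []
    regions = results[0].node_metrics["region"].tolist()
    for metric in METRICS:
        case_df, ctrl_df = _group_frames(results, metric)
        sys_case = case_df.T.groupby(list(system_map)).mean().T
        sys_ctrl = ctrl_df.T.groupby(list(system_map)).mean().T
        m_sys = [_compare(sys_case[s], sys_ctrl[s], metric, "system", s)
                 for s in systems]
        m_nodes = [_compare(case_df[i], ctrl_df[i], metric, "node", regions[i])
                   for i in range(len(regions))]
        # FDR within each (metric, level) analysis family
        for rows in (m_sys, m_nodes):
            adj = fdr_adjust([r["p"] for r in rows])
            for r, q in zip(rows, adj):
                r["p_fdr"] = float(q)
        sys_rows += m_sys
        node_rows += m_nodes
    sys_table = pd.DataFrame(sys_rows)
    node_table = pd.DataFrame(node_rows)

    # core-periphery from group-mean flexibility
    def group_mean_flex(rs):
        return np.mean([r.node_metrics["flexibility"].to_numpy() for r in rs],
                       axis=0)
    cp_case = core_periphery(group_mean_flex(case), k=config.core_k)
    cp_ctrl = core_periphery(group_mean_flex(ctrl), k=config.core_k)

    # symptom correlations for significant comparisons, case group only
    scored = [r for r in case if r.score is not None and np.isfinite(r.score)]
    correlations = []
    if len(scored) >= 3:
        scores = [r.score for r in scored]
        sig_nodes = node_table[node_table["p_fdr"] < config.alpha]
        for row in sig_nodes.itertuples(index=False):
            i = regions.index(row.unit)
            vals = [r.node_metrics[row.metric].iloc[i] for r in scored]
            if np.std(vals) == 0:
                continue
            c = symptom_correlation(vals, scores, region=row.unit)
            correlations.append({"metric": row.metric, "level": "node",
                                 "unit": row.unit, "r": c.r, "p": c.p,
                                 "n": c.n})
        sig_sys = sys_table[sys_table["p_fdr"] < config.alpha]
        for row in sig_sys.itertuples(index=False):
            vals = [aggregate_to_network(
                r.node_metrics[row.metric].to_numpy(), system_map)[row.unit]
                for r in scored]
            if np.std(vals) == 0:
                continue
            c = symptom_correlation(vals, scores, region=row.unit)
            correlations.append({"metric": row.metric, "level": "system",
                                 "unit": row.unit, "r": c.r, "p": c.p,
                                 "n": c.n})
    corr_table = pd.DataFrame(
        correlations, columns=["metric", "level", "unit", "r", "p", "n"])

    bundle = {
        "config": config,
        "subjects": results,
        "truths": truths,
        "system_map": list(system_map),
        "community_comparisons": comm,
        "system_comparisons": sys_table,
        "node_comparisons": node_table,
        "core_periphery": {"case": cp_case, "control": cp_ctrl,
                           "overlap": compare_core_periphery(cp_case, cp_ctrl)},
        "correlations": corr_table,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bio.write_table(bundle["community_comparisons"],
                    out_dir / "community_comparisons.tsv")
    bio.write_table(bundle["system_comparisons"],
                    out_dir / "system_comparisons.tsv")
    bio.write_table(bundle["node_comparisons"],
                    out_dir / "node_comparisons.tsv")
    bio.write_table(bundle["correlations"], out_dir / "correlations.tsv")
    per_subject = pd.DataFrame(
        [{"subject": r.subject_id, "group": r.group, "score": r.score,
          "mean_Q": r.mean_Q, "mean_quantity": r.mean_quantity}
         for r in bundle["subjects"]])
    bio.write_table(per_subject, out_dir / "subject_summary.tsv")
    cp = bundle["core_periphery"]
    manifest = {
        "config": dataclasses.asdict(bundle["config"]),
        "n_subjects": len(bundle["subjects"]),
        "core_case": cp["case"].core, "periphery_case": cp["case"].periphery,
        "core_control": cp["control"].core,
        "periphery_control": cp["control"].periphery,
        "overlap": cp["overlap"],
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
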