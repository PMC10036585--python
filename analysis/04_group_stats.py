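"""Group comparisons, core-periphery division, and symptom correlations.

Pooled-variance t tests compare case vs control on community quality and
quantity, on each metric per functional system, and on each metric per
node, with Benjamini-Hochberg FDR within each analysis family.  The two
groups' flexibility-ranked core/periphery sets are intersected, and the
case group's symptom scores are correlated with the planted-link node's
flexibility.  Tables are written under results/.
"""

import numpy as np
import pandas as pd

import braindyn.io as bio
from braindyn import (compare_core_periphery, core_periphery, fdr_adjust,
                      symptom_correlation, two_sample_t)
from study import CONFIG, RESULTS, SPEC

METRICS = ("recruitment", "integration", "flexibility", "promiscuity")


def compare(case_vals, ctrl_vals, metric, level, unit):
    r = two_sample_t(case_vals, ctrl_vals, metric=metric, level=level)
    return {"metric": metric, "level": level, "unit": unit, "t": r.t,
            "df": r.df, "p": r.p, "mean_case": r.mean_a,
            "mean_control": r.mean_b}


def main():
    comm = pd.read_csv(RESULTS / "community_summary.tsv", sep="\t")
    node = pd.read_csv(RESULTS / "node_metrics.tsv", sep="\t")
    case, ctrl = comm["group"] == "case", comm["group"] == "control"

    rows = [compare(comm.loc[case, c], comm.loc[ctrl, c], name,
                    "community", "Q" if c == "mean_Q" else "count")
            for c, name in (("mean_Q", "community_quality"),
                            ("mean_quantity", "community_quantity"))]
    comm_table = pd.DataFrame(rows)
    comm_table["p_fdr"] = fdr_adjust(comm_table["p"])
    bio.write_table(comm_table, RESULTS / "community_comparisons.tsv")

    frames = []
    for metric in METRICS:
        for level, key in (("system", "system"), ("node", "region")):
            grp = (node.groupby(["subject", "group", key])[metric]
                   .mean().reset_index())
            rows = []
            for unit, sub in grp.groupby(key):
                rows.append(compare(sub.loc[sub["group"] == "case", metric],
                                    sub.loc[sub["group"] == "control", metric],
                                    metric, level, unit))
            fam = pd.DataFrame(rows)
            fam["p_fdr"] = fdr_adjust(fam["p"])
            frames.append(fam)
    comparisons = pd.concat(frames, ignore_index=True)
    bio.write_table(comparisons, RESULTS / "group_comparisons.tsv")

    flex = node[node.columns.intersection(
        ["subject", "group", "region", "flexibility"])]
    cp = {}
    for group in ("case", "control"):
        mean_flex = (flex[flex["group"] == group]
                     .groupby("region", sort=False)["flexibility"].mean())
        cp[group] = core_periphery(mean_flex.to_numpy(), k=CONFIG.core_k)
    overlap = compare_core_periphery(cp["case"], cp["control"])
    regions = flex["region"].drop_duplicates().tolist()
    named = {k: [regions[i] for i in v] for k, v in overlap.items()}
    bio.write_table(pd.DataFrame([{"set": k, "regions": ",".join(v)}
                                  for k, v in named.items()]),
                    RESULTS / "core_periphery_overlap.tsv")

    link = f"ROI_{SPEC.symptom_link_node + 1:03d}"
    cases = node[(node["group"] == "case") & (node["region"] == link)]
    scores = comm.loc[comm["group"] == "case",
                      ["subject", "score"]].set_index("subject")
    merged = cases.set_index("subject").join(scores)
    corr = symptom_correlation(merged["flexibility"], merged["score"],
                               region=link)
    bio.write_table(pd.DataFrame([{"region": link, "metric": "flexibility",
                                   "r": corr.r, "p": corr.p, "n": corr.n}]),
                    RESULTS / "symptom_correlation.tsv")

    sig = comparisons[comparisons["p_fdr"] < CONFIG.alpha]
    q = comm_table.iloc[0]
    print(f"community quality: t({q['df']:.0f}) = {q['t']:.3f}, "
          f"P(FDR) = {q['p_fdr']:.4f}")
    print(f"{len(sig)} significant metric comparisons after FDR "
          f"({', '.join(sorted(sig['metric'].unique())) or 'none'})")
    print(f"core overlap between groups: {len(named['core_common'])}/"
          f"{CONFIG.core_k}; periphery overlap: "
          f"{len(named['periphery_common'])}/{CONFIG.core_k}")
    print(f"symptom correlation at {link} (flexibility): "
          f"r = {corr.r:.4f}, P = {corr.p:.4f}, n = {corr.n}")


if __name__ == "__main__":
    main()
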