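"""Generate the synthetic cohort and write it to disk.

Writes each subject's region x time series (tab-separated) plus the cohort
manifest and the region -> system map under scratch/ (bulk data), and a
small ground-truth summary — per-subject planted switch counts and planted
flexibility at the symptom-linked region — under results/.
"""

import numpy as np
import pandas as pd

import braindyn.io as bio
from braindyn import generate_cohort
from study import RESULTS, SCRATCH, SPEC


def main():
    series_dir = SCRATCH / "cohort"
    series_dir.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    subjects, truths, system_map, scores = generate_cohort(SPEC)

    rows = []
    for s, score in zip(subjects, scores):
        path = series_dir / f"{s.subject_id}.tsv"
        bio.write_series(s, path)
        rows.append({"subject": s.subject_id, "group": s.group,
                     "score": score, "path": str(path)})
    bio.write_manifest(rows, series_dir / "manifest.tsv")
    bio.write_system_map(subjects[0].region_ids, system_map,
                         series_dir / "system_map.tsv")

    truth = pd.DataFrame({
        "subject": [s.subject_id for s in subjects],
        "group": [s.group for s in subjects],
        "planted_switches": [int(np.count_nonzero(np.diff(t.state_sequence)))
                             for t in truths],
        "planted_flex_link_node": [t.planted_flexibility[SPEC.symptom_link_node]
                                   for t in truths],
        "score": scores,
    })
    bio.write_table(truth, RESULTS / "planted_truth_summary.tsv")

    by_group = truth.groupby("group")["planted_switches"].mean()
    print(f"wrote {len(subjects)} subjects to {series_dir}")
    print(f"mean planted switches: case {by_group['case']:.1f}, "
          f"control {by_group['control']:.1f} "
          f"(rates {SPEC.switch_rate_case} vs {SPEC.switch_rate_control} "
          f"per 100 samples)")


if __name__ == "__main__":
    main()
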