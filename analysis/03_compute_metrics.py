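"""Dynamic community metrics from the cached assignment ensembles.

Per subject, the 10 runs are pooled into a module-allegiance matrix, from
which recruitment and integration follow; flexibility and promiscuity are
averaged over runs.  Writes the per-subject node-level metric table
(long format) and the group-mean system-level table under results/.
"""

import numpy as np
import pandas as pd

import braindyn.io as bio
from braindyn import node_metrics_table
from braindyn.community import MultilayerAssignment
from study import CONFIG, RESULTS, SCRATCH

SERIES_DIR = SCRATCH / "cohort"
LABELS_DIR = SCRATCH / "assignments"
METRICS = ("recruitment", "integration", "flexibility", "promiscuity")


def load_runs(subject_id):
    z = np.load(LABELS_DIR / f"{subject_id}.npz")
    return [MultilayerAssignment(labels=lab, Q=q, seed=int(sd),
                                 gamma=CONFIG.gamma, omega=CONFIG.omega)
            for lab, q, sd in zip(z["labels"], z["q"], z["seeds"])]


def main():
    if not LABELS_DIR.exists():
        raise SystemExit("run 02_detect_communities.py first")
    subjects = bio.read_manifest(SERIES_DIR / "manifest.tsv")
    system_map = bio.read_system_map(SERIES_DIR / "system_map.tsv",
                                     subjects[0].region_ids)

    tables = []
    for s in subjects:
        tab = node_metrics_table(load_runs(s.subject_id), system_map,
                                 region_ids=s.region_ids)
        tab.insert(0, "subject", s.subject_id)
        tab.insert(1, "group", s.group)
        tables.append(tab)
    node_long = pd.concat(tables, ignore_index=True)
    bio.write_table(node_long, RESULTS / "node_metrics.tsv")

    sys_means = (node_long.groupby(["group", "system"])[list(METRICS)]
                 .mean().reset_index())
    bio.write_table(sys_means, RESULTS / "system_metrics_group_means.tsv")
    print(f"node metrics for {len(subjects)} subjects "
          f"({node_long['region'].nunique()} regions)")
    print(sys_means.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
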