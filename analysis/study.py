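"""Shared study definition for the analysis scripts.

One synthetic two-group cohort emulating the study design — a control
group and a case group whose planted community structure switches faster —
at a desk scale that runs in minutes: 10 subjects per group, 20 regions in
4 functional systems, 120 samples per subject, 20-sample windows advancing
by 4 samples (26 layers), and a 10-run community-detection ensemble per
subject.  All scripts derive their inputs deterministically from this
spec, so each can be re-run in isolation.
"""

from pathlib import Path

from braindyn import CohortSpec, PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "study"
SCRATCH = ROOT / "scratch" / "study"

SPEC = CohortSpec(
    n_subjects_per_group=10,
    n_regions=20,
    n_samples=120,
    n_systems=4,
    n_states=3,
    switch_rate_control=2.0,
    switch_rate_case=6.0,
    within_block_corr=0.8,
    between_block_corr=0.1,
    noise_sd=0.5,
    symptom_link_node=10,
    symptom_noise_sd=2.0,
    reassign_fraction=0.3,
    seed=2023,
)

CONFIG = PipelineConfig(
    window_samples=20,
    step_samples=4,
    gamma=1.0,
    omega=1.0,
    n_runs=10,
    negative_policy="zero",
    core_k=3,
    alpha=0.05,
    base_seed=2023,
)
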