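"""Shared configuration for the numbered analysis scripts.

One desk-scale demonstration cohort: 120 subjects, 20 components
(7 networks), 160 TRs at TR = 2 s, half patients carrying a +5 year
connectivity-age acceleration, cognitive scores coupled to the latent
acceleration at -0.5 points/year. All scripts read and write under
results/run/.
"""

from pathlib import Path

from dynbag import CohortSpec, FncConfig, RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"


def demo_config(seed: int = 7) -> RunConfig:
    return RunConfig(
        cohort=CohortSpec(n_subjects=120, n_components=20, n_timepoints=160,
                          seed=seed),
        fnc=FncConfig(stride=5),
        sfnc_architecture="linear_baseline",
        dfnc_architecture="linear_baseline",
        include_subnetworks=True,
        seed=seed,
    )
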