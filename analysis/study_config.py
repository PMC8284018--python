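"""Shared configuration of the desk-scale synthetic study.

One cohort drives all numbered analysis scripts: four donor groups (healthy,
untreated, and two treatments), six single-stimulus conditions plus media
control, five phosphoprotein readouts, three deregulated edges per diseased
group of which two are left unreverted by each treatment.  Moderate
measurement noise (cv 10%) and donor-to-donor variability (3% edge flips)
keep the fitting problem realistic while each script still runs in seconds.
"""

from combilogic.logic_fit import TrainingParams
from combilogic.pipeline import PipelineConfig, SyntheticSpec

OUTDIR = "results/cohort"
SEED = 20260924


def study_config() -> PipelineConfig:
    return PipelineConfig(
        outdir=OUTDIR,
        seed=SEED,
        synthetic=SyntheticSpec(
            n_donors_per_group=8,
            groups=("healthy", "untreated", "FTY", "IFNB"),
            n_stimuli=6, n_readouts=5, n_intermediates=8,
            n_deregulated=3, n_unreverted=2,
            effect_size=4.0, cv=0.10, donor_variability=0.03),
        training=TrainingParams(population=40, max_generations=150,
                                stall_generations=30, n_runs=10),
    )
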