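import pytest

from triadkit.genodata import qc_filter
from triadkit.synthdata import SimulationConfig, SnpModel, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort_with_truth():
    """Study-scale cohort with no genotype effects, with injected missingness
    and Mendelian corruption."""
    cfg = SimulationConfig(
        snps=(SnpModel(q=0.25),),
        n_triads=256,
        n_dyads=360,
        miss_rate=0.05,
        mendel_err_rate=0.01,
        seed=101,
    )
    return cfg, *simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort_qc():
    """Study-scale cohort with fetal and maternal effects, QC-passed."""
    cfg = SimulationConfig(
        snps=(SnpModel(q=0.3, R1=1.4, R2=2.0, S1=1.3, S2=1.8),),
        n_triads=256,
        n_dyads=360,
        miss_rate=0.0,
        mendel_err_rate=0.0,
        seed=202,
    )
    cohort, truth = simulate_cohort(cfg)
    filtered, _ = qc_filter(cohort, "SNP1")
    return cfg, filtered, truth


@pytest.fixture(scope="session")
def clean_null_cohort_qc():
    """Null cohort without injected corruption, QC-passed."""
    cfg = SimulationConfig(
        snps=(SnpModel(q=0.25),),
        n_triads=256,
        n_dyads=360,
        miss_rate=0.0,
        mendel_err_rate=0.0,
        seed=303,
    )
    cohort, _ = simulate_cohort(cfg)
    filtered, _ = qc_filter(cohort, "SNP1")
    return filtered
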