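"""Synthetic hybrid cohorts with known ground truth.

The generator emulates the sampling design of a hybrid case-parent-triad /
control-mother-dyad study of a pregnancy disorder: parents drawn under
Hardy-Weinberg equilibrium and random mating, Mendelian transmission to the
child, a multiplicative maternal/fetal genotype effect on the mother's
disease risk with an optional maternal gene-environment interaction, and
ascertainment by rejection sampling on disease status.  Genotype
missingness and Mendelian-error corruption are injected after sampling,
with full bookkeeping in a :class:`TruthRecord` so QC and estimation stages
can be checked against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .genodata import (
    CASE_TRIAD,
    CONTROL_DYAD,
    DOSES,
    DYAD_CELLS,
    MISSING,
    TRIAD_CELLS,
    FamilyCohort,
    FamilyRecord,
    SnpDef,
    mating_weight,
    transmission_prob,
)

__all__ = [
    "SnpModel",
    "SimulationConfig",
    "TruthRecord",
    "simulate_cohort",
    "expected_cell_distribution",
]


class SimulationError(RuntimeError):
    """Unachievable sampling configuration (e.g. zero disease probability)."""


@dataclass(frozen=True)
class SnpModel:
    """Generative parameters for one biallelic SNP.

    q is the variant-allele frequency; R1/R2 and S1/S2 the fetal and
    maternal genotype relative risks for doses 1 and 2; I1/I2 the extra
    multiplicative maternal risks applied when the mother is exposed.
    """

    snp_id: str = "SNP1"
    q: float = 0.25
    R1: float = 1.0
    R2: float = 1.0
    S1: float = 1.0
    S2: float = 1.0
    I1: float = 1.0
    I2: float = 1.0
    allele_ref: str = "A"
    allele_var: str = "B"

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"{self.snp_id}: q must lie in (0,1), got {self.q}")
        for name in ("R1", "R2", "S1", "S2", "I1", "I2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.snp_id}: {name} must be positive")

    def fetal_rr(self, gc: int) -> float:
        return (1.0, self.R1, self.R2)[gc]

    def maternal_rr(self, gm: int, exposed: bool = False) -> float:
        s = (1.0, self.S1, self.S2)[gm]
        if exposed:
            s *= (1.0, self.I1, self.I2)[gm]
        return s

    def snp_def(self) -> SnpDef:
        return SnpDef(self.snp_id, self.allele_ref, self.allele_var)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale generative configuration.

    Defaults mirror the target study: 256 case triads (39 mild / 217 severe)
    and 360 control dyads, baseline disease probability 5% (the reported
    population incidence of preeclampsia in China is ~5.2%), maternal
    exposure prevalence 0.37 (the share of case mothers with pre-pregnancy
    BMI >= 24 kg/m^2), and small genotyping-failure and Mendelian-error
    rates typical of PCR/TaqMan assays.
    """

    snps: tuple[SnpModel, ...] = (SnpModel(),)
    n_triads: int = 256
    n_dyads: int = 360
    f0: float = 0.05
    exposure_prev: float = 0.37
    mpe_fraction: float = 39 / 256
    miss_rate: float = 0.02
    mendel_err_rate: float = 0.005
    bmi_threshold: float = 24.0
    seed: int = 0
    max_attempts: int = 2_000_000

    def __post_init__(self) -> None:
        for name in ("f0", "exposure_prev", "mpe_fraction", "miss_rate", "mendel_err_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in snps")
        max_risk = math.prod(
            max(s.R1, s.R2, 1.0) * max(s.S1 * max(s.I1, 1.0), s.S2 * max(s.I2, 1.0), 1.0)
            for s in self.snps
        )
        if self.f0 * max_risk > 1.0:
            raise ValueError("f0 times the maximal relative risk exceeds 1")


@dataclass
class TruthRecord:
    """Latent per-family ground truth for a simulated cohort.

    ``genotypes[fid][snp_id]`` holds the uncorrupted (gm, gf, gc) doses
    (gf is None for dyads); ``exposed[fid]`` the maternal exposure;
    ``n_missing_injected``/``corrupted_children`` the per-SNP injection
    bookkeeping (a corrupted child may remain Mendelian-consistent by
    chance, so detected errors are at most the injected count).
    """

    genotypes: dict[str, dict[str, tuple[int, int | None, int]]] = field(default_factory=dict)
    exposed: dict[str, bool] = field(default_factory=dict)
    disease: dict[str, bool] = field(default_factory=dict)
    n_missing_injected: dict[str, int] = field(default_factory=dict)
    missing_families: dict[str, set[str]] = field(default_factory=dict)
    corrupted_children: dict[str, set[str]] = field(default_factory=dict)
    n_attempts: int = 0


def expected_cell_distribution(
    q: float,
    R1: float = 1.0,
    R2: float = 1.0,
    S1: float = 1.0,
    S2: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact cell probabilities implied by the generative model.

    Returns ``(triad_probs, dyad_probs)`` aligned with
    :data:`~triadkit.genodata.TRIAD_CELLS` and
    :data:`~triadkit.genodata.DYAD_CELLS`.  Case-triad cell mass is
    proportional to HWE mating frequency x Mendelian transmission x fetal
    RR x maternal RR, normalized over the 15 compatible cells; control-dyad
    mass marginalizes the father with all RRs at 1 (rare-disease
    approximation: controls follow the source population).
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0,1), got {q}")
    R = (1.0, R1, R2)
    S = (1.0, S1, S2)
    hwe = [(1 - q) ** 2, 2 * q * (1 - q), q**2]

    triad = np.array(
        [
            hwe[gm] * hwe[gf] * transmission_prob(gm, gf, gc) * R[gc] * S[gm]
            for gm, gf, gc in TRIAD_CELLS
        ]
    )
    triad /= triad.sum()

    dyad = np.array(
        [
            sum(hwe[gm] * hwe[gf] * transmission_prob(gm, gf, gc) for gf in DOSES)
            for gm, gc in DYAD_CELLS
        ]
    )
    dyad /= dyad.sum()
    return triad, dyad


def _draw_child(rng: np.random.Generator, gm: int, gf: int) -> int:
    tm = rng.integers(2) if gm == 1 else gm // 2
    tf = rng.integers(2) if gf == 1 else gf // 2
    return int(tm + tf)


def simulate_cohort(config: SimulationConfig) -> tuple[FamilyCohort, TruthRecord]:
    """Draw a synthetic hybrid cohort; identical seeds give identical cohorts.

    Families are sampled until the target numbers of case triads and control
    dyads are reached (rejection sampling on disease status); fathers of
    control families are discarded.  Missingness and child-genotype
    corruption are applied afterwards at the configured rates.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthRecord()
    truth.n_missing_injected = {s.snp_id: 0 for s in config.snps}
    truth.missing_families = {s.snp_id: set() for s in config.snps}
    truth.corrupted_children = {s.snp_id: set() for s in config.snps}

    records: list[FamilyRecord] = []
    n_cases = 0
    n_controls = 0
    attempts = 0
    while n_cases < config.n_triads or n_controls < config.n_dyads:
        attempts += 1
        if attempts > config.max_attempts:
            raise SimulationError(
                f"exceeded {config.max_attempts} sampling attempts "
                f"({n_cases}/{config.n_triads} triads, {n_controls}/{config.n_dyads} dyads)"
            )
        trios = {}
        for s in config.snps:
            gm = int(rng.binomial(2, s.q))
            gf = int(rng.binomial(2, s.q))
            gc = _draw_child(rng, gm, gf)
            trios[s.snp_id] = (gm, gf, gc)
        exposed = bool(rng.random() < config.exposure_prev)
        p_disease = config.f0 * math.prod(
            s.fetal_rr(trios[s.snp_id][2]) * s.maternal_rr(trios[s.snp_id][0], exposed)
            for s in config.snps
        )
        disease = bool(rng.random() < p_disease)
        if disease:
            if n_cases >= config.n_triads:
                continue
            n_cases += 1
            fid = f"case{n_cases:05d}"
            severity = "mPE" if rng.random() < config.mpe_fraction else "sPE"
            arm = CASE_TRIAD
        else:
            if n_controls >= config.n_dyads:
                continue
            n_controls += 1
            fid = f"ctrl{n_controls:05d}"
            severity = "control"
            arm = CONTROL_DYAD

        covariates = _draw_covariates(rng, exposed, config)
        genotypes: dict[str, dict[str, int]] = {"mother": {}, "child": {}}
        if arm == CASE_TRIAD:
            genotypes["father"] = {}
        truth.genotypes[fid] = {}
        truth.exposed[fid] = exposed
        truth.disease[fid] = disease
        for s in config.snps:
            gm, gf, gc = trios[s.snp_id]
            truth.genotypes[fid][s.snp_id] = (gm, gf if arm == CASE_TRIAD else None, gc)
            # child corruption: replace with a uniform random dose
            if rng.random() < config.mendel_err_rate:
                gc = int(rng.integers(3))
                truth.corrupted_children[s.snp_id].add(fid)
            member_doses = {"mother": gm, "child": gc}
            if arm == CASE_TRIAD:
                member_doses["father"] = gf
            fam_missing = False
            for role, dose in member_doses.items():
                if rng.random() < config.miss_rate:
                    dose = MISSING
                    fam_missing = True
                genotypes[role][s.snp_id] = dose
            if fam_missing:
                truth.n_missing_injected[s.snp_id] += 1
                truth.missing_families[s.snp_id].add(fid)

        records.append(
            FamilyRecord(
                family_id=fid,
                arm=arm,
                severity=severity,
                genotypes=genotypes,
                covariates=covariates,
            )
        )
    truth.n_attempts = attempts
    cohort = FamilyCohort(
        records=records,
        panel=[s.snp_def() for s in config.snps],
        provenance=f"simulated (seed={config.seed})",
    )
    return cohort, truth


def _draw_covariates(rng: np.random.Generator, exposed: bool, config: SimulationConfig) -> dict:
    """Maternal covariates: BMI consistent with exposure, plus simple draws.

    Pre-pregnancy BMI is drawn from a normal (sd 3.7 around 21.5) truncated
    to the exposed/unexposed side of the BMI threshold, so dichotomizing BMI
    downstream reproduces the latent exposure exactly.  Education and age
    are independent parametric draws that exercise descriptive statistics;
    they carry no effect on risk.
    """
    while True:
        bmi = rng.normal(21.5, 3.7)
        if (bmi >= config.bmi_threshold) == exposed:
            break
    return {
        "bmi": round(float(bmi), 2),
        "education_low": int(rng.random() < 0.5),
        "maternal_age": round(float(rng.normal(28.5, 5.0)), 1),
        "exposed": int(exposed),
    }


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["snps"] = [asdict(s) for s in config.snps]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["snps"] = tuple(SnpModel(**s) for s in d.get("snps", [{}]))
    return SimulationConfig(**d)
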