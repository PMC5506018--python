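"""Data model, pedigree I/O, genotype coding, Mendelian QC and mating types.

Genotypes at a biallelic SNP are coded as the dose of the *variant* allele
(the low-frequency, "mutant" allele declared in the map file): 0, 1 or 2,
with :data:`MISSING` (-1) for a failed genotype.  Declaring the variant
allele per SNP in the map — rather than inferring it from whichever subset
of the data is in hand — keeps the coding stable across strata and subsets.

Families come in two arms: *case triads* (affected mother, father, child,
all genotyped) and *control dyads* (unaffected mother and child, no father).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "MISSING",
    "DOSES",
    "SnpDef",
    "FamilyRecord",
    "FamilyCohort",
    "QcReport",
    "TRIAD_CELLS",
    "DYAD_CELLS",
    "transmission_prob",
    "mating_type",
    "mating_weight",
    "MATING_TYPES",
    "mendel_check",
    "mendel_check_dyad",
    "qc_filter",
    "cohort_summary",
    "read_pedigree",
    "write_pedigree",
    "read_covariates",
    "attach_covariates",
    "merge_cohorts",
]

#: Sentinel dose for a failed/absent genotype.
MISSING = -1

#: Valid non-missing doses.
DOSES = (0, 1, 2)

CASE_TRIAD = "case_triad"
CONTROL_DYAD = "control_dyad"

SEVERITIES = ("mPE", "sPE", "control")


class PedigreeFormatError(ValueError):
    """Malformed PED/MAP content (bad allele symbol, wrong column count...)."""


class PedigreeStructureError(ValueError):
    """Family structure not representable as a case triad or control dyad."""


class UndefinedInputError(ValueError):
    """An operation received a MISSING dose it is not defined for."""


@dataclass(frozen=True)
class SnpDef:
    """A biallelic SNP: reference allele and (low-frequency) variant allele."""

    snp_id: str
    allele_ref: str
    allele_var: str

    def __post_init__(self) -> None:
        if self.allele_ref == self.allele_var:
            raise ValueError(f"{self.snp_id}: reference and variant allele are equal")
        if "0" in (self.allele_ref, self.allele_var):
            raise ValueError(f"{self.snp_id}: '0' is reserved for missing alleles")


@dataclass
class FamilyRecord:
    """One family: genotypes per role plus maternal covariates.

    ``genotypes`` maps role ("mother", "father", "child") to a per-SNP dose
    map.  Control dyads carry no "father" entry.  ``severity`` is "control"
    for dyads and "mPE"/"sPE" for case triads.
    """

    family_id: str
    arm: str
    severity: str
    genotypes: dict[str, dict[str, int]]
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in (CASE_TRIAD, CONTROL_DYAD):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.arm == CONTROL_DYAD:
            if "father" in self.genotypes:
                raise ValueError(f"{self.family_id}: control dyad with father genotypes")
            if self.severity != "control":
                raise ValueError(f"{self.family_id}: control dyad must have severity 'control'")
        else:
            if self.severity == "control":
                raise ValueError(f"{self.family_id}: case triad cannot have severity 'control'")

    @property
    def roles(self) -> tuple[str, ...]:
        return ("mother", "father", "child") if self.arm == CASE_TRIAD else ("mother", "child")

    def doses(self, snp_id: str) -> tuple[int, ...]:
        """Doses for this SNP in role order (mother, [father,] child)."""
        return tuple(self.genotypes[r].get(snp_id, MISSING) for r in self.roles)


@dataclass
class FamilyCohort:
    """A roster of triad/dyad records genotyped on a common SNP panel."""

    records: list[FamilyRecord]
    panel: list[SnpDef]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.family_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate family_id(s): {dup}")
        panel_ids = [s.snp_id for s in self.panel]
        if len(set(panel_ids)) != len(panel_ids):
            raise ValueError("duplicate snp_id in panel")
        valid = set(DOSES) | {MISSING}
        for rec in self.records:
            for role, gmap in rec.genotypes.items():
                for snp_id, dose in gmap.items():
                    if snp_id not in panel_ids:
                        raise ValueError(f"{rec.family_id}/{role}: unknown SNP {snp_id!r}")
                    if dose not in valid:
                        raise ValueError(f"{rec.family_id}/{role}/{snp_id}: bad dose {dose!r}")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.panel]

    def snp(self, snp_id: str) -> SnpDef:
        for s in self.panel:
            if s.snp_id == snp_id:
                return s
        raise KeyError(f"SNP {snp_id!r} not in panel")

    def triads(self) -> list[FamilyRecord]:
        return [r for r in self.records if r.arm == CASE_TRIAD]

    def dyads(self) -> list[FamilyRecord]:
        return [r for r in self.records if r.arm == CONTROL_DYAD]


@dataclass(frozen=True)
class QcReport:
    """Per-SNP exclusion tally: missing-genotype and Mendelian-error families."""

    snp_id: str
    n_input_families: int
    n_excluded_missing: int
    n_excluded_mendel: int

    @property
    def n_retained(self) -> int:
        return self.n_input_families - self.n_excluded_missing - self.n_excluded_mendel


# ---------------------------------------------------------------------------
# Mendelian structure shared by the tabulations, the simulator and the
# log-linear likelihood.

#: The six unordered parental dose pairs.
MATING_TYPES: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def transmission_prob(gm: int, gf: int, gc: int) -> float:
    """P(child dose = gc | parental doses gm, gf) under Mendelian transmission.

    Each parent transmits one of their two alleles uniformly at random.
    """
    p = 0.0
    for tm in _transmissible(gm):
        for tf in _transmissible(gf):
            if tm + tf == gc:
                p += _transmit_prob(gm, tm) * _transmit_prob(gf, tf)
    return p


def _transmissible(g: int) -> tuple[int, ...]:
    return {0: (0,), 1: (0, 1), 2: (1,)}[g]


def _transmit_prob(g: int, allele: int) -> float:
    return 0.5 if g == 1 else 1.0


def _compatible_cells() -> tuple[tuple[int, int, int], ...]:
    return tuple(
        (gm, gf, gc)
        for gm, gf, gc in itertools.product(DOSES, DOSES, DOSES)
        if transmission_prob(gm, gf, gc) > 0
    )


#: The 15 Mendelian-compatible ordered (mother, father, child) dose cells.
TRIAD_CELLS: tuple[tuple[int, int, int], ...] = _compatible_cells()

#: The 7 mother-child dose cells compatible with some paternal genotype.
DYAD_CELLS: tuple[tuple[int, int], ...] = tuple(
    sorted({(gm, gc) for gm, _, gc in TRIAD_CELLS})
)


def mating_type(gm: int, gf: int) -> tuple[int, int]:
    """Unordered parental dose pair; symmetric in its arguments."""
    if gm not in DOSES or gf not in DOSES:
        raise UndefinedInputError(f"mating_type needs non-missing doses, got ({gm}, {gf})")
    return (gm, gf) if gm <= gf else (gf, gm)


def mating_weight(gm: int, gf: int) -> float:
    """Ordered-pair weight under mating symmetry.

    An unordered heterogeneous pair splits its mass over two ordered cells,
    so each ordered cell gets weight 1/2; an equal-genotype pair has a single
    ordered representative with weight 1.
    """
    return 1.0 if gm == gf else 0.5


def mendel_check(gm: int, gf: int, gc: int) -> bool:
    """True iff the child dose is producible from one allele of each parent."""
    for name, g in (("gm", gm), ("gf", gf), ("gc", gc)):
        if g not in DOSES:
            raise UndefinedInputError(f"mendel_check: {name}={g} is not a non-missing dose")
    return transmission_prob(gm, gf, gc) > 0


def mendel_check_dyad(gm: int, gc: int) -> bool:
    """True iff some paternal allele makes the mother-child pair consistent.

    With the father unobserved only the opposite-homozygote pairs
    (0,2) and (2,0) are detectable errors.
    """
    for name, g in (("gm", gm), ("gc", gc)):
        if g not in DOSES:
            raise UndefinedInputError(f"mendel_check_dyad: {name}={g} is not a non-missing dose")
    return (gm, gc) in DYAD_CELLS


def qc_filter(cohort: FamilyCohort, snp_id: str) -> tuple[FamilyCohort, QcReport]:
    """Per-SNP exclusion of incomplete and Mendelian-inconsistent families.

    Families with any MISSING member genotype at this SNP are dropped first;
    of the remainder, triads failing :func:`mendel_check` and dyads failing
    :func:`mendel_check_dyad` are dropped.  Filtering is per SNP: a family
    excluded here may be retained for another SNP's analyses.
    """
    cohort.snp(snp_id)  # raises KeyError for unknown SNP
    kept: list[FamilyRecord] = []
    n_missing = 0
    n_mendel = 0
    for rec in cohort.records:
        doses = rec.doses(snp_id)
        if MISSING in doses:
            n_missing += 1
            continue
        if rec.arm == CASE_TRIAD:
            ok = mendel_check(*doses)
        else:
            ok = mendel_check_dyad(*doses)
        if not ok:
            n_mendel += 1
            continue
        kept.append(rec)
    report = QcReport(
        snp_id=snp_id,
        n_input_families=len(cohort.records),
        n_excluded_missing=n_missing,
        n_excluded_mendel=n_mendel,
    )
    filtered = FamilyCohort(
        records=kept,
        panel=list(cohort.panel),
        provenance=cohort.provenance,
    )
    return filtered, report


def cohort_summary(cohort: FamilyCohort) -> dict[str, int]:
    """Counts of triads, dyads, subjects and the severity breakdown."""
    n_triads = len(cohort.triads())
    n_dyads = len(cohort.dyads())
    sev = {s: 0 for s in ("mPE", "sPE")}
    for rec in cohort.triads():
        sev[rec.severity] += 1
    return {
        "n_triads": n_triads,
        "n_dyads": n_dyads,
        "n_subjects": 3 * n_triads + 2 * n_dyads,
        "n_mPE": sev["mPE"],
        "n_sPE": sev["sPE"],
    }


# ---------------------------------------------------------------------------
# PED/MAP I/O.
#
# PLINK-style PED: 6 leading columns (family, individual, father, mother,
# sex, phenotype), then two whitespace-separated allele symbols per SNP in
# map order; "0" marks a missing allele.  The MAP file has three columns:
# snp_id, allele_ref, allele_var.  The phenotype column on the *mother* row
# carries severity: 1=control, 2=mPE, 3=sPE (configurable).

DEFAULT_PHENOTYPE_CODING = {"1": "control", "2": "mPE", "3": "sPE"}


def read_map(map_path) -> list[SnpDef]:
    panel = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 3:
                raise PedigreeFormatError(
                    f"{map_path}:{lineno}: expected 3 columns (snp_id ref var), got {len(fields)}"
                )
            panel.append(SnpDef(*fields))
    return panel


def write_map(panel: list[SnpDef], map_path) -> None:
    with open(map_path, "w") as fh:
        for s in panel:
            fh.write(f"{s.snp_id}\t{s.allele_ref}\t{s.allele_var}\n")


def _decode_genotype(a1: str, a2: str, snp: SnpDef, where: str) -> int:
    if a1 == "0" or a2 == "0":
        return MISSING
    dose = 0
    for a in (a1, a2):
        if a == snp.allele_var:
            dose += 1
        elif a != snp.allele_ref:
            raise PedigreeFormatError(
                f"{where}: allele {a!r} is neither "
                f"{snp.allele_ref!r} nor {snp.allele_var!r} for SNP {snp.snp_id}"
            )
    return dose


def read_pedigree(
    ped_path,
    map_path,
    phenotype_coding: dict[str, str] | None = None,
) -> FamilyCohort:
    """Read a PED + MAP pair into a :class:`FamilyCohort`.

    Family structure is inferred from the pedigree: a child row naming both
    parents makes a case triad; a child naming only a mother makes a control
    dyad.  A child with a father but no mother is a structure error.
    """
    coding = dict(DEFAULT_PHENOTYPE_CODING if phenotype_coding is None else phenotype_coding)
    panel = read_map(map_path)
    n_cols = 6 + 2 * len(panel)

    # family_id -> individual_id -> (father_id, mother_id, phenotype, doses)
    families: dict[str, dict[str, tuple[str, str, str, dict[str, int]]]] = {}
    order: list[str] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != n_cols:
                raise PedigreeFormatError(
                    f"{ped_path}:{lineno}: expected {n_cols} columns, got {len(fields)}"
                )
            fam_id, ind_id, fa_id, mo_id, _sex, pheno = fields[:6]
            doses = {}
            for i, snp in enumerate(panel):
                a1, a2 = fields[6 + 2 * i : 8 + 2 * i]
                doses[snp.snp_id] = _decode_genotype(a1, a2, snp, f"{ped_path}:{lineno}")
            fam = families.setdefault(fam_id, {})
            if fam_id not in order:
                order.append(fam_id)
            if ind_id in fam:
                raise PedigreeFormatError(f"{ped_path}:{lineno}: duplicate individual {ind_id!r}")
            fam[ind_id] = (fa_id, mo_id, pheno, doses)

    records = []
    for fam_id in order:
        members = families[fam_id]
        children = [(i, v) for i, v in members.items() if v[0] != "0" or v[1] != "0"]
        if len(children) != 1:
            raise PedigreeStructureError(
                f"family {fam_id}: expected exactly one child row, found {len(children)}"
            )
        child_id, (fa_id, mo_id, _, child_doses) = children[0]
        if mo_id == "0":
            raise PedigreeStructureError(f"family {fam_id}: child has a father but no mother")
        if mo_id not in members:
            raise PedigreeStructureError(f"family {fam_id}: mother {mo_id!r} has no row")
        mother_pheno = members[mo_id][2]
        if mother_pheno not in coding:
            raise PedigreeFormatError(
                f"family {fam_id}: mother phenotype {mother_pheno!r} not in coding {sorted(coding)}"
            )
        severity = coding[mother_pheno]
        genotypes = {"mother": members[mo_id][3], "child": child_doses}
        if fa_id != "0":
            if fa_id not in members:
                raise PedigreeStructureError(f"family {fam_id}: father {fa_id!r} has no row")
            genotypes["father"] = members[fa_id][3]
            arm = CASE_TRIAD
        else:
            arm = CONTROL_DYAD
        extra = set(members) - {child_id, mo_id} - ({fa_id} if fa_id != "0" else set())
        if extra:
            raise PedigreeStructureError(f"family {fam_id}: unexpected members {sorted(extra)}")
        records.append(
            FamilyRecord(family_id=fam_id, arm=arm, severity=severity, genotypes=genotypes)
        )
    return FamilyCohort(records=records, panel=panel, provenance=f"read from {ped_path}")


_SEVERITY_CODE = {"control": "1", "mPE": "2", "sPE": "3"}


def _encode_genotype(dose: int, snp: SnpDef) -> str:
    if dose == MISSING:
        return "0 0"
    return " ".join([snp.allele_ref] * (2 - dose) + [snp.allele_var] * dose)


def write_pedigree(cohort: FamilyCohort, ped_path, map_path) -> None:
    """Write a cohort in canonical PED/MAP form.

    Rows per family are mother, father (triads only), child, with ids
    ``<fam>-M``/``<fam>-F``/``<fam>-C``; sex coded 2/1/0, the mother row
    carrying the severity phenotype.  Reading the output back reproduces the
    cohort, and rewriting a file produced here is byte-identical.
    """
    write_map(cohort.panel, map_path)
    with open(ped_path, "w") as fh:
        for rec in cohort.records:
            fid = rec.family_id
            mother_id, father_id, child_id = f"{fid}-M", f"{fid}-F", f"{fid}-C"
            pheno = _SEVERITY_CODE[rec.severity]

            def row(ind_id, fa, mo, sex, ph, role):
                geno = " ".join(
                    _encode_genotype(rec.genotypes[role].get(s.snp_id, MISSING), s)
                    for s in cohort.panel
                )
                fh.write(f"{fid} {ind_id} {fa} {mo} {sex} {ph} {geno}\n")

            row(mother_id, "0", "0", "2", pheno, "mother")
            if rec.arm == CASE_TRIAD:
                row(father_id, "0", "0", "1", "1", "father")
                row(child_id, father_id, mother_id, "0", "1", "child")
            else:
                row(child_id, "0", mother_id, "0", "1", "child")


# ---------------------------------------------------------------------------
# Covariate table: delimited text keyed by family_id and role.


def read_covariates(path) -> pd.DataFrame:
    """Read the covariate table (TSV with 'family_id' and 'role' columns)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("family_id", "role"):
        if col not in df.columns:
            raise PedigreeFormatError(f"covariate table missing required column {col!r}")
    df["family_id"] = df["family_id"].astype(str)
    return df


def write_covariates(cohort: FamilyCohort, path) -> None:
    rows = []
    for rec in cohort.records:
        if rec.covariates:
            rows.append({"family_id": rec.family_id, "role": "mother", **rec.covariates})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def attach_covariates(cohort: FamilyCohort, covariates: pd.DataFrame) -> FamilyCohort:
    """Attach maternal covariates from the table onto the records (copy)."""
    by_fam = {
        str(row["family_id"]): {
            k: v for k, v in row.items() if k not in ("family_id", "role") and pd.notna(v)
        }
        for _, row in covariates.iterrows()
        if row["role"] == "mother"
    }
    records = [
        replace(rec, covariates={**rec.covariates, **by_fam.get(rec.family_id, {})})
        for rec in cohort.records
    ]
    return FamilyCohort(records=records, panel=list(cohort.panel), provenance=cohort.provenance)


def merge_cohorts(*cohorts: FamilyCohort, provenance: str = "merged") -> FamilyCohort:
    """Concatenate cohorts sharing an identical SNP panel."""
    if not cohorts:
        raise ValueError("need at least one cohort")
    panel = cohorts[0].panel
    for c in cohorts[1:]:
        if [s.snp_id for s in c.panel] != [s.snp_id for s in panel]:
            raise ValueError("cohorts have different SNP panels")
    records = [rec for c in cohorts for rec in c.records]
    return FamilyCohort(records=records, panel=list(panel), provenance=provenance)
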