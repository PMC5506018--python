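"""Data model, Mendelian checks, mating types, QC and pedigree round-trips."""

import itertools

import pytest

from triadkit.genodata import (
    DOSES,
    DYAD_CELLS,
    MISSING,
    TRIAD_CELLS,
    FamilyCohort,
    FamilyRecord,
    PedigreeFormatError,
    PedigreeStructureError,
    SnpDef,
    UndefinedInputError,
    cohort_summary,
    mating_type,
    mendel_check,
    mendel_check_dyad,
    qc_filter,
    read_pedigree,
    write_pedigree,
)


def _alleles(g):
    """Genotype dose as an explicit unordered allele pair (0=ref, 1=var)."""
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g]


def _oracle_mendel(gm, gf, gc):
    """Brute force over the four parental transmission pairs."""
    return any(
        am + af == gc for am in _alleles(gm) for af in _alleles(gf)
    )


class TestMendelChecks:
    def test_triad_truth_table_matches_enumeration(self):
        for gm, gf, gc in itertools.product(DOSES, repeat=3):
            assert mendel_check(gm, gf, gc) == _oracle_mendel(gm, gf, gc)

    def test_dyad_truth_table_matches_enumeration(self):
        for gm, gc in itertools.product(DOSES, repeat=2):
            oracle = any(_oracle_mendel(gm, gf, gc) for gf in DOSES)
            assert mendel_check_dyad(gm, gc) == oracle

    @pytest.mark.parametrize(
        "trio, ok",
        [((0, 0, 1), False), ((1, 1, 2), True), ((2, 2, 1), False), ((0, 2, 1), True)],
    )
    def test_spot_cases(self, trio, ok):
        assert mendel_check(*trio) is ok

    def test_dyad_spot_cases(self):
        assert not mendel_check_dyad(0, 2)
        assert not mendel_check_dyad(2, 0)
        assert mendel_check_dyad(2, 1)

    def test_symmetry_in_parents(self):
        for gm, gf, gc in itertools.product(DOSES, repeat=3):
            assert mendel_check(gm, gf, gc) == mendel_check(gf, gm, gc)

    def test_dyad_is_or_over_fathers(self):
        for gm, gc in itertools.product(DOSES, repeat=2):
            assert mendel_check_dyad(gm, gc) == any(
                mendel_check(gm, gf, gc) for gf in DOSES
            )

    def test_missing_dose_rejected(self):
        with pytest.raises(UndefinedInputError):
            mendel_check(MISSING, 0, 0)
        with pytest.raises(UndefinedInputError):
            mendel_check_dyad(0, MISSING)


class TestMatingTypes:
    def test_symmetric(self):
        for gm, gf in itertools.product(DOSES, repeat=2):
            assert mating_type(gm, gf) == mating_type(gf, gm)

    def test_six_categories(self):
        cats = {mating_type(gm, gf) for gm, gf in itertools.product(DOSES, repeat=2)}
        assert len(cats) == 6
        assert mating_type(2, 2) == (2, 2)

    def test_compatible_cell_counts(self):
        # 15 ordered Mendelian-compatible triad cells; 7 dyad cells
        assert len(TRIAD_CELLS) == 15
        assert len(DYAD_CELLS) == 7
        assert set(DYAD_CELLS) == {(0, 0), (0, 1), (1, 0), (1, 1), (1, 2), (2, 1), (2, 2)}


def _cohort(records):
    return FamilyCohort(records=records, panel=[SnpDef("SNP1", "A", "B")])


def _triad(fid, gm, gf, gc, severity="sPE"):
    return FamilyRecord(
        family_id=fid,
        arm="case_triad",
        severity=severity,
        genotypes={"mother": {"SNP1": gm}, "father": {"SNP1": gf}, "child": {"SNP1": gc}},
    )


class TestQcFilter:
    def test_clean_cohort_passes_unchanged(self):
        cohort = _cohort([_triad(f"f{i}", 1, 1, i % 3) for i in range(5)])
        filtered, report = qc_filter(cohort, "SNP1")
        assert len(filtered.records) == 5
        assert report.n_excluded_missing == report.n_excluded_mendel == 0
        assert report.n_retained == 5

    def test_exclusion_arithmetic(self):
        recs = [_triad(f"ok{i}", 1, 1, 1) for i in range(7)]
        recs += [_triad("m1", 1, MISSING, 1), _triad("m2", 0, MISSING, 0)]
        recs += [_triad("x1", 0, 0, 2)]  # Mendelian error
        filtered, report = qc_filter(_cohort(recs), "SNP1")
        assert report.n_input_families == 10
        assert report.n_excluded_missing == 2
        assert report.n_excluded_mendel == 1
        assert report.n_retained == 7 == len(filtered.records)

    def test_idempotent(self):
        recs = [_triad("a", 1, 1, 1), _triad("b", 0, 0, 1), _triad("c", 2, MISSING, 1)]
        once, _ = qc_filter(_cohort(recs), "SNP1")
        twice, rep2 = qc_filter(once, "SNP1")
        assert [r.family_id for r in twice.records] == [r.family_id for r in once.records]
        assert rep2.n_excluded_missing == rep2.n_excluded_mendel == 0

    def test_unknown_snp(self):
        with pytest.raises(KeyError):
            qc_filter(_cohort([_triad("a", 1, 1, 1)]), "nope")

    def test_counts_match_simulator_bookkeeping(self, null_cohort_with_truth):
        cfg, cohort, truth = null_cohort_with_truth
        _, report = qc_filter(cohort, "SNP1")
        assert report.n_excluded_missing == truth.n_missing_injected["SNP1"]
        # corrupted children may stay consistent by chance, and some are
        # hidden behind missingness: detected <= injected
        detectable = truth.corrupted_children["SNP1"] - truth.missing_families["SNP1"]
        assert 0 < report.n_excluded_mendel <= len(detectable)


class TestCohortSummary:
    def test_study_scale_arithmetic(self):
        recs = [_triad(f"c{i}", 1, 1, 1, "mPE" if i < 39 else "sPE") for i in range(256)]
        recs += [
            FamilyRecord(
                family_id=f"d{i}",
                arm="control_dyad",
                severity="control",
                genotypes={"mother": {"SNP1": 0}, "child": {"SNP1": 0}},
            )
            for i in range(360)
        ]
        s = cohort_summary(_cohort(recs))
        assert s["n_subjects"] == 1488
        assert s["n_mPE"] == 39 and s["n_sPE"] == 217
        assert s["n_mPE"] + s["n_sPE"] == s["n_triads"] == 256

    def test_empty(self):
        assert cohort_summary(_cohort([]))["n_subjects"] == 0


class TestPedigreeIO:
    def test_minimal_triad(self, tmp_path):
        (tmp_path / "t.map").write_text("SNP1\tI\tD\n")
        (tmp_path / "t.ped").write_text(
            "f1 f1-M 0 0 2 3 I D\n"
            "f1 f1-F 0 0 1 1 I I\n"
            "f1 f1-C f1-F f1-M 0 1 I D\n"
        )
        cohort = read_pedigree(tmp_path / "t.ped", tmp_path / "t.map")
        assert len(cohort.records) == 1
        rec = cohort.records[0]
        assert rec.arm == "case_triad" and rec.severity == "sPE"
        assert rec.doses("SNP1") == (1, 0, 1)
        assert cohort_summary(cohort)["n_subjects"] == 3

    def test_write_read_write_is_byte_identical(self, tmp_path, null_cohort_with_truth):
        _, cohort, _ = null_cohort_with_truth
        write_pedigree(cohort, tmp_path / "a.ped", tmp_path / "a.map")
        again = read_pedigree(tmp_path / "a.ped", tmp_path / "a.map")
        write_pedigree(again, tmp_path / "b.ped", tmp_path / "b.map")
        assert (tmp_path / "a.ped").read_bytes() == (tmp_path / "b.ped").read_bytes()
        assert (tmp_path / "a.map").read_bytes() == (tmp_path / "b.map").read_bytes()

    def test_roundtrip_preserves_structure(self, tmp_path, null_cohort_with_truth):
        _, cohort, _ = null_cohort_with_truth
        write_pedigree(cohort, tmp_path / "c.ped", tmp_path / "c.map")
        again = read_pedigree(tmp_path / "c.ped", tmp_path / "c.map")
        assert cohort_summary(again) == cohort_summary(cohort)
        for a, b in zip(cohort.records, again.records):
            assert a.doses("SNP1") == b.doses("SNP1")
            assert (a.arm, a.severity) == (b.arm, b.severity)

    def test_unknown_allele_is_format_error(self, tmp_path):
        (tmp_path / "t.map").write_text("SNP1\tI\tD\n")
        (tmp_path / "t.ped").write_text(
            "f1 f1-M 0 0 2 3 I X\n"
            "f1 f1-F 0 0 1 1 I I\n"
            "f1 f1-C f1-F f1-M 0 1 I D\n"
        )
        with pytest.raises(PedigreeFormatError, match="SNP1"):
            read_pedigree(tmp_path / "t.ped", tmp_path / "t.map")

    def test_father_without_mother_is_structure_error(self, tmp_path):
        (tmp_path / "t.map").write_text("SNP1\tA\tB\n")
        (tmp_path / "t.ped").write_text(
            "f1 f1-F 0 0 1 1 A A\n"
            "f1 f1-C f1-F 0 0 1 A B\n"
        )
        with pytest.raises(PedigreeStructureError):
            read_pedigree(tmp_path / "t.ped", tmp_path / "t.map")


class TestRecordValidation:
    def test_dyad_with_father_rejected(self):
        with pytest.raises(ValueError):
            FamilyRecord(
                family_id="x",
                arm="control_dyad",
                severity="control",
                genotypes={"mother": {}, "father": {}, "child": {}},
            )

    def test_case_triad_needs_case_severity(self):
        with pytest.raises(ValueError):
            _triad("x", 0, 0, 0, severity="control")

    def test_duplicate_family_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _cohort([_triad("a", 1, 1, 1), _triad("a", 0, 0, 0)])
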