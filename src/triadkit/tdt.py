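"""Transmission disequilibrium test on case-parent triads.

Each parent in a complete case triad contributes one (transmitted,
untransmitted) allele pair, inferred from the trio's doses.  Homozygous
parents fill the diagonal of the 2x2 transmission table (reported for
completeness); only the discordant off-diagonal counts b and c from
heterozygous parents are informative, and the test is McNemar's
(b - c)^2 / (b + c) on 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genodata import FamilyCohort, mendel_check

__all__ = ["TransmissionTable", "TdtResult", "tally_transmissions", "tdt_test"]

_REF, _VAR = 0, 1


@dataclass(frozen=True)
class TransmissionTable:
    """2x2 transmitted-by-untransmitted allele counts (index 0=ref, 1=var)."""

    snp_id: str
    counts: tuple[tuple[int, int], tuple[int, int]]

    @property
    def b(self) -> int:
        """Parents transmitting the reference allele over the variant."""
        return self.counts[_REF][_VAR]

    @property
    def c(self) -> int:
        """Parents transmitting the variant allele over the reference."""
        return self.counts[_VAR][_REF]

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))


@dataclass(frozen=True)
class TdtResult:
    b: int
    c: int
    statistic: float
    df: int
    p: float
    defined: bool


def _transmissible(g: int) -> tuple[int, ...]:
    return {0: (0,), 1: (0, 1), 2: (1,)}[g]


def _trio_pairs(gm: int, gf: int, gc: int) -> list[tuple[int, int]]:
    """(transmitted, untransmitted) pairs for the two parents of one trio.

    The doubly ambiguous configuration (both parents heterozygous, child
    heterozygous) has two allele-assignment resolutions, but both yield the
    same pair multiset {(ref, var), (var, ref)}, so the tally is
    well-defined.
    """
    solutions = sorted(
        {
            (tm, tf)
            for tm in _transmissible(gm)
            for tf in _transmissible(gf)
            if tm + tf == gc
        }
    )
    if not solutions:
        raise RuntimeError(
            f"Mendelian-inconsistent trio ({gm},{gf},{gc}) reached the TDT tally; "
            "run qc_filter first"
        )
    if len(solutions) == 1:
        tm, tf = solutions[0]
        return [(tm, gm - tm), (tf, gf - tf)]
    # both parents het, child het: one parent transmitted each allele
    return [(_REF, _VAR), (_VAR, _REF)]


def tally_transmissions(cohort: FamilyCohort, snp_id: str) -> TransmissionTable:
    """Tally parental transmissions over the QC-passed case triads."""
    counts = np.zeros((2, 2), dtype=int)
    for rec in cohort.triads():
        gm, gf, gc = rec.doses(snp_id)
        if not mendel_check(gm, gf, gc):
            raise RuntimeError(
                f"family {rec.family_id}: Mendelian-inconsistent trio at {snp_id}; "
                "run qc_filter first"
            )
        for t, u in _trio_pairs(gm, gf, gc):
            counts[t, u] += 1
    return TransmissionTable(snp_id=snp_id, counts=tuple(map(tuple, counts.tolist())))


def tdt_test(table: TransmissionTable | tuple[int, int]) -> TdtResult:
    """McNemar TDT on the discordant transmission counts (no correction)."""
    if isinstance(table, TransmissionTable):
        b, c = table.b, table.c
    else:
        b, c = table
    if b < 0 or c < 0:
        raise ValueError("negative discordant counts")
    if b + c == 0:
        return TdtResult(b=b, c=c, statistic=float("nan"), df=1, p=float("nan"), defined=False)
    statistic = (b - c) ** 2 / (b + c)
    return TdtResult(
        b=b,
        c=c,
        statistic=float(statistic),
        df=1,
        p=float(stats.chi2.sf(statistic, df=1)),
        defined=True,
    )
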