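"""Likelihood-ratio test for maternal gene-environment interaction.

Case-parent triads are split by a binary maternal exposure.  The full
model gives each exposure stratum its own mating-type frequencies and its
own maternal relative risks (S1, S2), with the fetal relative risks shared
across strata; the reduced model shares the maternal block too.  The LRT
statistic 2*(l_full - l_reduced) is referred to chi-squared on 2 df (the
two maternal interaction parameters).  When the test is significant,
stratum-specific triad-only fits report the maternal ORs separately per
stratum.  Control dyads do not enter: the interaction test is a pure
case-parent-triad analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import stats

from .genodata import FamilyCohort, FamilyRecord
from .loglinear import (
    LogLinearFit,
    TriadCellCounts,
    _Engine,
    _estimable_doses,
    _T_GC,
    _T_GM,
    build_cells,
    fit_triads,
)

__all__ = ["GxeResult", "dichotomize", "gxe_lrt", "stratified_fit"]


@dataclass(frozen=True)
class GxeResult:
    snp_id: str
    exposure: str
    statistic: float
    df: int
    p: float
    n_exposed: int
    n_unexposed: int
    loglik_full: float
    loglik_reduced: float
    stratified: dict[str, LogLinearFit] | None = None


def dichotomize(
    cohort: FamilyCohort, covariate: str, threshold: float, name: str | None = None
) -> FamilyCohort:
    """Add a binary maternal covariate ``name`` = 1 when covariate >= threshold."""
    name = name or f"{covariate}_ge_{threshold:g}"
    records = []
    for rec in cohort.records:
        cov = dict(rec.covariates)
        if covariate in cov and cov[covariate] is not None:
            cov[name] = int(float(cov[covariate]) >= threshold)
        records.append(_dc_replace(rec, covariates=cov))
    return FamilyCohort(records=records, panel=list(cohort.panel), provenance=cohort.provenance)


def _split_triads(
    cohort: FamilyCohort, exposure: str
) -> tuple[list[FamilyRecord], list[FamilyRecord]]:
    exposed, unexposed = [], []
    for rec in cohort.triads():
        if exposure not in rec.covariates or rec.covariates[exposure] is None:
            raise ValueError(f"family {rec.family_id}: exposure {exposure!r} missing")
        (exposed if int(rec.covariates[exposure]) == 1 else unexposed).append(rec)
    return exposed, unexposed


def _stratum_cells(
    cohort: FamilyCohort, records: list[FamilyRecord], snp_id: str, label: str
) -> TriadCellCounts:
    sub = FamilyCohort(records=records, panel=list(cohort.panel), provenance=cohort.provenance)
    cells, _ = build_cells(sub, snp_id)
    return TriadCellCounts(snp_id, cells.counts, stratum=label)


def gxe_lrt(
    cohort: FamilyCohort,
    snp_id: str,
    exposure: str,
    alpha: float = 0.05,
) -> GxeResult:
    """Maternal G-E interaction LRT on the QC-passed case triads.

    Requires the exposure to be a non-missing binary maternal covariate on
    every case triad.  When p < alpha the per-stratum triad-only fits are
    attached (otherwise ``stratified`` is None).
    """
    exposed, unexposed = _split_triads(cohort, exposure)
    for label, recs in (("exposed", exposed), ("unexposed", unexposed)):
        if not recs:
            raise ValueError(f"exposure stratum {label!r} has no informative case triads")
    cells = [
        _stratum_cells(cohort, unexposed, snp_id, "unexposed").counts,
        _stratum_cells(cohort, exposed, snp_id, "exposed").counts,
    ]
    pooled = cells[0] + cells[1]
    fetal = _estimable_doses(pooled, _T_GC)
    maternal = _estimable_doses(pooled, _T_GM)

    full = _Engine(cells, None, fetal, maternal, maternal_per_stratum=True)
    reduced = _Engine(cells, None, fetal, maternal, maternal_per_stratum=False)
    res_full = full.fit()
    res_reduced = reduced.fit()
    ll_full, ll_reduced = -res_full.fun, -res_reduced.fun
    chi2 = max(0.0, 2.0 * (ll_full - ll_reduced))
    p = float(stats.chi2.sf(chi2, 2))

    stratified = None
    if p < alpha:
        stratified = stratified_fit(cohort, snp_id, exposure)
    return GxeResult(
        snp_id=snp_id,
        exposure=exposure,
        statistic=float(chi2),
        df=2,
        p=p,
        n_exposed=len(exposed),
        n_unexposed=len(unexposed),
        loglik_full=float(ll_full),
        loglik_reduced=float(ll_reduced),
        stratified=stratified,
    )


def stratified_fit(
    cohort: FamilyCohort, snp_id: str, exposure: str
) -> dict[str, LogLinearFit]:
    """Triad-only log-linear fit within each exposure stratum.

    Returns {'unexposed': fit, 'exposed': fit}; each fit carries the
    per-genotype maternal ORs with Wald CIs and the 2-df maternal block p.
    """
    exposed, unexposed = _split_triads(cohort, exposure)
    fits = {}
    for label, recs in (("unexposed", unexposed), ("exposed", exposed)):
        if not recs:
            raise ValueError(f"exposure stratum {label!r} has no informative case triads")
        fits[label] = fit_triads(_stratum_cells(cohort, recs, snp_id, label))
    return fits
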