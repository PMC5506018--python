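"""Single-locus case-control tests, HWE, descriptive comparisons, FDR.

Implements the test-selection convention of classical genetic-epidemiology
reporting: Pearson's chi-squared by default, replaced by a Monte-Carlo
p-value when more than 20% of expected cell frequencies fall in [1, 5), and
by Fisher's exact probability when any expected frequency is below 1 (for
2x2 tables Fisher also replaces the Monte-Carlo branch).  Genotype effects
are summarized under dominant (carrier vs non-carrier) and recessive
(homozygous variant vs rest) collapsings with Woolf confidence intervals,
and p-values are adjusted by the Benjamini-Hochberg step-up FDR procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genodata import CASE_TRIAD, MISSING, FamilyCohort

__all__ = [
    "GenotypeCountTable",
    "OrResult",
    "ContingencyResult",
    "hwe_test",
    "contingency_test",
    "fisher_exact_2x2",
    "model_or",
    "bh_fdr",
    "genotype_counts",
    "describe_cohort",
]


@dataclass(frozen=True)
class GenotypeCountTable:
    """Case/control genotype dose counts (0/1/2) with derived allele counts."""

    snp_id: str
    case: tuple[int, int, int]
    control: tuple[int, int, int]

    def allele_counts(self, group: str) -> tuple[int, int]:
        """(reference, variant) allele counts for 'case' or 'control'."""
        n0, n1, n2 = getattr(self, group)
        return (2 * n0 + n1, n1 + 2 * n2)


@dataclass(frozen=True)
class ContingencyResult:
    p: float
    method: str  # 'pearson', 'monte_carlo', or 'fisher'
    statistic: float | None = None


@dataclass(frozen=True)
class OrResult:
    """Odds ratio under a genotype collapsing; undefined when a cell is 0."""

    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float
    model: str
    method: str
    defined: bool


def hwe_test(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Goodness-of-fit chi-squared for Hardy-Weinberg proportions (1 df).

    Expected counts come from the sample allele frequency; returns
    (statistic, p).  A monomorphic sample has no test: (nan, nan).
    """
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("hwe_test needs a non-empty sample")
    q = (n1 + 2 * n2) / (2 * n)
    if q in (0.0, 1.0):
        return (float("nan"), float("nan"))
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
    stat = float(((np.array(counts) - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def _expected_cells(table: np.ndarray) -> np.ndarray:
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    return np.outer(row, col) / table.sum()


def contingency_test(
    table,
    mc_reps: int = 10_000,
    seed: int = 0,
) -> ContingencyResult:
    """R x C association test with sparse-cell substitution.

    Pearson chi-squared without continuity correction by default; a
    Monte-Carlo p-value (random tables with fixed margins) when >20% of
    expected frequencies lie in [1, 5); Fisher's exact probability when any
    expected frequency is <1.  For 2x2 tables Fisher replaces both
    substitution branches.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (table < 0).any():
        raise ValueError("negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")

    expected = _expected_cells(table)
    any_below_1 = bool((expected < 1).any())
    frac_sparse = float(((expected >= 1) & (expected < 5)).mean())
    is_2x2 = table.shape == (2, 2)

    if any_below_1 or (is_2x2 and frac_sparse > 0.2):
        if is_2x2:
            a, b, c, d = table.astype(int).ravel()
            return ContingencyResult(p=fisher_exact_2x2(a, b, c, d), method="fisher")
        # exact r x c test is impractical in general; fall through to MC
        return _monte_carlo_p(table, mc_reps, seed)
    if frac_sparse > 0.2:
        return _monte_carlo_p(table, mc_reps, seed)

    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ContingencyResult(p=float(p), method="pearson", statistic=float(stat))


def _pearson_stat(table: np.ndarray) -> float:
    expected = _expected_cells(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = (table - expected) ** 2 / expected
    return float(np.nansum(cells))


def _monte_carlo_p(table: np.ndarray, reps: int, seed: int) -> ContingencyResult:
    """Monte-Carlo p: chi-squared rank among random fixed-margin tables."""
    obs = _pearson_stat(table)
    sampler = stats.random_table(table.sum(axis=1).astype(int), table.sum(axis=0).astype(int))
    sims = sampler.rvs(reps, random_state=np.random.default_rng(seed))
    sim_stats = np.array([_pearson_stat(t) for t in sims])
    p = (1 + np.sum(sim_stats >= obs - 1e-9)) / (reps + 1)
    return ContingencyResult(p=float(p), method="monte_carlo", statistic=obs)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric point probabilities of all tables with the same
    margins whose probability does not exceed the observed table's (ties
    within a relative tolerance of 1e-7 are included).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("negative counts")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    dist = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def model_or(
    case_counts: tuple[int, int, int],
    control_counts: tuple[int, int, int],
    model: str,
    mc_reps: int = 10_000,
    seed: int = 0,
) -> OrResult:
    """Dominant/recessive-model odds ratio with Woolf 95% CI.

    Collapses the three genotype classes to a 2x2 table — dominant: variant
    carriers vs homozygous reference; recessive: homozygous variant vs the
    rest — then reports the cross-product OR, the log-OR normal (Woolf)
    interval, and a p-value from :func:`contingency_test` on the collapsed
    table.  Any zero cell makes the OR undefined (rendered "-" in reports);
    the p-value is still returned.
    """
    if model == "dominant":
        collapse = lambda n: (n[1] + n[2], n[0])  # noqa: E731 - (at-risk, reference)
    elif model == "recessive":
        collapse = lambda n: (n[2], n[0] + n[1])  # noqa: E731
    else:
        raise ValueError(f"unknown model {model!r}")
    a, b = collapse(case_counts)
    c, d = collapse(control_counts)
    res = contingency_test([[a, b], [c, d]], mc_reps=mc_reps, seed=seed)
    if min(a, b, c, d) == 0:
        return OrResult(None, None, None, res.p, model, res.method, defined=False)
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) + np.array([-1, 1]) * 1.959963984540054 * se)
    return OrResult(float(or_), float(lo), float(hi), res.p, model, res.method, defined=True)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genotype_counts(cohort: FamilyCohort, snp_id: str, role: str) -> GenotypeCountTable:
    """Tabulate dose counts for one role, case families vs control families."""
    case = [0, 0, 0]
    control = [0, 0, 0]
    for rec in cohort.records:
        dose = rec.genotypes.get(role, {}).get(snp_id, MISSING)
        if dose == MISSING:
            continue
        (case if rec.arm == CASE_TRIAD else control)[dose] += 1
    return GenotypeCountTable(snp_id=snp_id, case=tuple(case), control=tuple(control))


def describe_cohort(
    cohort: FamilyCohort,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    mc_reps: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Case/control covariate comparison table.

    Continuous covariates get mean +/- SD per group and an equal-variance
    two-sample t-test; categorical covariates get per-level counts and a
    :func:`contingency_test` p.  Covariates named in neither list are
    classified by dtype.  All-missing covariates are dropped with a warning
    column rather than an error.
    """
    rows = []
    df = pd.DataFrame(
        [
            {"__group__": "case" if r.arm == CASE_TRIAD else "control", **r.covariates}
            for r in cohort.records
        ]
    )
    if df.empty or df.shape[1] <= 1:
        return pd.DataFrame(
            columns=["covariate", "kind", "case_summary", "control_summary", "statistic", "p", "method"]
        )
    continuous = list(continuous or [])
    categorical = list(categorical or [])
    for name in [c for c in df.columns if c != "__group__"]:
        series = df[name]
        if series.dropna().empty:
            continue
        if name in continuous:
            kind = "continuous"
        elif name in categorical:
            kind = "categorical"
        else:
            kind = "continuous" if pd.api.types.is_float_dtype(series) else "categorical"
        case = series[df["__group__"] == "case"].dropna()
        ctrl = series[df["__group__"] == "control"].dropna()
        if kind == "continuous":
            t, p = stats.ttest_ind(case, ctrl, equal_var=True)
            rows.append(
                {
                    "covariate": name,
                    "kind": kind,
                    "case_summary": f"{case.mean():.2f} ± {case.std(ddof=1):.2f}",
                    "control_summary": f"{ctrl.mean():.2f} ± {ctrl.std(ddof=1):.2f}",
                    "statistic": float(t),
                    "p": float(p),
                    "method": "t",
                }
            )
        else:
            levels = sorted(series.dropna().unique().tolist())
            table = [[int((grp == lev).sum()) for lev in levels] for grp in (case, ctrl)]
            res = contingency_test(table, mc_reps=mc_reps, seed=seed)
            fmt = lambda counts: ", ".join(f"{lev}:{n}" for lev, n in zip(levels, counts))  # noqa: E731
            rows.append(
                {
                    "covariate": name,
                    "kind": kind,
                    "case_summary": fmt(table[0]),
                    "control_summary": fmt(table[1]),
                    "statistic": res.statistic,
                    "p": res.p,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)
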