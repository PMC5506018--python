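"""Hybrid-design log-linear likelihood for maternal and fetal relative risks.

The model jointly analyses case-parent triads and control-mother dyads.
Case-triad probability over the 15 Mendelian-compatible ordered
(mother, father, child) dose cells is

    P(gm, gf, gc | case)  prop.to  mu_{M(gm,gf)} * w(gm,gf) * T(gc|gm,gf)
                                   * R_{gc} * S_{gm}

where mu are the six mating-type frequencies (shared across arms, simplex
constrained), w the ordered-pair weight under mating symmetry, T Mendelian
transmission, and R/S the fetal/maternal genotype relative risks (dose 0 is
the reference).  Control-dyad probability over the 7 mother-child cells
marginalizes the unobserved father analytically with all relative risks at
1 — the rare-disease assumption: controls represent the source population.

Both arms contribute multinomial likelihoods with totals fixed by design;
maximization is quasi-Newton on unconstrained parameters (log relative
risks; multinomial logits of mu), covariance from the inverse observed
information, and each parameter block (fetal R1=R2=1; maternal S1=S2=1)
gets a 2-df likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from .genodata import (
    DOSES,
    DYAD_CELLS,
    MATING_TYPES,
    TRIAD_CELLS,
    FamilyCohort,
    mating_type,
    mating_weight,
    transmission_prob,
)

__all__ = [
    "TriadCellCounts",
    "DyadCellCounts",
    "HybridModelSpec",
    "LrtResult",
    "OrEntry",
    "LogLinearFit",
    "build_cells",
    "cell_probabilities",
    "hybrid_loglik",
    "fit_hybrid",
    "fit_triads",
    "subtype_fits",
]

_Z95 = 1.959963984540054

_MT_INDEX = {mt: i for i, mt in enumerate(MATING_TYPES)}
_T_MT = np.array([_MT_INDEX[mating_type(gm, gf)] for gm, gf, _ in TRIAD_CELLS])
_T_BASE = np.array(
    [mating_weight(gm, gf) * transmission_prob(gm, gf, gc) for gm, gf, gc in TRIAD_CELLS]
)
_T_GM = np.array([gm for gm, _, _ in TRIAD_CELLS])
_T_GC = np.array([gc for _, _, gc in TRIAD_CELLS])

# dyad cell j gets sum over fathers of mu[mt] * w * T: a 7 x 6 matrix
_D_MAT = np.zeros((len(DYAD_CELLS), len(MATING_TYPES)))
for _j, (_gm, _gc) in enumerate(DYAD_CELLS):
    for _gf in DOSES:
        _D_MAT[_j, _MT_INDEX[mating_type(_gm, _gf)]] += mating_weight(
            _gm, _gf
        ) * transmission_prob(_gm, _gf, _gc)


@dataclass(frozen=True)
class TriadCellCounts:
    """Counts over the 15 compatible ordered triad cells (may be expected
    counts, hence float)."""

    snp_id: str
    counts: np.ndarray
    stratum: str | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (len(TRIAD_CELLS),):
            raise ValueError(f"expected {len(TRIAD_CELLS)} triad cells, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("negative cell counts")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class DyadCellCounts:
    """Counts over the 7 compatible mother-child dyad cells."""

    snp_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (len(DYAD_CELLS),):
            raise ValueError(f"expected {len(DYAD_CELLS)} dyad cells, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("negative cell counts")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class HybridModelSpec:
    """Which relative-risk blocks are active (reference dose is always 0)."""

    fetal: bool = True
    maternal: bool = True


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class OrEntry:
    """exp(log-RR) point estimate with Wald 95% CI; undefined when the data
    carry no information on the parameter (zero support)."""

    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    defined: bool


@dataclass
class LogLinearFit:
    """MLEs, Wald intervals and block LRTs from the hybrid likelihood."""

    snp_id: str
    estimates: dict[str, float]
    std_errors: dict[str, float]
    mu: np.ndarray
    loglik: float
    or_fetal: dict[int, OrEntry]
    or_maternal: dict[int, OrEntry]
    lrt: dict[str, LrtResult] = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    grad_norm: float = float("nan")

    def odds_ratio(self, block: str, dose: int) -> OrEntry:
        return (self.or_fetal if block == "fetal" else self.or_maternal)[dose]


def build_cells(cohort: FamilyCohort, snp_id: str) -> tuple[TriadCellCounts, DyadCellCounts]:
    """Cross-classify QC-passed case triads and control dyads into cells."""
    t_index = {cell: i for i, cell in enumerate(TRIAD_CELLS)}
    d_index = {cell: i for i, cell in enumerate(DYAD_CELLS)}
    t_counts = np.zeros(len(TRIAD_CELLS))
    d_counts = np.zeros(len(DYAD_CELLS))
    for rec in cohort.triads():
        cell = rec.doses(snp_id)
        if cell not in t_index:
            raise RuntimeError(
                f"family {rec.family_id}: incompatible trio {cell} at {snp_id}; run qc_filter first"
            )
        t_counts[t_index[cell]] += 1
    for rec in cohort.dyads():
        cell = rec.doses(snp_id)
        if cell not in d_index:
            raise RuntimeError(
                f"family {rec.family_id}: incompatible dyad {cell} at {snp_id}; run qc_filter first"
            )
        d_counts[d_index[cell]] += 1
    return TriadCellCounts(snp_id, t_counts), DyadCellCounts(snp_id, d_counts)


def _softmax_mu(logits: np.ndarray) -> np.ndarray:
    z = np.concatenate([[0.0], logits])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def cell_probabilities(
    lnR: np.ndarray, lnS: np.ndarray, mu: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Model cell probabilities for given log-RRs (length-3, index = dose,
    entry 0 must be 0) and mating-type frequencies mu (length 6, simplex)."""
    t = mu[_T_MT] * _T_BASE * np.exp(lnR[_T_GC] + lnS[_T_GM])
    d = _D_MAT @ mu
    return t / t.sum(), d / d.sum()


def hybrid_loglik(
    triad_counts: np.ndarray,
    dyad_counts: np.ndarray | None,
    lnR: np.ndarray,
    lnS: np.ndarray,
    mu: np.ndarray,
) -> float:
    """Joint multinomial log-likelihood of the two arms (up to the
    multinomial coefficients, which do not depend on parameters)."""
    tp, dp = cell_probabilities(np.asarray(lnR, float), np.asarray(lnS, float), np.asarray(mu, float))
    with np.errstate(divide="ignore"):
        ll = float(np.where(triad_counts > 0, triad_counts * np.log(tp), 0.0).sum())
        if dyad_counts is not None:
            ll += float(np.where(dyad_counts > 0, dyad_counts * np.log(dp), 0.0).sum())
    return ll


# ---------------------------------------------------------------------------
# Internal parametrized likelihood engine.
#
# Supports K triad strata (stratum-specific mu; maternal log-RRs either
# shared or per stratum; fetal log-RRs shared) plus an optional dyad arm
# tied to stratum 0's mu.  The hybrid fit is the K=1 case.


@dataclass
class _Engine:
    triad_counts: list[np.ndarray]
    dyad_counts: np.ndarray | None
    free_fetal: tuple[int, ...]
    free_maternal: tuple[int, ...]
    maternal_per_stratum: bool = False

    def __post_init__(self) -> None:
        self.K = len(self.triad_counts)
        self.names: list[str] = [f"lnR{g}" for g in self.free_fetal]
        self._fetal_slots = {g: i for i, g in enumerate(self.free_fetal)}
        self._maternal_slots: dict[tuple[int, int], int] = {}
        if self.maternal_per_stratum:
            for k in range(self.K):
                for g in self.free_maternal:
                    self._maternal_slots[(k, g)] = len(self.names)
                    self.names.append(f"lnS{g}[{k}]")
        else:
            for g in self.free_maternal:
                slot = len(self.names)
                self.names.append(f"lnS{g}")
                for k in range(self.K):
                    self._maternal_slots[(k, g)] = slot
        self._mu_slots: dict[int, int] = {}
        for k in range(self.K):
            self._mu_slots[k] = len(self.names)
            self.names += [f"mu{j}[{k}]" for j in range(1, len(MATING_TYPES))]
        self.n_params = len(self.names)
        self._n_mu = len(MATING_TYPES) - 1

    def unpack(self, theta: np.ndarray):
        pos = 0
        lnR = np.zeros(3)
        for g in self.free_fetal:
            lnR[g] = theta[pos]
            pos += 1
        lnS_list = []
        if self.maternal_per_stratum:
            for _k in range(self.K):
                lnS = np.zeros(3)
                for g in self.free_maternal:
                    lnS[g] = theta[pos]
                    pos += 1
                lnS_list.append(lnS)
        else:
            lnS = np.zeros(3)
            for g in self.free_maternal:
                lnS[g] = theta[pos]
                pos += 1
            lnS_list = [lnS] * self.K
        mus = []
        for _k in range(self.K):
            mus.append(_softmax_mu(theta[pos : pos + self._n_mu]))
            pos += self._n_mu
        return lnR, lnS_list, mus

    def loglik(self, theta: np.ndarray) -> float:
        lnR, lnS_list, mus = self.unpack(theta)
        ll = 0.0
        for k in range(self.K):
            ll += hybrid_loglik(
                self.triad_counts[k],
                self.dyad_counts if k == 0 else None,
                lnR,
                lnS_list[k],
                mus[k],
            )
        return ll

    def nll_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative log-likelihood with its analytic gradient.

        For a multinomial with cell weights u_i(theta), d ll = sum_i
        (n_i - N p_i) d log u_i; the softmax parametrization of mu makes the
        mu-logit gradient the residual summed within each mating type.
        """
        lnR, lnS_list, mus = self.unpack(theta)
        ll = 0.0
        grad = np.zeros(self.n_params)
        for k in range(self.K):
            n = self.triad_counts[k]
            mu = mus[k]
            u = mu[_T_MT] * _T_BASE * np.exp(lnR[_T_GC] + lnS_list[k][_T_GM])
            p = u / u.sum()
            with np.errstate(divide="ignore"):
                ll += float(np.where(n > 0, n * np.log(p), 0.0).sum())
            resid = n - n.sum() * p
            for g, slot in self._fetal_slots.items():
                grad[slot] += resid[_T_GC == g].sum()
            for g in self.free_maternal:
                grad[self._maternal_slots[(k, g)]] += resid[_T_GM == g].sum()
            base = self._mu_slots[k]
            for j in range(1, len(MATING_TYPES)):
                grad[base + j - 1] += resid[_T_MT == j].sum()
            if k == 0 and self.dyad_counts is not None:
                m = self.dyad_counts
                ud = _D_MAT @ mu
                pd = ud / ud.sum()
                with np.errstate(divide="ignore"):
                    ll += float(np.where(m > 0, m * np.log(pd), 0.0).sum())
                resid_d = m - m.sum() * pd
                # d log u_j / d a_k = mu_k (D[j,k]/u_j - 1); the -1 part
                # cancels since the residuals sum to zero
                contrib = (resid_d / ud) @ _D_MAT  # length 6
                grad[base : base + self._n_mu] += (mu * contrib)[1:]
        return -ll, -grad

    def fit(self):
        x0 = np.zeros(self.n_params)
        # warm-start the mating-type logits from the observed margins
        for k in range(self.K):
            mtc = np.array(
                [self.triad_counts[k][_T_MT == j].sum() for j in range(len(MATING_TYPES))]
            )
            if k == 0 and self.dyad_counts is not None:
                dyad_tot = self.dyad_counts.sum()
                if dyad_tot > 0:
                    mt_share = _D_MAT / _D_MAT.sum(axis=1, keepdims=True)
                    mtc = mtc + self.dyad_counts @ mt_share
            mtc = mtc + 0.5
            base = self._mu_slots[k]
            x0[base : base + self._n_mu] = np.log(mtc[1:] / mtc[0])
        res = optimize.minimize(
            self.nll_and_grad,
            x0,
            method="BFGS",
            jac=True,
            options={"gtol": 1e-9, "maxiter": 500},
        )
        # BFGS frequently stops with a precision-loss flag essentially at the
        # optimum; judge convergence by the analytic gradient at the final
        # point (relative to the data scale), polishing once if needed.
        scale = max(1.0, max(float(t.sum()) for t in self.triad_counts))
        if not res.success and np.linalg.norm(self.nll_and_grad(res.x)[1]) > 1e-6 * scale:
            res2 = optimize.minimize(
                self.nll_and_grad, res.x, method="L-BFGS-B", jac=True,
                options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 1000},
            )
            if res2.fun <= res.fun:
                res = res2
        res.final_grad_norm = float(np.linalg.norm(self.nll_and_grad(res.x)[1]))
        res.converged = bool(res.success or res.final_grad_norm <= 1e-6 * scale)
        return res

    def covariance(self, theta: np.ndarray) -> np.ndarray:
        if self.n_params == 0:
            return np.zeros((0, 0))
        hess = approx_hess(theta, lambda th: -self.loglik(th))
        try:
            return np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            # ridge fallback for an ill-conditioned observed information
            return np.linalg.inv(hess + 1e-8 * np.eye(self.n_params))


def _estimable_doses(counts: np.ndarray, by: np.ndarray) -> tuple[int, ...]:
    """Doses in {1, 2} with positive count support, given positive reference
    support; otherwise the corresponding log-RR is not identified."""
    support = {g: counts[by == g].sum() for g in DOSES}
    if support[0] <= 0:
        return ()
    return tuple(g for g in (1, 2) if support[g] > 0)


class NonConvergenceError(RuntimeError):
    pass


def _or_entries(
    engine: _Engine, theta: np.ndarray, cov: np.ndarray, prefix: str, active: tuple[int, ...]
) -> dict[int, OrEntry]:
    entries: dict[int, OrEntry] = {}
    for g in (1, 2):
        name = f"{prefix}{g}"
        if name in engine.names and g in active:
            i = engine.names.index(name)
            est = theta[i]
            var = cov[i, i] if cov.size else np.nan
            se = np.sqrt(var) if var > 0 else np.nan
            entries[g] = OrEntry(
                float(np.exp(est)),
                float(np.exp(est - _Z95 * se)),
                float(np.exp(est + _Z95 * se)),
                defined=True,
            )
        else:
            entries[g] = OrEntry(None, None, None, defined=False)
    return entries


def _fit_counts(
    triads: TriadCellCounts,
    dyads: DyadCellCounts | None,
    spec: HybridModelSpec,
) -> LogLinearFit:
    tc = triads.counts
    dc = dyads.counts if dyads is not None else None
    if tc.sum() <= 0:
        raise ValueError("no case triads to fit")
    fetal_doses = _estimable_doses(tc, _T_GC) if spec.fetal else ()
    maternal_doses = _estimable_doses(tc, _T_GM) if spec.maternal else ()

    full = _Engine([tc], dc, fetal_doses, maternal_doses)
    res = full.fit()
    grad_norm = res.final_grad_norm
    if not res.converged:
        raise NonConvergenceError(
            f"optimizer failed after {res.nit} iterations: {res.message} (|grad|={grad_norm:.3g})"
        )
    theta = res.x
    cov = full.covariance(theta)
    lnR, lnS_list, mus = full.unpack(theta)
    loglik = -res.fun

    fit = LogLinearFit(
        snp_id=triads.snp_id,
        estimates=dict(zip(full.names, map(float, theta))),
        std_errors={
            n: float(np.sqrt(cov[i, i])) if cov.size and cov[i, i] > 0 else float("nan")
            for i, n in enumerate(full.names)
        },
        mu=mus[0],
        loglik=loglik,
        or_fetal=_or_entries(full, theta, cov, "lnR", fetal_doses),
        or_maternal=_or_entries(full, theta, cov, "lnS", maternal_doses),
        converged=True,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
    )

    # block LRTs against the full model, always on 2 df
    for block, doses_here in (("fetal", fetal_doses), ("maternal", maternal_doses)):
        if not (spec.fetal if block == "fetal" else spec.maternal):
            continue
        null = _Engine(
            [tc],
            dc,
            () if block == "fetal" else fetal_doses,
            () if block == "maternal" else maternal_doses,
        )
        res0 = null.fit()
        chi2 = max(0.0, 2.0 * (loglik - (-res0.fun)))
        fit.lrt[block] = LrtResult(chi2, 2, float(stats.chi2.sf(chi2, 2)))
    return fit


def fit_hybrid(
    triads: TriadCellCounts,
    dyads: DyadCellCounts,
    spec: HybridModelSpec | None = None,
) -> LogLinearFit:
    """Maximize the joint triad + dyad multinomial likelihood.

    Returns relative-risk MLEs with Wald 95% CIs, the shared mating-type
    frequency estimates, and 2-df block LRTs (fetal: R1=R2=1; maternal:
    S1=S2=1).  A genotype class absent from the case triads leaves its
    relative risk undefined (reported as a blank entry, not an error).
    """
    return _fit_counts(triads, dyads, spec or HybridModelSpec())


def fit_triads(triads: TriadCellCounts, spec: HybridModelSpec | None = None) -> LogLinearFit:
    """Classic case-parent-triad log-linear fit (no control arm)."""
    return _fit_counts(triads, None, spec or HybridModelSpec())


def subtype_fits(
    cohort: FamilyCohort, snp_id: str, subtype: str
) -> LogLinearFit:
    """Refit the hybrid model using only case triads of one severity
    subtype against all control dyads."""
    from .genodata import FamilyCohort as _FC  # local alias for clarity

    sub = [r for r in cohort.triads() if r.severity == subtype]
    if not sub:
        raise ValueError(f"no case triads with severity {subtype!r}")
    sub_cohort = _FC(
        records=sub + cohort.dyads(), panel=list(cohort.panel), provenance=cohort.provenance
    )
    triad_cells, dyad_cells = build_cells(sub_cohort, snp_id)
    triad_cells = TriadCellCounts(snp_id, triad_cells.counts, stratum=subtype)
    return fit_hybrid(triad_cells, dyad_cells)
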