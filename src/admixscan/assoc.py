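"""Case-control association testing under an ordered-FWER plan.

Candidate sites produced by a selection scan arrive *ranked*.  Instead
of a flat Bonferroni correction, the familywise error rate over the n
ordered tests is controlled by assigning rank k the significance
threshold d/k, where the constant d solves

    prod_{k=1..n} (1 - d/k) = 1 - alpha.

For independent p-values this product is exactly the probability of no
false rejection, so the procedure holds FWER at alpha while spending
most of the budget on the top-ranked (most trusted) candidates.

Per-site effects come from an additive logistic model: case status ~
derived-allele dosage + covariates, fitted by iteratively reweighted
least squares, with Wald p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm as _norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "OrderedPlan",
    "AssocResult",
    "solve_d",
    "ordered_plan",
    "apply_ordered_fwer",
    "fit_logistic_additive",
    "assoc_scan",
    "DegeneratePhenotypeError",
    "DegeneratePredictorError",
]


class DegeneratePhenotypeError(ValueError):
    """Phenotype contains a single class; no association model exists."""


class DegeneratePredictorError(ValueError):
    """Genotype dosage is constant; its effect is not identifiable."""


def solve_d(alpha=0.05, n=10, tol=1e-12):
    """Solve prod_{k=1..n}(1 - d/k) = 1 - alpha for d on (0, 1).

    The product is strictly decreasing in d, so plain bisection finds
    the unique root; iteration stops when the residual is below
    ``tol``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n < 1:
        raise ValueError("need at least one ordered test")
    k = np.arange(1, n + 1, dtype=float)

    def resid(d):
        return float(np.prod(1.0 - d / k) - (1.0 - alpha))

    lo, hi = 0.0, 1.0 - 1e-15
    if resid(lo) <= 0 or resid(hi) >= 0:
        raise RuntimeError("no sign change on (0, 1); cannot bracket d")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = resid(mid)
        if abs(r) < tol:
            return mid
        if r > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class OrderedPlan:
    """Solved ordered-FWER testing plan.

    ``thresholds[i]`` is the significance level for rank ``i + 1``,
    i.e. d/(i+1); thresholds decrease strictly with rank.
    """

    alpha: float
    n: int
    d: float
    thresholds: np.ndarray
    ranked_ids: list = field(default_factory=list)


def ordered_plan(alpha=0.05, n=10, ranked_ids=None):
    """Build an :class:`OrderedPlan` for ``n`` ordered tests at level alpha."""
    d = solve_d(alpha, n)
    thresholds = d / np.arange(1, n + 1, dtype=float)
    return OrderedPlan(alpha=alpha, n=n, d=d, thresholds=thresholds,
                       ranked_ids=list(ranked_ids) if ranked_ids is not None else [])


def apply_ordered_fwer(plan, p_values):
    """Reject rank k iff p_k <= d/k.

    Each rank is tested against its own threshold with no sequential
    gating; a p-value exactly equal to its threshold is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.shape[-1] != plan.n:
        raise ValueError(f"expected {plan.n} ordered p-values, got {p.shape[-1]}")
    return p <= plan.thresholds


@dataclass
class AssocResult:
    site_id: str
    effect: float        # log-odds per derived-allele copy
    se: float
    p: float
    converged: bool
    rank: int | None = None
    covariates: tuple = ()


def fit_logistic_additive(dosage, phenotype, covariates=None, max_iter=50,
                          tol=1e-8, site_id=""):
    """Additive logistic association of case status on allele dosage.

    Parameters
    ----------
    dosage : array-like of {0, 1, 2}
        Derived-allele counts per individual (missing as NaN; those
        individuals are dropped).
    phenotype : array-like of {0, 1}
        Case status.
    covariates : DataFrame or 2-D array, optional
        Adjustment covariates, one column per covariate.

    Returns
    -------
    AssocResult
        Wald test of the dosage effect against the standard normal.
        On complete separation the fit is flagged unconverged and the
        p-value is NaN.
    """
    dosage = np.asarray(dosage, dtype=float)
    phen = np.asarray(phenotype, dtype=float)
    mask = ~np.isnan(dosage)
    dosage, phen = dosage[mask], phen[mask]

    if phen.min() == phen.max():
        raise DegeneratePhenotypeError(
            "phenotype has a single class; cannot fit a case-control model")
    if dosage.min() == dosage.max():
        raise DegeneratePredictorError(
            f"dosage is constant at site {site_id or '<unnamed>'}")

    cov_names: tuple = ()
    X = dosage[:, None]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        cov_names = tuple(str(c) for c in cov.columns)
        X = np.column_stack([X, cov.to_numpy(dtype=float)[mask]])
    X = sm.add_constant(X, prepend=True)

    try:
        with np.errstate(all="ignore"):
            model = sm.GLM(phen, X, family=sm.families.Binomial())
            res = model.fit(maxiter=max_iter, tol=tol)
        effect = float(res.params[1])
        se = float(res.bse[1])
        converged = bool(res.converged) and np.isfinite(se) and se < 1e3
    except PerfectSeparationError:
        effect, se, converged = np.nan, np.nan, False

    if converged:
        z = effect / se
        p = 2.0 * float(_norm.sf(abs(z)))
        p = max(p, np.finfo(float).tiny)
    else:
        p = np.nan
    return AssocResult(site_id=site_id, effect=effect if converged else np.nan,
                       se=se if converged else np.nan, p=p,
                       converged=converged, covariates=cov_names)


def assoc_scan(genotypes, ranked_ids, phenotype, covariates=None,
               alpha=0.05):
    """Ordered association testing of ranked candidate sites.

    Parameters
    ----------
    genotypes : CohortGenotypes
        Cohort dosage matrix (missing as the negative sentinel).
    ranked_ids : sequence of str
        Candidate site ids in scan-rank order (rank 1 first).
    phenotype : array-like of {0, 1}
        Case status per cohort sample, in sample order.
    covariates : DataFrame, optional
    alpha : float
        FWER level for the ordered plan.

    Returns
    -------
    DataFrame with one row per rank: site_id, rank, effect, se, p,
    threshold (d/k) and rejected flag.
    """
    plan = ordered_plan(alpha=alpha, n=len(ranked_ids), ranked_ids=ranked_ids)
    site_index = {s: j for j, s in enumerate(genotypes.site_ids)}
    rows = []
    for rank, sid in enumerate(ranked_ids, start=1):
        dos = genotypes.dosage[:, site_index[sid]].astype(float)
        dos[dos < 0] = np.nan
        res = fit_logistic_additive(dos, phenotype, covariates, site_id=sid)
        rows.append({"site_id": sid, "rank": rank, "effect": res.effect,
                     "se": res.se, "p": res.p, "converged": res.converged})
    out = pd.DataFrame(rows)
    out["threshold"] = plan.thresholds
    with np.errstate(invalid="ignore"):
        out["rejected"] = out["p"].to_numpy() <= out["threshold"].to_numpy()
    return out
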