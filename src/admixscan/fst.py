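"""Hudson's pairwise FST estimator and the branch-length transform.

Per-site FST between two populations is estimated from derived-allele
frequencies and haploid sample sizes with Hudson's estimator (the
ratio-of-averages form is used for genome-wide values, which is the
standard unbiased aggregation).  The transform ``T = -ln(1 - FST)``
converts an FST value into an additive branch length used by the
population branch statistic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "hudson_fst_components",
    "hudson_fst_site",
    "hudson_fst_global",
    "t_transform",
]

#: FST values this close to 1 are clamped before the log transform.
FST_CLAMP = 1e-8


def _validate_inputs(p1, n1, p2, n2):
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("Hudson's estimator requires >= 2 chromosomes per population")
    for p in (p1, p2):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
    return p1, n1, p2, n2


def hudson_fst_components(p1, n1, p2, n2):
    """Per-site numerator and denominator of Hudson's FST estimator.

    Parameters
    ----------
    p1, p2 : array-like of float
        Derived-allele frequencies in the two populations.
    n1, n2 : array-like of int
        Haploid (chromosome) sample sizes behind each frequency.

    Returns
    -------
    (numerator, denominator) : tuple of ndarray
        ``num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` and
        ``den = p1(1-p2) + p2(1-p1)``.  The denominator is zero when
        both populations are fixed for the same allele, in which case
        the per-site estimate is undefined.
    """
    p1, n1, p2, n2 = _validate_inputs(p1, n1, p2, n2)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst_site(p1, n1, p2, n2):
    """Per-site Hudson FST estimate; NaN where the denominator is zero.

    The estimate may be slightly negative at undifferentiated sites;
    negative values are retained (not clamped to zero) so that the
    ratio-of-averages genome-wide estimate stays unbiased.
    """
    num, den = hudson_fst_components(p1, n1, p2, n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if fst.ndim == 0:
        return float(fst)
    return fst


def hudson_fst_global(p1, n1, p2, n2):
    """Genome-wide Hudson FST as a ratio of averages.

    Sites with a zero denominator (shared fixation) are skipped.  This
    is the mean-of-numerators over mean-of-denominators aggregation,
    not the mean of per-site ratios.
    """
    num, den = hudson_fst_components(p1, n1, p2, n2)
    num = np.atleast_1d(num)
    den = np.atleast_1d(den)
    usable = den > 0
    if not usable.any():
        raise ValueError("no site with a defined Hudson FST estimate")
    return float(num[usable].mean() / den[usable].mean())


def t_transform(fst):
    """Branch length ``T = -ln(1 - FST)``.

    FST values at or above ``1 - FST_CLAMP`` are clamped so that fixed
    differences map to the finite value ``-ln(FST_CLAMP)`` instead of
    infinity.  Negative FST yields a (small) negative T; NaN passes
    through.
    """
    fst = np.asarray(fst, dtype=float)
    clamped = np.minimum(fst, 1.0 - FST_CLAMP)
    with np.errstate(invalid="ignore"):
        t = -np.log1p(-clamped)
    if t.ndim == 0:
        return float(t)
    return t
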