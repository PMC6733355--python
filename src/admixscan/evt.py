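"""Extreme-value calibration of genome-scan maxima.

How surprising is the top score of a scan?  The distribution of the
maximum of a fixed-size random subsample of scores is estimated by
repeated subsampling, a generalized extreme value (GEV) distribution is
fitted to the replicate maxima by maximum likelihood, and the fitted
upper tail gives the probability that such a maximum reaches a given
score.

The GEV shape convention is the Coles parameterization: shape ``xi > 0``
is the heavy-tailed Fréchet domain, ``xi = 0`` the Gumbel limit and
``xi < 0`` the bounded Weibull domain.  (SciPy's ``genextreme`` uses
``c = -xi``.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GevFit", "sample_maxima", "fit_gev", "tail_prob"]


@dataclass
class GevFit:
    """Maximum-likelihood GEV fit to subsample maxima."""

    mu: float          # location
    sigma: float       # scale, > 0
    xi: float          # shape (Coles convention)
    n_maxima: int
    sample_size: int | None = None
    seed: int | None = None
    loglik: float = float("nan")


def sample_maxima(values, sample_size=1000, reps=1000, seed=None, rng=None):
    """Maxima (and means) of repeated random subsamples.

    Each replicate draws ``sample_size`` scores without replacement
    from ``values``.  The replicate means are returned alongside the
    maxima for diagnostic use but are not modelled further.

    Returns
    -------
    (maxima, means) : tuple of ndarray, each of length ``reps``.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if sample_size > values.size:
        raise ValueError(
            f"sample_size {sample_size} exceeds the {values.size} available values")
    if rng is None:
        rng = np.random.default_rng(seed)
    maxima = np.empty(reps)
    means = np.empty(reps)
    for r in range(reps):
        draw = values[rng.choice(values.size, size=sample_size, replace=False)]
        maxima[r] = draw.max()
        means[r] = draw.mean()
    return maxima, means


def fit_gev(maxima, sample_size=None, seed=None):
    """Fit a GEV distribution to block maxima by maximum likelihood.

    Requires at least 30 non-constant maxima.  The Gumbel case is the
    continuous ``xi -> 0`` limit of the same likelihood, so no special
    casing is needed beyond SciPy's numerics.

    Raises
    ------
    ValueError
        On constant input or a non-finite optimum.
    """
    maxima = np.asarray(maxima, dtype=float)
    if maxima.size < 30:
        raise ValueError("need at least 30 maxima for a stable GEV fit")
    if np.ptp(maxima) == 0:
        raise ValueError("maxima are constant; the GEV likelihood is degenerate")
    c, loc, scale = stats.genextreme.fit(maxima)
    loglik = float(np.sum(stats.genextreme.logpdf(maxima, c, loc=loc, scale=scale)))
    if not np.isfinite(loglik) or scale <= 0:
        raise ValueError(
            f"GEV fit failed to converge: c={c:.4g} loc={loc:.4g} "
            f"scale={scale:.4g} loglik={loglik:.4g}")
    return GevFit(mu=float(loc), sigma=float(scale), xi=float(-c),
                  n_maxima=int(maxima.size), sample_size=sample_size,
                  seed=seed, loglik=loglik)


def tail_prob(fit, x):
    """P(subsample maximum >= x) under the fitted GEV.

    Outside the support of a non-zero-shape GEV the survival function
    is exactly 0 (above an upper endpoint) or 1 (below a lower
    endpoint); SciPy handles both limits.
    """
    x = np.asarray(x, dtype=float)
    p = stats.genextreme.sf(x, -fit.xi, loc=fit.mu, scale=fit.sigma)
    if p.ndim == 0:
        return float(p)
    return p
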