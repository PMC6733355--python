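"""Matched randomization test for enrichment of small association p-values.

Are the top-ranked scan hits enriched for small case-control p-values?
Because recombination rate and derived-allele frequency both shape a
site's chance of a low p-value, each top site is matched to a pool of
background sites with similar values of the two covariates (within a
±5% relative window by default).  Null p-value sets are built by
sampling one site per pool, repeated many times, and compared with the
observed top-set p-values by a one-tailed Welch t-test (alternative:
observed mean smaller).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchedPool",
    "build_pools",
    "sample_null_sets",
    "welch_one_tailed",
    "enrichment_report",
]


@dataclass
class MatchedPool:
    """Background sites matched to one top site on (recomb rate, DAF)."""

    top_site: str
    members: np.ndarray            # integer indices into the annotation table
    fallback: bool = False         # True when the matched window was empty
    degenerate_window: bool = False  # a zero-valued covariate collapses its window


def build_pools(annotations, top_sites, rel_window=0.05, mode="relative"):
    """Build a matched background pool for each top site.

    Parameters
    ----------
    annotations : DataFrame
        Must contain columns ``site_id``, ``recomb_rate`` and ``daf``
        covering every candidate background site.
    top_sites : sequence of str
        The top-ranked sites; all of them are excluded from every pool.
    rel_window : float
        Half-width of the matching window as a fraction of the observed
        value (``[0.95 r, 1.05 r]`` at the default 0.05).
    mode : {"relative", "quantile"}
        Relative windows around the observed values (default), or
        windows of ±``rel_window`` in quantile space of each covariate.

    Notes
    -----
    A zero covariate value collapses its relative window to the single
    point {0}; the pool is then restricted to sites sharing that zero
    and the pool is flagged.  A pool that ends up empty falls back to
    the global complement of the top set, with a warning.
    """
    ann = annotations.reset_index(drop=True)
    top_set = set(top_sites)
    in_top = ann["site_id"].isin(top_set).to_numpy()
    r = ann["recomb_rate"].to_numpy(dtype=float)
    f = ann["daf"].to_numpy(dtype=float)

    if mode == "quantile":
        r_q = stats.rankdata(r) / r.size
        f_q = stats.rankdata(f) / f.size
    elif mode != "relative":
        raise ValueError("mode must be 'relative' or 'quantile'")

    by_id = {s: i for i, s in enumerate(ann["site_id"])}
    pools = []
    for s in top_sites:
        i = by_id[s]
        if mode == "relative":
            r_lo, r_hi = sorted((r[i] * (1 - rel_window), r[i] * (1 + rel_window)))
            f_lo, f_hi = sorted((f[i] * (1 - rel_window), f[i] * (1 + rel_window)))
            match = (r >= r_lo) & (r <= r_hi) & (f >= f_lo) & (f <= f_hi)
            degenerate = (r[i] == 0.0) or (f[i] == 0.0)
        else:
            match = ((np.abs(r_q - r_q[i]) <= rel_window)
                     & (np.abs(f_q - f_q[i]) <= rel_window))
            degenerate = False
        members = np.flatnonzero(match & ~in_top)
        fallback = members.size == 0
        if fallback:
            warnings.warn(
                f"empty matched pool for top site {s}; "
                "falling back to the global complement", stacklevel=2)
            members = np.flatnonzero(~in_top)
        pools.append(MatchedPool(top_site=s, members=members,
                                 fallback=fallback,
                                 degenerate_window=degenerate))
    return pools


def sample_null_sets(pools, p_values, reps=1000, seed=None, rng=None,
                     max_retries=100):
    """Sample null p-value sets: one site per pool, no duplicates per replicate.

    Parameters
    ----------
    pools : list of MatchedPool
    p_values : ndarray
        Per-site p-values aligned with the annotation table the pools
        index into.
    reps : int
        Number of replicate sets.

    Returns
    -------
    ndarray of shape (reps, len(pools))
        Sampled p-values.

    Within a replicate, a site may serve only one pool; collisions are
    resolved by redrawing the colliding pools (bounded retries), which
    keeps each pool's marginal draw uniform.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p_values = np.asarray(p_values, dtype=float)
    n_pools = len(pools)
    members = [p.members for p in pools]
    sizes = np.array([m.size for m in members])
    if (sizes == 0).any():
        raise ValueError("cannot sample from an empty pool")

    out = np.empty((reps, n_pools))
    for rep in range(reps):
        picks = None
        for _ in range(max_retries):
            picks = _draw_replicate(rng, members, sizes, n_pools)
            if picks is not None:
                break
        if picks is None:
            raise RuntimeError(
                "pool exhaustion: could not draw a duplicate-free "
                f"replicate after {max_retries} retries")
        out[rep] = p_values[picks]
    return out


def _draw_replicate(rng, members, sizes, n_pools):
    """One duplicate-free draw of a site per pool, or None on failure.

    A vectorized redraw of colliding pools resolves almost every
    replicate in a pass or two; the rare tight configurations fall
    back to an exact sequential draw over unused members.
    """
    picks = np.array([m[rng.integers(s)] for m, s in zip(members, sizes)])
    for _ in range(10):
        _, first_idx = np.unique(picks, return_index=True)
        dup = np.ones(n_pools, dtype=bool)
        dup[first_idx] = False
        if not dup.any():
            return picks
        for j in np.flatnonzero(dup):
            picks[j] = members[j][rng.integers(sizes[j])]
    # Exact pass: random pool order, sampling without replacement.
    picks = np.empty(n_pools, dtype=np.int64)
    used = set()
    for j in rng.permutation(n_pools):
        avail = members[j][[m not in used for m in members[j]]]
        if avail.size == 0:
            return None
        picks[j] = avail[rng.integers(avail.size)]
        used.add(int(picks[j]))
    return picks


def welch_one_tailed(top_pvalues, null_pvalues):
    """Welch two-sample t-test, one-tailed (top mean < null mean).

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom.
    """
    a = np.asarray(top_pvalues, dtype=float)
    b = np.asarray(null_pvalues, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("constant samples: the Welch statistic is undefined")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return float(res.statistic), float(res.df), float(res.pvalue)


def enrichment_report(scan_table, p_values, annotations,
                      k_list=(5, 10, 25, 50, 100), reps=1000, seed=None,
                      rel_window=0.05, mode="relative", pooled=True):
    """Per-k enrichment test of top scan hits for small association p-values.

    Parameters
    ----------
    scan_table : DataFrame
        Scan output with ``site_id`` sorted by descending score (rank
        order), e.g. the PBSn1 scan table.
    p_values : DataFrame
        Columns ``site_id`` and ``p`` covering the scanned sites.
    annotations : DataFrame
        Columns ``site_id``, ``recomb_rate``, ``daf``.
    k_list : iterable of int
        Top-set sizes to evaluate.
    pooled : bool
        Compare the k observed p-values against all reps*k null draws
        pooled into one sample (default) or against per-replicate means.

    Returns
    -------
    DataFrame with one row per k: observed and null means, Welch t, df
    and one-tailed p.
    """
    rng = np.random.default_rng(seed)
    merged = annotations.merge(p_values, on="site_id", how="inner")
    pmap = dict(zip(merged["site_id"], merged["p"]))
    ranked = [s for s in scan_table["site_id"] if s in pmap]

    rows = []
    for k in k_list:
        if k > len(ranked):
            warnings.warn(f"top-{k} exceeds the {len(ranked)} scanned sites "
                          "with p-values; skipped", stacklevel=2)
            continue
        top = ranked[:k]
        pools = build_pools(merged, top, rel_window=rel_window, mode=mode)
        null = sample_null_sets(pools, merged["p"].to_numpy(), reps=reps,
                                rng=rng)
        obs = np.array([pmap[s] for s in top])
        null_sample = null.ravel() if pooled else null.mean(axis=1)
        t, df, p = welch_one_tailed(obs, null_sample)
        rows.append({"k": k, "observed_mean": obs.mean(),
                     "null_mean": float(null.mean()), "t": t, "df": df,
                     "p": p,
                     "n_fallback_pools": sum(pl.fallback for pl in pools)})
    return pd.DataFrame(rows)
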