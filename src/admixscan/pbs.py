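"""Admixture-corrected PBSn1 genome scan.

The scan targets selective sweeps that happened on the focal branch
*before* admixture.  Cohort derived-allele frequencies are first
corrected for European admixture,

    f* = (f_obs - alpha * f_EUR) / (1 - alpha),

where ``alpha`` is the per-site European local-ancestry proportion.
Pairwise Hudson FST values between the corrected focal population and
the two reference populations are transformed to branch lengths
``T = -ln(1 - FST)``, combined into per-population branch statistics

    PBS1 = (T12 + T13 - T23) / 2    (focal branch)

and normalised as ``PBSn1 = PBS1 / (1 + PBS1 + PBS2 + PBS3)``, which
damps inflation when every branch is long.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fst as _fst

__all__ = [
    "correct_frequency",
    "polymorphism_filter",
    "pbs_site",
    "scan",
]

#: PBSn1 is reported as invalid when 1 + PBS1 + PBS2 + PBS3 falls below this.
PBS_DENOM_FLOOR = 1e-8


def correct_frequency(f_obs, alpha, f_src):
    """Recover the unadmixed focal frequency from an admixed cohort.

    Parameters
    ----------
    f_obs : array-like
        Observed derived-allele frequency in the admixed cohort.
    alpha : array-like
        Per-site admixing-source (European) ancestry proportion, in
        ``[0, 1)``.
    f_src : array-like
        Derived-allele frequency in the admixing source panel.

    Returns
    -------
    (f_corrected, clipped) : tuple of ndarray
        The corrected frequency ``(f_obs - alpha*f_src)/(1 - alpha)``
        clipped into ``[0, 1]``, and a boolean flag marking sites where
        the raw value fell outside the unit interval.  With noisy or
        rounded inputs the raw formula can leave [0, 1]; clipping keeps
        downstream FST estimates defined.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    f_src = np.asarray(f_src, dtype=float)
    if np.any(alpha >= 1.0) or np.any(alpha < 0.0):
        raise ValueError("alpha must lie in [0, 1): a fully admixed site "
                         "has no unadmixed component to recover")
    raw = (f_obs - alpha * f_src) / (1.0 - alpha)
    clipped = (raw < 0.0) | (raw > 1.0)
    corrected = np.clip(raw, 0.0, 1.0)
    if corrected.ndim == 0:
        return float(corrected), bool(clipped)
    return corrected, clipped


def polymorphism_filter(*freq_tables):
    """Mask of sites polymorphic in at least two of the given populations.

    A site is dropped when it is monomorphic (frequency exactly 0 or 1)
    in two or more of the populations; such sites carry no three-way
    branch information.

    Parameters
    ----------
    *freq_tables : array-like
        Aligned per-site frequency vectors, one per population.

    Returns
    -------
    ndarray of bool
        True where the site is retained.
    """
    arrays = [np.asarray(f, dtype=float) for f in freq_tables]
    n = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != n:
            raise ValueError("frequency tables are misaligned")
    mono = sum(((a == 0.0) | (a == 1.0)).astype(int) for a in arrays)
    return mono <= 1


def pbs_site(t12, t13, t23):
    """Per-site PBS for all three populations plus PBSn1.

    Returns a dict of arrays: PBS1 (focal), PBS2, PBS3, PBSn1, and a
    ``valid`` flag which is False where the PBSn1 denominator
    ``1 + PBS1 + PBS2 + PBS3`` is not safely positive.
    """
    t12 = np.asarray(t12, dtype=float)
    t13 = np.asarray(t13, dtype=float)
    t23 = np.asarray(t23, dtype=float)
    pbs1 = (t12 + t13 - t23) / 2.0
    pbs2 = (t12 + t23 - t13) / 2.0
    pbs3 = (t13 + t23 - t12) / 2.0
    denom = 1.0 + pbs1 + pbs2 + pbs3
    valid = denom > PBS_DENOM_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        pbsn1 = np.where(valid, pbs1 / np.where(valid, denom, 1.0), np.nan)
    return {"PBS1": pbs1, "PBS2": pbs2, "PBS3": pbs3,
            "PBSn1": pbsn1, "valid": valid}


@dataclass
class ScanResult:
    """Full per-site scan table plus the top-k extraction."""

    table: pd.DataFrame
    top: pd.DataFrame
    n_dropped_polymorphism: int
    n_dropped_undefined_fst: int


def scan(site_ids, f_cohort, alpha, f_src, n_src, f_pop2, n_pop2,
         f_pop3, n_pop3, *, n_cohort, k=10, effective_n=True):
    """Run the admixture-corrected PBSn1 scan over aligned sites.

    Parameters
    ----------
    site_ids : sequence of str
        Site identifiers, aligned across every frequency vector.
    f_cohort : array-like
        Observed derived-allele frequency in the admixed cohort.
    alpha : array-like
        Per-site European local-ancestry proportion (mean European
        dosage / 2).
    f_src, n_src : array-like
        Admixing-source (European) panel frequencies and haploid sizes.
    f_pop2, n_pop2 : array-like
        Second (sister) population frequencies and haploid sizes.
    f_pop3, n_pop3 : array-like
        Outgroup population frequencies and haploid sizes.
    n_cohort : int
        Number of diploid cohort individuals.
    k : int
        Number of top-ranked sites to extract.
    effective_n : bool
        When True (default), the corrected focal frequencies enter the
        FST estimator with an effective haploid size
        ``round(2 * n_cohort * (1 - mean(alpha)))`` — the chromosomes
        that actually carry focal ancestry.  When False the full
        ``2 * n_cohort`` is used.

    Returns
    -------
    ScanResult
        ``table`` holds every retained site sorted by PBSn1 descending
        (ties broken by site id); ``top`` is the head of that table.
    """
    site_ids = np.asarray(site_ids, dtype=object)
    f_cohort = np.asarray(f_cohort, dtype=float)
    alpha = np.asarray(alpha, dtype=float)

    f_corr, clipped = correct_frequency(f_cohort, alpha, f_src)

    keep = polymorphism_filter(f_corr, f_pop2, f_pop3)
    n_poly_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("no polymorphic site retained for the scan")

    alpha_bar = float(np.mean(alpha))
    if effective_n:
        n_focal = max(2, int(round(2 * n_cohort * (1.0 - alpha_bar))))
    else:
        n_focal = 2 * n_cohort

    f1 = f_corr[keep]
    f2 = np.asarray(f_pop2, dtype=float)[keep]
    f3 = np.asarray(f_pop3, dtype=float)[keep]
    n2 = np.broadcast_to(np.asarray(n_pop2), f_cohort.shape)[keep]
    n3 = np.broadcast_to(np.asarray(n_pop3), f_cohort.shape)[keep]

    fst12 = _fst.hudson_fst_site(f1, n_focal, f2, n2)
    fst13 = _fst.hudson_fst_site(f1, n_focal, f3, n3)
    fst23 = _fst.hudson_fst_site(f2, n2, f3, n3)

    defined = ~(np.isnan(fst12) | np.isnan(fst13) | np.isnan(fst23))
    n_fst_dropped = int((~defined).sum())

    t12 = _fst.t_transform(fst12[defined])
    t13 = _fst.t_transform(fst13[defined])
    t23 = _fst.t_transform(fst23[defined])
    rec = pbs_site(t12, t13, t23)

    ids_kept = site_ids[keep][defined]
    table = pd.DataFrame({
        "site_id": ids_kept,
        "f_cohort": f_cohort[keep][defined],
        "alpha": alpha[keep][defined] if alpha.ndim else np.full(ids_kept.size, float(alpha)),
        "f_corrected": f1[defined],
        "clipped": clipped[keep][defined],
        "f_pop2": f2[defined],
        "f_pop3": f3[defined],
        "T12": t12, "T13": t13, "T23": t23,
        "PBS1": rec["PBS1"], "PBS2": rec["PBS2"], "PBS3": rec["PBS3"],
        "PBSn1": rec["PBSn1"], "valid": rec["valid"],
    })
    table = table[table["valid"]].copy()
    table = table.sort_values(
        ["PBSn1", "site_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)

    if k > len(table):
        warnings.warn(
            f"requested top {k} but only {len(table)} sites retained; "
            "returning all", stacklevel=2)
        k = len(table)
    return ScanResult(
        table=table,
        top=table.head(k).copy(),
        n_dropped_polymorphism=n_poly_dropped,
        n_dropped_undefined_fst=n_fst_dropped,
    )
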