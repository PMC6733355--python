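"""Local-ancestry deviation scan for post-admixture selection.

Each individual carries 0, 1 or 2 alleles of a given ancestry at each
site, modelled as Binomial(2, p_j) where p_j is the ancestry proportion
at site j.  Post-admixture selection pulls p_j away from the
genome-wide mean p0, so each site is tested with

    z = (p_hat_j - p0) / sqrt(p0 (1 - p0) / 2N),

a score-type statistic with the variance evaluated at the null, and a
two-sided normal p-value.  When the expected minor count
``2N * min(p0, 1 - p0)`` is small the normal approximation is replaced
by an exact binomial test.

The case/control stratified filter keeps sites that deviate
significantly in the whole cohort and in controls but *not* in cases:
a control-specific excess of the adaptive ancestry is the signature of
ongoing selection against the disease phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AncestryDosage",
    "genomewide_ancestry_means",
    "deviation_test",
    "stratified_scan",
    "annotate_candidates",
    "SIGNIFICANCE_THRESHOLD",
]

#: Per-site significance threshold recommended for recently admixed cohorts.
SIGNIFICANCE_THRESHOLD = 5e-5

#: Below this expected minor-class count, use the exact binomial test.
EXACT_ROUTE_MIN_COUNT = 10


@dataclass
class AncestryDosage:
    """Per-individual, per-site counts of focal-ancestry alleles (0/1/2)."""

    sample_ids: list
    site_ids: list
    X: np.ndarray                    # (n_samples, n_sites) int
    groups: np.ndarray | None = None  # "case" / "control" per sample

    def __post_init__(self):
        self.X = np.asarray(self.X)
        if self.X.shape != (len(self.sample_ids), len(self.site_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        if not np.isin(self.X, (0, 1, 2)).all():
            raise ValueError("ancestry dosages must be 0, 1 or 2")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
            if self.groups.shape[0] != len(self.sample_ids):
                raise ValueError("group labels do not match samples")


def genomewide_ancestry_means(dosage):
    """Genome-wide mean ancestry proportions.

    Returns a dict with the focal (e.g. Native-American) mean
    ``dosage/2`` over all individuals and sites, and its two-way
    complement.  The focal mean is the default null proportion p0 of
    the deviation scan.
    """
    if dosage.X.size == 0:
        raise ValueError("empty ancestry dosage matrix")
    focal = float(dosage.X.mean() / 2.0)
    return {"focal": focal, "other": 1.0 - focal}


def _exact_two_sided(counts, n_chrom, p0):
    return np.array([
        stats.binomtest(int(c), n_chrom, p0, alternative="two-sided").pvalue
        for c in counts
    ])


def deviation_test(X, p0, variance="null"):
    """Per-site test of ancestry proportion against the genome-wide mean.

    Parameters
    ----------
    X : 2-D array (n_samples, n_sites) or 1-D column
        Focal-ancestry allele counts in {0, 1, 2}.
    p0 : float
        Null ancestry proportion.
    variance : {"null", "mle"}
        Evaluate the binomial variance at p0 (score-type, default) or
        at the per-site estimate p_hat (Wald-type).

    Returns
    -------
    DataFrame with columns p_hat, z, p, selected (p < 5e-5).
    """
    X = np.atleast_2d(np.asarray(X))
    if X.shape[0] == 0:
        raise ValueError("no individuals in ancestry column")
    n_chrom = 2 * X.shape[0]
    counts = X.sum(axis=0)
    p_hat = counts / n_chrom

    if n_chrom * min(p0, 1.0 - p0) < EXACT_ROUTE_MIN_COUNT:
        p = _exact_two_sided(counts, n_chrom, p0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.sign(p_hat - p0) * stats.norm.isf(np.clip(p / 2, 1e-300, 1.0))
    else:
        if variance == "null":
            var = p0 * (1.0 - p0)
        elif variance == "mle":
            var = np.clip(p_hat * (1.0 - p_hat), 1e-12, None)
        else:
            raise ValueError("variance must be 'null' or 'mle'")
        z = (p_hat - p0) / np.sqrt(var / n_chrom)
        p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "p_hat": p_hat, "z": z, "p": p,
        "selected": p < SIGNIFICANCE_THRESHOLD,
    })


def stratified_scan(dosage, p0=None, threshold=SIGNIFICANCE_THRESHOLD,
                    variance="null"):
    """Deviation scan in the whole cohort, cases and controls.

    A single p0 — the whole-cohort genome-wide mean unless given — is
    used for all three groups.  The candidate set contains sites
    significant in the whole cohort AND in controls, but NOT in cases.

    Returns
    -------
    (candidates, table) : (list of str, DataFrame)
        ``table`` is long-form with one row per site per group.
    """
    if dosage.groups is None:
        raise ValueError("stratified scan requires case/control labels")
    is_case = dosage.groups == "case"
    is_control = dosage.groups == "control"
    if not is_case.any() or not is_control.any():
        raise ValueError("both cases and controls must be present")

    if p0 is None:
        p0 = genomewide_ancestry_means(dosage)["focal"]

    parts = []
    sig = {}
    for name, mask in (("all", slice(None)), ("cases", is_case),
                       ("controls", is_control)):
        res = deviation_test(dosage.X[mask], p0, variance=variance)
        res["p_hat"] = res["p_hat"].astype(float)
        res.insert(0, "site_id", dosage.site_ids)
        res.insert(1, "group", name)
        res["selected"] = res["p"] < threshold
        sig[name] = res["selected"].to_numpy()
        parts.append(res)
    table = pd.concat(parts, ignore_index=True)

    keep = sig["all"] & sig["controls"] & ~sig["cases"]
    candidates = [s for s, k in zip(dosage.site_ids, keep) if k]
    return candidates, table


def annotate_candidates(candidates, annotations, scan_table,
                        pbs_table=None):
    """Join candidate sites with annotations and scan statistics.

    Candidates missing from the annotation table are retained with
    missing fields; the report is sorted by whole-cohort p ascending.
    """
    if len(candidates) == 0:
        return pd.DataFrame(columns=["site_id"])
    wide = (scan_table.pivot(index="site_id", columns="group", values="p")
            .rename(columns={"all": "p_all", "cases": "p_cases",
                             "controls": "p_controls"}))
    out = pd.DataFrame({"site_id": list(candidates)}).join(
        wide, on="site_id")
    if annotations is not None:
        out = out.merge(annotations, on="site_id", how="left")
    if pbs_table is not None:
        out = out.merge(pbs_table[["site_id", "PBSn1"]], on="site_id",
                        how="left")
    return out.sort_values("p_all", kind="mergesort").reset_index(drop=True)
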