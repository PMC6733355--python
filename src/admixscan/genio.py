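"""Genotype I/O and array-style quality control.

Genotypes live in a :class:`CohortGenotypes` matrix of alternate-allele
dosages (0/1/2, ``MISSING`` = -1) and can be read from a VCF (GT field,
biallelic diploid sites only) or a dosage TSV.  Quality control follows
the conventional array pipeline, applied in this fixed order:

1. drop individuals with call rate below ``mind``;
2. drop markers with call rate below ``geno`` (among survivors);
3. drop markers with minor allele frequency <= ``maf``;
4. drop markers with Hardy-Weinberg exact-test p <= ``hwe``.

Allele frequencies use pairwise-complete denominators (called
chromosomes at the site).  The HWE test is the exact conditional test
(sum over heterozygote counts of the same parity whose conditional
probability does not exceed the observed one), which stays calibrated
at low genotype counts where the chi-square test does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "CohortGenotypes",
    "QcThresholds",
    "QcReport",
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "read_annotations",
    "write_annotations",
    "qc_filter",
    "hwe_exact_p",
]

MISSING = -1


@dataclass
class CohortGenotypes:
    """Diploid dosage matrix: samples x sites, values {0, 1, 2, MISSING}."""

    sample_ids: list
    site_ids: list
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.site_ids)):
            raise ValueError("dosage shape does not match id lists")
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or the missing sentinel")

    @property
    def n_samples(self):
        return len(self.sample_ids)

    @property
    def n_sites(self):
        return len(self.site_ids)

    def called(self):
        return self.dosage != MISSING

    def sample_call_rate(self):
        return self.called().mean(axis=1)

    def site_call_rate(self):
        return self.called().mean(axis=0)

    def allele_freq(self):
        """Alternate-allele frequency per site over called chromosomes."""
        called = self.called()
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        chroms = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(chroms > 0, alt / np.where(chroms > 0, chroms, 1),
                            np.nan)

    def subset(self, sample_mask=None, site_mask=None):
        sm = np.ones(self.n_samples, bool) if sample_mask is None else sample_mask
        tm = np.ones(self.n_sites, bool) if site_mask is None else site_mask
        return CohortGenotypes(
            sample_ids=[s for s, k in zip(self.sample_ids, sm) if k],
            site_ids=[s for s, k in zip(self.site_ids, tm) if k],
            dosage=self.dosage[np.ix_(sm, tm)],
        )


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    site_ids, columns = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multi-allelic site at {v.CHROM}:{v.POS}; split or drop it first")
        gts = v.genotype.array()
        if gts.shape[1] != 3:  # two alleles + phasing flag
            raise ValueError(f"non-diploid genotypes at {v.CHROM}:{v.POS}")
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        d = np.asarray(v.gt_types, dtype=np.int8)
        d[d == 3] = MISSING
        site_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        columns.append(d)
    if not columns:
        raise ValueError(f"no variant records in {path}")
    return CohortGenotypes(samples, site_ids,
                           np.column_stack(columns))


def _read_dosage_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosage = df.to_numpy()
    dosage = np.where(pd.isna(df).to_numpy(), MISSING, dosage).astype(np.int8)
    return CohortGenotypes(list(df.index.astype(str)),
                           list(df.columns.astype(str)), dosage)


def read_genotypes(path, fmt="vcf"):
    """Read a cohort dosage matrix from ``vcf`` or ``dosage-tsv``."""
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes, path, annotations=None):
    """Write a minimal VCF 4.2 with GT only.

    Positions/alleles come from ``annotations`` (columns chrom, pos,
    ref, alt indexed by site_id) when given; otherwise synthetic
    chrom 1 coordinates and A/G alleles are emitted.
    """
    ann = None
    if annotations is not None:
        ann = annotations.set_index("site_id")
    sites = []
    for j, sid in enumerate(genotypes.site_ids):
        if ann is not None and sid in ann.index:
            row = ann.loc[sid]
            sites.append((str(row["chrom"]), int(row["pos"]),
                          str(row.get("ref", "A")), str(row.get("alt", "G"))))
        else:
            sites.append(("1", j + 1, "A", "G"))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(c for c, *_ in sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        for j, (sid, (chrom, pos, ref, alt)) in enumerate(
                zip(genotypes.site_ids, sites)):
            gts = "\t".join(_GT_CODE[int(d)] for d in genotypes.dosage[:, j])
            fh.write(f"{chrom}\t{pos}\t{sid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_dosage_tsv(genotypes, path):
    df = pd.DataFrame(genotypes.dosage.astype(float),
                      index=genotypes.sample_ids,
                      columns=genotypes.site_ids)
    df[df < 0] = np.nan
    df.to_csv(path, sep="\t", float_format="%.0f")


ANNOTATION_COLUMNS = ["site_id", "chrom", "pos", "ref", "alt", "derived_is_alt",
                      "recomb_rate", "B", "gene"]


def read_annotations(path):
    """Site annotation TSV: position, derived flag, recombination rate, B."""
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "B" in ann.columns:
        b = ann["B"].to_numpy(dtype=float)
        if np.nanmin(b) < 0 or np.nanmax(b) > 1:
            raise ValueError("background-selection coefficient B must lie in [0, 1]")
    if ann["site_id"].duplicated().any():
        raise ValueError("duplicate site ids in annotation table")
    return ann


def write_annotations(ann, path):
    ann.to_csv(path, sep="\t", index=False)


@dataclass
class QcThresholds:
    """Array QC thresholds; markers at or below maf/hwe floors are removed."""

    mind: float = 0.90
    geno: float = 0.90
    maf: float = 0.01
    hwe: float = 1e-5

    def __post_init__(self):
        for name in ("mind", "geno", "maf", "hwe"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class QcReport:
    individuals_removed: int = 0
    markers_callrate: int = 0
    markers_maf: int = 0
    markers_hwe: int = 0
    removed_samples: list = field(default_factory=list)
    removed_sites: dict = field(default_factory=dict)

    def to_json(self, path=None):
        payload = {
            "individuals_removed": self.individuals_removed,
            "markers_callrate": self.markers_callrate,
            "markers_maf": self.markers_maf,
            "markers_hwe": self.markers_hwe,
            "removed_samples": self.removed_samples,
            "removed_sites": self.removed_sites,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def hwe_exact_p(n_aa_hom, n_het, n_alt_hom):
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts (same parity as the minor-allele count)
    whose conditional probability does not exceed that of the observed
    count.

    Parameters are the three genotype counts (major hom, het, minor
    hom, in either orientation — the test is symmetric).
    """
    n_aa_hom, n_het, n_alt_hom = int(n_aa_hom), int(n_het), int(n_alt_hom)
    if min(n_aa_hom, n_het, n_alt_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_alt_hom
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_rare = 2 * min(n_aa_hom, n_alt_hom) + n_het

    # Support: heterozygote counts with the parity of the rare-allele count.
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # log P(het | n, n_rare) up to a constant, via log-factorials.
    lf = np.cumsum(np.concatenate(([0.0], np.log(np.arange(1, 2 * n + 1)))))

    def logfact(x):
        return lf[x]

    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (hets * np.log(2) - logfact(hets) - logfact(rare_hom)
            - logfact(common_hom))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    return float(probs[probs <= observed * (1 + 1e-12)].sum())


def qc_filter(genotypes, thresholds=None):
    """Apply the four ordered QC filters; returns (filtered, report)."""
    thr = thresholds or QcThresholds()
    g = genotypes

    sample_keep = g.sample_call_rate() >= thr.mind
    report = QcReport()
    report.individuals_removed = int((~sample_keep).sum())
    report.removed_samples = [s for s, k in zip(g.sample_ids, sample_keep)
                              if not k]
    if not sample_keep.any():
        raise ValueError("all individuals removed by the call-rate filter")
    g = g.subset(sample_mask=sample_keep)

    site_keep = g.site_call_rate() >= thr.geno
    report.markers_callrate = int((~site_keep).sum())
    report.removed_sites["callrate"] = [
        s for s, k in zip(g.site_ids, site_keep) if not k]
    g = g.subset(site_mask=site_keep)

    freq = g.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    site_keep = maf > thr.maf
    report.markers_maf = int((~site_keep).sum())
    report.removed_sites["maf"] = [
        s for s, k in zip(g.site_ids, site_keep) if not k]
    g = g.subset(site_mask=site_keep)

    called = g.called()
    het = ((g.dosage == 1) & called).sum(axis=0)
    hom_ref = ((g.dosage == 0) & called).sum(axis=0)
    hom_alt = ((g.dosage == 2) & called).sum(axis=0)
    hwe_p = np.array([hwe_exact_p(a, h, b)
                      for a, h, b in zip(hom_ref, het, hom_alt)])
    site_keep = hwe_p > thr.hwe
    report.markers_hwe = int((~site_keep).sum())
    report.removed_sites["hwe"] = [
        s for s, k in zip(g.site_ids, site_keep) if not k]
    g = g.subset(site_mask=site_keep)

    if g.n_sites == 0:
        raise ValueError("all markers removed by QC")
    return g, report
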