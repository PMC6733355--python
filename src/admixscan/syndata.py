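"""Synthetic cohorts with the structure the scan pipeline assumes.

The generator emulates the study design end to end: three drifted
Native-American-side populations (an East Asian outgroup ``EAS``, a
Mesoamerican sister population ``MA`` and the focal Andean ancestor
``ANDES``) plus a European source population ``SPN``, all drawn from a
shared ancestral frequency under the Balding-Nichols model; a two-way
admixed case-control cohort whose genome-wide focal-ancestry
proportion defaults to 0.44; planted frequency sweeps in the unadmixed
focal ancestor; planted post-admixture ancestry-enrichment regions;
and a logistic case-control phenotype tied to a designated risk site.

Frequency-level simulation is deliberate: every statistic downstream
consumes allele frequencies and per-site ancestry dosages, never
haplotypes, so Balding-Nichols drift plus independent per-site
ancestry draws reproduces exactly the moments the scan sees.  Local
ancestry is drawn independently per site (no ancestry-tract LD) — a
documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import CohortGenotypes
from .ancscan import AncestryDosage

__all__ = [
    "Sweep",
    "AncestryEnrichment",
    "PhenotypeModel",
    "SimConfig",
    "simulate_panels",
    "simulate_admixed_cohort",
    "simulate_phenotype",
    "simulate_annotations",
    "simulate_all",
]

POPULATIONS = ("EAS", "MA", "ANDES", "SPN")


@dataclass
class Sweep:
    """A planted pre-admixture sweep: the focal ancestor's derived
    frequency at ``site`` is forced to ``target``.  When
    ``ancestral`` is given, the shared ancestral frequency at the site
    is pinned too (so the other populations stay near it)."""

    site: int
    target: float
    ancestral: float | None = None


@dataclass
class AncestryEnrichment:
    """A planted post-admixture signal: focal-ancestry proportion
    ``theta`` over sites ``[start, stop)``, in everyone or only in
    controls."""

    start: int
    stop: int
    theta: float
    scope: str = "all"  # "all" or "controls_only"


@dataclass
class PhenotypeModel:
    """Logistic case-control model: logit P(case) = intercept +
    beta * dosage(risk_site) + covariate terms."""

    risk_site: int = 0
    beta: float = 0.5
    intercept: float = -1.3
    beta_age: float = 0.01       # per year
    beta_sex: float = 0.2
    beta_smoking: float = 0.8
    beta_orf: float = 0.4


@dataclass
class SimConfig:
    seed: int = 0
    n_sites: int = 50_000
    cohort_size: int = 200
    panel_sizes: dict = field(default_factory=lambda: {
        "EAS": 100, "MA": 50, "ANDES": 50, "SPN": 100})
    drift: dict = field(default_factory=lambda: {
        "EAS": 0.09, "MA": 0.03, "ANDES": 0.03, "SPN": 0.12})
    theta_na: float = 0.44
    sweeps: list = field(default_factory=list)
    ancestry_enrichments: list = field(default_factory=list)
    phenotype: PhenotypeModel = field(default_factory=PhenotypeModel)

    def __post_init__(self):
        if not 0.0 <= self.theta_na <= 1.0:
            raise ValueError("theta_na must lie in [0, 1]")
        for pop, F in self.drift.items():
            if not 0.0 < F < 1.0:
                raise ValueError(
                    f"drift F for {pop} must lie strictly in (0, 1), got {F}")
        for pop, n in self.panel_sizes.items():
            if n < 2:
                raise ValueError(f"panel {pop} needs at least 2 diploids")
        for sw in self.sweeps:
            if not 0.0 < sw.target < 1.0:
                raise ValueError("sweep target frequency must lie in (0, 1)")
            if not 0 <= sw.site < self.n_sites:
                raise ValueError("sweep site outside the simulated genome")
        for en in self.ancestry_enrichments:
            if not 0.0 <= en.theta <= 1.0:
                raise ValueError("enrichment proportion must lie in [0, 1]")
            if not (0 <= en.start < en.stop <= self.n_sites):
                raise ValueError("enrichment interval outside [0, n_sites)")
            if en.scope not in ("all", "controls_only"):
                raise ValueError(f"unknown enrichment scope {en.scope!r}")


def _balding_nichols(rng, ancestral, F):
    """Population frequencies ~ Beta with mean = ancestral, dispersion F."""
    shape = (1.0 - F) / F
    return rng.beta(np.clip(ancestral * shape, 1e-12, None),
                    np.clip((1.0 - ancestral) * shape, 1e-12, None))


def simulate_panels(config, rng=None, genotypes=True):
    """Draw panel frequencies (and genotypes) for the four populations.

    Returns
    -------
    dict with keys
        ``ancestral`` : shared ancestral frequencies (U[0.05, 0.95]);
        ``true_freq`` : per-population Balding-Nichols frequencies,
        with any planted sweep overwriting the ANDES value;
        ``obs_freq`` : frequencies observed in the finite panels;
        ``n_chrom`` : haploid panel sizes;
        ``genotypes`` : per-population diploid dosage matrices
        (omitted when ``genotypes=False``; observed frequencies are
        then drawn as binomial allele counts, which is distributionally
        identical for every site-level statistic).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ancestral = rng.uniform(0.05, 0.95, config.n_sites)
    for sw in config.sweeps:
        if sw.ancestral is not None:
            ancestral[sw.site] = sw.ancestral

    true_freq = {}
    for pop in POPULATIONS:
        true_freq[pop] = _balding_nichols(rng, ancestral, config.drift[pop])
    for sw in config.sweeps:
        true_freq["ANDES"][sw.site] = sw.target

    obs_freq, geno = {}, {}
    n_chrom = {pop: 2 * config.panel_sizes[pop] for pop in POPULATIONS}
    for pop in POPULATIONS:
        if genotypes:
            g = rng.binomial(
                2, true_freq[pop][None, :],
                size=(config.panel_sizes[pop], config.n_sites)).astype(np.int8)
            geno[pop] = g
            obs_freq[pop] = g.mean(axis=0) / 2.0
        else:
            counts = rng.binomial(n_chrom[pop], true_freq[pop])
            obs_freq[pop] = counts / n_chrom[pop]

    out = {"ancestral": ancestral, "true_freq": true_freq,
           "obs_freq": obs_freq, "n_chrom": n_chrom}
    if genotypes:
        out["genotypes"] = geno
    return out


def _theta_matrix(config, groups):
    """Per-sample x per-site focal-ancestry proportion with enrichments."""
    n = config.cohort_size
    theta = np.full((n, config.n_sites), config.theta_na)
    for en in config.ancestry_enrichments:
        if en.scope == "all":
            theta[:, en.start:en.stop] = en.theta
        else:
            theta[groups == "control", en.start:en.stop] = en.theta
    return theta


def _assign_groups(config, rng):
    """Balanced case/control design labels (shuffled)."""
    n = config.cohort_size
    labels = np.array(["case"] * (n // 2) + ["control"] * (n - n // 2),
                      dtype=object)
    rng.shuffle(labels)
    return labels


def simulate_admixed_cohort(config, panels, rng=None, individuals=True):
    """Simulate the admixed cohort: genotypes, ancestry dosages, truth.

    Each individual at each site carries ``d`` focal-ancestry alleles,
    d ~ Binomial(2, theta_site); the d focal alleles are derived with
    the ANDES panel's true frequency and the 2 - d European alleles
    with the SPN true frequency.

    When a controls-only enrichment is configured, case/control design
    labels are assigned up front (balanced, shuffled) so the enrichment
    can target controls; the labels are returned and reused by
    :func:`simulate_phenotype`.

    Parameters
    ----------
    individuals : bool
        When False, only per-site summaries are generated (cohort
        derived-allele frequency, ancestry dosage totals and true
        alpha) by drawing site-level binomial totals directly — the
        exact distribution of the individual-level sums, at a fraction
        of the cost.

    Returns
    -------
    dict with ``genotypes`` (CohortGenotypes), ``ancestry``
    (AncestryDosage), ``alpha_true`` (per-site European proportion,
    1 - mean dosage/2), ``cohort_freq``, ``groups``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    needs_groups = any(en.scope == "controls_only"
                       for en in config.ancestry_enrichments)
    groups = _assign_groups(config, rng)

    f_andes = panels["true_freq"]["ANDES"]
    f_spn = panels["true_freq"]["SPN"]
    n = config.cohort_size

    if individuals:
        theta = _theta_matrix(config, groups)
        d = rng.binomial(2, theta).astype(np.int8)
        derived = (rng.binomial(d, np.broadcast_to(f_andes, d.shape))
                   + rng.binomial(2 - d, np.broadcast_to(f_spn, d.shape))
                   ).astype(np.int8)
        sample_ids = [f"S{i:04d}" for i in range(n)]
        site_ids = [f"snp{j:06d}" for j in range(config.n_sites)]
        geno = CohortGenotypes(sample_ids, site_ids, derived)
        anc = AncestryDosage(sample_ids, site_ids, d, groups=groups)
        alpha_true = 1.0 - d.mean(axis=0) / 2.0
        cohort_freq = derived.astype(float).mean(axis=0) / 2.0
        return {"genotypes": geno, "ancestry": anc,
                "alpha_true": alpha_true, "cohort_freq": cohort_freq,
                "groups": groups}

    # Site-level fast path: binomial totals over iid individuals.
    if needs_groups:
        n_ctrl = int((groups == "control").sum())
        n_case = n - n_ctrl
        theta_ctrl = np.full(config.n_sites, config.theta_na)
        theta_case = np.full(config.n_sites, config.theta_na)
        for en in config.ancestry_enrichments:
            theta_ctrl[en.start:en.stop] = en.theta
            if en.scope == "all":
                theta_case[en.start:en.stop] = en.theta
        na_alleles = (rng.binomial(2 * n_ctrl, theta_ctrl)
                      + rng.binomial(2 * n_case, theta_case))
    else:
        theta = np.full(config.n_sites, config.theta_na)
        for en in config.ancestry_enrichments:
            theta[en.start:en.stop] = en.theta
        na_alleles = rng.binomial(2 * n, theta)
    derived = (rng.binomial(na_alleles, f_andes)
               + rng.binomial(2 * n - na_alleles, f_spn))
    alpha_true = 1.0 - na_alleles / (2.0 * n)
    return {"genotypes": None, "ancestry": None,
            "alpha_true": alpha_true,
            "cohort_freq": derived / (2.0 * n),
            "groups": groups}


def simulate_phenotype(config, genotypes, rng=None, groups=None):
    """Covariates and case status for the cohort.

    Covariates: age ~ Normal(60, 10), sex ~ Bernoulli(0.5), smoking ~
    Bernoulli(0.4), occupational risk factor ~ Bernoulli(0.15).  Case
    status is Bernoulli with the configured logistic model on the risk
    site's dosage, unless ``groups`` design labels are supplied (the
    controls-only enrichment scenario), in which case case status *is*
    the design label and only covariates are simulated.

    Returns a DataFrame indexed like the cohort samples with columns
    case, age, sex, smoking, orf.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    pm = config.phenotype
    n = genotypes.n_samples
    age = rng.normal(60.0, 10.0, n)
    sex = rng.binomial(1, 0.5, n)
    smoking = rng.binomial(1, 0.4, n)
    orf = rng.binomial(1, 0.15, n)

    if groups is not None:
        case = (np.asarray(groups, dtype=object) == "case").astype(int)
    else:
        dosage = genotypes.dosage[:, pm.risk_site].astype(float)
        dosage[dosage < 0] = np.nan
        dosage = np.nan_to_num(dosage, nan=float(np.nanmean(dosage)))
        logit = (pm.intercept + pm.beta * dosage + pm.beta_age * age
                 + pm.beta_sex * sex + pm.beta_smoking * smoking
                 + pm.beta_orf * orf)
        case = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)))
    return pd.DataFrame({"case": case, "age": age, "sex": sex,
                         "smoking": smoking, "orf": orf},
                        index=genotypes.sample_ids)


def simulate_annotations(config, panels, cohort, rng=None):
    """Site annotation table: position, recombination rate, B, truth flags.

    Recombination rates are lognormal with median ~1 cM/Mb; B
    coefficients Beta(7, 2) (mean ~0.78, the genome-wide typical
    value).  Truth columns record planted sweeps and enrichments and
    the true per-site European proportion.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    n = config.n_sites
    site_ids = [f"snp{j:06d}" for j in range(n)]
    sweep_flag = np.zeros(n, bool)
    for sw in config.sweeps:
        sweep_flag[sw.site] = True
    enrich_flag = np.zeros(n, bool)
    for en in config.ancestry_enrichments:
        enrich_flag[en.start:en.stop] = True
    return pd.DataFrame({
        "site_id": site_ids,
        "chrom": "1",
        "pos": np.arange(1, n + 1) * 1000,
        "ref": "A",
        "alt": "G",
        "derived_is_alt": True,
        "recomb_rate": rng.lognormal(0.0, 0.6, n),
        "B": rng.beta(7.0, 2.0, n),
        "gene": [f"GENE{j // 50:05d}" for j in range(n)],
        "alpha_true": cohort["alpha_true"],
        "is_sweep": sweep_flag,
        "is_enrichment": enrich_flag,
    })


def simulate_all(config):
    """One-call simulation of panels, cohort, phenotype and annotations."""
    rng = np.random.default_rng(config.seed)
    panels = simulate_panels(config, rng=rng)
    cohort = simulate_admixed_cohort(config, panels, rng=rng)
    needs_groups = any(en.scope == "controls_only"
                       for en in config.ancestry_enrichments)
    pheno = simulate_phenotype(config, cohort["genotypes"], rng=rng,
                               groups=cohort["groups"] if needs_groups else None)
    if not needs_groups:
        # Align the ancestry-table group labels with the simulated phenotype.
        groups = np.where(pheno["case"].to_numpy() == 1, "case",
                          "control").astype(object)
        cohort["ancestry"].groups = groups
        cohort["groups"] = groups
    ann = simulate_annotations(config, panels, cohort, rng=rng)
    return {"panels": panels, "cohort": cohort, "phenotype": pheno,
            "annotations": ann}
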