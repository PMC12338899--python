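"""Synthetic cohorts with the statistical structure of a recent founder population.

The generator emulates the study design the analysis assumes, so every
downstream stage is testable without restricted data:

* a *source* population with a rare-variant-dominated site-frequency
  spectrum (MAFs ~ Beta(shape, 1) rescaled to (0, 0.5]),
* a *founder* population produced by Wright-Fisher binomial drift through a
  diploid bottleneck of size ``founder_size`` for ``generations`` rounds —
  this is what creates the heavy tail of rare-variant fold enrichment,
* regional subclusters drawn from a Balding-Nichols distribution around the
  founder frequency (Beta(p(1-F)/F, (1-p)(1-F)/F) per region),
* mother-father-affected-child trios with multiplicative transmission
  distortion at planted risk sites,
* case/control phenotypes from a logistic liability model with planted
  log-odds effects.

Default parameter values are the study conditions used throughout the test
suite and the reproduction script; see ``docs/methods.md`` for the rationale
behind each.  All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning, so any sub-simulation is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import TrioSet
from .io_formats import MISSING, GenotypeMatrix, Pedigree

__all__ = [
    "SimConfig",
    "PopulationPair",
    "simulate_founder_frequencies",
    "simulate_genotypes",
    "simulate_trios",
    "simulate_case_control",
    "simulate_annotations",
    "simulate_reference_counts",
    "simulate_ancestry_scene",
]

# Class mix loosely mirroring an exome's functional composition, with
# loss-of-function variants held at lower frequency by purifying selection:
# the per-class multiplier scales the Beta SFS shape downward, making the
# class rarer on average.
DEFAULT_CLASS_PROBS = {
    "synonymous": 0.30,
    "missense": 0.55,
    "pLoF_HC": 0.05,
    "other": 0.10,
}
DEFAULT_CLASS_SFS_SCALE = {
    "synonymous": 1.0,
    "missense": 0.8,
    "pLoF_HC": 0.3,
    "other": 1.0,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Counts are all non-negative; odds ratios positive; region F values in
    [0, 1).  ``planted_effects`` is a list of ``(variant_index, allelic
    odds ratio)`` pairs shared by the trio and case/control generators.
    """

    n_variants: int = 20_000
    sfs_shape: float = 0.15
    founder_size: int = 200
    generations: int = 15
    fst_regions: tuple[float, ...] = (0.002, 0.015, 0.02)
    n_ref: int = 500
    n_cohort: int = 2323
    n_trios: int = 318
    n_cases: int = 1032
    n_controls: int = 761
    prevalence: float = 0.00825
    planted_effects: tuple[tuple[int, float], ...] = ()
    an_ref: int = 113_770
    maf_floor: float = 2.5e-5
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    class_sfs_scale: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SFS_SCALE))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_variants", "founder_size", "generations", "n_ref",
                     "n_cohort", "n_trios", "n_cases", "n_controls", "an_ref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sfs_shape <= 0:
            raise ValueError("sfs_shape must be > 0")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        for f in self.fst_regions:
            if not 0 <= f < 1:
                raise ValueError("fst values must be in [0, 1)")
        for _, odds in self.planted_effects:
            if odds <= 0:
                raise ValueError("allelic odds ratios must be > 0")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")

    def rng(self, *spawn_key: int) -> np.random.Generator:
        """Child generator derived deterministically from the global seed."""
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=spawn_key))
        )


@dataclass
class PopulationPair:
    """Source vs founder (and per-region) allele frequencies, one per variant."""

    source_freq: np.ndarray
    founder_freq: np.ndarray
    region_freq: np.ndarray  # (n_regions, n_variants)

    def __post_init__(self) -> None:
        if self.source_freq.shape != self.founder_freq.shape:
            raise ValueError("source and founder frequency vectors differ in length")
        if self.region_freq.ndim != 2 or self.region_freq.shape[1] != len(self.source_freq):
            raise ValueError("region_freq must be (n_regions, n_variants)")
        for arr in (self.source_freq, self.founder_freq, self.region_freq):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("frequencies must lie in [0, 1]")


def _source_frequencies(config: SimConfig, classes: np.ndarray | None,
                        rng: np.random.Generator) -> np.ndarray:
    """Source-population MAFs: Beta(shape, 1) rescaled to (0, 0.5].

    Frequencies are floored at ``maf_floor`` (default one-ish copy at the
    reference panel's AN): a real population cannot hold alleles below its
    own frequency resolution, and the unbounded Beta tail would otherwise
    place most rare mass at frequencies no cohort or panel could observe.
    """
    shape = np.full(config.n_variants, config.sfs_shape)
    if classes is not None:
        scale = np.array([config.class_sfs_scale.get(c, 1.0) for c in classes])
        shape = shape * scale
    return np.maximum(rng.beta(shape, 1.0) / 2.0, config.maf_floor)


def wright_fisher_drift(p: np.ndarray, founder_size: int, generations: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Binomial resampling of allele frequencies through a diploid bottleneck.

    Fixation at 0 or 1 is permitted and retained.  Drift is unbiased:
    E[p_t] = p_0, with Var[p_t] = p(1-p)(1 - (1 - 1/2N)^t).
    """
    if generations > 0 and founder_size == 0:
        raise ValueError("founder_size must be > 0 when generations > 0")
    n_alleles = 2 * founder_size
    p = np.asarray(p, dtype=float).copy()
    for _ in range(generations):
        p = rng.binomial(n_alleles, p) / n_alleles
    return p


def balding_nichols(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Subpopulation frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) around *p*.

    F = 0 is the degenerate case (frequencies unchanged); fixed sites
    (p in {0, 1}) stay fixed for any F.
    """
    p = np.asarray(p, dtype=float)
    if fst == 0:
        return p.copy()
    out = p.copy()
    seg = (p > 0) & (p < 1)
    ratio = (1.0 - fst) / fst
    out[seg] = rng.beta(p[seg] * ratio, (1.0 - p[seg]) * ratio)
    return out


def simulate_founder_frequencies(config: SimConfig,
                                 classes: np.ndarray | None = None) -> PopulationPair:
    """Draw source MAFs, drift them through the bottleneck, add substructure.

    When *classes* (per-variant consequence labels) is given, each class uses
    its own SFS shape multiplier so that e.g. pLoF sites are simulated rarer.
    """
    rng = config.rng(0)
    source = _source_frequencies(config, classes, rng)
    founder = wright_fisher_drift(source, config.founder_size, config.generations, rng)
    regions = np.stack(
        [balding_nichols(founder, f, rng) for f in config.fst_regions]
    ) if config.fst_regions else np.empty((0, config.n_variants))
    return PopulationPair(source_freq=source, founder_freq=founder, region_freq=regions)


def _variant_table(m: int, prefix: str = "1") -> pd.DataFrame:
    """Synthetic biallelic SNV coordinates: chrom 1, positions 1000 apart."""
    return pd.DataFrame(
        {
            "chrom": np.full(m, prefix, dtype=object),
            "pos": np.arange(1, m + 1, dtype=np.int64) * 1000,
            "ref": np.full(m, "A", dtype=object),
            "alt": np.full(m, "G", dtype=object),
        }
    )


def simulate_genotypes(
    freq: np.ndarray,
    n: int,
    seed: int | np.random.Generator,
    missing_rate: float = 0.0,
    mean_depth: float | None = None,
    sample_prefix: str = "S",
    variants: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: dosage ~ Binomial(2, p) per individual.

    Optionally synthesizes per-genotype depth (Poisson with mean
    ``mean_depth``) and allele depths (hets split reads Binomial(DP, 1/2);
    homozygotes put all reads on their allele) plus uniform missingness —
    enough structure to exercise the depth/allele-balance QC filters.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq = np.asarray(freq, dtype=float)
    if ((freq < 0) | (freq > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    m = len(freq)
    dosage = rng.binomial(2, freq, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random((n, m)) < missing_rate] = MISSING
    depth = ad_ref = ad_alt = None
    if mean_depth is not None:
        depth = rng.poisson(mean_depth, size=(n, m)).astype(np.int32)
        alt_reads = np.zeros((n, m), dtype=np.int32)
        het = dosage == 1
        alt_reads[het] = rng.binomial(depth[het], 0.5)
        hom_alt = dosage == 2
        alt_reads[hom_alt] = depth[hom_alt]
        ad_alt = alt_reads
        ad_ref = depth - alt_reads
    return GenotypeMatrix(
        samples=[f"{sample_prefix}{i:05d}" for i in range(n)],
        variants=_variant_table(m) if variants is None else variants.reset_index(drop=True),
        dosage=dosage,
        depth=depth,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
    )


def _transmit(parent: np.ndarray, p_minor: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Allele (0/1) transmitted by each parent genotype.

    Homozygotes transmit their allele; heterozygotes transmit the minor
    allele with probability ``p_minor`` (0.5 under Mendel, OR/(OR+1) with
    multiplicative transmission distortion at a planted risk site).
    """
    u = rng.random(parent.shape)
    return ((parent == 2) | ((parent == 1) & (u < p_minor))).astype(np.int8)


def simulate_trios(
    freq: np.ndarray,
    n_trios: int,
    planted_effects: tuple[tuple[int, float], ...] = (),
    seed: int | np.random.Generator = 0,
) -> TrioSet:
    """Trios with parents under HWE and affected-child ascertainment.

    At a planted site with allelic odds ratio OR, a heterozygous parent
    transmits the risk (minor) allele with probability OR/(OR+1) — the
    classic transmission probability under multiplicative risk with
    single-affected-child ascertainment.  Children are Mendelian-consistent
    by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq = np.asarray(freq, dtype=float)
    m = len(freq)
    p_minor = np.full(m, 0.5)
    for idx, odds in planted_effects:
        p_minor[idx] = odds / (odds + 1.0)
    father = rng.binomial(2, freq, size=(n_trios, m)).astype(np.int8)
    mother = rng.binomial(2, freq, size=(n_trios, m)).astype(np.int8)
    child = _transmit(father, p_minor, rng) + _transmit(mother, p_minor, rng)
    return TrioSet(father=father, mother=mother, child=child,
                   variants=_variant_table(m))


def simulate_case_control(
    freq: np.ndarray,
    planted_effects: tuple[tuple[int, float], ...],
    prevalence: float,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Case/control genotypes under a logistic liability model.

    Disease probability is logistic in the planted dosages:
    logit P(D) = alpha + sum_j log(OR_j) g_j, with alpha chosen so the
    population prevalence is approximately ``prevalence`` at mean dosage.
    Individuals are rejection-sampled to the fixed case/control quotas;
    genotypes at non-planted sites are independent of phenotype and are
    drawn only for the retained individuals.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq = np.asarray(freq, dtype=float)
    m = len(freq)
    planted_idx = np.array([i for i, _ in planted_effects], dtype=np.int64)
    betas = np.array([np.log(o) for _, o in planted_effects])
    alpha = np.log(prevalence / (1 - prevalence))
    if len(planted_idx):
        alpha -= float(betas @ (2 * freq[planted_idx]))

    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    batch = max(2048, int(4 * (n_cases / prevalence + n_controls)) // 8)
    guard = 0
    while len(case_rows) < n_cases or len(ctrl_rows) < n_controls:
        guard += 1
        if guard > 1000:
            raise RuntimeError("rejection sampling failed to fill quotas")
        g_planted = rng.binomial(2, freq[planted_idx], size=(batch, len(planted_idx)))
        eta = alpha + (g_planted @ betas if len(planted_idx) else 0.0)
        p_case = 1.0 / (1.0 + np.exp(-np.broadcast_to(eta, (batch,)).astype(float)))
        is_case = rng.random(batch) < p_case
        for i in np.nonzero(is_case)[0]:
            if len(case_rows) < n_cases:
                case_rows.append(g_planted[i])
        for i in np.nonzero(~is_case)[0]:
            if len(ctrl_rows) < n_controls:
                ctrl_rows.append(g_planted[i])

    n_total = n_cases + n_controls
    dosage = rng.binomial(2, freq, size=(n_total, m)).astype(np.int8)
    if len(planted_idx):
        kept = np.vstack(case_rows + ctrl_rows).astype(np.int8)
        dosage[:, planted_idx] = kept
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int64), np.zeros(n_controls, dtype=np.int64)]
    )
    gm = GenotypeMatrix(
        samples=[f"CC{i:05d}" for i in range(n_total)],
        variants=_variant_table(m),
        dosage=dosage,
    )
    return gm, phenotype


def simulate_annotations(config: SimConfig, variants: pd.DataFrame | None = None,
                         genes_per_chrom: int | None = None) -> pd.DataFrame:
    """Consequence / clinical-significance / gene labels for each variant.

    Consequence classes are drawn from ``class_probs``; consecutive variants
    are grouped into synthetic genes of ~20 variants; a small fraction of
    pLoF and missense sites receive P/LP ClinVar labels so that the
    prevalence stage has pathogenic variants to count.
    """
    rng = config.rng(1)
    m = config.n_variants
    classes = rng.choice(
        list(config.class_probs), size=m, p=list(config.class_probs.values())
    )
    gene_size = 20
    genes = np.array([f"GENE{i // gene_size:04d}" for i in range(m)])
    clinvar = np.full(m, "none", dtype=object)
    damaging = np.isin(classes, ["pLoF_HC", "missense"])
    u = rng.random(m)
    clinvar[damaging & (u < 0.05)] = "P"
    clinvar[damaging & (u >= 0.05) & (u < 0.08)] = "LP"
    clinvar[damaging & (u >= 0.08) & (u < 0.12)] = "conflicting"
    clinvar[~damaging & (u < 0.02)] = "benign"
    vt = _variant_table(m) if variants is None else variants.reset_index(drop=True)
    out = vt.copy()
    out["consequence"] = classes
    out["clinvar"] = clinvar
    out["gene"] = genes
    return out


def simulate_reference_counts(config: SimConfig, source_freq: np.ndarray,
                              variants: pd.DataFrame | None = None) -> pd.DataFrame:
    """gnomAD-NFE-like reference allele-count table sampled from the source.

    AC ~ Binomial(AN, p_source) at the configured reference AN, so the
    reference panel carries sampling noise of its own.
    """
    rng = config.rng(2)
    m = len(source_freq)
    ac = rng.binomial(config.an_ref, source_freq)
    vt = _variant_table(m) if variants is None else variants.reset_index(drop=True)
    out = vt.copy()
    out["ac"] = ac.astype(np.int64)
    out["an"] = np.full(m, config.an_ref, dtype=np.int64)
    return out


def simulate_ancestry_scene(
    config: SimConfig,
    n_per_ref: int = 100,
    cohort_sizes: tuple[int, int, int] = (150, 30, 20),
    fst_eur: float = 0.01,
    fst_outgroup: float = 0.15,
) -> dict:
    """Three-population scene for the two-stage ancestry assignment.

    Populations: a founder population (``FC``, drifted from the EUR-like
    frequencies through the configured bottleneck), a continental ``EUR``
    population, and a diverged ``OUT`` outgroup (both Balding-Nichols around
    the source).  Returns labeled reference panels mirroring the worldwide
    panel (stage 1: EUR + OUT) and the regional panel (stage 2: ERRQ-like FC
    + EUR), plus a mixed cohort with known truth labels
    (``FC``/``EUR``/``OUT``), given in ``cohort_sizes`` order.
    """
    rng = config.rng(3)
    source = _source_frequencies(config, None, rng)
    common = source > 0.05  # ancestry-informative sites only
    src = source[common]
    p_eur = balding_nichols(src, fst_eur, rng)
    p_out = balding_nichols(src, fst_outgroup, rng)
    p_fc = wright_fisher_drift(p_eur, config.founder_size, config.generations, rng)
    variants = _variant_table(len(src))

    def draw(p, n, prefix):
        return simulate_genotypes(p, n, rng, sample_prefix=prefix, variants=variants)

    ref_eur = draw(p_eur, n_per_ref, "EUR")
    ref_out = draw(p_out, n_per_ref, "OUT")
    ref_fc = draw(p_fc, n_per_ref, "FCR")
    n_fc, n_eur, n_out = cohort_sizes
    cohort_parts = [draw(p_fc, n_fc, "QFC"), draw(p_eur, n_eur, "QEU"),
                    draw(p_out, n_out, "QOU")]
    cohort = GenotypeMatrix(
        samples=[s for part in cohort_parts for s in part.samples],
        variants=variants,
        dosage=np.vstack([part.dosage for part in cohort_parts]),
    )
    truth = np.array(["FC"] * n_fc + ["EUR"] * n_eur + ["OUT"] * n_out)
    stage1 = GenotypeMatrix(
        samples=ref_eur.samples + ref_out.samples,
        variants=variants,
        dosage=np.vstack([ref_eur.dosage, ref_out.dosage]),
    )
    stage2 = GenotypeMatrix(
        samples=ref_fc.samples + ref_eur.samples,
        variants=variants,
        dosage=np.vstack([ref_fc.dosage, ref_eur.dosage]),
    )
    return {
        "stage1_ref": stage1,
        "stage1_labels": np.array(["EUR"] * n_per_ref + ["OUT"] * n_per_ref),
        "stage2_ref": stage2,
        "stage2_labels": np.array(["FC"] * n_per_ref + ["EUR"] * n_per_ref),
        "cohort": cohort,
        "truth": truth,
    }


def trios_to_pedigree(trios: TrioSet, prefix: str = "T") -> Pedigree:
    """FAM-style pedigree matching a simulated :class:`TrioSet`.

    Children are coded affected (phenotype 2), parents unaffected (1);
    sexes follow the father/mother roles.
    """
    rows = []
    for t in range(trios.n_trios):
        fam = f"{prefix}FAM{t:04d}"
        fa, mo, ch = f"{prefix}F{t:04d}", f"{prefix}M{t:04d}", f"{prefix}C{t:04d}"
        rows.append((fam, fa, "0", "0", 1, 1))
        rows.append((fam, mo, "0", "0", 2, 1))
        rows.append((fam, ch, fa, mo, 1, 2))
    return Pedigree(pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
    ))
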