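"""Per-variant allele-frequency enrichment against a reference panel.

For each variant the target cohort's minor/major allele counts are compared
with a large reference panel (a gnomAD-NFE-like count table):

* **fold** — the MAF ratio target/reference (undefined when the variant is
  absent from the reference; use the bias-corrected OR there),
* **one-sided Fisher p** — the hypergeometric upper-tail probability of the
  target minor-allele count at fixed margins (enrichment direction only),
* **bias-corrected OR** — the odds ratio after adding 0.5 to every allele
  count (Haldane-Anscombe), finite even at zero reference counts,
* frequency-bin and consequence-class labels for cohort-level summaries of
  how much of the exome is enriched beyond 4x / 10x / 100x.

Minor-allele orientation: counts are oriented to the allele that is minor
in the *reference* panel; when the variant is absent from the reference the
target defines minor.  A variant absent from the reference table gets
ac_ref = 0 with a user-supplied default reference AN so the corrected OR
remains computable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import VARIANT_COLS, GenotypeMatrix

__all__ = [
    "build_frequency_table",
    "orient_to_minor",
    "maf_fold",
    "fisher_one_sided",
    "bias_corrected_or",
    "assign_freq_bin",
    "enrichment_table",
    "enrichment_summary",
]

FREQ_BINS = ("ultra_rare", "rare", "intermediate", "common")


def build_frequency_table(
    target: GenotypeMatrix | pd.DataFrame,
    reference: pd.DataFrame,
    default_ref_an: int,
) -> pd.DataFrame:
    """Join target allele counts with a reference count table by variant key.

    *target* is a genotype matrix (counts computed over called genotypes) or
    a count table with ``ac``/``an`` columns.  Variants missing from the
    reference receive ``ac_ref = 0`` and ``an_ref = default_ref_an`` so the
    bias-corrected OR path stays usable.  Output columns: variant key +
    ``ac_target, an_target, ac_ref, an_ref`` (ALT-allele counts, unoriented).
    """
    if isinstance(target, GenotypeMatrix):
        ac, an = target.allele_counts()
        tgt = target.variants.copy()
        tgt["ac"], tgt["an"] = ac, an
    else:
        tgt = target.copy()
    tgt = tgt.rename(columns={"ac": "ac_target", "an": "an_target"})
    ref = reference.rename(columns={"ac": "ac_ref", "an": "an_ref"})
    out = tgt.merge(ref[VARIANT_COLS + ["ac_ref", "an_ref"]],
                    on=VARIANT_COLS, how="left")
    absent = out["an_ref"].isna()
    out.loc[absent, "ac_ref"] = 0
    out.loc[absent, "an_ref"] = default_ref_an
    out["ac_ref"] = out["ac_ref"].astype(np.int64)
    out["an_ref"] = out["an_ref"].astype(np.int64)
    return out


def orient_to_minor(freq: pd.DataFrame) -> pd.DataFrame:
    """Flip counts so they track the reference panel's minor allele.

    If the reference frequency exceeds 1/2 both panels' counts are flipped
    (ac -> an - ac); if the variant is absent from the reference, the
    target's minor allele defines the orientation.  Adds a ``flipped``
    bookkeeping column.
    """
    out = freq.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_af = np.where(out["an_ref"] > 0, out["ac_ref"] / out["an_ref"], np.nan)
        tgt_af = np.where(out["an_target"] > 0,
                          out["ac_target"] / out["an_target"], np.nan)
    ref_present = out["ac_ref"].to_numpy() > 0
    flip = np.where(ref_present, ref_af > 0.5, tgt_af > 0.5)
    out["ac_target"] = np.where(flip, out["an_target"] - out["ac_target"],
                                out["ac_target"])
    out["ac_ref"] = np.where(flip, out["an_ref"] - out["ac_ref"], out["ac_ref"])
    out["flipped"] = flip
    return out


def maf_fold(ac_target, an_target, ac_ref, an_ref):
    """MAF ratio (target / reference); NaN where the reference MAF is zero.

    Counts must already be minor-oriented.  A variant absent from the target
    gives fold 0; one absent from the reference gives NaN (use the
    bias-corrected OR instead).
    """
    ac_t = np.asarray(ac_target, dtype=float)
    an_t = np.asarray(an_target, dtype=float)
    ac_r = np.asarray(ac_ref, dtype=float)
    an_r = np.asarray(an_ref, dtype=float)
    if (an_t <= 0).any() or (an_r <= 0).any():
        raise ValueError("AN must be positive in both panels")
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = (ac_t / an_t) / (ac_r / an_r)
    return np.where(ac_r > 0, fold, np.where(ac_t > 0, np.nan, 0.0))


def fisher_one_sided(ac_target, an_target, ac_ref, an_ref):
    """One-sided Fisher exact p for target minor-allele excess.

    Hypergeometric upper tail at fixed margins: the probability that the
    target panel holds at least the observed number of minor alleles when
    minor alleles are distributed at random between the panels.  A target
    count of zero gives p = 1 (the least extreme outcome).
    """
    ac_t = np.asarray(ac_target, dtype=np.int64)
    an_t = np.asarray(an_target, dtype=np.int64)
    ac_r = np.asarray(ac_ref, dtype=np.int64)
    an_r = np.asarray(an_ref, dtype=np.int64)
    total = an_t + an_r
    if (total <= 0).any():
        raise ValueError("zero total allele count")
    return stats.hypergeom.sf(ac_t - 1, total, ac_t + ac_r, an_t)


def bias_corrected_or(ac_target, an_target, ac_ref, an_ref):
    """Haldane-Anscombe odds ratio: 0.5 added to minor and major counts.

    ((ac_t + .5)/(an_t - ac_t + .5)) / ((ac_r + .5)/(an_r - ac_r + .5));
    finite and positive for every table, including zero reference counts.
    """
    ac_t = np.asarray(ac_target, dtype=float)
    an_t = np.asarray(an_target, dtype=float)
    ac_r = np.asarray(ac_ref, dtype=float)
    an_r = np.asarray(an_ref, dtype=float)
    return ((ac_t + 0.5) / (an_t - ac_t + 0.5)) / ((ac_r + 0.5) / (an_r - ac_r + 0.5))


def assign_freq_bin(ac_target, an_target):
    """Frequency-bin labels from target minor counts.

    ``ultra_rare`` (AC < 4) takes precedence; the remaining bins partition
    by target MAF with closed-left boundaries: rare < 0.01 <= intermediate
    < 0.05 <= common.
    """
    ac = np.asarray(ac_target, dtype=float)
    an = np.asarray(an_target, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(an > 0, ac / an, np.nan)
    out = np.where(
        ac < 4, "ultra_rare",
        np.where(m < 0.01, "rare", np.where(m < 0.05, "intermediate", "common")),
    )
    return out.astype(object)


def enrichment_table(
    freq: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    significance_alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-variant enrichment statistics for a joined frequency table.

    Orients counts to the reference minor allele, then computes fold,
    one-sided Fisher p, bias-corrected OR, frequency bin, and a
    ``significant`` flag (raw p < alpha, matching the study's convention of
    reporting raw one-sided p-values; an optional Bonferroni column can be
    added but is off by default).
    """
    out = orient_to_minor(freq)
    out["maf_target"] = out["ac_target"] / out["an_target"]
    out["maf_ref"] = np.where(out["an_ref"] > 0, out["ac_ref"] / out["an_ref"], np.nan)
    out["fold"] = maf_fold(out["ac_target"], out["an_target"],
                           out["ac_ref"], out["an_ref"])
    out["p_one_sided"] = fisher_one_sided(out["ac_target"], out["an_target"],
                                          out["ac_ref"], out["an_ref"])
    out["or_corrected"] = bias_corrected_or(out["ac_target"], out["an_target"],
                                            out["ac_ref"], out["an_ref"])
    out["freq_bin"] = assign_freq_bin(out["ac_target"], out["an_target"])
    out["significant"] = out["p_one_sided"] < significance_alpha
    if bonferroni:
        out["p_bonferroni"] = np.minimum(out["p_one_sided"] * len(out), 1.0)
    if annotations is not None:
        out = out.merge(
            annotations[VARIANT_COLS + ["consequence", "clinvar", "gene"]],
            on=VARIANT_COLS, how="left",
        )
        out["consequence"] = out["consequence"].fillna("other")
    return out


def _effective_fold(results: pd.DataFrame) -> np.ndarray:
    """Fold where defined, bias-corrected OR where the reference MAF is zero."""
    fold = results["fold"].to_numpy(dtype=float)
    return np.where(np.isnan(fold), results["or_corrected"].to_numpy(dtype=float), fold)


def enrichment_summary(
    results: pd.DataFrame,
    folds: tuple[float, ...] = (4, 10, 100),
    by: tuple[str, ...] = ("consequence", "freq_bin"),
) -> dict:
    """Cohort-level fold-enrichment fractions, overall and stratified.

    For each fold threshold, reports the fraction of variants at or above it
    (with numerator and denominator), overall and within each stratum of the
    ``by`` columns.  Variants absent from the reference are counted through
    their bias-corrected OR.  Variants absent from the target (fold 0) count
    only in denominators.
    """
    eff = _effective_fold(results)

    def frac(mask: np.ndarray) -> dict:
        n = int(mask.sum())
        entry: dict = {"n": n}
        for f in folds:
            k = int((eff[mask] >= f).sum())
            entry[f"ge_{f:g}x"] = {
                "count": k,
                "fraction": (k / n) if n else float("nan"),
            }
        return entry

    summary = {"overall": frac(np.ones(len(results), dtype=bool))}
    for col in by:
        if col not in results.columns:
            continue
        strata = {}
        for value in sorted(results[col].dropna().unique()):
            strata[str(value)] = frac((results[col] == value).to_numpy())
        summary[f"by_{col}"] = strata
    return summary
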