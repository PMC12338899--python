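"""Carrier-frequency and birth-prevalence estimation for recessive disorders.

Exome-based estimator: with c_v heterozygous carriers of pathogenic variant
v among n sequenced individuals, the cumulative pathogenic allele frequency
is q = sum_v c_v / (2n) (homozygotes, if any, contribute two alleles), and
under Hardy-Weinberg equilibrium with full penetrance the disease birth
prevalence is q^2 — reported per 100,000 births and as "1 in N" with N
rounded after taking the reciprocal.  The per-variant carrier frequency is
reported as 1 in round(n / c_v).

The confidence interval is Clopper-Pearson on the summed allele count out
of 2n chromosomes, with the binomial bounds squared and scaled to
per-100,000 — a defensible default for a model whose published interval
method is unstated (so the CI is a reference output, not a reproduction
target).

Clinical estimator: observed cases divided by an effective birth
denominator — total registered births scaled by the population's language
fraction (default 0.8) and the ascertaining center's coverage of that
population (default 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CarrierSummary",
    "exome_birth_prevalence",
    "prevalence_ci",
    "clinical_birth_prevalence",
    "allele_share",
]


@dataclass
class CarrierSummary:
    """Gene-level carrier and birth-prevalence summary.

    ``prevalence_per_100k`` is exact (q^2 * 1e5); the two "one in N" fields
    hold reciprocals rounded to the nearest integer, or ``inf`` when the
    carrier count is zero.
    """

    gene: str
    carrier_counts: list[int]
    n_individuals: int
    total_carriers: int
    q: float
    carrier_one_in: float
    prevalence_per_100k: float
    prevalence_one_in: float
    ci_low_per_100k: float | None = None
    ci_high_per_100k: float | None = None
    assumptions: tuple[str, ...] = (
        "Hardy-Weinberg equilibrium",
        "full penetrance of pathogenic/likely-pathogenic variants",
        "no reproductive compensation",
    )
    per_variant_carrier_one_in: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "n_individuals": self.n_individuals,
            "total_carriers": self.total_carriers,
            "cumulative_allele_frequency": self.q,
            "carrier_one_in": self.carrier_one_in,
            "prevalence_per_100k": round(self.prevalence_per_100k, 2),
            "prevalence_one_in": self.prevalence_one_in,
            "ci_per_100k": [self.ci_low_per_100k, self.ci_high_per_100k],
            "assumptions": list(self.assumptions),
        }


def carrier_one_in(carriers: int, n_individuals: int) -> float:
    """Carrier frequency as '1 in N': round(n / carriers); inf at zero."""
    if carriers < 0 or n_individuals <= 0:
        raise ValueError("need carriers >= 0 and n_individuals > 0")
    if carriers == 0:
        return float("inf")
    return float(round(n_individuals / carriers))


def exome_birth_prevalence(
    carrier_counts,
    n_individuals: int,
    gene: str = "",
    hom_counts=None,
    ci_level: float | None = 0.95,
) -> CarrierSummary:
    """Birth prevalence of a recessive disorder from cohort carrier counts.

    *carrier_counts* are per-variant heterozygous-carrier counts;
    *hom_counts* (optional, same length) are homozygote counts contributing
    two alleles each.  q = (sum het + 2 sum hom) / (2 n); prevalence = q^2.
    Zero carriers gives prevalence 0 and infinite "one in N" values.
    """
    counts = [int(c) for c in np.atleast_1d(carrier_counts)]
    homs = ([0] * len(counts) if hom_counts is None
            else [int(h) for h in np.atleast_1d(hom_counts)])
    if len(homs) != len(counts):
        raise ValueError("hom_counts length must match carrier_counts")
    if any(c < 0 for c in counts) or any(h < 0 for h in homs):
        raise ValueError("carrier counts must be non-negative")
    total_het = sum(counts)
    total_hom = sum(homs)
    total_carriers = total_het + total_hom
    if total_carriers > n_individuals:
        raise ValueError("more carriers than individuals")
    alleles = total_het + 2 * total_hom
    q = alleles / (2 * n_individuals)
    prevalence = q**2
    ci_low = ci_high = None
    if ci_level is not None:
        ci_low, ci_high = prevalence_ci(alleles, n_individuals, level=ci_level)
    return CarrierSummary(
        gene=gene,
        carrier_counts=counts,
        n_individuals=n_individuals,
        total_carriers=total_carriers,
        q=q,
        carrier_one_in=carrier_one_in(total_carriers, n_individuals),
        prevalence_per_100k=prevalence * 1e5,
        prevalence_one_in=float(round(1.0 / prevalence)) if prevalence > 0 else float("inf"),
        ci_low_per_100k=ci_low,
        ci_high_per_100k=ci_high,
        per_variant_carrier_one_in=[carrier_one_in(c, n_individuals) for c in counts],
    )


def prevalence_ci(allele_count: int, n_individuals: int, level: float = 0.95
                  ) -> tuple[float, float]:
    """Clopper-Pearson interval on q, squared and scaled to per-100,000.

    The exact binomial interval for the allele count out of 2n chromosomes
    maps monotonically to prevalence under the q^2 model, so squaring the
    bounds preserves coverage.  allele_count = 0 gives a lower bound of 0.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    n_alleles = 2 * n_individuals
    alpha = 1.0 - level
    if allele_count == 0:
        q_low = 0.0
    else:
        q_low = stats.beta.ppf(alpha / 2, allele_count, n_alleles - allele_count + 1)
    if allele_count == n_alleles:
        q_high = 1.0
    else:
        q_high = stats.beta.ppf(1 - alpha / 2, allele_count + 1, n_alleles - allele_count)
    return float(q_low**2 * 1e5), float(q_high**2 * 1e5)


def clinical_birth_prevalence(
    cases: int,
    total_births: float,
    language_fraction: float = 0.8,
    center_coverage: float = 0.4,
) -> dict:
    """Birth prevalence from clinically ascertained cases.

    prevalence = cases / (total_births * language_fraction * center_coverage):
    registered births are scaled to the target population by its language
    fraction, then to the ascertaining center's catchment share.
    """
    if cases < 0:
        raise ValueError("cases must be >= 0")
    denom = total_births * language_fraction * center_coverage
    if denom <= 0:
        raise ValueError("effective birth denominator must be positive")
    prevalence = cases / denom
    return {
        "cases": cases,
        "effective_births": denom,
        "prevalence_per_100k": prevalence * 1e5,
        "prevalence_one_in": float(round(1.0 / prevalence)) if prevalence > 0 else float("inf"),
    }


def allele_share(variant_alleles: int, total_alleles: int) -> float:
    """Share (percent) of disease alleles attributable to one variant."""
    if total_alleles <= 0 or not 0 <= variant_alleles <= total_alleles:
        raise ValueError("need 0 <= variant_alleles <= total_alleles, total > 0")
    return 100.0 * variant_alleles / total_alleles
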