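"""Population structure: LD pruning, PCA projection, KNN and regional assignment.

The ancestry workflow mirrors a two-stage reference-projection design:
fit PCA on a labeled reference panel (worldwide panel first, then a regional
panel combined with continental Europeans), project study samples into that
space, and classify each sample by majority vote among its k nearest
reference samples.  Regional subpopulations are then assigned by fixed
cutoffs on the regional-panel PC coordinates, and per-variant carrier
concentration in a region is tested with a 2x2 chi-squared test.

Standardization uses the reference panel's allele frequencies for both the
fit and the projection — projection never re-estimates frequencies, which
keeps study coordinates comparable to the stored reference scores.
Low-overlap projections shrink toward the origin; this is documented, not
corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix, variant_key_index

__all__ = [
    "ld_prune",
    "AncestryModel",
    "fit_pca",
    "project",
    "knn_assign",
    "RegionalCutoffs",
    "assign_region",
    "regional_carrier_test",
]


def ld_prune(
    gm: GenotypeMatrix,
    window_bp: int = 50_000,
    step: int = 5,
    r2: float = 0.5,
    maf_min: float = 0.01,
    max_missing: float = 0.01,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns kept variant indices.

    Variants failing the MAF/missingness prefilter are excluded outright.
    Within each ``window_bp`` window (advanced by ``step`` variants), for
    every pair with squared correlation above ``r2`` the later-positioned
    variant is dropped — a deterministic greedy sweep in position order.
    """
    af = gm.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(af, 1 - af)
    ok = (maf > maf_min) & (gm.missingness() < max_missing) & ~np.isnan(af)
    cand = np.nonzero(ok)[0]
    if cand.size == 0:
        return cand
    # order candidates by (chrom, pos) for the positional sweep
    order = np.lexsort((gm.variants["pos"].to_numpy()[cand],
                        gm.variants["chrom"].to_numpy()[cand]))
    cand = cand[order]
    pos = gm.variants["pos"].to_numpy()[cand]
    chrom = gm.variants["chrom"].to_numpy()[cand]

    G = np.where(gm.dosage[:, cand] == MISSING, np.nan, gm.dosage[:, cand].astype(float))
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)
    G = G - G.mean(axis=0)
    norms = np.sqrt((G**2).sum(axis=0))
    norms[norms == 0] = np.inf
    G = G / norms

    keep = np.ones(cand.size, dtype=bool)
    start = 0
    while start < cand.size:
        # window = variants within window_bp of the window's first variant
        end = start
        while (end < cand.size and chrom[end] == chrom[start]
               and pos[end] - pos[start] <= window_bp):
            end += 1
        idx = np.arange(start, end)
        idx = idx[keep[idx]]
        if idx.size > 1:
            C2 = (G[:, idx].T @ G[:, idx]) ** 2
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                later = idx[a + 1:][keep[idx[a + 1:]]]
                hit = later[C2[a, a + 1:][keep[idx[a + 1:]]] > r2]
                keep[hit] = False
        start += step
    return np.sort(cand[keep])


@dataclass
class AncestryModel:
    """Fitted reference PCA with labeled reference coordinates.

    ``loadings`` columns are orthonormal; ``scores`` are the reference
    samples' coordinates (U * S); standardization constants come from the
    reference panel's allele frequencies.
    """

    variant_keys: pd.Index
    mean: np.ndarray            # 2 * p_hat per variant
    scale: np.ndarray           # sqrt(2 p_hat (1 - p_hat))
    loadings: np.ndarray        # (m, K)
    scores: np.ndarray          # (n_ref, K)
    explained_variance: np.ndarray
    ref_samples: list[str] = field(default_factory=list)
    ref_labels: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _standardize(gm: GenotypeMatrix, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    G = np.where(gm.dosage == MISSING, np.nan, gm.dosage.astype(float))
    G = np.where(np.isnan(G), mean, G)  # mean-impute residual missingness
    return (G - mean) / scale


def fit_pca(reference: GenotypeMatrix, K: int = 20,
            ref_labels: np.ndarray | None = None) -> AncestryModel:
    """PCA of a reference panel on (LD-pruned) variants.

    Genotypes are centered by 2*p_hat and scaled by sqrt(2 p_hat (1-p_hat))
    with p_hat from the reference panel, then decomposed by truncated SVD.
    Monomorphic variants are excluded from the model (zero scale).
    """
    if K > min(reference.n_samples, reference.n_variants):
        raise ValueError(f"K={K} exceeds the rank bound "
                         f"min(n={reference.n_samples}, m={reference.n_variants})")
    af = reference.allele_freq()
    poly = (af > 0) & (af < 1) & ~np.isnan(af)
    ref = reference.take_variants(np.nonzero(poly)[0])
    p = ref.allele_freq()
    mean = 2 * p
    scale = np.sqrt(2 * p * (1 - p))
    X = _standardize(ref, mean, scale)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :K], S[:K], Vt[:K]
    return AncestryModel(
        variant_keys=variant_key_index(ref.variants),
        mean=mean,
        scale=scale,
        loadings=Vt.T,
        scores=U * S,
        explained_variance=S**2 / max(ref.n_samples - 1, 1),
        ref_samples=list(ref.samples),
        ref_labels=None if ref_labels is None else np.asarray(ref_labels),
    )


def project(model: AncestryModel, gm: GenotypeMatrix) -> np.ndarray:
    """Project samples onto a fitted reference PCA.

    Uses the intersection of model and sample variants; missing genotypes
    are imputed to the reference mean.  With partial overlap the projected
    coordinates shrink toward the origin (no correction applied).
    """
    keys = variant_key_index(gm.variants)
    common = model.variant_keys.intersection(keys)
    if len(common) == 0:
        raise ValueError("no variants in common between model and samples")
    mpos = pd.Series(np.arange(len(model.variant_keys)), index=model.variant_keys)
    gpos = pd.Series(np.arange(len(keys)), index=keys)
    mi = mpos[common].to_numpy()
    gi = gpos[common].to_numpy()
    sub = gm.take_variants(gi)
    X = _standardize(sub, model.mean[mi], model.scale[mi])
    return X @ model.loadings[mi]


def knn_assign(
    model: AncestryModel,
    coords: np.ndarray,
    groupA_labels: set[str] | list[str],
    k: int = 10,
    threshold: int = 8,
    n_pcs: int = 20,
) -> np.ndarray:
    """Binary KNN population assignment against labeled reference scores.

    For each sample, Euclidean distances to every reference sample on the
    top ``n_pcs`` PCs are ranked (ties broken by reference-sample order, so
    the assignment is deterministic and invariant to sample order); if at
    least ``threshold`` of the ``k`` nearest reference samples carry a
    group-A label, the sample is assigned group A (returns True).
    """
    if model.ref_labels is None:
        raise ValueError("model has no reference labels")
    if k > len(model.ref_samples):
        raise ValueError(f"k={k} exceeds reference panel size {len(model.ref_samples)}")
    n_pcs = min(n_pcs, model.n_components)
    ref = model.scores[:, :n_pcs]
    pts = np.atleast_2d(coords)[:, :n_pcs]
    is_a = np.isin(model.ref_labels, list(groupA_labels))
    d2 = ((pts[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    # stable argsort: equal distances resolve by reference index order
    nearest = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = is_a[nearest].sum(axis=1)
    return votes >= threshold


@dataclass
class RegionalCutoffs:
    """Priority-ordered PC-coordinate rules for regional assignment.

    ``rules`` maps a region name to a list of ``(pc, op, value)`` clauses
    (1-based PC index, op in {"ge", "le"}), all of which must hold.  The
    first matching region wins; unmatched samples get ``"other"``.  The
    default carries the two regions with published numeric cutoffs —
    Saguenay-Lac-Saint-Jean (SAG: PC1 >= 0.025) and the North Shore
    (NS: PC1 <= -0.025 and PC2 >= 0.01).  No numeric rule is published for
    the Gaspesia Acadian region, so none ships; supply one here if needed.
    """

    rules: dict[str, list[tuple[int, str, float]]] = field(
        default_factory=lambda: {
            "SAG": [(1, "ge", 0.025)],
            "NS": [(1, "le", -0.025), (2, "ge", 0.01)],
        }
    )

    def __post_init__(self) -> None:
        for region, clauses in self.rules.items():
            for pc, op, _ in clauses:
                if op not in ("ge", "le"):
                    raise ValueError(f"{region}: op must be 'ge' or 'le', got {op!r}")
                if pc < 1:
                    raise ValueError(f"{region}: PC indices are 1-based")


def assign_region(coords: np.ndarray, cutoffs: RegionalCutoffs | None = None) -> np.ndarray:
    """Assign each sample to the first region whose PC clauses all hold."""
    cutoffs = cutoffs or RegionalCutoffs()
    pts = np.atleast_2d(coords)
    out = np.full(pts.shape[0], "other", dtype=object)
    unassigned = np.ones(pts.shape[0], dtype=bool)
    for region, clauses in cutoffs.rules.items():
        match = unassigned.copy()
        for pc, op, value in clauses:
            col = pts[:, pc - 1]
            match &= (col >= value) if op == "ge" else (col <= value)
        out[match] = region
        unassigned &= ~match
    return out.astype(str)


def regional_carrier_test(
    carrier: np.ndarray,
    region_labels: np.ndarray,
    region: str,
    correction: bool = False,
) -> tuple[float, float]:
    """Chi-squared test of carrier concentration within a region.

    Builds the 2x2 carrier x in-region contingency table and applies the
    Pearson chi-squared test (1 df, no continuity correction by default).
    A zero margin (no carriers, or nobody in/out of the region) yields
    (nan, nan) with a warning.
    """
    carrier = np.asarray(carrier, dtype=bool)
    in_region = np.asarray(region_labels) == region
    table = np.array([
        [(carrier & in_region).sum(), (carrier & ~in_region).sum()],
        [(~carrier & in_region).sum(), (~carrier & ~in_region).sum()],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); returning NaN")
        return float("nan"), float("nan")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)
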