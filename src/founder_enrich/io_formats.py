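"""Readers and writers for the file formats the pipeline touches.

Dialect decisions
-----------------
* VCF 4.2/4.3, **biallelic records only**.  Multiallelic sites must be split
  upstream (e.g. ``bcftools norm -m-``); a multiallelic record is a hard
  error, never silently dropped.  ``GT`` is required; ``DP`` and ``AD`` are
  optional and carried through when present.
* Coordinates are 1-based (VCF convention).  BED input is 0-based half-open
  and converted to 1-based **closed** intervals on read.
* PLINK FAM is whitespace-delimited, six columns, parent id ``0`` = founder.
* Frequency and annotation tables are TSV with a header line; the variant key
  ``(chrom, pos, ref, alt)`` is the only join key across tables and joins are
  order-independent.

Tabular record types (FrequencyRecord, AnnotationRecord) are represented as
:class:`pandas.DataFrame` objects with documented, validated columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("founder_enrich.io")

#: sentinel for a missing genotype / depth value in integer arrays
MISSING = -1

#: columns forming the variant key, in order
VARIANT_COLS = ["chrom", "pos", "ref", "alt"]

#: closed vocabulary of functional consequence classes
CONSEQUENCES = frozenset({"synonymous", "missense", "pLoF_HC", "other"})

#: closed vocabulary of clinical-significance classes
CLINVAR_CLASSES = frozenset({"P", "LP", "conflicting", "benign", "VUS", "none"})


def variant_key_index(variants: pd.DataFrame) -> pd.Index:
    """``chrom:pos:ref:alt`` string key for each row of a variant table."""
    return pd.Index(
        variants["chrom"].astype(str)
        + ":"
        + variants["pos"].astype(str)
        + ":"
        + variants["ref"].astype(str)
        + ":"
        + variants["alt"].astype(str)
    )


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x variants ALT-allele dosage with optional depth fields.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, one per matrix row.
    variants : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (int, 1-based), ``ref``, ``alt``.
    dosage : ndarray of int8, shape (n_samples, n_variants)
        ALT-allele count per genotype: 0, 1, 2 or :data:`MISSING`.
    depth, ad_ref, ad_alt : ndarray of int32 or None
        Per-genotype total read depth and per-allele read depths; ``None``
        when the source carried no DP/AD, :data:`MISSING` per entry otherwise.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def keys(self) -> pd.Index:
        return variant_key_index(self.variants)

    # -- derived per-variant summaries ------------------------------------

    def called_mask(self) -> np.ndarray:
        return self.dosage != MISSING

    def missingness(self) -> np.ndarray:
        """Fraction of missing genotypes per variant."""
        return (self.dosage == MISSING).mean(axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(AC, AN) of the ALT allele per variant, over called genotypes."""
        called = self.called_mask()
        ac = np.where(called, self.dosage, 0).sum(axis=0).astype(np.int64)
        an = 2 * called.sum(axis=0).astype(np.int64)
        return ac, an

    def allele_freq(self) -> np.ndarray:
        """ALT-allele frequency per variant; NaN where fully missing."""
        ac, an = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / np.maximum(an, 1), np.nan)

    def genotype_counts(self) -> np.ndarray:
        """Per-variant genotype counts, shape (n_variants, 3): hom-ref, het, hom-alt."""
        out = np.empty((self.n_variants, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.dosage == g).sum(axis=0)
        return out

    # -- subsetting --------------------------------------------------------

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
            depth=None if self.depth is None else self.depth[:, idx].copy(),
            ad_ref=None if self.ad_ref is None else self.ad_ref[:, idx].copy(),
            ad_alt=None if self.ad_alt is None else self.ad_alt[:, idx].copy(),
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
            dosage=self.dosage[idx].copy(),
            depth=None if self.depth is None else self.depth[idx].copy(),
            ad_ref=None if self.ad_ref is None else self.ad_ref[idx].copy(),
            ad_alt=None if self.ad_alt is None else self.ad_alt[idx].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return self.take_samples(np.arange(self.n_samples))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are rejected with an instruction to pre-split;
    half-calls (``0/.``) and ``./.`` become missing; non-diploid genotypes
    are a hard error naming the offending record.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    n = len(samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    adr_rows: list[np.ndarray] = []
    ada_rows: list[np.ndarray] = []
    has_dp = False
    has_ad = False
    for rec in vcf:
        label = f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {label}: split multiallelic sites "
                "into biallelic variants first (bcftools norm -m-)"
            )
        dos = np.full(n, MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            # cyvcf2 genotype entry: [allele0, allele1, phased]
            if len(gt) != 3:
                raise ValueError(f"non-diploid genotype for sample {samples[i]} at {label}")
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:  # includes half-calls
                continue
            dos[i] = a0 + a1
        dosage_rows.append(dos)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])

        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_dp = True
            dp = dp.reshape(n).astype(np.int64)
            dp = np.where(dp < 0, MISSING, dp)
        depth_rows.append(dp if dp is not None else np.full(n, MISSING, dtype=np.int64))

        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is not None and ad.shape[1] >= 2:
            has_ad = True
            adr = ad[:, 0].astype(np.int64)
            ada = ad[:, 1].astype(np.int64)
            adr = np.where(adr < 0, MISSING, adr)
            ada = np.where(ada < 0, MISSING, ada)
        else:
            adr = np.full(n, MISSING, dtype=np.int64)
            ada = np.full(n, MISSING, dtype=np.int64)
        adr_rows.append(adr)
        ada_rows.append(ada)

    variants = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64), "ref": refs, "alt": alts}
    )
    m = len(variants)
    dosage = (
        np.stack(dosage_rows, axis=1) if m else np.zeros((n, 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)
    if has_dp and m:
        gm.depth = np.stack(depth_rows, axis=1).astype(np.int32)
    if has_ad and m:
        gm.ad_ref = np.stack(adr_rows, axis=1).astype(np.int32)
        gm.ad_alt = np.stack(ada_rows, axis=1).astype(np.int32)
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 text file."""
    with_dp = gm.depth is not None
    with_ad = gm.ad_ref is not None and gm.ad_alt is not None
    fmt = "GT" + (":DP" if with_dp else "") + (":AD" if with_ad else "")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if with_ad:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths (ref,alt)">\n'
            )
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(gm.n_variants):
            v = gm.variants.iloc[j]
            cells = []
            for i in range(gm.n_samples):
                cell = _GT_STR[int(gm.dosage[i, j])]
                if with_dp:
                    d = int(gm.depth[i, j])
                    cell += ":" + ("." if d == MISSING else str(d))
                if with_ad:
                    r, a = int(gm.ad_ref[i, j]), int(gm.ad_alt[i, j])
                    cell += ":" + (
                        ".,." if r == MISSING or a == MISSING else f"{r},{a}"
                    )
                cells.append(cell)
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t.\t{v['ref']}\t{v['alt']}\t.\t.\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Pedigree (PLINK FAM)
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """PLINK-FAM pedigree: columns fid, iid, father, mother, sex, phenotype.

    Phenotype coding is PLINK's: 1 unaffected, 2 affected, 0/-9 missing.
    Parent id ``"0"`` means unknown/founder.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = ["fid", "iid", "father", "mother", "sex", "phenotype"]
        missing_cols = [c for c in required if c not in self.table.columns]
        if missing_cols:
            raise ValueError(f"pedigree table lacks columns: {missing_cols}")
        ids = set(self.table["iid"])
        for col in ("father", "mother"):
            unresolved = set(self.table[col]) - ids - {"0"}
            if unresolved:
                logger.warning(
                    "%d %s ids not present as individuals (treated as founders)",
                    len(unresolved), col,
                )
        self._check_no_ancestor_cycle()

    def _check_no_ancestor_cycle(self) -> None:
        parents = {
            r.iid: [p for p in (r.father, r.mother) if p != "0"]
            for r in self.table.itertuples()
        }
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(node: str, stack: list[str]) -> None:
            if state.get(node) == 1:
                return
            if state.get(node) == 0:
                raise ValueError(f"pedigree cycle: individual {node} is its own ancestor")
            state[node] = 0
            for p in parents.get(node, []):
                visit(p, stack)
            state[node] = 1

        for iid in parents:
            visit(iid, [])

    def complete_trios(self, samples: list[str] | None = None) -> pd.DataFrame:
        """Rows (child, father, mother) where both parents are resolvable.

        If *samples* is given, all three members must be in it.
        """
        present = set(self.table["iid"]) if samples is None else set(samples)
        ids = set(self.table["iid"])
        rows = []
        for r in self.table.itertuples():
            if r.father == "0" or r.mother == "0":
                continue
            if r.father not in ids or r.mother not in ids:
                continue
            if {r.iid, r.father, r.mother} <= present:
                rows.append((r.iid, r.father, r.mother))
        return pd.DataFrame(rows, columns=["child", "father", "mother"])


def read_fam(path: str) -> Pedigree:
    """Read a whitespace-delimited 6-column PLINK FAM file."""
    table = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    table["sex"] = table["sex"].astype(int)
    table["phenotype"] = table["phenotype"].astype(int)
    if table["iid"].duplicated().any():
        dup = table.loc[table["iid"].duplicated(), "iid"].iloc[0]
        raise ValueError(f"duplicate individual id in FAM: {dup}")
    return Pedigree(table)


def write_fam(ped: Pedigree, path: str) -> None:
    ped.table.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Frequency and annotation tables
# ---------------------------------------------------------------------------


def _check_variant_table(df: pd.DataFrame, path: str) -> pd.DataFrame:
    for col in VARIANT_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    dup = variant_key_index(df).duplicated()
    if dup.any():
        key = variant_key_index(df)[dup][0]
        raise ValueError(f"{path}: duplicate variant key {key}")
    return df


def read_frequency_table(path: str) -> pd.DataFrame:
    """Read a per-panel allele-count TSV.

    Expected columns: ``chrom  pos  ref  alt  AC  AN`` (header required).
    Returns a DataFrame with lower-cased ``ac``/``an`` int64 columns.
    Raises on AC > AN, negative counts or duplicate variant keys.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = [c.lower() for c in df.columns]
    df = _check_variant_table(df, str(path))
    for col in ("ac", "an"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col.upper()}'")
        df[col] = df[col].astype(np.int64)
    if (df["ac"] < 0).any() or (df["an"] < 0).any():
        raise ValueError(f"{path}: negative allele counts")
    bad = df["ac"] > df["an"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"{path}: AC > AN at {row['chrom']}:{row['pos']} ({row['ac']} > {row['an']})"
        )
    return df[VARIANT_COLS + ["ac", "an"]]


def maf(ac: np.ndarray, an: np.ndarray) -> np.ndarray:
    """Minor-allele frequency from allele counts: min(AC, AN-AC)/AN."""
    ac = np.asarray(ac, dtype=float)
    an = np.asarray(an, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(an > 0, np.minimum(ac, an - ac) / an, np.nan)


def read_annotations(path: str) -> pd.DataFrame:
    """Read a variant annotation TSV.

    Expected columns: ``chrom pos ref alt consequence clinvar gene``.
    Unknown consequence strings are mapped to ``"other"`` and unknown
    clinical-significance strings to ``"none"``, each with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = [c.lower() for c in df.columns]
    df = _check_variant_table(df, str(path))
    for col in ("consequence", "clinvar", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    unknown = ~df["consequence"].isin(CONSEQUENCES)
    if unknown.any():
        logger.warning(
            "%d unknown consequence values mapped to 'other' (e.g. %r)",
            int(unknown.sum()), df.loc[unknown, "consequence"].iloc[0],
        )
        df.loc[unknown, "consequence"] = "other"
    unknown = ~df["clinvar"].isin(CLINVAR_CLASSES)
    if unknown.any():
        logger.warning(
            "%d unknown clinvar values mapped to 'none' (e.g. %r)",
            int(unknown.sum()), df.loc[unknown, "clinvar"].iloc[0],
        )
        df.loc[unknown, "clinvar"] = "none"
    return df[VARIANT_COLS + ["consequence", "clinvar", "gene"]]


def write_frequency_table(df: pd.DataFrame, path: str) -> None:
    out = df.rename(columns={"ac": "AC", "an": "AN"})
    out.to_csv(path, sep="\t", index=False)


def write_annotations(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED capture targets
# ---------------------------------------------------------------------------


def read_bed(path: str) -> pd.DataFrame:
    """Read BED intervals, converting to 1-based closed coordinates.

    Returns a DataFrame with columns ``chrom``, ``start``, ``end`` where
    ``start``/``end`` are both inclusive 1-based positions.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str}, comment="#",
    )
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64) + 1  # 0-based half-open -> 1-based closed
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] < df["start"] - 1).any():
        raise ValueError(f"{path}: interval with end < start")
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    """Write 1-based closed intervals back to 0-based half-open BED."""
    out = df.copy()
    out["start"] = out["start"] - 1
    out[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# JSON export
# ---------------------------------------------------------------------------


def write_json(obj: dict, path: str) -> None:
    """Deterministic JSON export (sorted keys, stable float formatting)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
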