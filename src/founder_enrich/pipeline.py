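"""Pipeline driver: simulate -> qc -> ancestry -> enrich -> prevalence -> assoc.

One :class:`RunConfig` (a declarative YAML file; CLI flags override config
keys) drives a reproducible run.  Each stage reads the files the previous
stage wrote under the run directory, so stages can be toggled and rerun;
a manifest records the package version, the seed, SHA-256 hashes of every
stage input, and per-stage record counts.  The manifest carries no
timestamps, so a rerun with the same config is byte-identical for all
deterministic stages (which, with a fixed seed, is all of them).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import association as assoc_mod
from . import enrichment as enr
from . import io_formats as iof
from . import prevalence as prev
from . import qc as qc_mod
from . import simdata as sim

logger = logging.getLogger("founder_enrich.pipeline")

ALL_STAGES = ("simulate", "qc", "ancestry", "enrich", "prevalence", "assoc")

#: downstream file dependencies per stage, used to fail fast on gaps
STAGE_INPUTS = {
    "simulate": (),
    "qc": ("simulate/cohort.vcf", "simulate/trios.vcf", "simulate/trios.fam",
           "simulate/targets_kit1.bed", "simulate/targets_kit2.bed"),
    "ancestry": ("simulate/ref1.vcf", "simulate/ref2.vcf", "simulate/cohort_scene.vcf"),
    "enrich": ("qc/cohort_qc.vcf", "simulate/ref_counts.tsv",
               "simulate/annotations.tsv"),
    "prevalence": ("qc/cohort_qc.vcf", "simulate/annotations.tsv"),
    "assoc": ("qc/trios_qc.vcf", "simulate/trios.fam", "simulate/cc.vcf",
              "simulate/phenotypes.tsv", "simulate/annotations.tsv"),
}


@dataclass
class RunConfig:
    """Declarative run configuration; see ``RunConfig.from_yaml``."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: dict = field(default_factory=dict)           # SimConfig overrides
    qc: dict = field(default_factory=dict)            # QCConfig overrides
    ancestry: dict = field(default_factory=dict)      # k/threshold/n_pcs/K
    enrich: dict = field(default_factory=dict)        # folds, alpha
    prevalence: dict = field(default_factory=dict)    # gene
    assoc: dict = field(default_factory=dict)         # maf_min, n_genes

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def sim_config(self) -> sim.SimConfig:
        return sim.SimConfig(seed=self.seed, **self.sim)

    def qc_config(self) -> qc_mod.QCConfig:
        return qc_mod.QCConfig(**self.qc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _package_version() -> str:
    try:
        return _pkg_version("founder-enrich")
    except PackageNotFoundError:
        return "unknown"


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, run_dir: Path) -> dict:
    out = run_dir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    sc = cfg.sim_config()
    annotations = sim.simulate_annotations(sc)
    pair = sim.simulate_founder_frequencies(
        sc, classes=annotations["consequence"].to_numpy()
    )
    rng = sc.rng(10)

    cohort = sim.simulate_genotypes(
        pair.founder_freq, sc.n_cohort, rng,
        missing_rate=0.005, mean_depth=40, sample_prefix="U",
    )
    iof.write_vcf(cohort, out / "cohort.vcf")

    trios = sim.simulate_trios(pair.founder_freq, sc.n_trios,
                               sc.planted_effects, rng)
    ped = sim.trios_to_pedigree(trios)
    trio_gm = iof.GenotypeMatrix(
        samples=list(ped.table["iid"]),
        variants=trios.variants,
        dosage=np.vstack([
            np.stack([trios.father[t], trios.mother[t], trios.child[t]])
            for t in range(trios.n_trios)
        ]) if trios.n_trios else np.zeros((0, trios.n_variants), dtype=np.int8),
    )
    iof.write_vcf(trio_gm, out / "trios.vcf")
    iof.write_fam(ped, out / "trios.fam")

    cc, phen = sim.simulate_case_control(
        pair.founder_freq, sc.planted_effects, sc.prevalence,
        sc.n_cases, sc.n_controls, rng,
    )
    iof.write_vcf(cc, out / "cc.vcf")
    pd.DataFrame({"sample": cc.samples, "phenotype": phen}).to_csv(
        out / "phenotypes.tsv", sep="\t", index=False
    )

    ref_counts = sim.simulate_reference_counts(sc, pair.source_freq)
    iof.write_frequency_table(ref_counts, out / "ref_counts.tsv")
    iof.write_annotations(annotations, out / "annotations.tsv")

    # two overlapping capture kits whose padded intersection covers most sites
    m = sc.n_variants
    pos_max = (m + 1) * 1000
    kit1 = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [pos_max - 2000]})
    kit2 = pd.DataFrame({"chrom": ["1"], "start": [500], "end": [pos_max]})
    iof.write_bed(kit1, out / "targets_kit1.bed")
    iof.write_bed(kit2, out / "targets_kit2.bed")

    scene = sim.simulate_ancestry_scene(sc)
    iof.write_vcf(scene["stage1_ref"], out / "ref1.vcf")
    iof.write_vcf(scene["stage2_ref"], out / "ref2.vcf")
    iof.write_vcf(scene["cohort"], out / "cohort_scene.vcf")
    pd.DataFrame({"sample": scene["stage1_ref"].samples,
                  "label": scene["stage1_labels"]}).to_csv(
        out / "labels1.tsv", sep="\t", index=False)
    pd.DataFrame({"sample": scene["stage2_ref"].samples,
                  "label": scene["stage2_labels"]}).to_csv(
        out / "labels2.tsv", sep="\t", index=False)
    pd.DataFrame({"sample": scene["cohort"].samples,
                  "label": scene["truth"]}).to_csv(
        out / "scene_truth.tsv", sep="\t", index=False)
    return {
        "n_variants": sc.n_variants,
        "n_cohort": sc.n_cohort,
        "n_trios": sc.n_trios,
        "n_case_control": sc.n_cases + sc.n_controls,
    }


def stage_qc(cfg: RunConfig, run_dir: Path) -> dict:
    out = run_dir / "qc"
    out.mkdir(parents=True, exist_ok=True)
    qcfg = cfg.qc_config()
    sim_dir = run_dir / "simulate"

    cohort = iof.read_vcf(sim_dir / "cohort.vcf")
    cohort = qc_mod.allele_balance_mask(cohort, qcfg)
    cohort = qc_mod.depth_mask(cohort, qcfg)
    targets = qc_mod.intersect_targets(
        [iof.read_bed(sim_dir / "targets_kit1.bed"),
         iof.read_bed(sim_dir / "targets_kit2.bed")],
        pad=qcfg.target_pad,
    )
    cohort, report = qc_mod.variant_filters(cohort, qcfg, targets)
    iof.write_vcf(cohort, out / "cohort_qc.vcf")

    unrelated = qc_mod.select_unrelated(cohort, qcfg.kinship_threshold)
    (out / "unrelated_samples.txt").write_text("\n".join(unrelated) + "\n")
    report["n_unrelated"] = len(unrelated)

    trio_gm = iof.read_vcf(sim_dir / "trios.vcf")
    ped = iof.read_fam(sim_dir / "trios.fam")
    trio_gm, mendel_errors = qc_mod.mendelian_error_mask(trio_gm, ped)
    iof.write_vcf(trio_gm, out / "trios_qc.vcf")
    report["mendelian_errors"] = int(len(mendel_errors))
    iof.write_json(report, out / "qc_report.json")
    return report


def stage_ancestry(cfg: RunConfig, run_dir: Path) -> dict:
    out = run_dir / "ancestry"
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = run_dir / "simulate"
    params = {"k": 10, "threshold": 8, "n_pcs": 20, "K": 20} | cfg.ancestry

    ref1 = iof.read_vcf(sim_dir / "ref1.vcf")
    ref2 = iof.read_vcf(sim_dir / "ref2.vcf")
    cohort = iof.read_vcf(sim_dir / "cohort_scene.vcf")
    labels1 = pd.read_csv(sim_dir / "labels1.tsv", sep="\t")["label"].to_numpy()
    labels2 = pd.read_csv(sim_dir / "labels2.tsv", sep="\t")["label"].to_numpy()

    K = min(params["K"], ref1.n_samples - 1)
    pruned1 = anc.ld_prune(ref1)
    model1 = anc.fit_pca(ref1.take_variants(pruned1), K=K, ref_labels=labels1)
    coords1 = anc.project(model1, cohort)
    is_eur = anc.knn_assign(model1, coords1, {"EUR"}, k=params["k"],
                            threshold=params["threshold"], n_pcs=params["n_pcs"])

    pruned2 = anc.ld_prune(ref2)
    model2 = anc.fit_pca(ref2.take_variants(pruned2), K=K, ref_labels=labels2)
    coords2 = anc.project(model2, cohort)
    is_fc = anc.knn_assign(model2, coords2, {"FC"}, k=params["k"],
                           threshold=params["threshold"], n_pcs=params["n_pcs"])

    assigned = np.where(~is_eur, "OUT", np.where(is_fc, "FC", "EUR"))
    regions = anc.assign_region(coords2)
    table = pd.DataFrame({
        "sample": cohort.samples,
        "assigned": assigned,
        "region": regions,
    })
    for i in range(min(4, coords2.shape[1])):
        table[f"PC{i+1}"] = coords2[:, i]
    table.to_csv(out / "assignments.tsv", sep="\t", index=False)

    truth = pd.read_csv(sim_dir / "scene_truth.tsv", sep="\t")["label"].to_numpy()
    accuracy = float((assigned == truth).mean())
    result = {"n_samples": int(cohort.n_samples), "accuracy": accuracy,
              "n_fc": int((assigned == "FC").sum())}
    iof.write_json(result, out / "ancestry_report.json")
    return result


def stage_enrich(cfg: RunConfig, run_dir: Path) -> dict:
    out = run_dir / "enrich"
    out.mkdir(parents=True, exist_ok=True)
    cohort = iof.read_vcf(run_dir / "qc" / "cohort_qc.vcf")
    ref = iof.read_frequency_table(run_dir / "simulate" / "ref_counts.tsv")
    ann = iof.read_annotations(run_dir / "simulate" / "annotations.tsv")
    table = enr.build_frequency_table(cohort, ref,
                                      default_ref_an=int(ref["an"].max()))
    results = enr.enrichment_table(table, annotations=ann)
    results.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    folds = tuple(cfg.enrich.get("folds", (4, 10, 100)))
    summary = enr.enrichment_summary(results, folds=folds)
    iof.write_json(summary, out / "summary.json")
    return {"n_variants": int(len(results)),
            "n_significant": int(results["significant"].sum())}


def stage_prevalence(cfg: RunConfig, run_dir: Path) -> dict:
    out = run_dir / "prevalence"
    out.mkdir(parents=True, exist_ok=True)
    cohort = iof.read_vcf(run_dir / "qc" / "cohort_qc.vcf")
    ann = iof.read_annotations(run_dir / "simulate" / "annotations.tsv")
    ann = ann.merge(cohort.variants.assign(_in=True), on=iof.VARIANT_COLS, how="inner")
    plp = ann[ann["clinvar"].isin(["P", "LP"])]
    gene = cfg.prevalence.get("gene")
    if gene is None:
        if plp.empty:
            iof.write_json({"note": "no pathogenic variants in call set"},
                           out / "prevalence.json")
            return {"n_genes": 0}
        gene = plp["gene"].value_counts().idxmax()
    sel = plp[plp["gene"] == gene]
    keys = iof.variant_key_index(sel)
    pos = pd.Series(np.arange(cohort.n_variants), index=cohort.keys())
    idx = pos[keys].to_numpy()
    het = (cohort.dosage[:, idx] == 1).sum(axis=0)
    hom = (cohort.dosage[:, idx] == 2).sum(axis=0)
    summary = prev.exome_birth_prevalence(het, cohort.n_samples, gene=gene,
                                          hom_counts=hom)
    iof.write_json(summary.as_dict(), out / "prevalence.json")
    return {"gene": gene, "total_carriers": summary.total_carriers}


def stage_assoc(cfg: RunConfig, run_dir: Path) -> dict:
    out = run_dir / "assoc"
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = run_dir / "simulate"
    params = {"maf_min": 0.001, "n_genes": 20, "p_full_fit": 1e-3} | cfg.assoc

    trio_gm = iof.read_vcf(run_dir / "qc" / "trios_qc.vcf")
    ped = iof.read_fam(sim_dir / "trios.fam")
    trios = assoc_mod.trio_set_from_matrix(trio_gm, ped)
    tdt_res = assoc_mod.tdt(trios)
    beta_t, var_t = assoc_mod.tdt_effect(tdt_res["T"].to_numpy(),
                                         tdt_res["U"].to_numpy())
    tdt_res["beta_tdt"], tdt_res["var_tdt"] = beta_t, var_t

    cc = iof.read_vcf(sim_dir / "cc.vcf")
    phen = pd.read_csv(sim_dir / "phenotypes.tsv", sep="\t")
    phen = phen.set_index("sample").loc[cc.samples, "phenotype"].to_numpy()

    # covariates: sex (simulated) + top 4 PCs of the case/control samples
    rng = cfg.sim_config().rng(20)
    sex = rng.integers(1, 3, size=cc.n_samples).astype(float)
    pruned = anc.ld_prune(cc)
    pca = anc.fit_pca(cc.take_variants(pruned), K=4)
    covars = np.column_stack([sex, pca.scores[:, :4]])

    af = cc.allele_freq()
    maf = np.minimum(af, 1 - af)
    testable = np.nonzero(maf > params["maf_min"])[0]
    null = assoc_mod.fit_null_model(phen, covars)
    chi2_cc, p_cc = assoc_mod.score_test_matrix(cc.dosage[:, testable], null)

    single = cc.variants.iloc[testable].reset_index(drop=True)
    single["p_cc"] = p_cc
    single["chi2_cc"] = chi2_cc
    # full logistic fit (beta/se) + meta only for promising variants
    hits = np.nonzero(p_cc < params["p_full_fit"])[0]
    single["beta_cc"] = np.nan
    single["se_cc"] = np.nan
    single["beta_meta"] = np.nan
    single["p_meta"] = np.nan
    keys_t = iof.variant_key_index(trio_gm.variants)
    tpos = pd.Series(np.arange(len(keys_t)), index=keys_t)
    keys_s = iof.variant_key_index(single)
    for i in hits:
        fit = assoc_mod.single_variant_test(cc.dosage[:, testable[i]], phen,
                                            covars, null=null)
        single.loc[i, "beta_cc"] = fit["beta"]
        single.loc[i, "se_cc"] = fit["se"]
        key = keys_s[i]
        if key in tpos.index and np.isfinite(fit.get("beta", np.nan)):
            j = tpos[key]
            bm, sm, pm = assoc_mod.inverse_variance_meta(
                beta_t[j], var_t[j], fit["beta"], fit["se"] ** 2)
            single.loc[i, "beta_meta"] = bm
            single.loc[i, "p_meta"] = pm
    tdt_res = pd.concat([trio_gm.variants, tdt_res], axis=1)
    tdt_res.to_csv(out / "tdt.tsv", sep="\t", index=False)
    single.to_csv(out / "single_variant.tsv", sep="\t", index=False)

    ann = iof.read_annotations(sim_dir / "annotations.tsv")
    ann_cc = cc.variants.merge(ann, on=iof.VARIANT_COLS, how="left")
    ann_cc["consequence"] = ann_cc["consequence"].fillna("other")
    genes = ann_cc["gene"].dropna().unique()[: params["n_genes"]]
    rows = []
    for gene in genes:
        for group in ("LoF", "non-synonymous", "synonymous"):
            for max_maf in (0.001, 0.01, 0.05):
                mask = assoc_mod.GeneSetMask(gene, group, max_maf).select(ann_cc, maf)
                if not mask.any():
                    continue
                res = assoc_mod.burden_test(cc, phen, covars, mask, null=null)
                p_skat = assoc_mod.skat_component_test(cc, phen, covars, mask,
                                                       null=null)
                rows.append((gene, group, max_maf, res["p"], res.get("beta"),
                             p_skat, res["mac_case"], res["mac_control"]))
    burden = pd.DataFrame(rows, columns=[
        "gene", "group", "max_maf", "p_burden", "beta_burden", "p_skat",
        "mac_case", "mac_control",
    ])
    burden.to_csv(out / "burden.tsv", sep="\t", index=False)
    return {"n_trio_variants": int(len(tdt_res)),
            "n_single_tests": int(len(single)),
            "n_set_tests": int(len(burden))}


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "ancestry": stage_ancestry,
    "enrich": stage_enrich,
    "prevalence": stage_prevalence,
    "assoc": stage_assoc,
}


def run_pipeline(config: RunConfig, run_dir: str | Path) -> dict:
    """Execute the configured stages in order and write a manifest.

    A stage whose declared inputs are absent (because an upstream stage was
    disabled) fails fast with a machine-readable error report written to
    ``<run_dir>/error.json``.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _package_version(),
        "seed": config.seed,
        "stages": {},
        "input_hashes": {},
    }
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            for rel in STAGE_INPUTS[stage]:
                path = run_dir / rel
                if not path.exists():
                    raise FileNotFoundError(
                        f"stage '{stage}' requires missing input {rel} "
                        "(upstream stage disabled or failed)"
                    )
                manifest["input_hashes"][rel] = _sha256(path)
            logger.info("running stage %s", stage)
            manifest["stages"][stage] = STAGE_FUNCS[stage](config, run_dir)
    except Exception as exc:  # machine-readable failure report
        iof.write_json(
            {"error": type(exc).__name__, "message": str(exc)},
            run_dir / "error.json",
        )
        raise
    iof.write_json(manifest, run_dir / "manifest.json")
    return manifest
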