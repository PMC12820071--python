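"""End-to-end orchestration: simulate -> phenotype -> genetics ->
survival -> multi-task + stability -> GRS -> enrichment.

One :class:`PipelineConfig` drives every stage; a single global seed
fans out to per-stage seeds through a splitmix-style derivation so any
stage can be rerun in isolation reproducibly.  Every artifact is a TSV
(or VCF) under the output directory and is sha256-hashed into a JSON
manifest; stages communicate only through those artifact files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import genetics, grs, io, metrics, phenotyping, simulate, stability
from . import survival as surv

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed",
           "demo_gene_sets"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 via splitmix-style mixing of the
    global seed with the stage name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    z = int.from_bytes(h[:8], "little")
    z = (z ^ (z >> 30)) * 0xBF58476D1CE4E5B9 % (1 << 64)
    z = (z ^ (z >> 27)) * 0x94D049BB133111EB % (1 << 64)
    return (z ^ (z >> 31)) % (1 << 31)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # stage toggles
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "phenotype": True, "genetics": True,
        "survival": True, "stability": True, "grs": True,
        "enrichment": True})
    # synthetic-cohort overrides passed to default_config()
    simulation: dict = field(default_factory=dict)
    # module parameters
    n_pcs: int = 5
    n_iter: int = 50
    retention_threshold: float = 0.25
    split_fraction: float = 0.8
    rho_grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    n_alphas: int = 20
    alpha_decades: float = 3.0
    cv_folds: int = 5
    grs_test_fraction: float = 0.2
    gmt_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def demo_gene_sets(annotation: pd.DataFrame, truth_snps: pd.DataFrame,
                   seed: int, n_random_sets: int = 20,
                   set_size: int = 12) -> enr.GeneSetCollection:
    """Gene-set collection over the simulated gene universe: one set
    built around the genes of the truly shared SNPs plus random filler
    sets, so enrichment of a correct shared-risk set is detectable."""
    rng = np.random.default_rng(seed)
    universe = sorted(set(annotation["mapped_genes"]))
    shared_genes = sorted(set(
        annotation.set_index("snp_id").loc[
            truth_snps.loc[truth_snps["role"] == "shared", "snp_id"],
            "mapped_genes"]))
    sets = {}
    pad = [g for g in universe if g not in shared_genes]
    sets["SHARED_ARCHITECTURE"] = set(
        shared_genes + list(rng.choice(pad, size=min(4, len(pad)),
                                       replace=False)))
    for i in range(n_random_sets):
        sets[f"RANDOM_SET_{i:02d}"] = set(
            rng.choice(universe, size=set_size, replace=False))
    return enr.GeneSetCollection(sets=sets, universe=set(universe))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dict (also
    written to ``manifest.json``).  A stage failure raises with the
    stage name attached."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "artifacts": {}, "summary": {}}
    report: list[str] = []

    def save(df, name):
        p = io.write_table(df, out / name)
        manifest["artifacts"][name] = _sha256(p)

    state: dict = {}
    try:
        _run_stages(config, out, manifest, report, save, state)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {state.get('stage')!r} failed: "
                           f"{exc}") from exc

    (out / "report.txt").write_text("\n".join(report) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_stages(config, out, manifest, report, save, state):
    stages = config.stages
    # ----------------------------------------------------------- simulate
    state["stage"] = "simulate"
    sim_cfg = simulate.default_config(
        seed=derive_seed(config.seed, "simulate"), **config.simulation)
    genos, annotation = simulate.simulate_genotypes(sim_cfg)
    cohort_sim, truth = simulate.simulate_phenotypes(genos, sim_cfg)
    pmap = phenotyping.PhecodeMap.default()
    encounters = simulate.simulate_encounters(cohort_sim, pmap, sim_cfg)
    if stages.get("simulate", True):
        save(cohort_sim, "cohort_simulated.tsv")
        save(encounters, "encounters.tsv")
        save(annotation, "snp_annotation.tsv")
        save(truth.snp_table, "truth_snps.tsv")
        save(truth.liabilities, "truth_liabilities.tsv")
        p = io.write_vcf_dosages(genos, annotation, out / "genotypes.vcf")
        manifest["artifacts"]["genotypes.vcf"] = _sha256(p)
    report.append(f"simulated {genos.n_samples} individuals x "
                  f"{genos.n_snps} SNPs; AD cases "
                  f"{int(cohort_sim['ad_case'].sum())}, LOE cases "
                  f"{int(cohort_sim['loe_case'].sum())}")

    # ---------------------------------------------------------- phenotype
    state["stage"] = "phenotype"
    demo = cohort_sim[["patient_id", "sex", "deceased", "death_age"]]
    cohort = phenotyping.assemble_cohort(encounters, demo, pmap)
    cohort_full = phenotyping.apply_cohort_filters(cohort, mode="full")
    cohort_model = phenotyping.apply_cohort_filters(cohort,
                                                    mode="modeling")
    if stages.get("phenotype", True):
        save(cohort_full, "cohort_full.tsv")
        save(cohort_model, "cohort_modeling.tsv")
        for trait in ("ad", "loe"):
            try:
                save(phenotyping.descriptive_stats(cohort_full, trait),
                     f"descriptives_{trait}.tsv")
            except ValueError:
                pass
    n_ad = int((cohort_model["ad_status"] == "case").sum())
    n_loe = int((cohort_model["loe_status"] == "case").sum())
    report.append(f"phenotyped cohort: full n={len(cohort_full)}, "
                  f"modeling n={len(cohort_model)} "
                  f"(AD {n_ad}, LOE {n_loe})")

    # ----------------------------------------------------------- genetics
    state["stage"] = "genetics"
    genos_qc, ann_qc, qc_counts = genetics.qc_filter(genos, annotation)
    pcs, _ = genetics.compute_pcs(genos_qc, k=config.n_pcs)
    candidates = genetics.select_candidates(ann_qc)
    if stages.get("genetics", True):
        save(pcs.reset_index(names="patient_id"), "ancestry_pcs.tsv")
    manifest["summary"]["qc_drop_counts"] = qc_counts
    report.append(f"QC kept {genos_qc.n_snps} SNPs; "
                  f"{len(candidates)} candidates")

    # ----------------------------------------------------------- survival
    if stages.get("survival", True):
        state["stage"] = "survival"
        rows = []
        for expo, outc in (("loe", "ad"), ("ad", "loe")):
            recs, n_rm = surv.build_survival_records(cohort_full, expo, outc)
            for fitter in (surv.fit_cox, surv.fit_fine_gray):
                est = fitter(recs)
                est.insert(0, "exposure", expo)
                est.insert(1, "outcome", outc)
                est["n"] = len(recs)
                est["n_removed"] = n_rm
                rows.append(est)
        hazards = pd.concat(rows, ignore_index=True)
        save(hazards, "survival_hazards.tsv")
        top = hazards[hazards["covariate"] == "exposed"]
        for r in top.itertuples(index=False):
            report.append(f"{r.outcome} ~ {r.exposure} [{r.model}]: "
                          f"HR {r.hr:.2f} ({r.ci_lower:.2f}, "
                          f"{r.ci_upper:.2f})")

    # -------------------------------------------------- multitask+stability
    shared = pd.DataFrame()
    if stages.get("stability", True):
        state["stage"] = "stability"
        model_ids = cohort_model["patient_id"]
        id_pos = {s: i for i, s in enumerate(genos_qc.samples)}
        rows_idx = [id_pos[s] for s in model_ids if s in id_pos]
        cm = cohort_model[cohort_model["patient_id"].isin(id_pos)].copy()
        snp_pos = {s: j for j, s in enumerate(genos_qc.snps)}
        cand_idx = [snp_pos[s] for s in candidates]
        X = genos_qc.dosages[np.ix_(rows_idx, cand_idx)]
        covs = np.column_stack([
            cm["age_last_visit"], cm["sex"],
            pcs.loc[cm["patient_id"]].to_numpy()])
        y = np.column_stack([(cm["ad_status"] == "case").astype(int),
                             (cm["loe_status"] == "case").astype(int)])
        result = stability.run_iterations(
            X, covs, y, n_iter=config.n_iter,
            base_seed=derive_seed(config.seed, "stability"),
            split_fraction=config.split_fraction, snp_ids=candidates,
            rho_grid=config.rho_grid, n_alphas=config.n_alphas,
            alpha_decades=config.alpha_decades, folds=config.cv_folds)
        retained = stability.select_stable(result,
                                           config.retention_threshold)
        shared = stability.identify_shared(result, retained, ann_qc)
        save(result.to_frame(), "stability_selection.tsv")
        save(shared, "shared_risk.tsv")
        if not shared.empty:
            save(stability.magnitude_report(shared),
                 "shared_magnitude.tsv")
        if result.n_success >= 5:
            cmp_rows = []
            for t, task in enumerate(("ad", "loe")):
                c = metrics.compare_auprc(result.auprc_mt[:, t],
                                          result.auprc_st[:, t])
                cmp_rows.append({"task": task, **c})
                report.append(
                    f"{task} AUPRC multi-task {c['mean_a']:.3f} vs "
                    f"single-task {c['mean_b']:.3f} (Wilcoxon p="
                    f"{c['p_value']:.3g})")
            save(pd.DataFrame(cmp_rows), "auprc_comparison.tsv")
        report.append(f"retained {len(retained)} SNPs at >= "
                      f"{config.retention_threshold:.0%}; "
                      f"{len(shared)} shared-risk")
        state["shared"] = shared

    # ---------------------------------------------------------------- GRS
    if stages.get("grs", True) and not shared.empty:
        state["stage"] = "grs"
        rng = np.random.default_rng(derive_seed(config.seed, "grs"))
        cm = cohort_model[cohort_model["patient_id"]
                          .isin(genos_qc.samples)].copy()
        y_comb = grs.combined_outcome(cm).to_numpy()
        dose = genos_qc.to_frame().loc[cm["patient_id"]]
        covs = np.column_stack([
            cm["age_last_visit"], cm["sex"],
            pcs.loc[cm["patient_id"]].to_numpy()[:, :5]])
        n = len(cm)
        test_mask = rng.random(n) < config.grs_test_fraction
        model = grs.fit_grs_weights(dose[~test_mask],
                                    list(shared["snp_id"]),
                                    y_comb[~test_mask], covs[~test_mask])
        scores = grs.score(dose, model)
        assoc_rows = []
        phenos = {
            "ad_or_loe": y_comb,
            "ad_only": (cm["ad_status"] == "case").to_numpy(int),
            "loe_only": (cm["loe_status"] == "case").to_numpy(int)}
        for name, yv in phenos.items():
            try:
                a = grs.test_association(scores[test_mask], yv[test_mask],
                                         covs[test_mask], label=name)
            except ValueError as err:
                report.append(f"GRS ~ {name}: skipped ({err})")
                continue
            assoc_rows.append(asdict(a))
            report.append(f"GRS ~ {name}: OR/SD {a.odds_ratio:.2f} "
                          f"({a.ci_lower:.2f}, {a.ci_upper:.2f}), "
                          f"explains {a.explained_variance_pct:.2f}%")
        save(pd.DataFrame(assoc_rows), "grs_associations.tsv")
        save(model.weights.rename_axis("snp_id").reset_index(),
             "grs_weights.tsv")
        try:
            no_apoe = grs.build_non_apoe_variant(
                model, ann_qc, dose[~test_mask], y_comb[~test_mask],
                covs[~test_mask])
            save(no_apoe.weights.rename_axis("snp_id").reset_index(),
                 "grs_weights_no_apoe.tsv")
        except ValueError as err:
            report.append(f"non-APOE GRS variant skipped: {err}")

    # ---------------------------------------------------------- enrichment
    if stages.get("enrichment", True) and not shared.empty:
        state["stage"] = "enrichment"
        if config.gmt_path:
            collection = enr.read_gmt(config.gmt_path)
        else:
            collection = demo_gene_sets(
                ann_qc, truth.snp_table,
                seed=derive_seed(config.seed, "enrichment"))
        genes = enr.map_shared_snps_to_genes(shared, ann_qc)
        table = enr.hypergeom_test(genes, collection)
        save(table, "enrichment.tsv")
        n_sig = int(table["significant"].sum())
        report.append(f"enrichment: {len(genes)} query genes, "
                      f"{n_sig} significant sets")
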