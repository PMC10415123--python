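"""End-to-end orchestration: simulate -> decompose -> DE -> deltaTE -> gene sets.

Produces a deterministic directory layout (counts/, decomposition/, de/,
deltate/, genesets/, logs/) plus a manifest listing every output with the
effective configuration and seed.  Stage failures are isolated: earlier
outputs stay on disk and the failure is recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import category_stats, decomposition, delta_te, differential_expression as de
from . import io as nio
from . import synthetic_data as sd
from .config import PipelineConfig
from .errors import NPTrapError

logger = logging.getLogger(__name__)


def _gene_sets_from_models(models):
    sets = []
    for mode in ("forwarded", "exclusive", "intensified", "buffered"):
        members = {m.gene_id for m in models if m.regulation_mode == mode}
        if members:
            sets.append(category_stats.GeneSet(name=f"planted_{mode}",
                                               members=members, source="simulation"))
    return sets


class PipelineRun:
    """Stateful runner so each stage can reuse in-memory results."""

    def __init__(self, config: PipelineConfig, outdir, seed: int | None = None):
        self.config = config
        self.seed = config.seed if seed is None else int(seed)
        self.outdir = Path(outdir)
        self.manifest = {
            "seed": self.seed,
            "config": config.to_dict(),
            "stages": {},
        }
        self.tables = None
        self.truth = None
        self.models = None
        self.design = None
        self.matrices = {}
        self.de_results = {}
        self.failed = []

    # -- helpers ------------------------------------------------------------

    def _stage_dir(self, name: str) -> Path:
        d = self.outdir / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _record(self, stage: str, outputs, params=None) -> None:
        self.manifest["stages"][stage] = {
            "status": "ok",
            "outputs": sorted(str(Path(o).relative_to(self.outdir)) for o in outputs),
            "params": params or {},
        }

    def _run_stage(self, name: str, fn) -> bool:
        try:
            fn()
            return True
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.error("stage %s failed: %s", name, exc)
            self.manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            self.failed.append(name)
            return False

    # -- stages -------------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config
        models = sd.generate_transcriptome(
            cfg.n_genes,
            utr_length_range=cfg.utr_length_range,
            u_content_range=cfg.u_content_range,
            orf_length_range=cfg.orf_length_range,
            seed=self.seed,
            read_length=cfg.read_length,
            conditions=cfg.conditions,
            k_deg_range=cfg.k_deg_range,
            loading_lag=cfg.loading_lag,
            loading_lag_orf_range=cfg.loading_lag_orf_range,
        )
        models = sd.assign_regulation(models, cfg.mode_fractions,
                                      effect_size_log2=cfg.effect_size_log2,
                                      seed=self.seed)
        design = sd.SimDesign(
            conditions=cfg.conditions, n_replicates=cfg.n_replicates,
            assays=cfg.assays, labeling_time=cfg.labeling_time,
            library_size=cfg.library_size, dispersion=cfg.dispersion,
            p_conv=cfg.p_conv, p_err=cfg.p_err, kinetics=cfg.kinetics,
            seed=self.seed,
        )
        tables, truth = sd.simulate_counts(models, design, seed=self.seed)
        self.models, self.design, self.tables, self.truth = models, design, tables, truth

        d = self._stage_dir("counts")
        outputs = []
        for sample_id, table in tables.items():
            path = d / f"{sample_id}.tcount.tsv"
            nio.write_tcount(table, path)
            outputs.append(path)
        truth_path = d / "truth.tsv"
        truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6g")
        outputs.append(truth_path)
        meta_path = d / "samples.tsv"
        nio.write_meta(design.sample_meta(), meta_path)
        outputs.append(meta_path)
        models_path = d / "models.tsv"
        pd.DataFrame(
            [
                {
                    "gene_id": m.gene_id, "utr_length": m.utr_length,
                    "n_uridines_per_read": m.n_uridines_per_read,
                    "orf_length": m.orf_length, "k_deg": m.k_deg,
                    "loading_lag": m.loading_lag,
                    "regulation_mode": m.regulation_mode,
                    "lfc_syn": m.lfc_syn, "lfc_te": m.lfc_te,
                }
                for m in models
            ]
        ).to_csv(models_path, sep="\t", index=False, float_format="%.6g")
        outputs.append(models_path)
        gmt_path = d / "planted_sets.gmt"
        sets = _gene_sets_from_models(models)
        if sets:
            nio.write_gmt(sets, gmt_path)
            outputs.append(gmt_path)
        self._record("simulate", outputs, {"n_genes": cfg.n_genes, "seed": self.seed})

    def stage_decompose(self) -> None:
        cfg = self.config
        d = self._stage_dir("decomposition")
        meta = self.design.sample_meta()
        outputs = []

        bulk, per_gene = decomposition.bulk_nascent_proportion(
            self.tables, min_support=cfg.min_support)
        bulk_path = d / "bulk_proportions.tsv"
        bulk.rename_axis("sample_id").reset_index().to_csv(
            bulk_path, sep="\t", index=False, float_format="%.6g")
        outputs.append(bulk_path)

        # sensitivity from pooled replicates of the transcriptome assay
        rna_samples = meta[meta["assay"] == "rna"]
        control = decomposition.sum_tables(
            self.tables[s] for s in rna_samples[rna_samples["condition"] == cfg.conditions[0]].index)
        treated = decomposition.sum_tables(
            self.tables[s] for s in rna_samples[rna_samples["condition"] == cfg.conditions[1]].index)
        est = decomposition.estimate_sensitivity(
            control, treated, top_k=cfg.top_k, formulation=cfg.formulation)
        sens_path = d / "sensitivity.tsv"
        est.per_gene.assign(s_pooled=est.s, formulation=est.formulation).to_csv(
            sens_path, sep="\t", index=False, float_format="%.6g")
        outputs.append(sens_path)

        per_gene = decomposition.correct_proportion(per_gene, est)
        props_path = d / "nascent_proportions.tsv"
        per_gene.to_csv(props_path, sep="\t", index=False, float_format="%.6g")
        outputs.append(props_path)

        for sample_id, table in self.tables.items():
            pre = decomposition.pre_existing_counts(table)
            path = d / f"{sample_id}.non_tc.tsv"
            pre.to_csv(path, sep="\t", index=False, float_format="%.6g")
            outputs.append(path)
        self.sensitivity = est
        self.proportions = per_gene
        self._record("decompose", outputs,
                     {"s": est.s, "top_k": cfg.top_k, "formulation": cfg.formulation})

    def stage_de(self) -> None:
        cfg = self.config
        d = self._stage_dir("de")
        meta = self.design.sample_meta()
        outputs = []
        for assay in self.design.assays:
            samples = meta.index[meta["assay"] == assay]
            tables = {s: self.tables[s] for s in samples}
            mats = nio.matrices_from_tcounts(tables, meta.loc[samples])
            factors = de.size_factors_median_of_ratios(mats["total"].counts)
            sf_path = d / f"{assay}.size_factors.tsv"
            factors.rename_axis("sample_id").reset_index().to_csv(
                sf_path, sep="\t", index=False, float_format="%.6g")
            outputs.append(sf_path)
            for read_class in ("total", "tc", "non_tc"):
                cm = de.apply_cross_normalization(mats[read_class], factors)
                res = de.nb_wald_test(cm, conditions=list(cfg.conditions),
                                      min_filter_mean=cfg.min_filter_mean)
                path = d / f"{assay}.{read_class}.de.tsv"
                nio.write_results(res, path)
                outputs.append(path)
                self.de_results[(assay, read_class)] = res
                mat_path = d / f"{assay}.{read_class}.counts.tsv"
                nio.write_matrix(cm.counts, mat_path)
                outputs.append(mat_path)
            self.matrices[assay] = mats
        self._record("de", outputs, {"alpha": cfg.alpha, "lfc": cfg.lfc_threshold})

    def stage_deltate(self) -> None:
        cfg = self.config
        translatome = [a for a in self.design.assays if a != "rna"]
        if not translatome or "rna" not in self.design.assays:
            raise NPTrapError("deltaTE requires an rna assay and a translatome assay")
        trap_assay = translatome[0]
        d = self._stage_dir("deltate")
        meta = self.design.sample_meta()
        all_tables = {s: self.tables[s] for s in meta.index
                      if meta.loc[s, "assay"] in ("rna", trap_assay)}
        mats_all = nio.matrices_from_tcounts(all_tables, meta.loc[list(all_tables)])
        factors = de.size_factors_median_of_ratios(mats_all["total"].counts)
        outputs = []
        for read_class in ("total", "tc"):
            rna_cm = de.CountMatrix(
                mats_all[read_class].counts[meta.index[meta["assay"] == "rna"]],
                meta, read_class=read_class)
            trap_cm = de.CountMatrix(
                mats_all[read_class].counts[meta.index[meta["assay"] == trap_assay]],
                meta, read_class=read_class)
            res = delta_te.fit_interaction_model(
                rna_cm, trap_cm, factors, conditions=list(cfg.conditions))
            res["category"] = delta_te.classify_regulation(
                res, alpha=cfg.deltate_alpha, lfc_threshold=cfg.deltate_lfc_threshold)
            path = d / f"deltate.{read_class}.tsv"
            nio.write_results(res, path)
            outputs.append(path)
            self.de_results[("deltate", read_class)] = res

            planted = pd.Series({m.gene_id: m.regulation_mode for m in self.models})
            confusion, metrics = delta_te.category_recovery_report(res["category"], planted)
            cpath = d / f"confusion.{read_class}.tsv"
            confusion.to_csv(cpath, sep="\t")
            outputs.append(cpath)
            mpath = d / f"recovery.{read_class}.tsv"
            metrics.to_csv(mpath, sep="\t", float_format="%.6g")
            outputs.append(mpath)
        self._record("deltate", outputs,
                     {"alpha": cfg.deltate_alpha, "trap_assay": trap_assay})

    def stage_genesets(self) -> None:
        cfg = self.config
        d = self._stage_dir("genesets")
        outputs = []
        sets = _gene_sets_from_models(self.models)
        lfc = self.de_results[("rna", "total")]["log2_fc"]

        shift_rows = []
        for gs in sets:
            res = category_stats.ecdf_shift(gs, lfc, min_set_size=cfg.min_set_size)
            if res is None:
                continue
            shift_rows.append(
                {
                    "set_name": res.set_name, "n_set": res.n_set,
                    "n_background": res.n_background, "u_stat": res.u_stat,
                    "p_value": res.p_value, "median_shift": res.median_shift,
                }
            )
            curve = pd.concat([
                res.ecdf_set.assign(which="set"),
                res.ecdf_background.assign(which="background"),
            ])
            cpath = d / f"ecdf.{res.set_name}.tsv"
            curve.to_csv(cpath, sep="\t", index=False, float_format="%.6g")
            outputs.append(cpath)
        if shift_rows:
            spath = d / "ecdf_shifts.tsv"
            pd.DataFrame(shift_rows).to_csv(spath, sep="\t", index=False,
                                            float_format="%.6g")
            outputs.append(spath)

        de_res = self.de_results[("rna", "total")]
        up, _down = de.call_degs(de_res, alpha=cfg.alpha, lfc_threshold=cfg.lfc_threshold)
        if up and sets:
            ora = category_stats.hypergeometric_ora(up, set(lfc.index), sets)
            opath = d / "ora_upregulated.tsv"
            ora.to_csv(opath, sep="\t", index=False, float_format="%.6g")
            outputs.append(opath)

        # nascent-proportion comparisons by assay x condition
        meta = self.design.sample_meta()
        props = self.proportions.merge(
            meta.reset_index()[["sample_id", "assay", "condition"]], on="sample_id")
        props["group"] = props["assay"] + "|" + props["condition"]
        cmp_path = d / "proportion_comparisons.tsv"
        category_stats.compare_nascent_proportions(props).to_csv(
            cmp_path, sep="\t", index=False, float_format="%.6g")
        outputs.append(cmp_path)

        # ORF-length stratification: transcriptome vs translatome, stress condition
        translatome = [a for a in self.design.assays if a != "rna"]
        if translatome:
            trap = translatome[0]
            stress = cfg.conditions[1]
            per_gene = props[props["condition"] == stress]
            a = per_gene[per_gene["assay"] == "rna"].groupby("gene_id")["raw_proportion"].mean()
            b = per_gene[per_gene["assay"] == trap].groupby("gene_id")["raw_proportion"].mean()
            orf = pd.Series({m.gene_id: m.orf_length for m in self.models})
            trend = category_stats.stratify_by_orf_length(
                a, b, orf, n_bins=cfg.n_length_bins)
            tpath = d / "orf_length_trend.tsv"
            trend.per_bin.assign(trend_rho=trend.trend_rho,
                                 trend_p=trend.trend_p).to_csv(
                tpath, sep="\t", index=False, float_format="%.6g")
            outputs.append(tpath)
        self._record("genesets", outputs, {"n_sets": len(sets)})

    # -- driver -------------------------------------------------------------

    def run(self) -> dict:
        self.outdir.mkdir(parents=True, exist_ok=True)
        logdir = self._stage_dir("logs")
        handler = logging.FileHandler(logdir / "pipeline.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        root = logging.getLogger("nptrap")
        root.addHandler(handler)
        try:
            logger.info("effective config: %s", json.dumps(self.config.to_dict(),
                                                           sort_keys=True))
            logger.info("seed: %d", self.seed)
            if self._run_stage("simulate", self.stage_simulate):
                self._run_stage("decompose", self.stage_decompose)
                self._run_stage("de", self.stage_de)
                if ("rna", "total") in self.de_results:
                    self._run_stage("deltate", self.stage_deltate)
                    self._run_stage("genesets", self.stage_genesets)
        finally:
            root.removeHandler(handler)
            handler.close()
            with open(self.outdir / "manifest.json", "w") as fh:
                json.dump(self.manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
        return self.manifest


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Run every stage; raises :class:`NPTrapError` if any stage failed."""
    runner = PipelineRun(config, outdir, seed=seed)
    manifest = runner.run()
    if runner.failed:
        raise NPTrapError(f"stages failed: {runner.failed}")
    return manifest
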