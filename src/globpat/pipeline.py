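"""End-to-end orchestration: simulate -> preprocess -> fit -> select ->
validate -> associate -> enrich -> phenotype, driven by a YAML config.

Every stage writes plain-text artifacts into the output directory and
records what it did in ``manifest.json`` (config hash, seed, outputs,
wall time).  Re-running a completed stage with an unchanged config is a
no-op (checksum guard); deterministic stages are bit-identical across
reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gqtl as gqtl_mod
from . import hmm_core, io, molecular_assoc, phenotype_assoc, preprocess, synthio, validation
from .datatypes import GenomeAnnotation
from .enrichment import overlap_enrichment

log = logging.getLogger("globpat")

STAGES = ["simulate", "preprocess", "fit", "select", "validate", "gqtl", "enrich", "assoc", "pheno"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


class Pipeline:
    """Stateful runner; artifacts live under ``outdir``."""

    def __init__(self, config: dict, outdir=None):
        self.config = config
        self.outdir = Path(outdir or config.get("outdir", "globpat_out"))
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config.get("seed", 0))
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )

    # -- manifest helpers -------------------------------------------------
    def _stage_done(self, stage: str, conf_hash: str) -> bool:
        entry = self.manifest.get(stage)
        if not entry or entry.get("config_hash") != conf_hash:
            return False
        return all(Path(p).exists() for p in entry.get("outputs", []))

    def _record(self, stage: str, conf_hash: str, outputs: list, t0: float, **info) -> None:
        self.manifest[stage] = {
            "config_hash": conf_hash,
            "outputs": [str(p) for p in outputs],
            "wall_s": round(time.time() - t0, 3),
            **info,
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, default=str))

    def _stage_conf(self, stage: str) -> dict:
        return dict(self.config.get(stage) or {})

    # -- stages -----------------------------------------------------------
    def run(self, stages=None) -> Path:
        stages = list(stages) if stages else [s for s in STAGES if self._enabled(s)]
        for stage in stages:
            if stage not in STAGES:
                raise StageError(stage, "unknown stage")
            t0 = time.time()
            try:
                getattr(self, f"stage_{stage}")()
            except StageError:
                raise
            except Exception as exc:  # halt with the stage name, keep partials
                raise StageError(stage, str(exc)) from exc
            log.info("stage %s done in %.1fs", stage, time.time() - t0)
        return self.outdir

    def _enabled(self, stage: str) -> bool:
        if stage in ("simulate",) and not self.config.get("simulate"):
            return False
        if stage == "pheno" and not (
            self._stage_conf("simulate").get("pheno_plan") or self.config.get("pheno")
        ):
            return False
        if stage == "assoc" and self.config.get("assoc") is False:
            return False
        return True

    def _sim_config(self) -> synthio.SyntheticConfig:
        conf = self._stage_conf("simulate")
        conf.pop("enabled", None)
        if "marks" in conf:
            conf["marks"] = tuple(conf["marks"])
        for key in ("gqtl_plan", "expr_plan"):
            if key in conf and conf[key] is not None:
                conf[key] = [tuple(e) for e in conf[key]]
        if conf.get("pheno_plan"):
            states, shift = conf["pheno_plan"]
            conf["pheno_plan"] = (tuple(states), float(shift))
        conf.setdefault("seed", self.seed)
        return synthio.SyntheticConfig(**conf)

    def stage_simulate(self) -> None:
        conf = self._stage_conf("simulate")
        h = _config_hash({"conf": conf, "seed": self.seed})
        out = self.outdir
        outputs = [
            out / n
            for n in (
                "counts.tsv", "covariates.tsv", "genotypes.tsv", "genotypes.vcf",
                "truth_states.bed", "expression.tsv", "tss.tsv", "labels.tsv",
                "true_emissions.tsv", "config.yaml",
            )
        ]
        if self._stage_done("simulate", h):
            return
        t0 = time.time()
        cfg = self._sim_config()
        truth = synthio.simulate_truth(cfg)
        genotypes = synthio.simulate_genotypes(cfg)
        labels = synthio.simulate_phenotype_labels(cfg)
        counts, cov = synthio.simulate_counts(
            truth, cfg, genotypes, labels if cfg.pheno_plan else None
        )
        expr, tss = synthio.simulate_expression(
            truth, cfg, genotypes=genotypes, labels=labels if cfg.pheno_plan else None
        )
        io.write_counts(counts, out / "counts.tsv")
        cov.to_csv(out / "covariates.tsv", sep="\t", index=False)
        io.write_genotypes_tsv(genotypes, out / "genotypes.tsv")
        io.write_vcf(genotypes, out / "genotypes.vcf")
        bed = truth.bins.copy()
        bed["state"] = truth.state_path
        bed.to_csv(out / "truth_states.bed", sep="\t", index=False, header=False)
        expr.rename_axis("gene").to_csv(out / "expression.tsv", sep="\t")
        tss.to_csv(out / "tss.tsv", sep="\t", index=False)
        labels.rename_axis("individual").to_csv(out / "labels.tsv", sep="\t")
        pd.DataFrame(truth.true_emissions).to_csv(
            out / "true_emissions.tsv", sep="\t", index=False, header=False
        )
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump({k: v for k, v in self.config.items()}, fh)
        self._record("simulate", h, outputs, t0, n_bins=cfg.n_bins, n_tracks=cfg.n_tracks)

    def stage_preprocess(self) -> None:
        conf = self._stage_conf("preprocess")
        h = _config_hash(conf)
        out = self.outdir
        outputs = [out / "calls.tsv"]
        if self._stage_done("preprocess", h):
            return
        t0 = time.time()
        counts = io.read_counts(out / "counts.tsv")
        cov = pd.read_csv(out / "covariates.tsv", sep="\t")
        norm = preprocess.quantile_normalize(counts, conf.get("group_by_mark", True))
        cov_cols = [c for c in cov.columns if c != "track"]
        corrected = (
            preprocess.regress_covariates(norm, cov[cov_cols], conf.get("group_by_mark", True))
            if cov_cols
            else norm
        )
        calls = preprocess.binarize(corrected, float(conf.get("pthresh", 1e-4)))
        io.write_calls(calls, out / "calls.tsv")
        self._record("preprocess", h, outputs, t0, call_rate=float(calls.calls.mean()))

    def stage_fit(self) -> None:
        conf = self._stage_conf("fit")
        h = _config_hash({"conf": conf, "seed": self.seed})
        k_grid = list(conf.get("k_grid", [5, 10, 15]))
        out = self.outdir
        outputs = [out / f"model_k{k}_emissions.tsv" for k in k_grid]
        if self._stage_done("fit", h):
            return
        t0 = time.time()
        calls = io.read_calls(out / "calls.tsv")
        for k in k_grid:
            model, trace = hmm_core.fit(
                calls,
                k=k,
                seed=self.seed,
                max_iter=int(conf.get("max_iter", 200)),
                tol=float(conf.get("tol", 1e-4)),
                restarts=int(conf.get("restarts", 1)),
            )
            io.write_model(model, out / f"model_k{k}")
            ann = hmm_core.annotate(model, calls)
            io.write_annotation_bed(ann, out / f"annotation_k{k}.bed")
        self._record("fit", h, outputs, t0, k_grid=k_grid)

    def _models(self):
        k_grid = list(self._stage_conf("fit").get("k_grid", [5, 10, 15]))
        return [io.read_model(self.outdir / f"model_k{k}") for k in k_grid]

    def stage_select(self) -> None:
        conf = self._stage_conf("gqtl")
        h = _config_hash({"conf": conf, "fit": self._stage_conf("fit")})
        out = self.outdir
        outputs = [out / "model_selection.tsv", out / "selected_k.json"]
        if self._stage_done("select", h):
            return
        t0 = time.time()
        genotypes = io.read_genotypes_tsv(out / "genotypes.tsv")
        best, counts = gqtl_mod.select_model(
            self._models(), genotypes, maf_min=float(conf.get("maf_min", 0.05))
        )
        counts.to_csv(out / "model_selection.tsv", sep="\t", index=False)
        (out / "selected_k.json").write_text(json.dumps({"k": best.k}))
        self._record("select", h, outputs, t0, chosen_k=best.k)

    def _selected_model(self):
        k = json.loads((self.outdir / "selected_k.json").read_text())["k"]
        return io.read_model(self.outdir / f"model_k{k}")

    def stage_validate(self) -> None:
        h = _config_hash({"fit": self._stage_conf("fit")})
        out = self.outdir
        outputs = [out / "validation.json"]
        if self._stage_done("validate", h):
            return
        t0 = time.time()
        model = self._selected_model()
        report: dict = {}
        if len(model.marks) >= 2:
            report["mark_pairs"] = mark_pairs = []
            for _, row in validation.mark_pair_correlation(model).iterrows():
                mark_pairs.append(dict(row))
        calls = io.read_calls(out / "calls.tsv")
        chroms = list(calls.bin_table.chrom_slices())
        if len(chroms) >= 2:
            half = [chroms[: len(chroms) // 2], chroms[len(chroms) // 2 :]]
            sub_models = []
            for part in half:
                keep = calls.bins["chrom"].isin(part).to_numpy()
                from .datatypes import BinaryCallMatrix

                sub = BinaryCallMatrix(
                    calls.calls[keep], calls.bins[keep].reset_index(drop=True), calls.tracks
                )
                m, _ = hmm_core.fit(sub, k=model.k, seed=self.seed)
                sub_models.append(m)
            match = validation.greedy_match_states(*sub_models)
            report["robustness_median_rho"] = match.median_rho
        report["singletons"] = {
            mark: validation.classify_singletons(model, mark=mark)["label"].tolist()
            for mark in model.marks
        }
        (out / "validation.json").write_text(json.dumps(report, indent=1, default=float))
        self._record("validate", h, outputs, t0)

    def stage_gqtl(self) -> None:
        conf = self._stage_conf("gqtl")
        h = _config_hash(conf)
        out = self.outdir
        outputs = [out / "gqtl_results.tsv"]
        if self._stage_done("gqtl", h):
            return
        t0 = time.time()
        if not (out / "genotypes.tsv").exists():
            raise StageError("gqtl", "missing genotype file genotypes.tsv")
        model = self._selected_model()
        genotypes = io.read_genotypes_tsv(out / "genotypes.tsv")
        pcs = None
        if conf.get("n_pcs"):
            pcs = gqtl_mod.compute_genotype_pcs(genotypes, int(conf["n_pcs"]))
        res = gqtl_mod.associate_gqtl(model, genotypes, pcs, float(conf.get("maf_min", 0.05)))
        res[res["significant"]].to_csv(out / "gqtl_results.tsv", sep="\t", index=False)
        self._record("gqtl", h, outputs, t0, n_gqtl=int(res["significant"].sum()))

    def stage_enrich(self) -> None:
        conf = self._stage_conf("enrich")
        h = _config_hash(conf)
        out = self.outdir
        outputs = [out / "enrichment.tsv"]
        if self._stage_done("enrich", h):
            return
        t0 = time.time()
        model = self._selected_model()
        calls = io.read_calls(out / "calls.tsv")
        ann = hmm_core.annotate(model, calls)
        bed_path = conf.get("bed")
        if bed_path:
            intervals = io.read_bed(bed_path, labeled=conf.get("labeled", False))
        else:
            truth_bed = pd.read_csv(
                out / "truth_states.bed", sep="\t", header=None,
                names=["chrom", "start", "end", "state"],
            )
            truth = self._truth_for_intervals(truth_bed)
            intervals = synthio.simulate_intervals(
                truth,
                conf.get("target_states", [2]),
                float(conf.get("coverage_fold", 5.0)),
                int(conf.get("n_intervals", 300)),
                seed=self.seed,
            )
        enr = overlap_enrichment(ann, intervals, fdr=float(conf.get("fdr", 0.05)))
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        self._record("enrich", h, outputs, t0)

    def _truth_for_intervals(self, truth_bed: pd.DataFrame) -> synthio.SyntheticTruth:
        cfg = self._sim_config()
        sizes = truth_bed.groupby("chrom")["end"].max().to_dict()
        return synthio.SyntheticTruth(
            state_path=truth_bed["state"].to_numpy(),
            bins=truth_bed[["chrom", "start", "end"]],
            true_emissions=np.clip(
                pd.read_csv(self.outdir / "true_emissions.tsv", sep="\t", header=None).to_numpy(),
                0, 1,
            ),
            tracks=cfg.tracks,
            chrom_sizes=sizes,
        )

    def stage_assoc(self) -> None:
        conf = self._stage_conf("assoc")
        h = _config_hash(conf)
        out = self.outdir
        outputs = [out / "expression_assoc.tsv"]
        if self._stage_done("assoc", h):
            return
        t0 = time.time()
        model = self._selected_model()
        expr = pd.read_csv(out / "expression.tsv", sep="\t", index_col=0)
        frames = [
            molecular_assoc.associate_emissions(model, mark, expr, float(conf.get("fdr", 0.05)))
            for mark in model.marks
        ]
        res = pd.concat(frames, ignore_index=True)
        res[res["significant"]].to_csv(out / "expression_assoc.tsv", sep="\t", index=False)
        self._record(
            "assoc", h, outputs, t0,
            n_sig_genes=int(res.loc[res["significant"], "feature"].nunique()),
        )

    def stage_pheno(self) -> None:
        conf = self._stage_conf("pheno")
        h = _config_hash(conf)
        out = self.outdir
        outputs = [out / "phenotype_assoc.tsv"]
        if self._stage_done("pheno", h):
            return
        t0 = time.time()
        model = self._selected_model()
        labels = pd.read_csv(out / "labels.tsv", sep="\t", index_col=0)["case"]
        mark = conf.get("mark", model.marks[0])
        res = phenotype_assoc.permutation_adjust(
            model, labels, mark=mark,
            n_perm=int(conf.get("n_perm", 1000)), seed=self.seed,
        )
        res.to_csv(out / "phenotype_assoc.tsv", sep="\t", index=False)
        self._record("pheno", h, outputs, t0, n_significant=int(res["significant"].sum()))


def run(config, outdir=None, stages=None) -> Path:
    """Run the pipeline from a YAML path or config dict; returns the
    artifact directory."""
    return Pipeline(load_config(config), outdir).run(stages)
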