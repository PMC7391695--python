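"""End-to-end orchestration: simulate/ingest → filter → collapse → diversity
→ LEfSe → index build/CV → external application, with one global seed.

Every stage derives its own seed from the global one by hashing the stage
name, so a stage can be re-run in isolation and the whole run is
byte-reproducible for a fixed config.  All artifacts are plain text (TSV,
newick, JSON) and each carries the config hash in the run report.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_io import (AbundanceTable, SampleMetadata, collapse_to_rank,
                      filter_low_confidence, read_abundance_table,
                      read_sample_metadata, read_tree, to_relative,
                      write_abundance_table, write_sample_metadata, write_tree)
from .diff_abundance import fb_ratio, lefse
from .diversity import compare_alpha, distance_matrix, pcoa, permanova
from .pmi import (apply_index, compute_pmi, cross_validate, define_index,
                  evaluate_at_cutoff, roc_curve, select_cutoff)
from .synthetic import (default_psoriasis_config, derive_seed,
                        generate_cohort, generate_tree)

logger = logging.getLogger("psomi")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, stage parameters and the single reproducibility seed.

    Exactly one of ``input_table`` (+ metadata, tree) or ``simulate`` must
    be given.  ``simulate`` holds overrides for the default psoriasis-like
    cohort generator (n_cases, n_controls, concentration, ...); setting
    ``external_cohort`` additionally simulates an independent cohort from
    the same generative model and applies the frozen index to it.
    """

    seed: int
    output_dir: str
    input_table: str | None = None
    input_metadata: str | None = None
    input_tree: str | None = None
    simulate: dict | None = None
    external_cohort: bool = True
    filter_min_fraction: float = 0.001
    filter_stage: str = "pre_collapse"      # or "post_collapse"
    collapse_rank: str = "genus"
    metrics: tuple[str, ...] = ("weighted_unifrac", "unweighted_unifrac")
    permanova_permutations: int = 999
    alpha_test: str = "mannwhitney"
    lefse_alpha: float = 0.05
    lda_threshold: float = 2.0
    lefse_boots: int = 30
    log_base: float = 10.0
    cv_folds: int = 10
    cv_reselect: bool = True

    def validate(self) -> None:
        has_inputs = self.input_table is not None
        has_sim = self.simulate is not None
        if has_inputs == has_sim:
            raise ValueError(
                "config must provide exactly one of input paths or a "
                "simulation block")
        if has_inputs and (self.input_metadata is None
                           or self.input_tree is None):
            raise ValueError(
                "input_table requires input_metadata and input_tree")
        if self.seed is None:
            raise ValueError("seed is required")
        if self.filter_stage not in ("pre_collapse", "post_collapse"):
            raise ValueError(f"unknown filter_stage {self.filter_stage!r}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        obj = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "metrics" in obj:
            obj["metrics"] = tuple(obj["metrics"])
        return cls(**obj)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def _load_or_simulate(cfg: PipelineConfig, outdir: Path):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", derive_seed(cfg.seed, "simulate"))
        ctor_keys = {"seed", "n_cases", "n_controls",
                     "verrucomicrobia_case_multiplier"}
        gen_cfg = default_psoriasis_config(
            **{k: v for k, v in sim.items() if k in ctor_keys})
        rest = {k: v for k, v in sim.items() if k not in ctor_keys}
        if rest:
            gen_cfg = dataclasses.replace(gen_cfg, **rest)
        table, md, truth = generate_cohort(gen_cfg)
        tree = generate_tree(table.taxon_ids, derive_seed(cfg.seed, "tree"))
        (outdir / "ground_truth.json").write_text(json.dumps({
            "increased": sorted(truth.increased_genera),
            "decreased": sorted(truth.decreased_genera)}, indent=2))
        return table, md, tree, gen_cfg
    table = read_abundance_table(cfg.input_table)
    md = read_sample_metadata(cfg.input_metadata)
    tree = read_tree(cfg.input_tree)
    return table, md, tree, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and return the run report (also written
    to ``<output_dir>/report.json``)."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": [],
    }

    def done(stage: str, **info):
        logger.info("stage %s done %s", stage, info or "")
        report["stages"].append(stage)
        report.update(info)

    table, md, tree, gen_cfg = _stage("ingest")(_load_or_simulate)(cfg, outdir)
    write_abundance_table(table, outdir / "counts.tsv")
    write_sample_metadata(md, outdir / "metadata.tsv")
    write_tree(tree, outdir / "tree.nwk")
    done("ingest", n_samples=len(table.sample_ids),
         n_taxa=len(table.taxon_ids))

    @_stage("filter")
    def _filter(t):
        return filter_low_confidence(t, cfg.filter_min_fraction)

    @_stage("collapse")
    def _collapse(t):
        return collapse_to_rank(t, cfg.collapse_rank)

    if cfg.filter_stage == "pre_collapse":
        table, dropped = _filter(table)
        genus_table = _collapse(table)
    else:
        genus_table = _collapse(table)
        genus_table, dropped = _filter(genus_table)
    write_abundance_table(genus_table, outdir / "genus_counts.tsv")
    done("filter+collapse", n_dropped_taxa=len(dropped),
         n_genera=len(genus_table.taxon_ids))

    rel = _stage("normalize")(to_relative)(genus_table)
    write_abundance_table(rel, outdir / "genus_relative.tsv")

    alpha = _stage("alpha_diversity")(compare_alpha)(
        genus_table, md, test=cfg.alpha_test,
        seed=derive_seed(cfg.seed, "rarefy"))
    alpha["chao1"].to_csv(outdir / "alpha_chao1.tsv", sep="\t")
    done("alpha_diversity", alpha_p_value=alpha["p_value"],
         rarefaction_depth=alpha["depth"])

    beta = {}
    for metric in cfg.metrics:
        dm = _stage(f"beta_{metric}")(distance_matrix)(rel, tree, metric)
        dm.to_frame().to_csv(outdir / f"distance_{metric}.tsv", sep="\t")
        perm = _stage(f"permanova_{metric}")(permanova)(
            dm, md.groups, cfg.permanova_permutations,
            derive_seed(cfg.seed, f"permanova_{metric}"))
        ord_res = _stage(f"pcoa_{metric}")(pcoa)(dm)
        coords = ord_res.coordinates
        pd.DataFrame(coords, index=ord_res.sample_ids,
                     columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
                     ).to_csv(outdir / f"pcoa_{metric}.tsv", sep="\t")
        beta[metric] = {"pseudo_f": perm.pseudo_f, "p_value": perm.p_value}
    done("beta_diversity", permanova=beta)

    fb = _stage("fb_ratio")(fb_ratio)(rel, md)
    done("fb_ratio",
         fb_ratio={"case_mean": fb.case_mean, "case_sd": fb.case_sd,
                   "control_mean": fb.control_mean, "control_sd": fb.control_sd,
                   "p_value": fb.p_value})

    feats = _stage("lefse")(lefse)(
        rel, md, alpha=cfg.lefse_alpha, lda_threshold=cfg.lda_threshold,
        n_boot=cfg.lefse_boots, seed=derive_seed(cfg.seed, "lefse"))
    with open(outdir / "features.tsv", "w") as fh:
        fh.write("genus\tdirection\tkw_p\tlda_score\n")
        for f in feats:
            fh.write(f"{f.genus}\t{f.direction}\t{f.kw_p:.6g}"
                     f"\t{f.lda_score:.6g}\n")
    done("lefse", n_features=len(feats))

    idx = _stage("define_index")(define_index)(feats, log_base=cfg.log_base)
    (outdir / "index.json").write_text(idx.to_json())

    scores = _stage("score")(compute_pmi)(rel, idx)
    scores.to_csv(outdir / "pmi_scores.tsv", sep="\t")
    labels = md.groups.reindex(scores.index).to_numpy()
    rc = _stage("roc")(roc_curve)(scores.to_numpy(), labels)
    cut = select_cutoff(rc, (float(scores.min()), float(scores.max())))
    _write_roc(rc, outdir / "roc_training.tsv")
    training = evaluate_at_cutoff(scores, md, cut.threshold,
                                  provenance="training")
    done("train",
         index={"increased": sorted(idx.increased_genera),
                "decreased": sorted(idx.decreased_genera)},
         training={"auc": rc.auc, "cutoff": cut.threshold,
                   "sensitivity": training.sensitivity,
                   "specificity": training.specificity})

    cv = _stage("cross_validate")(cross_validate)(
        rel, md, k=cfg.cv_folds, seed=derive_seed(cfg.seed, "cv"),
        reselect=cfg.cv_reselect, index=idx,
        lefse_params={"alpha": cfg.lefse_alpha,
                      "lda_threshold": cfg.lda_threshold,
                      "n_boot": cfg.lefse_boots})
    _write_roc(cv.roc, outdir / "roc_cv.tsv")
    done("cross_validate", cross_validation={"auc": cv.roc.auc,
                                             "k": cfg.cv_folds,
                                             "reselect": cfg.cv_reselect})

    if cfg.simulate is not None and cfg.external_cohort:
        @_stage("external")
        def _external():
            ext_cfg = dataclasses.replace(
                gen_cfg, seed=derive_seed(cfg.seed, "external"))
            etable, emd, _ = generate_cohort(ext_cfg)
            erel = to_relative(collapse_to_rank(etable, cfg.collapse_rank))
            return apply_index(erel, idx, cut.threshold, emd)

        ev = _external()
        ev.scores.to_csv(outdir / "pmi_scores_external.tsv", sep="\t")
        done("external", external={"auc": ev.auc,
                                   "sensitivity": ev.sensitivity,
                                   "specificity": ev.specificity,
                                   "cutoff": ev.cutoff})

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float))
    return report


def _write_roc(rc, path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tsensitivity\tspecificity\n")
        for t, se, sp in zip(rc.thresholds, rc.sensitivity, rc.specificity):
            fh.write(f"{t:.6g}\t{se:.6g}\t{sp:.6g}\n")
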