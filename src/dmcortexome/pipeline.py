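"""Configuration and one-command orchestration of the full analysis over
synthetic or user-supplied data.

``run_pipeline`` executes: simulate (optional) → splice-test → fdr → score →
correlate → motif → deconvolve → expr-score → celltype-enrich → biomarkers →
repeats → overlap, skipping stages whose inputs are absent, and writes a JSON
run manifest recording versions, seeds, thresholds, output hashes and
per-stage row counts.  A stage failure aborts the run with the stage name;
outputs of completed stages are preserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import deconvolution as dc
from . import expression as ex
from . import io as dio
from . import repeats as rp
from . import simulate as sim
from . import splicing as sp
from .motifs import count_kmers, kmer_enrichment

__all__ = ["RunConfig", "run_pipeline", "ConfigError", "StageError"]

log = logging.getLogger("dmcortexome")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Thresholds, seeds and paths for one pipeline run; defaults mirror the
    study's printed thresholds."""

    out_dir: str = "dmcortexome_run"
    simulate: bool = True
    seed: int = 0
    # input paths (ignored when simulating)
    psi_path: str | None = None
    tpm_path: str | None = None
    group_map_path: str | None = None
    de_table_path: str | None = None
    sc_reference_path: str | None = None
    molecules_path: str | None = None
    case_label: str = "DM1"
    control_label: str = "unaffected"
    # thresholds
    dpsi_min: float = 0.2
    alpha: float = 0.01
    overlap_dpsi_min: float = 0.1
    overlap_alpha: float = 0.01
    q_max: float = 0.01
    lfc_min: float = 1.0
    range_max: float = 0.25
    min_prop: float = 0.025
    specificity_threshold: float = 3.0
    k: int = 5
    n_shuffles: int = 20
    # sampler
    draws: int = 1000
    warmup: int = 1000
    chains: int = 4
    # repeats
    reference_flank_bp: float = 10_000.0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides

    def validate(self) -> None:
        checks = {
            "dpsi_min": (self.dpsi_min, 0, 1), "alpha": (self.alpha, 0, 1),
            "q_max": (self.q_max, 0, 1), "range_max": (self.range_max, 0, 1),
            "min_prop": (self.min_prop, 0, 1),
            "overlap_alpha": (self.overlap_alpha, 0, 1),
        }
        for name, (v, lo, hi) in checks.items():
            if not (lo < v <= hi):
                raise ConfigError(f"{name}={v} outside ({lo}, {hi}]")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.lfc_min < 0 or self.specificity_threshold <= 0:
            raise ConfigError("lfc_min must be >= 0 and specificity_threshold > 0")
        if not self.simulate and not (self.psi_path and self.group_map_path):
            raise ConfigError("without --simulate, psi_path and group_map_path are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dmcortexome {comment}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "dpsi_min": config.dpsi_min, "alpha": config.alpha,
            "q_max": config.q_max, "lfc_min": config.lfc_min,
            "range_max": config.range_max, "min_prop": config.min_prop,
            "specificity_threshold": config.specificity_threshold,
            "k": config.k,
        },
        "stages": {},
        "files": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage: str, status: str, **counts) -> None:
        manifest["stages"][stage] = {"status": status, **counts}
        log.info("stage=%s status=%s %s", stage, status,
                 " ".join(f"{k}={v}" for k, v in counts.items()))

    def emit(name: str, df: pd.DataFrame, comment: str) -> None:
        path = out / name
        _write_tsv(df, path, comment)
        manifest["files"][name] = _sha256(path)

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as err:
            record(stage, "failed", error=str(err))
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise StageError(stage, err) from err

    truth = None
    side = dio.SideTables()
    ccfg = None

    # ---- simulate ----------------------------------------------------------
    if config.simulate:
        def _simulate():
            nonlocal truth, ccfg
            ccfg = sim.CohortConfig(seed=config.seed, **config.cohort)
            psi, tpm, truth_, de = sim.simulate_cohort(ccfg)
            truth = truth_
            dio.write_psi_table(psi, out / "psi.tsv")
            dio.write_expression_table(tpm, out / "tpm.tsv")
            truth.to_json(out / "truth.json")
            _write_tsv(de, out / "de_table.tsv", "stand-in DE (rank-sum + BH)")
            mols = sim.simulate_molecules(truth, ccfg)
            dio.write_molecules(mols, out / "molecules.tsv")
            targets, background = sim.simulate_sequences(truth, ccfg)
            dio.write_regions_table(targets + background, out / "regions.tsv")
            for name in ("psi.tsv", "tpm.tsv", "de_table.tsv", "molecules.tsv",
                         "regions.tsv", "truth.json"):
                manifest["files"][name] = _sha256(out / name)
            return psi, tpm, de, mols, (targets, background)

        psi, tpm, de_table, molecules, (targets, background) = run_stage("simulate", _simulate)
        groups = dict(psi.groups)
        record("simulate", "completed", n_events=len(psi.events),
               n_samples=len(psi.samples), n_genes=len(tpm.genes))
        sc_reference = truth.reference
    else:
        groups = dio.read_group_map(config.group_map_path)
        psi = dio.read_psi_table(config.psi_path, groups)
        tpm = (dio.read_expression_table(config.tpm_path, groups)
               if config.tpm_path else None)
        de_table = (pd.read_csv(config.de_table_path, sep="\t", comment="#",
                                index_col=0) if config.de_table_path else None)
        sc_reference = (pd.read_csv(config.sc_reference_path, sep="\t",
                                    comment="#", index_col=0)
                        if config.sc_reference_path else None)
        molecules = (dio.read_molecules(config.molecules_path)
                     if config.molecules_path else None)
        targets = background = None
        record("simulate", "skipped")

    # ---- splice-test -------------------------------------------------------
    results = run_stage("splice-test", lambda: sp.test_events(
        psi, config.case_label, config.control_label,
        config.dpsi_min, config.alpha))
    emit("splicing_results.tsv", results.table, "per-event rank-sum results")
    record("splice-test", "completed", n_events=len(results.table),
           n_significant=results.n_significant())

    # ---- fdr ---------------------------------------------------------------
    fdr = run_stage("fdr", lambda: sp.estimate_fdr_by_shuffle(
        psi, config.case_label, config.control_label, config.dpsi_min,
        config.alpha, n_shuffles=config.n_shuffles, seed=config.seed + 1))
    manifest["fdr"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in fdr.items()}
    record("fdr", "completed", fdr=round(fdr["fdr"], 4) if fdr["fdr"] == fdr["fdr"] else "NA",
           n_observed=fdr["n_observed"])

    sig_events = results.significant_events

    # ---- score -------------------------------------------------------------
    if sig_events:
        scores = run_stage("score", lambda: sp.splicing_score(
            psi, sig_events, config.control_label))
        emit("splicing_scores.tsv", scores.table, "splicing dysregulation score S")
        panel = sp.select_display_panel(psi, sig_events, config.control_label,
                                        config.range_max)
        (out / "display_panel.txt").write_text(
            "# low-variance display panel\n" + "\n".join(panel) + "\n")
        record("score", "completed", n_samples=len(scores.table), n_panel=len(panel))
    else:
        scores = None
        record("score", "skipped", reason="no significant events")

    # ---- correlate ---------------------------------------------------------
    if len(sig_events) >= 2:
        corr = run_stage("correlate", lambda: sp.pairwise_correlations(
            psi, sig_events, n_shuffles=1, seed=config.seed + 2))
        manifest["correlations"] = {
            "n_pairs": int(corr.observed.size),
            "ks_statistic": corr.ks_statistic, "ks_pvalue": corr.ks_pvalue,
        }
        record("correlate", "completed", n_pairs=int(corr.observed.size))
    else:
        record("correlate", "skipped", reason="fewer than 2 significant events")

    # ---- motif -------------------------------------------------------------
    if targets is not None and sig_events:
        def _motif():
            sig = set(sig_events)
            frames = []
            for direction in ("included", "excluded"):
                tgt = [t for t in targets
                       if t.direction == direction and t.event_id in sig]
                if not tgt:
                    continue
                table = kmer_enrichment(count_kmers(tgt, config.k),
                                        count_kmers(background, config.k),
                                        direction_label=direction)
                frames.append(table)
            return pd.concat(frames, ignore_index=True) if frames else None

        motif_table = run_stage("motif", _motif)
        if motif_table is not None:
            emit("motif_enrichment.tsv", motif_table.set_index("kmer"),
                 f"k-mer enrichment (k={config.k}, binomial/Bonferroni)")
            record("motif", "completed",
                   n_significant=int(motif_table["significant"].sum()))
        else:
            record("motif", "skipped", reason="no direction-stratified targets")
    else:
        record("motif", "skipped", reason="no region sequences")

    # ---- deconvolve --------------------------------------------------------
    proportions = None
    if tpm is not None and sc_reference is not None:
        def _deconvolve():
            reference = dc.select_markers(sc_reference, top_n=50,
                                          expressed_genes=set(tpm.genes))
            est = dc.estimate_proportions(
                tpm, reference, draws=config.draws, warmup=config.warmup,
                chains=config.chains, seed=config.seed + 3)
            est, reference = dc.prune_and_refit(
                est, tpm, reference, min_prop=config.min_prop,
                draws=config.draws, warmup=config.warmup,
                chains=config.chains, seed=config.seed + 4)
            return est, reference

        proportions, used_ref = run_stage("deconvolve", _deconvolve)
        emit("proportions.tsv", proportions.means, "posterior mean cell-type proportions")
        (out / "deconvolution_diagnostics.json").write_text(json.dumps(
            proportions.diagnostics.to_dict(orient="index"), indent=1))
        ptest = dc.compare_proportions(proportions, groups,
                                       config.case_label, config.control_label)
        emit("proportion_tests.tsv", ptest, "per-cell-type rank-sum + BH")
        record("deconvolve", "completed", n_markers=proportions.n_markers,
               n_cell_types=len(proportions.cell_types))
    else:
        record("deconvolve", "skipped", reason="missing expression or reference")

    # ---- expr-score, celltype-enrich, biomarkers ---------------------------
    classes = None
    if de_table is not None and tpm is not None:
        classes = run_stage("expr-score", lambda: ex.classify_regulation(
            de_table, config.q_max, config.lfc_min))
        if classes.regulated:
            gscores = ex.expression_score(tpm, classes, config.control_label)
            emit("expression_scores.tsv", gscores.table,
                 "expression dysregulation score G")
            record("expr-score", "completed", n_up=len(classes.up),
                   n_down=len(classes.down))
        else:
            gscores = None
            record("expr-score", "skipped", reason="no regulated genes")
    else:
        gscores = None
        record("expr-score", "skipped", reason="missing DE table or expression")

    if classes is not None and classes.regulated and sc_reference is not None:
        def _enrich():
            spec = ex.assign_specificity(sc_reference, config.specificity_threshold)
            return ex.celltype_enrichment(
                spec, {"up": list(classes.up.index), "down": list(classes.down.index)},
                background=list(classes.unchanged.index))
        fisher = run_stage("celltype-enrich", _enrich)
        emit("celltype_enrichment.tsv", fisher.set_index("cell_type"),
             "Fisher exact cell-type enrichment")
        record("celltype-enrich", "completed", n_tests=len(fisher))
    else:
        record("celltype-enrich", "skipped", reason="missing classes or reference")

    if classes is not None and classes.regulated and scores is not None:
        def _biomarkers():
            corr = ex.correlate_to_splicing(tpm, classes, scores,
                                            pairs=False, n_shuffles=1,
                                            seed=config.seed + 5)
            return ex.prioritize_biomarkers(corr, side, tpm, config.control_label)
        candidates = run_stage("biomarkers", _biomarkers)
        emit("biomarkers.tsv", candidates, "ranked biomarker candidates")
        record("biomarkers", "completed", n_candidates=len(candidates))
    else:
        record("biomarkers", "skipped", reason="missing classes or splicing scores")

    # ---- repeats -----------------------------------------------------------
    if molecules is not None and scores is not None:
        def _repeats():
            units = rp.spans_to_units(molecules, config.reference_flank_bp)
            summaries = rp.repeat_percentiles(units)
            corr = rp.correlate_repeats(summaries, scores)
            return summaries, corr
        summaries, rcorr = run_stage("repeats", _repeats)
        emit("repeat_summaries.tsv", summaries, "per-sample repeat percentiles")
        emit("repeat_correlations.tsv", rcorr, "percentile vs S Pearson")
        record("repeats", "completed", n_samples=len(summaries))
    else:
        record("repeats", "skipped", reason="missing molecules or scores")

    # ---- overlap (needs >= 2 result sets; single-cohort runs skip it) ------
    record("overlap", "skipped", reason="single dataset")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
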