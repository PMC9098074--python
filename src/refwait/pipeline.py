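"""End-to-end driver: simulate -> label -> train -> select -> waits -> sweep.

Every stage writes its intermediate artifact as a plain delimited or
JSON-lines file so any stage can be rerun in isolation, and the run report
reconciles row counts in and out of each stage. All randomness flows from
the three named seeds in :class:`RunConfig`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import io as rio
from .cohort import (
    DEFAULT_EXCLUDED, DEFAULT_MIN_TOKENS, LabeledNote,
    derive_gold_pairs, filter_short_notes, specialty_counts,
)
from .diagnostics import accuracy_by_note_length, f1_vs_training_size, length_accuracy_table, threshold_sweep
from .grid import GridSpec, cv_results_table, run_grid, train_final
from .selection import (
    BEST_F1, GATE_MIN_PRECISION, GATE_MIN_RECALL, PRECISION_FLOOR,
    gate_specialties, select_all, selection_table,
)
from .synthetic import SyntheticConfig, generate_cohort
from .waits import (
    DEFAULT_BOOTSTRAP, DEFAULT_THRESHOLD, compare_periods, deploy,
    link_wait_times, summarize_by_specialty, wait_table,
)

logger = logging.getLogger(__name__)

DEFAULT_SWEEP_THRESHOLDS = tuple(round(0.05 * i, 2) for i in range(1, 20))


@dataclass
class RunConfig:
    out_dir: str = "refwait_run"
    notes_path: str | None = None       # None => simulate
    claims_path: str | None = None
    study_year: int = 2015
    min_tokens: int = DEFAULT_MIN_TOKENS
    excluded_specialties: tuple[str, ...] = tuple(DEFAULT_EXCLUDED)
    grid: GridSpec = field(default_factory=GridSpec)
    k_folds: int = 5
    gate_min_precision: float = GATE_MIN_PRECISION
    gate_min_recall: float = GATE_MIN_RECALL
    deploy_threshold: float = DEFAULT_THRESHOLD
    bootstrap_replicates: int = DEFAULT_BOOTSTRAP
    sweep_thresholds: tuple[float, ...] = DEFAULT_SWEEP_THRESHOLDS
    run_sweep: bool = True
    seed_cv: int = 0
    seed_bootstrap: int = 0
    seed_synthetic: int = 0
    synthetic: SyntheticConfig | None = None
    prior_period_path: str | None = None  # two columns: specialty, value

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid" in raw:
            raw["grid"] = GridSpec(**{k: tuple(v) for k, v in raw["grid"].items()})
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        for key in ("excluded_specialties", "sweep_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def seeds(self) -> dict[str, int]:
        return {"seed_cv": self.seed_cv, "seed_bootstrap": self.seed_bootstrap,
                "seed_synthetic": self.seed_synthetic}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages in order; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = dict(config.seeds())
    report: dict[str, Any] = {"seeds": config.seeds(), "stages": {}}

    def stage(name: str, **info: Any) -> None:
        report["stages"][name] = info
        logger.info("stage %s: %s", name, info)

    t0 = time.time()
    # ---- simulate or load --------------------------------------------
    if config.notes_path is None:
        syn = config.synthetic or SyntheticConfig(seed=config.seed_synthetic)
        notes, claims, truth = generate_cohort(syn)
        rio.write_notes_jsonl(notes, out / "notes.jsonl")
        rio.write_claims_jsonl(claims, out / "claims.jsonl")
        rio.write_notes_csv(notes, out / "notes.csv", header)
        rio.write_claims_csv(claims, out / "claims.csv", header)
        rio.write_truth_jsonl(truth, out / "truth.jsonl")
        specialties = list(syn.specialties)
        stage("simulate", n_notes=len(notes), n_claims=len(claims))
    else:
        notes = (rio.read_notes_jsonl(config.notes_path)
                 if str(config.notes_path).endswith(".jsonl")
                 else rio.read_notes_csv(config.notes_path))
        claims = (rio.read_claims_jsonl(config.claims_path)
                  if str(config.claims_path).endswith(".jsonl")
                  else rio.read_claims_csv(config.claims_path))
        specialties = sorted({c.specialty.strip().lower() for c in claims}
                             - {s.lower() for s in config.excluded_specialties})
        stage("load", n_notes=len(notes), n_claims=len(claims))

    # ---- label --------------------------------------------------------
    filtered = filter_short_notes(notes, config.min_tokens)
    labeled = derive_gold_pairs(filtered, claims, config.study_year,
                                config.excluded_specialties)
    counts = specialty_counts(labeled)
    rio.write_table(counts, out / "specialty_counts.csv", header)
    stage("label", notes_in=len(notes), notes_retained=len(filtered),
          notes_filtered=len(notes) - len(filtered), gold_pairs=len(labeled))
    if not labeled:
        report["eligible_specialties"] = []
        _write_report(report, out)
        return report

    # ---- train --------------------------------------------------------
    results = run_grid(labeled, specialties, config.grid, k=config.k_folds,
                       seed=config.seed_cv)
    rio.write_table(cv_results_table(results), out / "cv_results.csv", header)
    stage("train", specialties=len(results),
          configs=len(next(iter(results.values()))))

    # ---- select -------------------------------------------------------
    selections = select_all(results)
    pf = {s: sel[PRECISION_FLOOR] for s, sel in selections.items()}
    eligible = gate_specialties(pf, config.gate_min_precision, config.gate_min_recall)
    rio.write_table(selection_table(selections), out / "selections.csv", header)
    report["eligible_specialties"] = sorted(eligible)
    stage("select", specialties=len(selections), eligible=sorted(eligible))

    # ---- waits --------------------------------------------------------
    true_counts = {s: sum(ln.gold_specialty == s for ln in labeled) for s in selections}
    best_f1 = {s: sel[BEST_F1] for s, sel in selections.items()}
    rio.write_table(f1_vs_training_size(best_f1, true_counts),
                    out / "f1_vs_training_size.csv", header)

    if not eligible:
        stage("waits", skipped=True, reason="no specialty passed the gate")
        _write_report(report, out)
        return report

    classifiers = {s: train_final(labeled, s, pf[s].config, seed=config.seed_cv)
                   for s in sorted(eligible)}
    positives = deploy(classifiers, filtered, config.deploy_threshold)
    observations = link_wait_times(positives, filtered, claims, config.study_year)
    estimates = summarize_by_specialty(
        observations, B=config.bootstrap_replicates, seed=config.seed_bootstrap)
    rio.write_table(wait_table(estimates), out / "wait_times.csv", header)
    report["wait_estimates"] = {
        s: {"n": est.n,
            **{f"p{int(round(q * 100))}": est.quantiles[q].point for q in est.quantiles},
            **{f"p{int(round(q * 100))}_ci": [est.quantiles[q].ci_low, est.quantiles[q].ci_high]
               for q in est.quantiles}}
        for s, est in estimates.items()
    }
    stage("waits", n_positive_pairs=len(positives), n_observations=len(observations),
          specialties=sorted(estimates))

    if config.prior_period_path:
        prior = rio.read_table(config.prior_period_path)
        verdicts = []
        for row in prior.itertuples():
            spec = str(row.specialty).strip().lower()
            if spec in estimates:
                qe = estimates[spec].quantiles[0.5]
                verdicts.append({"specialty": spec, "prior_value": float(row.value),
                                 "verdict": compare_periods(qe, float(row.value))})
        report["period_comparison"] = verdicts

    # ---- diagnostics --------------------------------------------------
    best_f1_clfs = {s: train_final(labeled, s, best_f1[s].config, seed=config.seed_cv)
                    for s in sorted(selections)}
    rio.write_table(length_accuracy_table(
        accuracy_by_note_length(best_f1_clfs, labeled)),
        out / "accuracy_by_length.csv", header)
    if config.run_sweep:
        sweep = threshold_sweep(classifiers, labeled, filtered, claims,
                                list(config.sweep_thresholds), config.study_year)
        rio.write_table(sweep, out / "threshold_sweep.csv", header)
        stage("sweep", thresholds=len(config.sweep_thresholds))

    logger.info("pipeline finished in %.1fs", time.time() - t0)
    _write_report(report, out)
    return report


def run_synthetic_study(
    syn: SyntheticConfig,
    seed_cv: int = 0,
    seed_bootstrap: int = 0,
    grid: GridSpec | None = None,
    k: int = 5,
    threshold: float = DEFAULT_THRESHOLD,
    bootstrap_replicates: int = DEFAULT_BOOTSTRAP,
    gate_min_precision: float = GATE_MIN_PRECISION,
    gate_min_recall: float = GATE_MIN_RECALL,
) -> dict[str, Any]:
    """Run the full study in memory on one synthetic cohort.

    Returns every intermediate object (cohort, labeled corpus, grid
    results, selections, eligible set, classifiers, wait estimates) so
    callers can inspect any stage without touching the filesystem.
    """
    notes, claims, truth = generate_cohort(syn)
    filtered = filter_short_notes(notes)
    labeled = derive_gold_pairs(filtered, claims, syn.study_year)
    results = run_grid(labeled, list(syn.specialties), grid or GridSpec(),
                       k=k, seed=seed_cv)
    selections = select_all(results)
    pf = {s: sel[PRECISION_FLOOR] for s, sel in selections.items()}
    eligible = gate_specialties(pf, gate_min_precision, gate_min_recall)
    classifiers = {s: train_final(labeled, s, pf[s].config, seed=seed_cv)
                   for s in sorted(eligible)}
    positives = deploy(classifiers, filtered, threshold)
    observations = link_wait_times(positives, filtered, claims, syn.study_year)
    estimates = summarize_by_specialty(observations, B=bootstrap_replicates,
                                       seed=seed_bootstrap)
    return {
        "notes": notes, "claims": claims, "truth": truth,
        "filtered": filtered, "labeled": labeled,
        "results": results, "selections": selections, "eligible": eligible,
        "classifiers": classifiers, "positives": positives,
        "observations": observations, "estimates": estimates,
    }


def _write_report(report: Mapping[str, Any], out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
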