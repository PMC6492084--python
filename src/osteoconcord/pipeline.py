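"""End-to-end orchestration: molecular calls -> macroscopic estimates ->
concordance report, with every intermediate written to disk."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .concordance import (accuracy_rates, agreement, confusion_summary,
                          per_trait_confusions, rates_from_counts,
                          round_half_up, score_distribution)
from .datasets import load_trait_catalog
from .molecular import (DEFAULT_LOWER_THRESHOLD, DEFAULT_UPPER_THRESHOLD,
                        GeneticSexCall, call_counts_table, read_counts_tsv)
from .traits import (DEFAULT_MEAN_BINS, SexCategory, estimate_table,
                     harmonize_score)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    scores_path: str | os.PathLike
    out_dir: str | os.PathLike
    counts_path: str | os.PathLike | None = None  # per-sample X/Y counts TSV
    genetic_path: str | os.PathLike | None = None  # sample_id,genetic_sex CSV
    catalog_path: str | os.PathLike | None = None
    lower_threshold: float = DEFAULT_LOWER_THRESHOLD
    upper_threshold: float = DEFAULT_UPPER_THRESHOLD
    mapq_min: int = 30
    mean_bins: Sequence[float] = DEFAULT_MEAN_BINS
    strict_phenice: bool = False
    sex_weighted: bool = False
    seed: int | None = None

    def validate(self) -> None:
        if self.counts_path is None and self.genetic_path is None:
            raise ValueError("need a genetic-call table or an X/Y count table")
        for label, p in (("scores", self.scores_path),
                         ("counts", self.counts_path),
                         ("genetic", self.genetic_path),
                         ("catalog", self.catalog_path)):
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if not 0 < self.lower_threshold < self.upper_threshold < 1:
            raise ValueError("thresholds must satisfy 0 < lower < upper < 1")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps({k: str(v) for k, v in asdict(config).items()},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _element_report(macro: Mapping[str, SexCategory],
                    genetic: Mapping[str, str],
                    weighting: str) -> dict:
    cs = confusion_summary(macro, genetic)
    rates = accuracy_rates(cs, weighting=weighting)
    agr = agreement(cs)
    return {
        "counts": {
            "female": list(cs.female),
            "male": list(cs.male),
            "pooled": list(cs.pooled),
        },
        "accuracy": {k: round_half_up(v.accuracy, 1)
                     for k, v in rates.items()},
        "raw_accuracy": {k: round_half_up(v.raw_accuracy, 1)
                         for k, v in rates.items()},
        "kappa": round_half_up(agr.kappa, 3),
        "band": agr.band,
        "mcnemar_p": round_half_up(agr.mcnemar_p, 3),
        "n_sexed": agr.n_sexed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run molecular calling, macroscopic estimation and concordance.

    Writes per-stage CSV/TSV outputs, a JSON report and a manifest into
    ``config.out_dir`` and returns the report as a dict.  Every input
    sample appears in the outputs, including those whose genetic sex
    could not be assigned.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = load_trait_catalog(config.catalog_path)

    # --- stage 1: genetic sex ---
    stage = "molecular sex calling"
    if config.counts_path is not None:
        counts = read_counts_tsv(config.counts_path)
        calls = call_counts_table(counts,
                                  lower_threshold=config.lower_threshold,
                                  upper_threshold=config.upper_threshold)
        calls.to_csv(out / "genetic_calls.tsv", sep="\t", index=False,
                     float_format="%.6g")
        genetic = {}
        for r in calls.itertuples():
            binary = GeneticSexCall(r.call).binary
            if binary is None:
                logger.info("%s: sample %s not assigned a genetic sex",
                            stage, r.sample_id)
            else:
                genetic[str(r.sample_id)] = binary
    else:
        gtab = pd.read_csv(config.genetic_path)
        if not {"sample_id", "genetic_sex"}.issubset(gtab.columns):
            raise ValueError(f"{stage}: genetic table needs columns "
                             "sample_id, genetic_sex")
        genetic = {str(r.sample_id): str(r.genetic_sex)
                   for r in gtab.itertuples()
                   if str(r.genetic_sex) in ("F", "M")}
    logger.info("%s: %d samples with a binary genetic call", stage,
                len(genetic))

    # --- stage 2: macroscopic estimates ---
    stage = "macroscopic estimation"
    sep = "\t" if str(config.scores_path).endswith((".tsv", ".tab")) else ","
    scores_raw = pd.read_csv(config.scores_path, sep=sep)
    estimates = estimate_table(scores_raw, catalog=catalog,
                               mean_bins=config.mean_bins,
                               strict_phenice=config.strict_phenice)
    estimates.to_csv(out / "estimates.csv", index=False)

    harmonized = scores_raw.copy()
    harmonized["sample_id"] = harmonized["sample_id"].astype(str)
    try:
        harmonized["harmonized"] = [
            harmonize_score(r.raw_score, catalog[r.trait].scale, trait=r.trait)
            for r in harmonized.itertuples()
        ]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{stage}: {exc}") from exc

    # --- stage 3: concordance ---
    weighting = "sex_weighted" if config.sex_weighted else "unweighted"
    macro = {
        col.replace("_estimate", ""): {
            str(r.sample_id): SexCategory[getattr(r, col)]
            for r in estimates.itertuples() if getattr(r, col)
        }
        for col in ("combined_estimate", "os_coxae_estimate",
                    "skull_estimate")
    }
    report: dict = {"elements": {}, "traits": {}}
    for element, calls_ in macro.items():
        try:
            report["elements"][element] = _element_report(
                calls_, genetic, weighting)
        except ValueError:
            logger.warning("no genetically sexed samples for %s", element)

    trait_cs = per_trait_confusions(harmonized, genetic, catalog)
    trait_rows = []
    for trait, cs in trait_cs.items():
        pooled = rates_from_counts(*cs.pooled)
        agr = agreement(cs)
        row = {
            "trait": trait,
            "n_correct": cs.pooled[0],
            "n_indeterminate": cs.pooled[1],
            "n_incorrect": cs.pooled[2],
            "raw_accuracy": round_half_up(pooled.raw_accuracy, 1),
            "accuracy": round_half_up(pooled.accuracy, 1),
            "mcnemar_p": round_half_up(agr.mcnemar_p, 3),
            "kappa": round_half_up(agr.kappa, 3),
            "band": agr.band,
        }
        trait_rows.append(row)
        report["traits"][trait] = row
    pd.DataFrame(trait_rows).to_csv(out / "trait_summary.csv", index=False)

    dist = score_distribution(harmonized, genetic)
    dist.to_csv(out / "score_distribution.csv", index=False,
                float_format="%.6g")

    elem_rows = []
    for element, rep in report["elements"].items():
        for sex in ("pooled", "female", "male"):
            counts = rep["counts"][sex]
            elem_rows.append({
                "element": element, "sex": sex,
                "n_correct": counts[0], "n_indeterminate": counts[1],
                "n_incorrect": counts[2],
                "raw_accuracy": rep["raw_accuracy"].get(sex),
                "accuracy": rep["accuracy"].get(sex),
            })
    pd.DataFrame(elem_rows).to_csv(out / "element_summary.csv", index=False)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_samples_scored": int(scores_raw["sample_id"].nunique()),
        "n_samples_genetic": len(genetic),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
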