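"""Synthetic skeletal cohorts with known true sex.

Generates the two data streams the pipeline consumes, for cohorts whose
ground truth is known by construction:

* ordinal trait scores drawn per individual from per-sex categorical
  distributions over the harmonized 1-5 scale, with per-trait
  missingness (an unobservable trait simply has no score);
* X/Y chromosome read counts, with the total depth lognormal around a
  configured mean (ancient-DNA depth is heavy-tailed) and the Y count
  binomial with success probability set by the individual's true sex,
  optionally mixed with a contaminant of the other sex.

Defaults emulate the reference cohort: 66 individuals, 61.5% male,
per-trait score distributions and missingness taken from the bundled
reference tables, male Ry expectation 0.09 and female 0.002 (mismapping
noise) around the 0.016/0.075 decision thresholds, 10,000 informative
reads on average, no contamination.

A single global seed is split into one independent stream per
individual, so enlarging a cohort never perturbs the individuals already
drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .molecular import XYCounts
from .traits import TRAIT_CATALOG, Scale, TraitDefinition

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort",
           "generate_read_counts", "default_trait_distributions",
           "default_missingness"]

_HARMONIZED_TO_RAW = {
    Scale.THREE_POINT: {1: 1, 3: 2, 5: 3},
    Scale.FIVE_POINT: {h: h for h in range(1, 6)},
    Scale.WEA_FIVE_POINT: {h: h - 3 for h in range(1, 6)},
}


def default_trait_distributions() -> dict[str, dict[str, np.ndarray]]:
    """Per-trait per-sex score probabilities from the reference cohort.

    Rows are renormalized to sum to 1 (the source percentages carry
    rounding error, and one male row contains an obvious transcription
    slip summing well above 100).
    """
    from .datasets import reference_score_distributions

    wide = reference_score_distributions()
    out: dict[str, dict[str, np.ndarray]] = {}
    for _, row in wide.iterrows():
        p = np.nan_to_num(
            row[["s1", "s2", "s3", "s4", "s5"]].to_numpy(dtype=float))
        total = p.sum()
        if total <= 0:
            raise ValueError(f"empty distribution for {row['trait']}")
        sex = "F" if row["sex"] == "female" else "M"
        out.setdefault(row["trait"], {})[sex] = p / total
    return out


def default_missingness() -> dict[str, float]:
    """Per-trait probability a trait is unobservable, from the reference
    cohort's observed fractions."""
    from .datasets import REFERENCE_N_ASSESSED, reference_trait_totals

    totals = reference_trait_totals()
    return {t: float(np.clip(1.0 - n / REFERENCE_N_ASSESSED, 0.0, 1.0))
            for t, n in totals.items()}


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic cohort.

    ``trait_distributions`` maps trait -> {'F': p, 'M': p} with p a
    length-5 probability vector over harmonized scores 1..5;
    ``missingness`` maps trait -> P(unobservable).  ``p_male_ry`` and
    ``p_female_ry`` are the expected Y-read fractions for true males and
    females.  ``contamination`` mixes in a contaminant of
    ``contaminant_sex`` at the read level.  ``seed`` is mandatory.
    """

    seed: int
    n_individuals: int = 66
    prop_male: float = 0.615
    trait_distributions: dict[str, dict[str, np.ndarray]] = field(
        default_factory=default_trait_distributions)
    missingness: dict[str, float] = field(default_factory=default_missingness)
    mean_reads: float = 10_000.0
    read_dispersion: float = 0.6  # lognormal sigma
    p_male_ry: float = 0.09
    p_female_ry: float = 0.002
    contamination: float = 0.0
    contaminant_sex: str = "M"
    catalog: Mapping[str, TraitDefinition] = field(
        default_factory=lambda: dict(TRAIT_CATALOG))

    def validate(self) -> None:
        if not 0.0 <= self.prop_male <= 1.0:
            raise ValueError("prop_male must lie in [0, 1]")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must lie in [0, 1]")
        for p in (self.p_male_ry, self.p_female_ry):
            if not 0.0 <= p <= 1.0:
                raise ValueError("Ry expectations must lie in [0, 1]")
        if self.contaminant_sex not in ("F", "M"):
            raise ValueError("contaminant_sex must be 'F' or 'M'")
        if self.mean_reads <= 0:
            raise ValueError("mean_reads must be positive")
        for trait, by_sex in self.trait_distributions.items():
            cat = self.catalog.get(trait)
            if cat is None:
                raise KeyError(f"unknown trait {trait!r} in distributions")
            representable = set(_HARMONIZED_TO_RAW[cat.scale])
            for sex, p in by_sex.items():
                p = np.asarray(p, dtype=float)
                if p.shape != (5,) or (p < 0).any():
                    raise ValueError(
                        f"{trait}/{sex}: need 5 non-negative probabilities")
                if not math.isclose(float(p.sum()), 1.0, abs_tol=1e-8):
                    raise ValueError(f"{trait}/{sex}: probabilities must sum "
                                     f"to 1, got {p.sum():.6f}")
                mass_outside = sum(p[h - 1] for h in range(1, 6)
                                   if h not in representable)
                if mass_outside > 1e-12:
                    raise ValueError(
                        f"{trait}/{sex}: probability mass on scores the "
                        f"{cat.scale.value} scale cannot produce")
        for trait, m in self.missingness.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"missingness for {trait!r} outside [0, 1]")


@dataclass
class SyntheticCohort:
    """Generated individuals, their trait scores and read counts."""

    individuals: pd.DataFrame  # sample_id, true_sex, n_x, n_y
    scores_long: pd.DataFrame  # sample_id, trait, raw_score
    config: CohortConfig

    @property
    def truth(self) -> dict[str, str]:
        return dict(zip(self.individuals["sample_id"],
                        self.individuals["true_sex"]))


def _effective_p(true_sex: str, config: CohortConfig) -> float:
    p = {"M": config.p_male_ry, "F": config.p_female_ry}
    return ((1.0 - config.contamination) * p[true_sex]
            + config.contamination * p[config.contaminant_sex])


def generate_read_counts(true_sex: str, config: CohortConfig,
                         rng: np.random.Generator) -> XYCounts:
    """Draw one individual's X/Y read counts.

    The total is lognormal with mean ``mean_reads`` (sigma on the log
    scale is ``read_dispersion``); the Y count is binomial with the
    contamination-mixed success probability.
    """
    sigma = config.read_dispersion
    mu = math.log(config.mean_reads) - 0.5 * sigma**2
    total = max(1, int(round(rng.lognormal(mean=mu, sigma=sigma))))
    n_y = int(rng.binomial(total, _effective_p(true_sex, config)))
    return XYCounts(n_x=total - n_y, n_y=n_y)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort deterministically from the config's seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_individuals)

    scores = np.arange(1, 6)
    ind_rows, score_rows = [], []
    for i, child in enumerate(streams):
        rng = np.random.default_rng(child)
        sample_id = f"SYN{i:04d}"
        true_sex = "M" if rng.random() < config.prop_male else "F"
        counts = generate_read_counts(true_sex, config, rng)
        ind_rows.append({"sample_id": sample_id, "true_sex": true_sex,
                         "n_x": counts.n_x, "n_y": counts.n_y})
        for trait, by_sex in config.trait_distributions.items():
            if rng.random() < config.missingness.get(trait, 0.0):
                continue
            h = int(rng.choice(scores, p=np.asarray(by_sex[true_sex],
                                                    dtype=float)))
            raw = _HARMONIZED_TO_RAW[config.catalog[trait].scale][h]
            score_rows.append({"sample_id": sample_id, "trait": trait,
                               "raw_score": raw})
    return SyntheticCohort(
        individuals=pd.DataFrame(ind_rows),
        scores_long=pd.DataFrame(score_rows,
                                 columns=["sample_id", "trait", "raw_score"]),
        config=config,
    )
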