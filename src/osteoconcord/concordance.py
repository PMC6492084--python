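"""Agreement statistics between macroscopic and genetic sex estimates.

The genetic call is treated as ground truth ("expected") and the
macroscopic estimate as the observation.  Because an osteologist may
legitimately return "indeterminate", two rates are reported:

* **accuracy** — percent correct among individuals actually assigned a
  sex (indeterminates excluded from the denominator);
* **raw accuracy** — percent correct among all observed individuals,
  indeterminates counted in the denominator.

Accuracy can overstate a method's field performance when many specimens
are left unsexed, which is why both are kept side by side.  Systematic
direction of disagreement is tested with an exact McNemar test on the
discordant pairs; chance-corrected agreement with Cohen's kappa, banded
by the Watson & Petrie cut-points.  Per-score posterior probabilities of
being female, P(F | score) = f / (f + m) over the within-sex score
frequencies, locate where the male/female cut-off sits in a particular
population (Walker's approach with equal priors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .traits import SexCategory, TraitDefinition, classify_trait_score

__all__ = [
    "ConfusionSummary",
    "AccuracyReport",
    "AgreementResult",
    "confusion_summary",
    "accuracy_rates",
    "rates_from_counts",
    "mcnemar_exact",
    "mcnemar_chi2",
    "cohens_kappa",
    "agreement_band",
    "score_distribution",
    "prob_female_given_score",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at the last digit always rounds away)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionSummary:
    """Correct / indeterminate / incorrect counts per genetic sex.

    ``table_2x2`` is the sexed-only contingency table, rows genetic F/M,
    columns macroscopic F/M.
    """

    female: tuple[int, int, int]  # (correct, indeterminate, incorrect)
    male: tuple[int, int, int]

    @property
    def table_2x2(self) -> np.ndarray:
        f_corr, _, f_inc = self.female
        m_corr, _, m_inc = self.male
        return np.array([[f_corr, f_inc], [m_inc, m_corr]], dtype=int)

    @property
    def pooled(self) -> tuple[int, int, int]:
        return tuple(int(a + b) for a, b in zip(self.female, self.male))

    @property
    def discordant(self) -> tuple[int, int]:
        """(genetic F called M, genetic M called F)."""
        return self.female[2], self.male[2]


@dataclass(frozen=True)
class AccuracyReport:
    accuracy: float  # percent, NaN when nothing was sexed
    raw_accuracy: float  # percent
    n_observed: int
    n_sexed: int


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    band: str
    mcnemar_p: float
    n_sexed: int


def confusion_summary(
    macroscopic: Mapping[str, SexCategory],
    genetic: Mapping[str, str],
) -> ConfusionSummary:
    """Tally macroscopic calls against binary genetic sex.

    Probable categories collapse to their definite side; I counts as
    indeterminate.  Only samples present in both mappings (and with a
    binary genetic call) are tallied.
    """
    tallies = {"F": [0, 0, 0], "M": [0, 0, 0]}
    n = 0
    for sample, cat in macroscopic.items():
        g = genetic.get(sample)
        if g not in ("F", "M") or cat is None:
            continue
        n += 1
        b = cat.binary
        if b is None:
            tallies[g][1] += 1
        elif b == g:
            tallies[g][0] += 1
        else:
            tallies[g][2] += 1
    if n == 0:
        raise ValueError("no samples with both a macroscopic estimate "
                         "and a genetic call")
    return ConfusionSummary(female=tuple(tallies["F"]),
                            male=tuple(tallies["M"]))


def rates_from_counts(correct: int, indeterminate: int, incorrect: int
                      ) -> AccuracyReport:
    """Accuracy and raw accuracy (percent) from a count triple."""
    n_obs = correct + indeterminate + incorrect
    n_sexed = correct + incorrect
    if n_obs == 0:
        raise ValueError("no observed samples")
    raw = 100.0 * correct / n_obs
    acc = 100.0 * correct / n_sexed if n_sexed else float("nan")
    return AccuracyReport(accuracy=acc, raw_accuracy=raw,
                          n_observed=n_obs, n_sexed=n_sexed)


def accuracy_rates(cs: ConfusionSummary, weighting: str = "unweighted"
                   ) -> dict[str, AccuracyReport]:
    """Pooled and per-sex accuracy reports.

    ``weighting='sex_weighted'`` replaces the pooled rates by the mean of
    the two per-sex rates, so the minority sex is not swamped.
    """
    out = {
        "female": rates_from_counts(*cs.female),
        "male": rates_from_counts(*cs.male),
    }
    if weighting == "unweighted":
        out["pooled"] = rates_from_counts(*cs.pooled)
    elif weighting == "sex_weighted":
        f, m = out["female"], out["male"]
        pooled = rates_from_counts(*cs.pooled)
        out["pooled"] = AccuracyReport(
            accuracy=(f.accuracy + m.accuracy) / 2.0,
            raw_accuracy=(f.raw_accuracy + m.raw_accuracy) / 2.0,
            n_observed=pooled.n_observed,
            n_sexed=pooled.n_sexed,
        )
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return out


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p-value from the two discordant counts.

    Under marginal homogeneity the b discordant pairs among n = b + c are
    Binomial(n, 1/2); p = min(1, 2 * P(X >= max(b, c))).  p = 1 when
    there are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    k = max(b, c)
    return min(1.0, 2.0 * float(stats.binom.sf(k - 1, n, 0.5)))


def mcnemar_chi2(b: int, c: int, correction: bool = True) -> float:
    """Chi-square McNemar approximation (optionally continuity-corrected)."""
    if b + c == 0:
        return 1.0
    num = (abs(b - c) - 1) ** 2 if correction else (b - c) ** 2
    chi2 = num / (b + c)
    return float(stats.chi2.sf(chi2, df=1))


def cohens_kappa(table: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Cohen's kappa for a square contingency table.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed diagonal
    proportion and p_e the product-of-marginals chance agreement.
    Returns NaN when p_e = 1 (all mass in a single row/column pair),
    where agreement beyond chance is undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("kappa requires a square table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    n = t.sum()
    if n == 0:
        raise ValueError("empty table")
    p_o = np.trace(t) / n
    p_e = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


#: Watson & Petrie agreement bands on a two-decimal kappa grid.
_BANDS = (
    (-0.005, "poor"),        # k < 0.00
    (0.205, "slight"),       # 0.00 <= k <= 0.20
    (0.405, "fair"),         # 0.21 <= k <= 0.40
    (0.605, "moderate"),     # 0.41 <= k <= 0.60
    (0.805, "substantial"),  # 0.61 <= k <= 0.80
)


def agreement_band(kappa: float) -> str:
    """Qualitative agreement band for a kappa value.

    The cut-points are stated on a two-decimal grid, so kappa is rounded
    half-up to two decimals before banding.
    """
    if math.isnan(kappa):
        return "undefined"
    if not -1.0 - 1e-9 <= kappa <= 1.0 + 1e-9:
        raise ValueError("kappa must lie in [-1, 1]")
    k = round_half_up(kappa, 2)
    for cut, label in _BANDS:
        if k < cut:
            return label
    return "almost perfect"


def agreement(cs: ConfusionSummary) -> AgreementResult:
    """Kappa (sexed-only 2x2), its band, and the exact McNemar p."""
    kappa = cohens_kappa(cs.table_2x2)
    b, c = cs.discordant
    return AgreementResult(
        kappa=kappa,
        band=agreement_band(kappa),
        mcnemar_p=mcnemar_exact(b, c),
        n_sexed=int(cs.table_2x2.sum()),
    )


def per_trait_confusions(
    scores_long: pd.DataFrame,
    genetic: Mapping[str, str],
    catalog: Mapping[str, TraitDefinition],
) -> dict[str, ConfusionSummary]:
    """One ConfusionSummary per trait from harmonized single-trait calls.

    ``scores_long`` needs columns ``sample_id, trait, harmonized``; each
    score is classified through its trait's map and tallied against the
    genetic sex.  Traits with no genetically sexed observations are
    omitted.
    """
    out = {}
    for trait, grp in scores_long.groupby("trait", sort=True):
        if trait not in catalog:
            raise KeyError(f"unknown trait {trait!r}")
        calls = {str(r.sample_id): classify_trait_score(catalog[trait],
                                                        int(r.harmonized))
                 for r in grp.itertuples()}
        try:
            out[trait] = confusion_summary(calls, genetic)
        except ValueError:
            continue
    return out


def prob_female_given_score(pct_female: float, pct_male: float) -> float:
    """Equal-prior posterior P(female | score) from within-sex frequencies.

    NaN when neither sex ever produces the score.
    """
    if pct_female < 0 or pct_male < 0:
        raise ValueError("percentages must be non-negative")
    total = pct_female + pct_male
    if total == 0:
        return float("nan")
    return pct_female / total


def score_distribution(
    scores_long: pd.DataFrame,
    genetic: Mapping[str, str],
    score_levels: Sequence[int] = (1, 2, 3, 4, 5),
) -> pd.DataFrame:
    """Within-sex score frequency table with Walker posteriors.

    ``scores_long`` needs columns ``sample_id, trait, harmonized``.
    Returns one row per (trait, score) with the percentage of each sex's
    observed individuals at that score and ``prob_female``.  A sex with
    no observations for a trait yields NaN percentages and posteriors.
    """
    df = scores_long.copy()
    df["sex"] = df["sample_id"].map(genetic)
    df = df[df["sex"].isin(["F", "M"])]
    rows = []
    for trait, grp in df.groupby("trait", sort=True):
        pct = {}
        for sex in ("F", "M"):
            sub = grp[grp["sex"] == sex]
            if len(sub) == 0:
                pct[sex] = {s: float("nan") for s in score_levels}
            else:
                counts = sub["harmonized"].value_counts()
                pct[sex] = {s: 100.0 * counts.get(s, 0) / len(sub)
                            for s in score_levels}
        for s in score_levels:
            pf, pm = pct["F"][s], pct["M"][s]
            prob = (float("nan") if math.isnan(pf) or math.isnan(pm)
                    else prob_female_given_score(pf, pm))
            rows.append({"trait": trait, "score": s,
                         "pct_female": pf, "pct_male": pm,
                         "prob_female": prob})
    return pd.DataFrame(rows)
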