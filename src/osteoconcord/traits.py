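"""Macroscopic sex estimation from ordinal skeletal trait scores.

Eighteen sexually dimorphic traits of the os coxae (8) and skull (10) are
scored on one of three native scales used in osteological standards:

* ``three_point`` — 1 (female), 2 (unknown), 3 (male); used for the three
  Phenice pubic traits, forehead inclination, frontal bossing and overall
  mandible shape.
* ``five_point`` — 1 (female) .. 5 (male).
* ``wea_five_point`` — the Workshop of European Anthropologists scale,
  -2 (hyperfeminine) .. +2 (hypermasculine).

All scores are harmonized to a common 1 (hyperfeminine) .. 5
(hypermasculine) scale.  The preauricular sulcus is the one trait whose
meaning is not monotone in the usual way: presence (scores 1-4) indicates
a female, and only absence (score 5) indicates a male.

An element-level estimate (os coxae, skull) is the mean of the harmonized
scores mapped onto the five sex categories F / PF / I / PM / M.  Two
expert rules refine the arithmetic: an ambiguous os coxae mean is
overridden by the majority direction of the highly reliable Phenice
traits, and when skull and pelvis disagree the pelvis wins.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Scale",
    "SexCategory",
    "TraitDefinition",
    "TraitScore",
    "SkeletonRecord",
    "TRAIT_CATALOG",
    "PHENICE_TRAITS",
    "harmonize_score",
    "classify_trait_score",
    "element_estimate",
    "combined_estimate",
    "estimate_skeleton",
    "estimate_table",
]


class Scale(str, enum.Enum):
    THREE_POINT = "three_point"
    FIVE_POINT = "five_point"
    WEA_FIVE_POINT = "wea_five_point"


#: Native score domains per scale.
_SCALE_DOMAIN = {
    Scale.THREE_POINT: (1, 2, 3),
    Scale.FIVE_POINT: (1, 2, 3, 4, 5),
    Scale.WEA_FIVE_POINT: (-2, -1, 0, 1, 2),
}


class SexCategory(enum.IntEnum):
    """Ordered five-level sex assessment, female to male."""

    F = 1
    PF = 2
    I = 3
    PM = 4
    M = 5

    @property
    def binary(self) -> str | None:
        """Collapse probable categories to their definite side; I -> None."""
        if self in (SexCategory.F, SexCategory.PF):
            return "F"
        if self in (SexCategory.M, SexCategory.PM):
            return "M"
        return None


@dataclass(frozen=True)
class TraitDefinition:
    """One catalogued trait: its element, native scale and classification."""

    name: str
    element: str  # "os_coxae" | "skull"
    scale: Scale
    is_phenice: bool = False
    # preauricular sulcus: presence (1-4) confirms female, absence (5) male
    special_presence_map: bool = False

    def classify(self, harmonized: int) -> SexCategory:
        return classify_trait_score(self, harmonized)

    def mean_contribution(self, harmonized: int) -> int:
        """Score contributed to the element mean.

        For the preauricular sulcus the harmonized score is first passed
        through its classification map (1-4 contribute 1, 5 contributes 5)
        so a present sulcus never pushes the mean male-ward.
        """
        if self.special_presence_map:
            return 1 if harmonized <= 4 else 5
        return harmonized


def _catalog() -> dict[str, TraitDefinition]:
    T, S = Scale, TraitDefinition
    defs = [
        # --- os coxae (8) ---
        S("ventral_arc", "os_coxae", T.THREE_POINT, is_phenice=True),
        S("ischiopubic_ramus", "os_coxae", T.THREE_POINT, is_phenice=True),
        S("subpubic_concavity", "os_coxae", T.THREE_POINT, is_phenice=True),
        S("preauricular_sulcus", "os_coxae", T.FIVE_POINT,
          special_presence_map=True),
        S("sciatic_notch", "os_coxae", T.FIVE_POINT),
        S("subpubic_angle", "os_coxae", T.FIVE_POINT),
        S("arc_compose", "os_coxae", T.WEA_FIVE_POINT),
        S("ilium_shape", "os_coxae", T.WEA_FIVE_POINT),
        # --- skull (10) ---
        S("nuchal_crest", "skull", T.FIVE_POINT),
        S("mastoid_process", "skull", T.FIVE_POINT),
        S("glabella", "skull", T.FIVE_POINT),
        S("supraorbital_margin", "skull", T.FIVE_POINT),
        S("mental_eminence", "skull", T.FIVE_POINT),
        S("zygomatic_arch_extension", "skull", T.FIVE_POINT),
        S("frontal_bossing", "skull", T.THREE_POINT),
        S("forehead_inclination", "skull", T.THREE_POINT),
        S("overall_mandible_shape", "skull", T.THREE_POINT),
        S("gonial_flaring", "skull", T.WEA_FIVE_POINT),
    ]
    return {d.name: d for d in defs}


TRAIT_CATALOG: dict[str, TraitDefinition] = _catalog()
PHENICE_TRAITS = tuple(n for n, d in TRAIT_CATALOG.items() if d.is_phenice)

assert sum(d.element == "os_coxae" for d in TRAIT_CATALOG.values()) == 8
assert sum(d.element == "skull" for d in TRAIT_CATALOG.values()) == 10
assert len(PHENICE_TRAITS) == 3


@dataclass(frozen=True)
class TraitScore:
    """A single observed trait score, native and harmonized."""

    sample_id: str
    trait: str
    raw_score: int
    harmonized: int

    @classmethod
    def from_raw(cls, sample_id: str, trait: str, raw_score: int,
                 catalog: Mapping[str, TraitDefinition] | None = None
                 ) -> "TraitScore":
        catalog = catalog or TRAIT_CATALOG
        if trait not in catalog:
            raise KeyError(f"unknown trait {trait!r}")
        h = harmonize_score(raw_score, catalog[trait].scale, trait=trait)
        return cls(sample_id, trait, int(raw_score), h)


@dataclass
class SkeletonRecord:
    """One individual: trait scores, element estimates and the genetic call."""

    sample_id: str
    scores: dict[str, int] = field(default_factory=dict)  # trait -> harmonized
    os_coxae_estimate: SexCategory | None = None
    skull_estimate: SexCategory | None = None
    combined_estimate: SexCategory | None = None
    genetic_sex: str | None = None  # "F" | "M" | None
    age_band: str | None = None
    phenice_override_applied: bool = False
    n_traits_used: int = 0


def harmonize_score(raw: int, scale: Scale | str, trait: str = "") -> int:
    """Map a native-scale score onto the common 1-5 scale.

    three_point: 1->1, 2->3, 3->5; wea_five_point: -2..+2 -> 1..5;
    five_point: identity.
    """
    scale = Scale(scale)
    raw = int(raw)
    if raw not in _SCALE_DOMAIN[scale]:
        where = f" for trait {trait!r}" if trait else ""
        raise ValueError(
            f"score {raw} outside the {scale.value} domain"
            f" {_SCALE_DOMAIN[scale]}{where}"
        )
    if scale is Scale.THREE_POINT:
        return {1: 1, 2: 3, 3: 5}[raw]
    if scale is Scale.WEA_FIVE_POINT:
        return raw + 3
    return raw


def classify_trait_score(trait: TraitDefinition, harmonized: int) -> SexCategory:
    """Sex category indicated by one harmonized score.

    Standard map: 1->F, 2->PF, 3->I, 4->PM, 5->M.  The preauricular
    sulcus maps 1-4 -> F (trait present) and 5 -> M (trait absent).
    """
    if harmonized not in (1, 2, 3, 4, 5):
        raise ValueError(f"harmonized score must be 1-5, got {harmonized}")
    if trait.special_presence_map:
        return SexCategory.F if harmonized <= 4 else SexCategory.M
    return SexCategory(harmonized)


#: Mean-score bin edges: mean <= 1.5 F; <= 2.5 PF; < 3.5 I; < 4.5 PM; else M.
DEFAULT_MEAN_BINS = (1.5, 2.5, 3.5, 4.5)


def _mean_to_category(mean: float, bins: Sequence[float] = DEFAULT_MEAN_BINS
                      ) -> SexCategory:
    b1, b2, b3, b4 = bins
    if mean <= b1:
        return SexCategory.F
    if mean <= b2:
        return SexCategory.PF
    if mean < b3:
        return SexCategory.I
    if mean < b4:
        return SexCategory.PM
    return SexCategory.M


def _phenice_direction(scores: Mapping[str, int],
                       catalog: Mapping[str, TraitDefinition],
                       strict: bool) -> SexCategory | None:
    """Majority direction of observed Phenice traits; None if no winner.

    Female votes are harmonized score 1, male votes score 5; the neutral
    score 3 abstains.  In strict mode at least two Phenice traits must be
    observable before any override.
    """
    observed = [s for t, s in scores.items()
                if t in catalog and catalog[t].is_phenice]
    if strict and len(observed) < 2:
        return None
    f_votes = sum(1 for s in observed if s < 3)
    m_votes = sum(1 for s in observed if s > 3)
    if f_votes > m_votes:
        return SexCategory.F
    if m_votes > f_votes:
        return SexCategory.M
    return None


def element_estimate(
    scores: Mapping[str, int],
    element: str,
    *,
    catalog: Mapping[str, TraitDefinition] | None = None,
    mean_bins: Sequence[float] = DEFAULT_MEAN_BINS,
    strict_phenice: bool = False,
) -> tuple[SexCategory | None, bool, int]:
    """Estimate sex from one element's harmonized scores.

    Returns ``(category, phenice_override_applied, n_traits_used)``;
    the category is None when no trait of the element is observable.
    The estimate is the mean harmonized score binned into categories; an
    ambiguous (I) os coxae estimate is replaced by the Phenice majority
    direction when one exists.
    """
    catalog = catalog or TRAIT_CATALOG
    elem_scores = {t: s for t, s in scores.items()
                   if t in catalog and catalog[t].element == element}
    if not elem_scores:
        return None, False, 0
    contributions = [catalog[t].mean_contribution(s)
                     for t, s in elem_scores.items()]
    cat = _mean_to_category(sum(contributions) / len(contributions), mean_bins)
    override = False
    if element == "os_coxae" and cat is SexCategory.I:
        direction = _phenice_direction(elem_scores, catalog, strict_phenice)
        if direction is not None:
            cat, override = direction, True
    return cat, override, len(elem_scores)


def combined_estimate(pelvis: SexCategory | None,
                      skull: SexCategory | None) -> SexCategory | None:
    """Overall estimate with pelvic priority.

    The pelvis wins any conflict; an indeterminate or missing element
    defers to the other; both indeterminate stays indeterminate; both
    missing yields no estimate.
    """
    if pelvis is None and skull is None:
        return None
    if pelvis is None:
        return skull
    if skull is None:
        return pelvis
    if pelvis is SexCategory.I:
        return skull
    return pelvis


def estimate_skeleton(
    sample_id: str,
    raw_scores: Mapping[str, int],
    *,
    catalog: Mapping[str, TraitDefinition] | None = None,
    mean_bins: Sequence[float] = DEFAULT_MEAN_BINS,
    strict_phenice: bool = False,
) -> SkeletonRecord:
    """Full macroscopic workup of one individual from native-scale scores."""
    catalog = catalog or TRAIT_CATALOG
    harmonized = {
        t: harmonize_score(r, catalog[t].scale, trait=t)
        for t, r in raw_scores.items()
        if t in catalog
    }
    unknown = set(raw_scores) - set(catalog)
    if unknown:
        raise KeyError(f"unknown trait(s): {sorted(unknown)}")
    pelvis, override, n_pelvis = element_estimate(
        harmonized, "os_coxae", catalog=catalog, mean_bins=mean_bins,
        strict_phenice=strict_phenice)
    skull, _, n_skull = element_estimate(
        harmonized, "skull", catalog=catalog, mean_bins=mean_bins)
    return SkeletonRecord(
        sample_id=sample_id,
        scores=harmonized,
        os_coxae_estimate=pelvis,
        skull_estimate=skull,
        combined_estimate=combined_estimate(pelvis, skull),
        phenice_override_applied=override,
        n_traits_used=n_pelvis + n_skull,
    )


def estimate_table(
    scores_long,
    *,
    catalog: Mapping[str, TraitDefinition] | None = None,
    mean_bins: Sequence[float] = DEFAULT_MEAN_BINS,
    strict_phenice: bool = False,
) -> "pd.DataFrame":
    """Per-sample estimates from a long table ``sample_id, trait, raw_score``.

    Missing scores are simply absent rows; they are never imputed.
    """
    import pandas as pd

    required = {"sample_id", "trait", "raw_score"}
    if not required.issubset(scores_long.columns):
        raise KeyError(f"score table needs columns {sorted(required)}")
    rows = []
    for sample_id, grp in scores_long.groupby("sample_id", sort=True):
        raw = dict(zip(grp["trait"], grp["raw_score"]))
        rec = estimate_skeleton(str(sample_id), raw, catalog=catalog,
                                mean_bins=mean_bins,
                                strict_phenice=strict_phenice)
        rows.append({
            "sample_id": rec.sample_id,
            "os_coxae_estimate": rec.os_coxae_estimate.name
            if rec.os_coxae_estimate else "",
            "skull_estimate": rec.skull_estimate.name
            if rec.skull_estimate else "",
            "combined_estimate": rec.combined_estimate.name
            if rec.combined_estimate else "",
            "n_traits_used": rec.n_traits_used,
            "phenice_override_applied": rec.phenice_override_applied,
        })
    return pd.DataFrame(rows)
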