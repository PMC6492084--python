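"""Bundled reference data: concordance counts from a genetically sexed
medieval skeletal assemblage.

The package ships, as plain CSV, the per-sex outcome counts of a
reference cohort in which every individual's sex was established
genetically and then estimated macroscopically blind to the genetic
result: element-level summaries (os coxae, skull, combined), per-trait
per-sex correct/indeterminate/incorrect counts, and within-sex score
distributions for each of the 18 traits.  These drive the acceptance
checks and provide realistic defaults for the synthetic-cohort
generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .concordance import ConfusionSummary
from .traits import Scale, TraitDefinition

#: Individuals assessable macroscopically in the reference cohort.
REFERENCE_N_ASSESSED = 63


def _read_csv(name: str) -> pd.DataFrame:
    ref = resources.files("osteoconcord") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def reference_element_counts() -> pd.DataFrame:
    """Element-level correct/indeterminate/incorrect counts by sex.

    ``sex`` is 'female', 'male' or 'pooled'; the pooled rows are the
    published pooled counts, which for the combined element disagree by
    one with the sum of the per-sex rows (a known inconsistency of the
    source; the per-sex rows are authoritative here).
    """
    return _read_csv("element_summary.csv")


def reference_trait_counts() -> pd.DataFrame:
    """Per-trait per-sex correct/incorrect/indeterminate counts."""
    return _read_csv("trait_sex_counts.csv")


def reference_score_distributions() -> pd.DataFrame:
    """Within-sex percentage of individuals at each harmonized score.

    Wide format: ``trait, sex, s1..s5``; blank cells are scores the
    trait's native scale cannot produce.  Rows are percentages as
    printed in the source and need not sum to exactly 100.
    """
    return _read_csv("score_distributions.csv")


def _confusion_from_rows(df: pd.DataFrame) -> ConfusionSummary:
    by_sex = {}
    for sex in ("female", "male"):
        row = df[df["sex"] == sex]
        if len(row) != 1:
            raise ValueError(f"expected one {sex} row, got {len(row)}")
        r = row.iloc[0]
        by_sex[sex] = (int(r["n_correct"]), int(r["n_indeterminate"]),
                       int(r["n_incorrect"]))
    return ConfusionSummary(female=by_sex["female"], male=by_sex["male"])


def element_confusion(element: str) -> ConfusionSummary:
    """ConfusionSummary for 'combined', 'os_coxae' or 'skull', built from
    the per-sex rows."""
    df = reference_element_counts()
    sub = df[df["element"] == element]
    if sub.empty:
        raise KeyError(f"unknown element {element!r}")
    return _confusion_from_rows(sub)


def trait_confusion(trait: str) -> ConfusionSummary:
    """ConfusionSummary for one of the 18 traits."""
    df = reference_trait_counts()
    sub = df[df["trait"] == trait]
    if sub.empty:
        raise KeyError(f"unknown trait {trait!r}")
    return _confusion_from_rows(sub)


def reference_trait_totals() -> pd.Series:
    """Observed individuals per trait (both sexes), indexed by trait."""
    df = reference_trait_counts()
    totals = (df["n_correct"] + df["n_incorrect"] + df["n_indeterminate"])
    return totals.groupby(df["trait"]).sum()


def load_trait_catalog(path=None) -> dict[str, TraitDefinition]:
    """Load a trait catalogue from YAML (the bundled default if no path)."""
    if path is None:
        ref = resources.files("osteoconcord") / "data" / "trait_catalog.yaml"
        with resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    catalog = {}
    for name, spec in raw["traits"].items():
        catalog[name] = TraitDefinition(
            name=name,
            element=spec["element"],
            scale=Scale(spec["scale"]),
            is_phenice=bool(spec.get("phenice", False)),
            special_presence_map=bool(spec.get("presence_map", False)),
        )
    return catalog
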