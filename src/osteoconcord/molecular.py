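"""Molecular sex estimation from X/Y chromosome read counts.

Shotgun-sequenced ancient-DNA libraries carry a sex signal in the ratio of
reads aligning to the Y chromosome over all reads aligning to X or Y:

    Ry = n_Y / (n_X + n_Y)

Females (XX) contribute essentially no Y reads beyond mismapping noise, so
Ry sits near zero; males (XY) have one Y per two X copies and in practice
show Ry around 0.075 or higher.  Treating n_Y as binomial in n_X + n_Y
gives a standard error sqrt(Ry(1-Ry)/n) and a 95% confidence interval of
+/- 1.96*SE, and the interval's position relative to a female threshold
(0.016) and a male threshold (0.075) yields a five-way call: a confident
XX or XY, a "consistent with" call when the interval excludes one karyotype
but not the other, or Not Assigned when too few reads are available.
"""

from __future__ import annotations

import enum
import logging
import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: Ry upper bound for a confident XX call.
DEFAULT_LOWER_THRESHOLD = 0.016
#: Ry lower bound for a confident XY call.
DEFAULT_UPPER_THRESHOLD = 0.075
#: Minimum mapping quality for a read to be counted from alignments.
DEFAULT_MIN_MAPQ = 30

Z_95 = 1.96


class GeneticSexCall(str, enum.Enum):
    """Five-way molecular sex assignment."""

    XX = "XX"
    XY = "XY"
    CONSISTENT_XX_NOT_XY = "consistent with XX but not XY"
    CONSISTENT_XY_NOT_XX = "consistent with XY but not XX"
    NOT_ASSIGNED = "Not Assigned"

    @property
    def binary(self) -> str | None:
        """Collapse to 'F'/'M' for concordance analysis; None if uncalled."""
        if self in (GeneticSexCall.XX, GeneticSexCall.CONSISTENT_XX_NOT_XY):
            return "F"
        if self in (GeneticSexCall.XY, GeneticSexCall.CONSISTENT_XY_NOT_XX):
            return "M"
        return None


@dataclass(frozen=True)
class XYCounts:
    """Read counts on the two sex chromosomes for one sample."""

    n_x: int
    n_y: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.n_x < 0 or self.n_y < 0:
            raise ValueError("read counts must be non-negative")
        if self.n_x != int(self.n_x) or self.n_y != int(self.n_y):
            raise ValueError("read counts must be integers")

    @property
    def n_total(self) -> int:
        return self.n_x + self.n_y


@dataclass(frozen=True)
class RyEstimate:
    """Ry with its binomial standard error and 95% CI half-width."""

    ry: float
    se: float
    ci_half_width: float
    n_total: int


def _normalize_chrom(name: str) -> str:
    """Canonical form of a chromosome label: lowercase, 'chr' prefix removed."""
    name = str(name).strip().lower()
    if name.startswith("chr"):
        name = name[3:]
    return name


def compute_ry(counts: XYCounts) -> RyEstimate:
    """Ry = n_y/(n_x+n_y) with binomial SE and 1.96*SE half-width.

    Raises ``ValueError`` on zero informative reads; the caller should
    report such samples as Not Assigned.
    """
    n = counts.n_total
    if n == 0:
        raise ValueError(
            f"no informative reads for sample {counts.sample_id!r}: "
            "zero reads on both sex chromosomes"
        )
    ry = counts.n_y / n
    se = math.sqrt(ry * (1.0 - ry) / n)
    return RyEstimate(ry=ry, se=se, ci_half_width=Z_95 * se, n_total=n)


def assign_genetic_sex(
    est: RyEstimate,
    lower_threshold: float = DEFAULT_LOWER_THRESHOLD,
    upper_threshold: float = DEFAULT_UPPER_THRESHOLD,
) -> GeneticSexCall:
    """Five-way call from the Ry confidence interval.

    Rules, in precedence order (all inequalities strict):

    * XX when ry + CI < lower_threshold
    * XY when ry - CI > upper_threshold
    * consistent with XX but not XY when ry - CI < lower and ry + CI < upper
    * consistent with XY but not XX when ry - CI > lower and ry + CI > upper
    * otherwise Not Assigned
    """
    if not 0 < lower_threshold < upper_threshold < 1:
        raise ValueError("thresholds must satisfy 0 < lower < upper < 1")
    lo = est.ry - est.ci_half_width
    hi = est.ry + est.ci_half_width
    if hi < lower_threshold:
        return GeneticSexCall.XX
    if lo > upper_threshold:
        return GeneticSexCall.XY
    if lo < lower_threshold and hi < upper_threshold:
        return GeneticSexCall.CONSISTENT_XX_NOT_XY
    if lo > lower_threshold and hi > upper_threshold:
        return GeneticSexCall.CONSISTENT_XY_NOT_XX
    return GeneticSexCall.NOT_ASSIGNED


def call_sample(
    counts: XYCounts,
    lower_threshold: float = DEFAULT_LOWER_THRESHOLD,
    upper_threshold: float = DEFAULT_UPPER_THRESHOLD,
) -> tuple[RyEstimate | None, GeneticSexCall]:
    """Estimate Ry and call one sample; zero reads yield Not Assigned."""
    if counts.n_total == 0:
        logger.warning(
            "sample %s has no reads on the sex chromosomes; Not Assigned",
            counts.sample_id or "<unnamed>",
        )
        return None, GeneticSexCall.NOT_ASSIGNED
    est = compute_ry(counts)
    return est, assign_genetic_sex(est, lower_threshold, upper_threshold)


def count_xy_reads(
    records: Union[str, os.PathLike, Mapping[str, int], pd.DataFrame],
    *,
    mapq_min: int = DEFAULT_MIN_MAPQ,
    x_name: str = "chrX",
    y_name: str = "chrY",
    sample_id: str = "",
) -> XYCounts:
    """Count X- and Y-mapped reads from a count table or SAM alignments.

    ``records`` may be a mapping of chromosome name to read count, a
    one-row DataFrame with chromosome columns, or a path to a SAM text
    file.  For SAM input only primary, mapped records with mapping quality
    >= ``mapq_min`` are counted.  Chromosome labels are matched after
    normalization, so "X" and "chrX" dialects are interchangeable.
    """
    if isinstance(records, (str, os.PathLike)):
        return _count_from_sam(
            records, mapq_min=mapq_min, x_name=x_name, y_name=y_name,
            sample_id=sample_id,
        )
    if isinstance(records, pd.DataFrame):
        if len(records) != 1:
            raise ValueError("count table must contain exactly one sample row")
        records = records.iloc[0].to_dict()
    return _count_from_table(records, x_name=x_name, y_name=y_name,
                             sample_id=sample_id)


def _count_from_table(
    table: Mapping[str, int], *, x_name: str, y_name: str, sample_id: str
) -> XYCounts:
    by_norm = {_normalize_chrom(k): v for k, v in table.items()
               if _normalize_chrom(k) not in ("sample_id", "sample")}
    nx_key, ny_key = _normalize_chrom(x_name), _normalize_chrom(y_name)
    for label, key in ((x_name, nx_key), (y_name, ny_key)):
        if key not in by_norm:
            raise KeyError(f"unknown chromosome label {label!r} in count table")
    n_x, n_y = int(by_norm[nx_key]), int(by_norm[ny_key])
    if n_x == 0 and n_y == 0:
        raise ValueError(f"no informative reads for sample {sample_id!r}")
    return XYCounts(n_x=n_x, n_y=n_y, sample_id=sample_id)


def _count_from_sam(
    path: str | os.PathLike, *, mapq_min: int, x_name: str, y_name: str,
    sample_id: str,
) -> XYCounts:
    import pysam

    nx_key, ny_key = _normalize_chrom(x_name), _normalize_chrom(y_name)
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        refs = {_normalize_chrom(r) for r in (sam.references or ())}
        for label, key in ((x_name, nx_key), (y_name, ny_key)):
            if refs and key not in refs:
                raise KeyError(
                    f"unknown chromosome label {label!r}: not in SAM header"
                )
        n_x = n_y = n_records = 0
        for rec in sam.fetch(until_eof=True):
            n_records += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            ref = _normalize_chrom(rec.reference_name)
            if ref == nx_key:
                n_x += 1
            elif ref == ny_key:
                n_y += 1
    if n_records == 0:
        raise ValueError("empty SAM input: no alignment records")
    if n_x == 0 and n_y == 0:
        raise ValueError(f"no informative reads for sample {sample_id!r}")
    return XYCounts(n_x=n_x, n_y=n_y, sample_id=sample_id)


def call_counts_table(
    table: pd.DataFrame,
    *,
    lower_threshold: float = DEFAULT_LOWER_THRESHOLD,
    upper_threshold: float = DEFAULT_UPPER_THRESHOLD,
    x_col: str = "chrX",
    y_col: str = "chrY",
) -> pd.DataFrame:
    """Call every sample in a per-sample chromosome count table.

    Expects columns ``sample_id``, ``x_col``, ``y_col`` (chromosome-name
    dialects accepted).  Returns a frame with columns ``sample_id, n_x,
    n_y, ry, se, ci, call``; samples without informative reads appear as
    Not Assigned with empty statistics rather than being dropped.
    """
    cols = {_normalize_chrom(c): c for c in table.columns}
    try:
        xc, yc = cols[_normalize_chrom(x_col)], cols[_normalize_chrom(y_col)]
    except KeyError as exc:
        raise KeyError(f"unknown chromosome column {exc.args[0]!r}") from None
    if "sample_id" not in table.columns:
        raise KeyError("count table must have a 'sample_id' column")
    if table.empty:
        raise ValueError("empty count table")

    rows = []
    for _, row in table.iterrows():
        counts = XYCounts(n_x=int(row[xc]), n_y=int(row[yc]),
                          sample_id=str(row["sample_id"]))
        est, call = call_sample(counts, lower_threshold, upper_threshold)
        rows.append({
            "sample_id": counts.sample_id,
            "n_x": counts.n_x,
            "n_y": counts.n_y,
            "ry": est.ry if est else float("nan"),
            "se": est.se if est else float("nan"),
            "ci": est.ci_half_width if est else float("nan"),
            "call": call.value,
        })
    return pd.DataFrame(rows)


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV count table with header ``sample_id <TAB> chrX <TAB> chrY``."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty count table: {path}")
    return df


def iter_calls(
    counts: Iterable[XYCounts],
    lower_threshold: float = DEFAULT_LOWER_THRESHOLD,
    upper_threshold: float = DEFAULT_UPPER_THRESHOLD,
) -> Iterable[tuple[XYCounts, RyEstimate | None, GeneticSexCall]]:
    for c in counts:
        est, call = call_sample(c, lower_threshold, upper_threshold)
        yield c, est, call
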