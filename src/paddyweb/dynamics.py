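"""Expression-dynamics summaries of read pools and qPCR copy numbers.

Two temporal summaries of community activity:

* proportions of read pools — e.g. bacterial or archaeal mRNA as a
  percentage of total RNA reads, or CAZyme transcripts as a percentage
  of total mRNA — averaged over biological replicates per sampling day;
* the mcrA transcript-to-gene copy ratio (RT-qPCR over qPCR), a proxy
  for the per-cell expression level of the methanogenesis marker gene.

Proportions are computed per sample first and then averaged (replicates
are biological, not technical); SE is the sample standard deviation
(n-1 denominator) divided by sqrt(n).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from paddyweb.errors import ValidationError

logger = logging.getLogger(__name__)

_META_COLS = ["day", "temperature_C"]


def _se(x: pd.Series) -> float:
    return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0


def _summarise(per_sample: pd.DataFrame, value_col: str) -> pd.DataFrame:
    ok = per_sample.dropna(subset=[value_col])
    out = (
        ok.groupby(_META_COLS, sort=True)[value_col]
        .agg(mean="mean", se=_se, n="size")
        .reset_index()
    )
    return out


def group_proportion_series(
    pools: pd.DataFrame, numerator: str, denominator: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of one read pool within another, per day.

    ``pools`` is a tidy table with one row per sample: columns
    ``sample``, ``day``, ``temperature_C``, ``replicate`` plus one count
    column per pool (e.g. ``total_RNA``, ``bacterial_mRNA``).  Returns
    ``(per_sample, summary)``: the per-sample percentages and the
    replicate mean +/- SE per (day, temperature).  Samples with a zero
    denominator yield a missing value and are excluded from the mean.
    """
    for col in (numerator, denominator, *_META_COLS, "replicate"):
        if col not in pools.columns:
            raise ValidationError(f"read-pool table lacks column {col!r}")
    if (pools[[numerator, denominator]].values < 0).any():
        raise ValidationError("read counts must be non-negative")
    if (pools[numerator] > pools[denominator]).any():
        raise ValidationError(f"{numerator!r} exceeds {denominator!r} in some sample")

    per_sample = pools[[*_META_COLS, "replicate", numerator, denominator]].copy()
    zero = per_sample[denominator] == 0
    if zero.any():
        logger.warning("%d samples with zero %s excluded from means", int(zero.sum()), denominator)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * per_sample[numerator] / per_sample[denominator]
    per_sample["percent"] = pct.where(~zero)
    return per_sample, _summarise(per_sample, "percent")


def transcript_gene_ratio(qpcr: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """mcrA transcript/gene copy ratio per sample and per-day mean +/- SE.

    ``qpcr`` columns: ``day``, ``temperature_C``, ``replicate``,
    ``gene_copies``, ``transcript_copies`` (copies per g dry soil).
    Samples with zero gene copies yield a missing ratio (logged).
    """
    for col in (*_META_COLS, "replicate", "gene_copies", "transcript_copies"):
        if col not in qpcr.columns:
            raise ValidationError(f"qPCR table lacks column {col!r}")
    if (qpcr[["gene_copies", "transcript_copies"]].values < 0).any():
        raise ValidationError("copy numbers must be non-negative")
    per_sample = qpcr[[*_META_COLS, "replicate", "gene_copies", "transcript_copies"]].copy()
    zero = per_sample["gene_copies"] == 0
    if zero.any():
        logger.warning("%d samples with zero gene copies excluded", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = per_sample["transcript_copies"] / per_sample["gene_copies"]
    per_sample["ratio"] = ratio.where(~zero)
    return per_sample, _summarise(per_sample, "ratio")


def functional_subset_composition(
    subset_counts: pd.DataFrame,
    lineage: dict[str, str],
    rank: str = "phylum",
    min_fraction: float = 0.005,
) -> pd.DataFrame:
    """Taxonomic composition of a functional transcript pool per day.

    ``subset_counts``: tidy table with columns ``taxon``, ``day``,
    ``count`` (counts of e.g. GH/CBM transcripts assigned to each
    taxon, pooled over replicates or per sample).  Groups are formed at
    ``rank`` ("phylum" or "family") from the lineage map; groups whose
    overall share of the pool is below ``min_fraction`` are pooled into
    "other".  Per-day fractions sum to 1.
    """
    from paddyweb.conet import LINEAGE_RANKS

    if rank not in ("phylum", "family"):
        raise ValidationError(f"rank must be 'phylum' or 'family', got {rank!r}")
    for col in ("taxon", "day", "count"):
        if col not in subset_counts.columns:
            raise ValidationError(f"subset table lacks column {col!r}")
    if subset_counts["count"].sum() <= 0:
        raise ValidationError("functional subset is empty")
    depth = LINEAGE_RANKS.index(rank) + 1

    def group_of(taxon: str) -> str:
        fields = [f.strip() for f in lineage.get(taxon, "").split(";")]
        if len(fields) >= depth and fields[depth - 1]:
            return fields[depth - 1]
        return "unclassified"

    df = subset_counts.copy()
    df["group"] = df["taxon"].map(group_of)
    pooled = df.groupby(["group", "day"], sort=True)["count"].sum().reset_index()
    overall = pooled.groupby("group")["count"].sum()
    overall_frac = overall / overall.sum()
    minor = set(overall_frac.index[overall_frac < min_fraction])
    if minor:
        pooled["group"] = pooled["group"].where(~pooled["group"].isin(minor), "other")
        pooled = pooled.groupby(["group", "day"], sort=True)["count"].sum().reset_index()
    day_totals = pooled.groupby("day")["count"].transform("sum")
    pooled["fraction"] = pooled["count"] / day_totals
    return pooled
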