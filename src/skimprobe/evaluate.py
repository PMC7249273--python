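"""Capture-success statistics for a probe panel.

Given capture reads (or pre-assembled contigs) per sample, this module
recomputes the standard target-enrichment report: per-template recovery
(with the HybPiper-style default identity threshold), templates recovered
at >=50% of reference length, potential-paralog flags (multiple long
contigs for one locus), percent on-target reads, per-locus rollups that
combine the success of a locus's multiple templates, per-clade summaries
(mean and min-max of each statistic), and alignment variation statistics
(parsimony-informative sites, constant sites, missing data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import edlib
import numpy as np
import pandas as pd

from .tier2 import Contig, Scoring, DEFAULT_SCORING, overlap_align, \
    percent_identity_gapped

logger = logging.getLogger("skimprobe")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding, matching how report tables print."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CaptureStats:
    """Per-sample, per-template recovery record."""

    sample_id: str
    template_id: str
    recovered_len: int
    reference_len: int
    identity_pct: float
    recovered: bool
    at_50pct: bool
    paralog_flag: bool = False

    def __post_init__(self) -> None:
        if self.recovered_len < 0:
            raise ValueError("negative recovered length")
        if self.at_50pct and not self.recovered:
            raise ValueError("at_50pct implies recovered")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct outside [0,100]")


@dataclass
class RecoveredSequence:
    seq: str
    recovered_len: int
    identity_pct: float
    overlap_identity: float
    template_interval: tuple[int, int]


def _infix_identity(template_seq: str, contig_seq: str):
    """Whole-contig identity to the template under infix (edit-distance)
    alignment: the shorter sequence must be accounted for end to end, so
    an unrelated contig cannot shrink its aligned region down to a lucky
    perfect island. Returns (identity, template span, template interval).
    """
    if len(contig_seq) <= len(template_seq):
        res = edlib.align(contig_seq, template_seq, mode="HW", task="locations")
        loc_s, loc_e = res["locations"][0]
        span = loc_e - loc_s + 1
        identity = 1.0 - res["editDistance"] / max(len(contig_seq), span)
        return identity, span, (loc_s, loc_e + 1)
    res = edlib.align(template_seq, contig_seq, mode="HW")
    identity = 1.0 - res["editDistance"] / len(template_seq)
    return identity, len(template_seq), (0, len(template_seq))


def recovered_sequence(
    template_seq: str,
    contigs: list[Contig],
    min_identity: float = 0.55,
    min_cov_fraction: float = 0.0,
    scores: Scoring = DEFAULT_SCORING,
) -> RecoveredSequence | None:
    """Best recovered sequence for one template, or None.

    Each contig is scored by whole-contig infix identity to the template
    (the default 55% floor with no length requirement follows the
    per-gene extraction convention of target-capture assemblers). The
    best passing contig — most matching columns — is reported.
    ``recovered_len`` is the template span of the match; ``identity_pct``
    is the gapped identity over ALL columns of a free-end-gap alignment,
    so trailing ends count against partial contigs.
    """
    best = None
    for contig in contigs:
        identity, span, t_iv = _infix_identity(template_seq, contig.seq)
        if identity < min_identity or span == 0:
            continue
        if span < min_cov_fraction * len(template_seq):
            continue
        quality = identity * span  # ~ matching columns
        if best is None or quality > best[0]:
            best = (quality, contig, identity, span, t_iv)
    if best is None:
        return None
    _, contig, identity, span, t_iv = best
    row_t, row_c = overlap_align(template_seq, contig.seq, scores)
    return RecoveredSequence(
        seq=contig.seq,
        recovered_len=span,
        identity_pct=percent_identity_gapped(row_t, row_c),
        overlap_identity=identity,
        template_interval=t_iv,
    )


def count_templates_at_50pct(stats: list[CaptureStats]) -> int:
    """Templates whose recovered length reaches half the reference length
    (inclusive) in one sample."""
    return sum(1 for s in stats if s.recovered
               and s.recovered_len >= 0.5 * s.reference_len)


def flag_paralogs(template_seq: str, contigs: list[Contig],
                  long_fraction: float = 0.85,
                  scores: Scoring = DEFAULT_SCORING) -> bool:
    """True iff >=2 distinct contigs each span >= ``long_fraction`` of the
    template: multiple long assemblies for one locus suggest a gene
    duplication rather than a single-copy target."""
    long_seqs = set()
    for contig in contigs:
        identity, span, _ = _infix_identity(template_seq, contig.seq)
        if identity >= 0.5 and span >= long_fraction * len(template_seq):
            long_seqs.add(contig.seq)
        if len(long_seqs) >= 2:
            return True
    return False


def on_target_fraction(n_placed: int, total_reads: int) -> float | None:
    """Percent of reads placed on any template; None when no reads."""
    if total_reads < n_placed:
        raise ValueError("placed reads exceed total reads")
    if total_reads == 0:
        logger.warning("on-target fraction undefined: zero total reads")
        return None
    return 100.0 * n_placed / total_reads


def locus_rollup(template_stats: pd.DataFrame,
                 template_locus: dict[str, str]) -> pd.DataFrame:
    """Combine per-template stats into per-locus stats.

    A locus is recovered in a sample iff ANY of its templates is; the
    locus recovered length is the max over templates; per-locus taxon
    counts are unions of per-template sample sets. Input needs columns
    sample_id, template_id, recovered, recovered_len.
    """
    df = template_stats.copy()
    df["locus_id"] = df["template_id"].map(template_locus)
    if df["locus_id"].isna().any():
        missing = df.loc[df["locus_id"].isna(), "template_id"].unique()
        raise ValueError(f"templates with no locus mapping: {list(missing)[:5]}")
    per = (
        df.groupby(["sample_id", "locus_id"], sort=True)
        .agg(recovered=("recovered", "any"),
             recovered_len=("recovered_len", "max"))
        .reset_index()
    )
    return per


def locus_taxon_counts(locus_rollup_df: pd.DataFrame) -> pd.Series:
    rec = locus_rollup_df[locus_rollup_df["recovered"]]
    return rec.groupby("locus_id")["sample_id"].nunique()


@dataclass
class CladeSummary:
    clade: str
    table: pd.DataFrame  # columns: statistic, mean, min, max


def clade_summary(sample_stats: pd.DataFrame, clade: str) -> CladeSummary:
    """Mean and (min-max) of each per-sample statistic over one clade.

    ``sample_stats`` has one row per sample; every numeric column is
    summarized. Supercontig length, where present, is exon + intron
    length per locus before summarizing (the caller provides it as a
    column built that way).
    """
    if sample_stats.empty:
        raise ValueError("clade_summary requires at least one sample")
    rows = []
    for col in sample_stats.columns:
        if col in ("sample_id", "clade"):
            continue
        vals = pd.to_numeric(sample_stats[col], errors="coerce").dropna()
        if vals.empty:
            continue
        rows.append({"statistic": col, "mean": float(vals.mean()),
                     "min": float(vals.min()), "max": float(vals.max())})
    table = pd.DataFrame(rows)
    bad = table[(table["min"] > table["mean"]) | (table["mean"] > table["max"])]
    assert bad.empty, "min <= mean <= max must hold per statistic"
    return CladeSummary(clade, table)


@dataclass
class VariationStats:
    """Alignment variation statistics over a set of locus alignments."""

    n_loci: int
    alignment_length: int
    pis_count: int
    constant_sites: int
    missing_pct: float

    def __post_init__(self) -> None:
        if self.pis_count + self.constant_sites > self.alignment_length:
            raise ValueError("site counts exceed alignment length")

    @property
    def pis_pct(self) -> float:
        return round_half_up(100.0 * self.pis_count / self.alignment_length, 1)


_MISSING = {"N", "-"}


def alignment_variation_stats(alignments: list[list[str]],
                              partition: str = "supercontigs") -> VariationStats:
    """Parsimony-informative/constant/missing statistics over concatenated
    locus alignments.

    A column is parsimony-informative iff at least two distinct
    non-missing states each occur in at least two sequences; constant iff
    exactly one distinct non-missing state occurs. 'N' and '-' are
    missing data. Percentages are reported half-up to one decimal.
    """
    if not alignments or all(not rows or not rows[0] for rows in alignments):
        raise ValueError("alignment_variation_stats requires nonzero columns")
    total_cols = 0
    pis = constant = 0
    missing_cells = 0
    total_cells = 0
    for rows in alignments:
        if not rows:
            continue
        if len({len(r) for r in rows}) != 1:
            raise ValueError("rows within one alignment must have equal length")
        arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)
        n_cols = arr.shape[1]
        total_cols += n_cols
        total_cells += arr.size
        miss = (arr == b"N") | (arr == b"-")
        missing_cells += int(miss.sum())
        for c in range(n_cols):
            col = arr[~miss[:, c], c]
            if col.size == 0:
                continue
            states, counts = np.unique(col, return_counts=True)
            if len(states) == 1:
                constant += 1
            elif (counts >= 2).sum() >= 2:
                pis += 1
    if total_cols == 0:
        raise ValueError("alignment_variation_stats requires nonzero columns")
    logger.info("variation stats (%s): %d loci, %d columns, %d PIS, %d constant",
                partition, len(alignments), total_cols, pis, constant)
    return VariationStats(
        n_loci=len(alignments),
        alignment_length=total_cols,
        pis_count=pis,
        constant_sites=constant,
        missing_pct=round_half_up(100.0 * missing_cells / total_cells, 1),
    )
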