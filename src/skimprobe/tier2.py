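"""Tier 2: recover per-locus contigs from genome-skim reads and select
probe-design templates.

Genome skims sequence the whole genome shallowly, so low-copy nuclear loci
are recovered only fragmentarily. This module maps skim reads onto the
Tier-1 reference sequences (exact k-mer seeding + edit-distance extension,
a deterministic desk-scale stand-in for BWA), calls a reference-guided
majority consensus, aligns the resulting contigs back to the reference
(reference-anchored star alignment standing in for MAFFT), and selects
one to four template sequences per locus: divergent sequences (<90%
gapped identity) are kept as separate templates so that probes tiled from
them can capture both study clades, short partial contigs are completed
into hybrid sequences on the reference backbone, and templates matching
organellar genomes are screened out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align

from .core_io import (
    ConsistencyError,
    FastqRead,
    SequenceRecord,
    reverse_complement,
)

logger = logging.getLogger("skimprobe")

# ---------------------------------------------------------------------------
# Pairwise alignment engine (shared with Tier 1's reciprocal-best-hit step)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring. ``open_gap`` is the score of the first gap
    position in a run, ``extend_gap`` of each subsequent one."""

    match: float = 2.0
    mismatch: float = -3.0
    open_gap: float = -8.0
    extend_gap: float = -2.0


DEFAULT_SCORING = Scoring()

#: Default alignment-score floor: the score of a perfect 60-bp match.
#: Acts like a BLAST e-value cutoff at desk scale.
DEFAULT_MIN_SCORE = 60 * DEFAULT_SCORING.match


def _make_aligner(scores: Scoring, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scores.match
    aligner.mismatch_score = scores.mismatch
    aligner.open_gap_score = scores.open_gap
    aligner.extend_gap_score = scores.extend_gap
    return aligner


def align_pair(a: str, b: str, scores: Scoring = DEFAULT_SCORING) -> tuple[str, str, float]:
    """Optimal global alignment with affine gaps.

    Returns the two equal-length gapped rows and the optimal score. Among
    co-optimal alignments the first in Biopython's deterministic
    enumeration order is returned.
    """
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    aligner = _make_aligner(scores, "global")
    aln = aligner.align(a, b)[0]
    rowa, rowb = str(aln[0]), str(aln[1])
    return rowa, rowb, aln.score


@dataclass
class LocalHit:
    """One local alignment: score, identity over aligned columns, spans."""

    score: float
    matches: int
    aligned_cols: int
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_cols if self.aligned_cols else 0.0


def _shares_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return a in b or b in a
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def local_score(a: str, b: str, scores: Scoring = DEFAULT_SCORING,
                prescreen_k: int = 12) -> float:
    """Optimal local (Smith-Waterman) alignment score.

    Sequence pairs sharing no exact ``prescreen_k``-mer are scored 0
    without running the quadratic DP; any pair clearing a realistic
    score floor shares many exact words.
    """
    if not a or not b:
        raise ValueError("local_score requires non-empty sequences")
    if prescreen_k and not _shares_kmer(a, b, prescreen_k):
        return 0.0
    return _make_aligner(scores, "local").score(a, b)


def local_align(a: str, b: str, scores: Scoring = DEFAULT_SCORING) -> LocalHit:
    aln = _make_aligner(scores, "local").align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    block_cols = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        block_cols += ae - as_
        matches += sum(1 for x, y in zip(a[as_:ae], b[bs:be]) if x == y)
    a_start, a_end = (blocks_a[0][0], blocks_a[-1][1]) if len(blocks_a) else (0, 0)
    b_start, b_end = (blocks_b[0][0], blocks_b[-1][1]) if len(blocks_b) else (0, 0)
    gap_cols = (a_end - a_start - block_cols) + (b_end - b_start - block_cols)
    return LocalHit(aln.score, matches, block_cols + gap_cols,
                    (a_start, a_end), (b_start, b_end))


def percent_identity_gapped(row_a: str, row_b: str) -> float:
    """Percent identity over ALL alignment columns, gaps and trailing ends
    included: 100 x (columns with equal non-gap characters) / (total
    columns). A contig covering half its reference therefore scores at
    most 50 even if the overlap is perfect.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal (aligned) length")
    if not row_a:
        raise ValueError("zero-length alignment")
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x != "-" and y != "-"
    )
    return 100.0 * matches / len(row_a)


def overlap_align(a: str, b: str, scores: Scoring) -> tuple[str, str]:
    """Pairwise alignment with free end gaps (overlap/fragment mode), the
    right convention for placing a partial contig on a full reference:
    uncovered reference ends stay as clean terminal gap runs instead of
    the fragment's edges scattering onto coincidental distant matches."""
    aligner = _make_aligner(scores, "global")
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def star_align(seqs: dict[str, str], ref_id: str,
               scores: Scoring = DEFAULT_SCORING) -> dict[str, str]:
    """Reference-anchored star alignment.

    Every sequence is aligned to the reference pairwise (affine gaps,
    free end gaps); the pairwise alignments are then projected into
    common columns (maximum insertion length per reference slot).
    Reference ungapped columns are preserved in order.
    """
    if ref_id not in seqs:
        raise ConsistencyError(f"reference row {ref_id!r} missing from input")
    ref = seqs[ref_id]
    L = len(ref)
    others = [sid for sid in seqs if sid != ref_id]
    # Per sequence: insertion strings at each of L+1 slots plus the
    # character aligned to each reference position.
    per_seq: dict[str, tuple[list[str], list[str]]] = {}
    ins_max = [0] * (L + 1)
    for sid in others:
        row_r, row_s = overlap_align(ref, seqs[sid], scores)
        inserts = [""] * (L + 1)
        chars = ["-"] * L
        p = 0
        for cr, cs in zip(row_r, row_s):
            if cr == "-":
                inserts[p] += cs
            else:
                chars[p] = cs
                p += 1
        per_seq[sid] = (inserts, chars)
        for i, s in enumerate(inserts):
            ins_max[i] = max(ins_max[i], len(s))

    def build(inserts: list[str], chars: list[str]) -> str:
        out = []
        for p in range(L + 1):
            out.append(inserts[p].ljust(ins_max[p], "-"))
            if p < L:
                out.append(chars[p])
        return "".join(out)

    result = {ref_id: build([""] * (L + 1), list(ref))}
    for sid in others:
        result[sid] = build(*per_seq[sid])
    return result


# ---------------------------------------------------------------------------
# Read mapping: exact k-mer seeding + edit-distance extension
# ---------------------------------------------------------------------------


class KmerIndex:
    """Exact k-mer index over a reference set (forward strand stored;
    minus-strand queries resolved through reverse complements)."""

    def __init__(self, refs: dict[str, str], k: int = 21) -> None:
        if k < 11:
            raise ValueError("k must be >= 11")
        if not refs:
            raise ValueError("no reference sequences to index")
        self.k = k
        self.refs: dict[str, str] = {}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in refs.items():
            if len(seq) < k:
                logger.warning("reference %s shorter than k=%d; skipped", rid, k)
                continue
            self.refs[rid] = seq
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((rid, i))

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """Positions of ``kmer`` on either strand of the references."""
        hits = [(rid, pos, "+") for rid, pos in self._index.get(kmer, ())]
        hits += [(rid, pos, "-")
                 for rid, pos in self._index.get(reverse_complement(kmer), ())]
        return hits


@dataclass
class ReadPlacement:
    """Best placement of one read on a reference (0-based, clipped to the
    reference; overhanging bases are carried as flank attachments)."""

    read_id: str
    ref_id: str
    ref_start: int
    strand: str
    aligned_len: int
    identity_fraction: float
    cigar: str = ""
    read_seq: str = ""          # oriented, in-reference portion
    left_flank: str = ""        # read bases overhanging before ref_start
    right_flank: str = ""       # read bases overhanging past the alignment end

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise ConsistencyError(f"read {self.read_id}: negative ref_start")
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ConsistencyError(f"read {self.read_id}: identity outside [0,1]")


@dataclass
class MappingResult:
    placements: list[ReadPlacement]
    n_unplaced: int
    n_ties: int


_DIAG_TOL = 12  # diagonal grouping tolerance (absorbs small indels)


def _candidate_regions(oriented: str, index: KmerIndex, max_candidates: int = 3):
    """Vote exact k-mer seeds onto (ref, diagonal) bands; return the
    top-voted bands as (ref_id, approx_start, votes)."""
    k = index.k
    votes: dict[tuple[str, int], int] = {}
    idx = index._index
    for i in range(0, len(oriented) - k + 1):
        for rid, pos in idx.get(oriented[i:i + k], ()):
            band = (rid, (pos - i) // _DIAG_TOL)
            votes[band] = votes.get(band, 0) + 1
    if not votes:
        return []
    # pool adjacent bands so an indel straddling a band edge still votes together
    pooled = {
        (rid, band): v + votes.get((rid, band + 1), 0)
        for (rid, band), v in votes.items()
    }
    ranked = sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    seen: set[tuple[str, int]] = set()
    for (rid, band), v in ranked:
        if any((rid, b) in seen for b in (band - 1, band, band + 1)):
            continue
        seen.add((rid, band))
        out.append((rid, band * _DIAG_TOL, v))
        if len(out) >= max_candidates:
            break
    return out


def _extend_once(oriented: str, ref: str, diag: int, flank_bp: int,
                 pad: int | None = None):
    """Edit-distance extension of a seeded candidate. Returns
    (identity, ref_start, ref_end, cigar, in_ref_read, left_flank, right_flank)
    or None when the in-reference overlap is too small."""
    L, Lr = len(ref), len(oriented)
    clip_left = max(0, -diag)
    clip_right = max(0, diag + Lr - L)
    read_part = oriented[clip_left:Lr - clip_right]
    if len(read_part) < 30:
        return None
    if pad is None:
        pad = 16 + len(read_part) // 20
    w_start = max(0, diag + clip_left - pad)
    w_end = min(L, diag + clip_left + len(read_part) + pad)
    res = edlib.align(read_part, ref[w_start:w_end], mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc_s, loc_e = res["locations"][0]
    ref_start, ref_end = w_start + loc_s, w_start + loc_e + 1
    span = max(len(read_part), ref_end - ref_start)
    identity = 1.0 - res["editDistance"] / span
    left = oriented[:clip_left][-flank_bp:] if clip_left else ""
    right = oriented[Lr - clip_right:][:flank_bp] if clip_right else ""
    return identity, ref_start, ref_end, res["cigar"], read_part, left, right


def _extend_candidate(oriented: str, ref: str, diag: int, flank_bp: int,
                      min_identity: float = 0.0):
    """Extension with a soft-clip fallback: when the whole read fails the
    identity floor (e.g. it spans an insertion relative to the reference,
    such as an intron absent from an exonic target), each read half is
    tried on its own and the better clipped alignment is used."""
    full = _extend_once(oriented, ref, diag, flank_bp)
    if full is not None and full[0] >= min_identity:
        return full
    mid = len(oriented) // 2
    candidates = [full] if full is not None else []
    if mid >= 40:
        # wider window: the unclipped half may sit up to an intron-length
        # away from the seeded diagonal
        half_a = _extend_once(oriented[:mid], ref, diag, 0, pad=120)
        half_b = _extend_once(oriented[mid:], ref, diag + mid, 0, pad=120)
        candidates += [h for h in (half_a, half_b) if h is not None]
    if not candidates:
        return None
    return max(candidates,
               key=lambda c: (c[0] >= min_identity, c[0] * len(c[4])))


def map_reads(reads: list[FastqRead], index: KmerIndex,
              min_identity: float = 0.80, flank_bp: int = 200) -> MappingResult:
    """Place each read at its best seed-supported location.

    At most one placement per read is emitted (best extension identity);
    exact identity ties between distinct locations drop the read. Reads
    whose best extension falls below ``min_identity`` are unplaced.
    """
    placements: list[ReadPlacement] = []
    n_unplaced = n_ties = 0
    for read in reads:
        best = None
        best_key = None
        tie = False
        for strand in ("+", "-"):
            oriented = read.seq if strand == "+" else reverse_complement(read.seq)
            for rid, diag, _votes in _candidate_regions(oriented, index):
                ext = _extend_candidate(oriented, index.refs[rid], diag,
                                        flank_bp, min_identity)
                if ext is None:
                    continue
                identity, ref_start, ref_end, cigar, read_part, lf, rf = ext
                key = (identity,)
                if best is None or identity > best[0]:
                    best = (identity, rid, ref_start, ref_end, strand, cigar,
                            read_part, lf, rf)
                    best_key = (rid, ref_start, strand)
                    tie = False
                elif identity == best[0] and (rid, ref_start, strand) != best_key:
                    tie = True
        if best is None or best[0] < min_identity:
            n_unplaced += 1
            continue
        if tie:
            n_ties += 1
            logger.debug("read %s dropped: tied best placements", read.id)
            continue
        identity, rid, ref_start, ref_end, strand, cigar, read_part, lf, rf = best
        placements.append(ReadPlacement(
            read_id=read.id, ref_id=rid, ref_start=ref_start, strand=strand,
            aligned_len=ref_end - ref_start, identity_fraction=identity,
            cigar=cigar, read_seq=read_part, left_flank=lf, right_flank=rf,
        ))
    return MappingResult(placements, n_unplaced, n_ties)


# ---------------------------------------------------------------------------
# Reference-guided consensus
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    """One consensus contig. ``ref_interval`` is clipped to the reference;
    flank lengths count consensus bases assembled beyond the reference
    ends from overhanging reads."""

    locus_id: str
    skim_taxon: str
    seq: str
    ref_interval: tuple[int, int]
    mean_depth: float
    left_flank: int = 0
    right_flank: int = 0
    contig_id: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ConsistencyError("empty contig sequence")
        if self.ref_interval[0] < 0 or self.ref_interval[1] < self.ref_interval[0]:
            raise ConsistencyError("contig interval outside reference")


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"


def _parse_cigar(cigar: str):
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            yield num, ch
            num = 0


def consensus_contigs(placements: list[ReadPlacement], reference: SequenceRecord,
                      min_depth: int = 2, flank_bp: int = 200,
                      skim_taxon: str = "") -> list[Contig]:
    """Majority-vote consensus over a pileup of placed reads.

    Per position the consensus base is the most frequent base among
    covering reads, ties broken toward the reference base (the
    reference-guided assembly convention; outside the reference, toward
    the alphabetically first base). Maximal runs with depth >=
    ``min_depth`` become contigs; read bases overhanging the reference
    ends extend the pileup by up to ``flank_bp``, which is how flanking
    (e.g. intronic) sequence adjacent to the targeted regions gets
    assembled.
    """
    L = len(reference.seq)
    F = flank_bp
    counts = np.zeros((4, L + 2 * F), dtype=np.int32)

    def add(pos: int, base: str) -> None:
        bi = _BASE_IDX.get(base)
        if bi is not None and 0 <= pos + F < L + 2 * F:
            counts[bi, pos + F] += 1

    for p in placements:
        if p.ref_id != reference.id:
            raise ConsistencyError(
                f"placement of {p.read_id} on {p.ref_id}, expected {reference.id}"
            )
        rpos, qpos = p.ref_start, 0
        if p.cigar:
            for n, op in _parse_cigar(p.cigar):
                if op in ("M", "=", "X"):
                    for j in range(n):
                        add(rpos + j, p.read_seq[qpos + j])
                    rpos += n
                    qpos += n
                elif op == "I":
                    qpos += n
                elif op == "D":
                    rpos += n
        else:
            for j, base in enumerate(p.read_seq):
                add(p.ref_start + j, base)
        for j, base in enumerate(reversed(p.left_flank)):
            add(p.ref_start - 1 - j, base)
        for j, base in enumerate(p.right_flank):
            add(p.ref_start + p.aligned_len + j, base)

    depth = counts.sum(axis=0)
    if not (depth >= min_depth).any():
        return []
    maxc = counts.max(axis=0)
    cons_idx = counts.argmax(axis=0)  # ties -> first row -> alphabetical
    ref_idx = np.full(L + 2 * F, -1, dtype=np.int64)
    for i, base in enumerate(reference.seq):
        bi = _BASE_IDX.get(base)
        if bi is not None:
            ref_idx[i + F] = bi
    in_ref = ref_idx >= 0
    ref_tied = in_ref & (counts[np.maximum(ref_idx, 0), np.arange(L + 2 * F)] == maxc)
    cons_idx = np.where(ref_tied, np.maximum(ref_idx, 0), cons_idx)

    covered = depth >= min_depth
    contigs: list[Contig] = []
    pos = 0
    n = L + 2 * F
    while pos < n:
        if not covered[pos]:
            pos += 1
            continue
        end = pos
        while end < n and covered[end]:
            end += 1
        seq = "".join(_IDX_BASE[cons_idx[i]] for i in range(pos, end))
        start0, end0 = pos - F, end - F
        clip_s, clip_e = max(0, start0), max(0, min(L, end0))
        clip_e = max(clip_e, clip_s)
        contigs.append(Contig(
            locus_id=reference.id, skim_taxon=skim_taxon, seq=seq,
            ref_interval=(clip_s, clip_e),
            mean_depth=float(depth[pos:end].mean()),
            left_flank=clip_s - start0, right_flank=end0 - clip_e,
        ))
        pos = end
    for i, c in enumerate(contigs, 1):
        c.contig_id = f"{skim_taxon}__{reference.id}__c{i}" if skim_taxon else \
            f"{reference.id}__c{i}"
    return contigs


# ---------------------------------------------------------------------------
# Template selection
# ---------------------------------------------------------------------------


@dataclass
class TemplateSequence:
    """One of 1-4 per-locus probe-design templates."""

    template_id: str
    locus_id: str
    seq: str
    source_class: str
    provenance: list[tuple[tuple[int, int], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "-" in self.seq:
            raise ConsistencyError(f"template {self.template_id}: gapped sequence")


SOURCE_CLASSES = ("skim_cladeA", "skim_cladeB", "transcriptome", "universal", "hybrid")


def hybrid_join(contig_seq: str, ref_interval: tuple[int, int],
                backbone: str, locus_id: str, template_id: str,
                contig_origin: str, backbone_origin: str) -> TemplateSequence:
    """Splice a partial contig into a full-length backbone.

    The output replaces backbone positions [start, end) with the contig,
    giving a full-length hybrid sequence whose divergent (clade-specific)
    region comes from the skim contig; provenance records the origin of
    every segment.
    """
    start, end = ref_interval
    if start < 0 or end > len(backbone) or start > end:
        raise ConsistencyError(
            f"hybrid_join: contig interval [{start},{end}) outside backbone "
            f"of length {len(backbone)}"
        )
    seq = backbone[:start] + contig_seq + backbone[end:]
    provenance: list[tuple[tuple[int, int], str]] = []
    if start > 0:
        provenance.append(((0, start), backbone_origin))
    provenance.append(((start, start + len(contig_seq)), contig_origin))
    if end < len(backbone):
        tail_start = start + len(contig_seq)
        provenance.append(((tail_start, tail_start + len(backbone) - end), backbone_origin))
    return TemplateSequence(template_id, locus_id, seq, "hybrid", provenance)


def _ungapped(row: str) -> str:
    return row.replace("-", "")


def stitch_contigs(contigs: list[Contig], backbone: str, row_id: str
                   ) -> tuple[str, list[tuple[tuple[int, int], str]], float]:
    """Splice one skim taxon's (disjoint) contigs into the reference
    backbone, producing that taxon's full-length candidate sequence.

    Returns (sequence, provenance segments, skim fraction): the fraction
    of the result that came from contigs rather than the backbone. Flank
    bases beyond the reference ends are trimmed before splicing.
    """
    ordered = sorted(contigs, key=lambda c: c.ref_interval)
    parts: list[str] = []
    provenance: list[tuple[tuple[int, int], str]] = []
    pos = 0
    out_len = 0
    skim_len = 0
    for c in ordered:
        start, end = c.ref_interval
        if end <= start:  # contig entirely in flank space; nothing to splice
            continue
        if start < pos:
            raise ConsistencyError(
                f"overlapping contigs for {row_id} at reference position {start}")
        if start > pos:
            parts.append(backbone[pos:start])
            provenance.append(((out_len, out_len + start - pos), row_id + "|backbone"))
            out_len += start - pos
        core = c.seq[c.left_flank:len(c.seq) - c.right_flank or None]
        parts.append(core)
        provenance.append(((out_len, out_len + len(core)), c.contig_id))
        out_len += len(core)
        skim_len += len(core)
        pos = end
    if pos < len(backbone):
        parts.append(backbone[pos:])
        provenance.append(((out_len, out_len + len(backbone) - pos),
                           row_id + "|backbone"))
        out_len += len(backbone) - pos
    seq = "".join(parts)
    return seq, provenance, (skim_len / len(seq) if seq else 0.0)


def _row_ref_interval(row: str, ref_row: str) -> tuple[int, int]:
    """Reference interval covered by a gapped row within a star alignment."""
    first = last = None
    for i, ch in enumerate(row):
        if ch != "-":
            if first is None:
                first = i
            last = i
    if first is None:
        return (0, 0)
    start = sum(1 for ch in ref_row[:first] if ch != "-")
    end = sum(1 for ch in ref_row[:last + 1] if ch != "-")
    return (start, end)


def select_templates(
    alignment: dict[str, str],
    ref_id: str,
    locus_id: str,
    source_method: str,
    row_class: dict[str, str] | None = None,
    row_stitch: dict[str, tuple[str, list, float]] | None = None,
    ident_threshold: float = 90.0,
    min_contig: int = 300,
    max_templates: int = 4,
    hybrid_cov_threshold: float = 0.90,
) -> list[TemplateSequence]:
    """Select 1-4 probe-design templates from a locus alignment.

    Rules, in order: a locus identified only through the transcriptome
    screen (source_method ``markerminer``) with no skim contigs at all is
    omitted; if every contig is shorter than ``min_contig`` the reference
    (transcriptome/universal) sequence is the sole template; otherwise
    rows are greedily single-linkage clustered in descending ungapped
    length at ``ident_threshold`` percent gapped identity, one template
    per cluster (longest ungapped member), capped at ``max_templates``
    (shortest representatives dropped, logged). A representative contig
    covering less than ``hybrid_cov_threshold`` of the reference length
    is completed into a hybrid sequence on the reference backbone.

    A row may come with a pre-built full-length completion through
    ``row_stitch`` (see :func:`stitch_contigs`): (stitched sequence,
    provenance, skim fraction). When such a row is selected, the stitched
    sequence becomes the template, classed ``hybrid`` when less than
    ``hybrid_cov_threshold`` of it is skim-derived. Clustering always
    works on the alignment rows themselves, so uncovered reference
    regions (trailing ends, holes) count against identity exactly as the
    gapped-identity definition demands.
    """
    if ref_id not in alignment:
        raise ConsistencyError(f"reference row {ref_id!r} missing from alignment")
    row_class = row_class or {}
    row_stitch = row_stitch or {}
    ref_class = row_class.get(ref_id, "universal" if source_method == "universal"
                              else "transcriptome")
    ref_seq = _ungapped(alignment[ref_id])
    contig_ids = [r for r in alignment if r != ref_id]
    if not contig_ids:
        if source_method == "markerminer":
            logger.info("locus %s omitted: no skim contigs assembled", locus_id)
            return []
        return [TemplateSequence(f"{locus_id}__t1__{ref_class}", locus_id,
                                 ref_seq, ref_class)]
    eligible = [r for r in contig_ids if len(_ungapped(alignment[r])) >= min_contig]
    if not eligible:
        logger.info("locus %s: all contigs < %d bp; reference is sole template",
                    locus_id, min_contig)
        return [TemplateSequence(f"{locus_id}__t1__{ref_class}", locus_id,
                                 ref_seq, ref_class)]

    order = sorted([ref_id] + eligible,
                   key=lambda r: (-len(_ungapped(alignment[r])), r))
    clusters: list[list[str]] = []
    for rid in order:
        placed = False
        for cluster in clusters:
            if any(percent_identity_gapped(alignment[rid], alignment[m])
                   >= ident_threshold for m in cluster):
                cluster.append(rid)
                placed = True
                break
        if not placed:
            clusters.append([rid])

    reps = []
    for cluster in clusters:
        rep = max(cluster, key=lambda r: (len(_ungapped(alignment[r])), r))
        reps.append((rep, cluster))
    reps.sort(key=lambda rc: (rc[0] != ref_id,
                              -len(_ungapped(alignment[rc[0]])), rc[0]))
    if len(reps) > max_templates:
        for rep, _ in reps[max_templates:]:
            logger.info("locus %s: template cap %d reached; dropped cluster "
                        "representative %s", locus_id, max_templates, rep)
        reps = reps[:max_templates]

    templates: list[TemplateSequence] = []
    for n, (rep, cluster) in enumerate(reps, 1):
        if rep == ref_id:
            templates.append(TemplateSequence(
                f"{locus_id}__t{n}__{ref_class}", locus_id, ref_seq, ref_class))
            continue
        contig_seq = _ungapped(alignment[rep])
        cls = row_class.get(rep, "skim_cladeA")
        if rep in row_stitch:
            stitched_seq, provenance, skim_fraction = row_stitch[rep]
            out_cls = "hybrid" if skim_fraction < hybrid_cov_threshold else cls
            templates.append(TemplateSequence(
                f"{locus_id}__t{n}__{out_cls}", locus_id, stitched_seq,
                out_cls, provenance))
        elif len(contig_seq) < hybrid_cov_threshold * len(ref_seq):
            interval = _row_ref_interval(alignment[rep], alignment[ref_id])
            templates.append(hybrid_join(
                contig_seq, interval, ref_seq, locus_id,
                f"{locus_id}__t{n}__hybrid", rep, ref_id))
        else:
            templates.append(TemplateSequence(
                f"{locus_id}__t{n}__{cls}", locus_id, contig_seq, cls))
    return templates


# ---------------------------------------------------------------------------
# Organellar contamination screen (seeded local-alignment search)
# ---------------------------------------------------------------------------


class SeedIndex:
    """Forward k-mer position index over one reference, for seeded local
    alignment (the BLAST stand-in used by the contamination screens)."""

    def __init__(self, seq: str, k: int = 13) -> None:
        self.seq = seq
        self.k = k
        self.positions: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            self.positions.setdefault(seq[i:i + k], []).append(i)


def find_local_hit(query: str, ref_index: SeedIndex, min_ident: float,
                   min_len: int, scores: Scoring = DEFAULT_SCORING) -> LocalHit | None:
    """Seeded local-alignment search of ``query`` (either strand) against
    an indexed reference. Returns a hit with identity >= ``min_ident``
    over >= ``min_len`` aligned columns, or None."""
    k = ref_index.k
    for oriented in (query, reverse_complement(query)):
        seeds: list[tuple[int, int]] = []  # (diag, qpos)
        for i in range(len(oriented) - k + 1):
            for rpos in ref_index.positions.get(oriented[i:i + k], ()):
                seeds.append((rpos - i, i))
        if not seeds:
            continue
        seeds.sort()
        bands: list[list[tuple[int, int]]] = []
        for diag, qpos in seeds:
            if bands and diag - bands[-1][-1][0] <= 20:
                bands[-1].append((diag, qpos))
            else:
                bands.append([(diag, qpos)])
        bands.sort(key=len, reverse=True)
        for band in bands[:5]:
            qmin = min(q for _, q in band)
            qmax = max(q for _, q in band) + k
            rmin = min(d + q for d, q in band)
            rmax = max(d + q for d, q in band) + k
            qseg = oriented[max(0, qmin - 40):qmax + 40]
            rseg = ref_index.seq[max(0, rmin - 50):rmax + 50]
            if not qseg or not rseg:
                continue
            hit = local_align(qseg, rseg, scores)
            if hit.aligned_cols >= min_len and hit.identity >= min_ident:
                return hit
    return None


def organelle_screen(
    templates: list[TemplateSequence],
    plastid_ref: str | None,
    mito_ref: str | None,
    min_ident: float = 0.90,
    min_len: int = 60,
) -> tuple[list[TemplateSequence], list[tuple[TemplateSequence, str]]]:
    """Remove templates with a local match to an organellar genome.

    Returns (kept, flagged) where each flagged entry names the matching
    organelle. With neither reference supplied the screen is skipped
    with a prominent warning.
    """
    refs = {}
    if plastid_ref:
        refs["plastid"] = SeedIndex(plastid_ref)
    if mito_ref:
        refs["mito"] = SeedIndex(mito_ref)
    if not refs:
        logger.warning("organelle screen SKIPPED: no organellar reference provided")
        return list(templates), []
    kept, flagged = [], []
    for tpl in templates:
        reason = None
        for name, idx in refs.items():
            if find_local_hit(tpl.seq, idx, min_ident, min_len) is not None:
                reason = name
                break
        if reason is None:
            kept.append(tpl)
        else:
            logger.info("template %s flagged: %s match", tpl.template_id, reason)
            flagged.append((tpl, reason))
    return kept, flagged
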