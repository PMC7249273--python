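"""Tier 1: select putatively single-copy nuclear (SCN) loci.

Candidate loci come from transcriptome screens against curated single-copy
gene lists of one or more reference genomes. Candidates are filtered on
gene length and on exon/intron structure (every exon must exceed the probe
length, every intron must be shorter than 100 bp, so a 120-bp probe panel
with 3x tiling can capture across introns), reduced to one representative
transcript per locus, deduplicated across reference genomes by reciprocal
best hit, and finally merged with universal (e.g. Angiosperms353),
previously published, and functional locus sets into one registry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core_io import (
    ConsistencyError,
    GeneModel,
    LocusRecord,
    LocusRegistry,
    SequenceRecord,
)
from .tier2 import DEFAULT_MIN_SCORE, DEFAULT_SCORING, Scoring, local_score

logger = logging.getLogger("skimprobe")


@dataclass
class LocusCandidate:
    """One candidate locus: a reference-genome gene id with its
    transcriptome hits."""

    locus_id: str
    transcript_hits: dict[str, SequenceRecord]
    genome_origin: str

    def __post_init__(self) -> None:
        if not self.transcript_hits:
            raise ConsistencyError(f"candidate {self.locus_id}: no transcript hits")

    @property
    def max_hit_length(self) -> int:
        return max(len(r.seq) for r in self.transcript_hits.values())


@dataclass
class RbhPair:
    idA: str
    idB: str
    scoreAB: float
    scoreBA: float


@dataclass
class RbhResult:
    pairs: list[RbhPair]
    #: queries whose best hit was tied (possible paralogy; pair suppressed)
    ties: list[str] = field(default_factory=list)


def filter_min_gene_length(candidates: list[LocusCandidate],
                           min_len: int = 500) -> list[LocusCandidate]:
    """Keep candidates whose longest transcript hit is >= ``min_len`` bp
    (inclusive: a 500-bp transcript passes the default)."""
    return [c for c in candidates if c.max_hit_length >= min_len]


def exon_intron_filter(model: GeneModel, min_exon: int = 120,
                       max_intron: int = 100) -> bool:
    """True iff every exon is strictly longer than ``min_exon`` and every
    intron strictly shorter than ``max_intron``. Boundary values fail on
    both thresholds; single-exon models satisfy the intron condition
    vacuously."""
    return (all(e > min_exon for e in model.exon_lengths)
            and all(i < max_intron for i in model.intron_lengths))


def choose_representative(hits: dict[str, SequenceRecord],
                          default_name: str) -> tuple[SequenceRecord, str]:
    """Pick the representative transcript for a locus: the longest hit;
    on an exact length tie the hit from ``default_name``; if the default
    source is absent from the tie, the lexicographically smallest source
    name (with a warning). Returns (record, winning source name)."""
    if not hits:
        raise ValueError("choose_representative requires at least one hit")
    max_len = max(len(r.seq) for r in hits.values())
    tied = sorted(name for name, r in hits.items() if len(r.seq) == max_len)
    if len(tied) == 1:
        return hits[tied[0]], tied[0]
    if default_name in tied:
        return hits[default_name], default_name
    logger.warning(
        "length tie without default source %r; falling back to %r",
        default_name, tied[0],
    )
    return hits[tied[0]], tied[0]


def reciprocal_best_hit_pairs(
    setA: dict[str, str],
    setB: dict[str, str],
    scores: Scoring = DEFAULT_SCORING,
    min_score: float = DEFAULT_MIN_SCORE,
) -> RbhResult:
    """Reciprocal-best-hit pairs between two locus sets.

    A pair (a, b) is emitted iff b is a's unique highest-scoring local
    alignment hit in B, a is b's unique best hit in A, and both scores
    reach ``min_score``. A tied best hit suppresses any pairing for that
    query: a tie signals possible paralogy, and suppression is the
    conservative action for a single-copy pipeline. Output sorted by idA.
    """
    if not setA or not setB:
        raise ValueError("reciprocal_best_hit_pairs requires nonempty sets")
    score: dict[tuple[str, str], float] = {}
    for ida, seqa in setA.items():
        for idb, seqb in setB.items():
            score[(ida, idb)] = local_score(seqa, seqb, scores)

    def unique_best(query: str, targets, lookup) -> str | None:
        best_score = None
        best_ids: list[str] = []
        for t in targets:
            s = lookup(query, t)
            if best_score is None or s > best_score:
                best_score, best_ids = s, [t]
            elif s == best_score:
                best_ids.append(t)
        if best_score is None or best_score < min_score:
            return None
        if len(best_ids) > 1:
            return "__TIE__"
        return best_ids[0]

    ties: list[str] = []
    bestA: dict[str, str] = {}
    for ida in setA:
        b = unique_best(ida, setB, lambda q, t: score[(q, t)])
        if b == "__TIE__":
            ties.append(ida)
            logger.info("RBH: best hit tie for %s; pair suppressed", ida)
        elif b is not None:
            bestA[ida] = b
    bestB: dict[str, str] = {}
    for idb in setB:
        a = unique_best(idb, setA, lambda q, t: score[(t, q)])
        if a == "__TIE__":
            ties.append(idb)
            logger.info("RBH: best hit tie for %s; pair suppressed", idb)
        elif a is not None:
            bestB[idb] = a

    pairs = [
        RbhPair(ida, idb, score[(ida, idb)], score[(ida, idb)])
        for ida, idb in sorted(bestA.items())
        if bestB.get(idb) == ida
    ]
    return RbhResult(pairs, ties)


def dedupe_overlapping(
    regA: dict[str, LocusRecord],
    regB: dict[str, LocusRecord],
    pairs: list[RbhPair],
    genome_precedence: str = "genomeB",
) -> LocusRegistry:
    """Merge two per-genome locus sets, collapsing each reciprocal-best-hit
    pair to a single locus.

    The merged registry always has exactly |A| + |B| - |pairs| loci. A
    paired locus is represented by the longer transcript; on an exact
    length tie the member from ``genome_precedence`` wins. ``genome_origin``
    records whether a locus came from one genome or both.
    """
    for p in pairs:
        if p.idA not in regA or p.idB not in regB:
            raise ConsistencyError(f"RBH pair ({p.idA},{p.idB}) references unknown locus")
    paired_a = {p.idA for p in pairs}
    paired_b = {p.idB for p in pairs}
    merged = LocusRegistry()
    for lid, rec in regA.items():
        if lid not in paired_a:
            merged.add(LocusRecord(lid, rec.source_method, "genomeA",
                                   rec.representative, representative_source=rec.representative_source))
    for lid, rec in regB.items():
        if lid not in paired_b:
            merged.add(LocusRecord(lid, rec.source_method, "genomeB",
                                   rec.representative, representative_source=rec.representative_source))
    for p in pairs:
        ra, rb = regA[p.idA], regB[p.idB]
        la, lb = len(ra.representative.seq), len(rb.representative.seq)
        if la > lb:
            winner, lid = ra, p.idA
        elif lb > la:
            winner, lid = rb, p.idB
        else:
            winner, lid = (rb, p.idB) if genome_precedence == "genomeB" else (ra, p.idA)
        merged.add(LocusRecord(lid, winner.source_method, "both",
                               winner.representative,
                               representative_source=winner.representative_source))
    assert len(merged) == len(regA) + len(regB) - len(pairs)
    return merged


def filter_universal_by_taxon(
    universal: dict[str, list[tuple[str, SequenceRecord]]],
    allowed_taxa: set[str],
) -> dict[str, SequenceRecord]:
    """Filter a universal locus set by taxon source.

    ``universal`` maps locus id to (taxon, sequence) pairs. A locus is
    kept iff at least one source taxon is allowed; its representative is
    the longest sequence among allowed taxa.
    """
    if not allowed_taxa:
        raise ValueError("allowed_taxa must be nonempty")
    kept: dict[str, SequenceRecord] = {}
    for lid, entries in universal.items():
        allowed = [rec for taxon, rec in entries if taxon in allowed_taxa]
        if allowed:
            kept[lid] = max(allowed, key=lambda r: (len(r.seq), r.id))
    return kept


def map_external_loci(
    queries: list[SequenceRecord],
    transcriptomes: dict[str, list[SequenceRecord]],
    default_name: str,
    scores: Scoring = DEFAULT_SCORING,
    min_score: float = DEFAULT_MIN_SCORE,
) -> tuple[dict[str, tuple[SequenceRecord, str]], list[str]]:
    """Map external (published/functional) query loci onto transcriptomes.

    Per query, the best local hit in each transcriptome is found, then the
    representative is chosen among per-transcriptome hits by the usual
    longest/default rule. Returns (mapping query_id -> (record, source),
    list of unmapped query ids).
    """
    if not queries:
        raise ValueError("map_external_loci requires nonempty queries")
    mapped: dict[str, tuple[SequenceRecord, str]] = {}
    unmapped: list[str] = []
    for q in queries:
        hits: dict[str, SequenceRecord] = {}
        for tname, records in transcriptomes.items():
            best_rec, best_s = None, min_score
            for rec in records:
                s = local_score(q.seq, rec.seq, scores)
                if s > best_s or (s == best_s and best_rec is None and s >= min_score):
                    best_rec, best_s = rec, s
            if best_rec is not None:
                hits[tname] = best_rec
        if not hits:
            unmapped.append(q.id)
            logger.info("external query %s: no transcriptome hit >= %.0f", q.id, min_score)
            continue
        mapped[q.id] = choose_representative(hits, default_name)
    return mapped, unmapped


def merge_sources(
    markerminer_reg: LocusRegistry,
    universal_reg: LocusRegistry,
    published_reg: LocusRegistry,
    functional_reg: LocusRegistry,
) -> LocusRegistry:
    """Merge the four locus sources into one registry.

    Locus ids are namespaced by source method, so the merged size is
    always the sum of the four inputs; a collision after namespacing is a
    consistency error.
    """
    merged = LocusRegistry()
    for reg, method in (
        (markerminer_reg, "markerminer"),
        (universal_reg, "universal"),
        (published_reg, "published"),
        (functional_reg, "functional"),
    ):
        for rec in reg:
            lid = rec.locus_id if rec.locus_id.startswith(f"{method}__") \
                else f"{method}__{rec.locus_id}"
            merged.add(LocusRecord(lid, method, rec.genome_origin,
                                   rec.representative,
                                   representative_source=rec.representative_source))
    expected = len(markerminer_reg) + len(universal_reg) + len(published_reg) + len(functional_reg)
    assert len(merged) == expected
    return merged


def self_similarity_scan(
    representatives: dict[str, str],
    transcriptome: list[SequenceRecord],
    ident_threshold: float = 0.90,
    scores: Scoring = DEFAULT_SCORING,
) -> list[str]:
    """Optional paralogy scan: flag loci whose representative matches more
    than one distinct transcript at >= ``ident_threshold`` identity.
    Report-only; flagged loci are not removed (single-copy status inside
    the focal clade cannot be confirmed, only suspected)."""
    from .tier2 import local_align

    flagged = []
    for lid, seq in representatives.items():
        n_hits = 0
        for rec in transcriptome:
            hit = local_align(seq, rec.seq, scores)
            if (hit.aligned_cols >= 0.5 * len(seq)
                    and hit.identity >= ident_threshold):
                n_hits += 1
                if n_hits > 1:
                    break
        if n_hits > 1:
            flagged.append(lid)
            logger.info("self-similarity scan: locus %s matches multiple transcripts", lid)
    return flagged
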