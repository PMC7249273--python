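"""Tier-2 machinery: alignment engine vs exhaustive oracle, read mapping,
reference-guided consensus, template selection and organelle screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skimprobe.core_io import ConsistencyError, FastqRead, SequenceRecord, \
    reverse_complement
from skimprobe.simulate import SimConfig, simulate_skim_reads
from skimprobe.tier2 import (
    DEFAULT_SCORING,
    Contig,
    KmerIndex,
    ReadPlacement,
    SeedIndex,
    TemplateSequence,
    align_pair,
    consensus_contigs,
    find_local_hit,
    hybrid_join,
    local_align,
    map_reads,
    organelle_screen,
    percent_identity_gapped,
    select_templates,
    star_align,
    stitch_contigs,
)

from conftest import random_dna


# ---------------------------------------------------------------------------
# global affine alignment vs exhaustive enumeration
# ---------------------------------------------------------------------------


def _enumerate_best_score(a, b, scores=DEFAULT_SCORING):
    """Independent oracle: enumerate every global alignment (all monotone
    paths through the edit grid) and score it column by column with
    run-aware gap costs. Exponential, only for tiny sequences."""
    best = [-np.inf]

    def walk(i, j, score, prev_gap):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = scores.match if a[i] == b[j] else scores.mismatch
            walk(i + 1, j + 1, score + s, None)
        if i < len(a):  # gap in b
            s = scores.extend_gap if prev_gap == "b" else scores.open_gap
            walk(i + 1, j, score + s, "b")
        if j < len(b):  # gap in a
            s = scores.extend_gap if prev_gap == "a" else scores.open_gap
            walk(i, j + 1, score + s, "a")

    walk(0, 0, 0.0, None)
    return best[0]


class TestAlignPair:
    def test_identity_no_gaps(self):
        ra, rb, score = align_pair("ACGT", "ACGT")
        assert (ra, rb) == ("ACGT", "ACGT")
        assert score == 4 * DEFAULT_SCORING.match

    def test_single_deletion_column(self):
        ra, rb, score = align_pair("ACGT", "AGT")
        assert len(ra) == len(rb) == 4
        assert rb.count("-") == 1
        assert score == _enumerate_best_score("ACGT", "AGT")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")

    def test_score_equals_exhaustive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        n_checked = 0
        while n_checked < 200:
            la, lb = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            a, b = random_dna(rng, la), random_dna(rng, lb)
            _, _, score = align_pair(a, b)
            assert score == pytest.approx(_enumerate_best_score(a, b)), (a, b)
            n_checked += 1

    def test_rows_reproduce_score(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = random_dna(rng, int(rng.integers(3, 9)))
            b = random_dna(rng, int(rng.integers(3, 9)))
            ra, rb, score = align_pair(a, b)
            total, prev = 0.0, None
            for x, y in zip(ra, rb):
                if x == "-" or y == "-":
                    which = "a" if x == "-" else "b"
                    total += (DEFAULT_SCORING.extend_gap if prev == which
                              else DEFAULT_SCORING.open_gap)
                    prev = which
                else:
                    total += (DEFAULT_SCORING.match if x == y
                              else DEFAULT_SCORING.mismatch)
                    prev = None
            assert total == pytest.approx(score)


class TestPercentIdentityGapped:
    def test_identical(self):
        assert percent_identity_gapped("A" * 100, "A" * 100) == 100.0

    def test_hand_count(self):
        assert percent_identity_gapped("AC-GT", "ACTGT") == 80.0

    def test_trailing_ends_count_against(self):
        # contig covering exactly half the reference, perfect in overlap
        ref = "ACGT" * 25
        row = ref[:50] + "-" * 50
        assert percent_identity_gapped(ref, row) == 50.0

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 30))
            a = "".join(rng.choice(list("ACGT-"), size=n))
            b = "".join(rng.choice(list("ACGT-"), size=n))
            pid = percent_identity_gapped(a, b)
            assert pid == percent_identity_gapped(b, a)
            assert 0.0 <= pid <= 100.0

    def test_hundred_iff_identical_gap_free(self):
        assert percent_identity_gapped("AC-T", "AC-T") < 100.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            percent_identity_gapped("", "")


class TestStarAlign:
    def test_identical_copies_no_gaps(self, rng):
        ref = random_dna(rng, 80)
        aln = star_align({"ref": ref, "c1": ref, "c2": ref}, "ref")
        assert all(row == ref for row in aln.values())

    def test_internal_deletion_gap_run(self, rng):
        ref = random_dna(rng, 100)
        deleted = ref[:40] + ref[50:]
        aln = star_align({"ref": ref, "d": deleted}, "ref")
        assert aln["ref"] == ref
        assert aln["d"].count("-") == 10

    def test_column_count_at_least_reference(self, rng):
        ref = random_dna(rng, 60)
        seqs = {"ref": ref}
        for i in range(3):
            s = ref[:20] + random_dna(rng, 5) + ref[20:]
            seqs[f"s{i}"] = s
        aln = star_align(seqs, "ref")
        lengths = {len(r) for r in aln.values()}
        assert len(lengths) == 1
        assert lengths.pop() >= len(ref)
        # reference ungapped column order preserved
        assert aln["ref"].replace("-", "") == ref


class TestKmerIndex:
    def test_positions_enumerated(self):
        idx = KmerIndex({"r": "ACGTACGTACG"}, k=11)
        # k > len would skip; use a k that fits
        idx4 = KmerIndex.__new__(KmerIndex)
        idx4.k = 4
        idx4.refs = {"r": "ACGTACGT"}
        idx4._index = {}
        for i in range(5):
            idx4._index.setdefault("ACGTACGT"[i:i + 4], []).append(("r", i))
        assert [p for _, p, s in idx4.lookup("ACGT") if s == "+"] == [0, 4]

    def test_absent_kmer_empty(self):
        idx = KmerIndex({"r": "A" * 30}, k=11)
        assert idx.lookup("C" * 11) == []

    def test_reverse_complement_hits_minus_strand(self):
        seq = "ACGTTGCAAGGTC" + "A" * 20
        idx = KmerIndex({"r": seq}, k=13)
        hits = idx.lookup(reverse_complement(seq[:13]))
        assert ("r", 0, "-") in hits

    def test_short_reference_skipped(self, caplog):
        idx = KmerIndex({"short": "ACGT", "ok": "A" * 40}, k=21)
        assert "short" not in idx.refs and "ok" in idx.refs

    def test_k_floor(self):
        with pytest.raises(ValueError):
            KmerIndex({"r": "A" * 50}, k=5)


def _reads_from(seq, positions, length, prefix="r", strand="+"):
    reads = []
    for i, pos in enumerate(positions):
        frag = seq[pos:pos + length]
        if strand == "-":
            frag = reverse_complement(frag)
        reads.append(FastqRead(f"{prefix}{i}", frag, "I" * len(frag)))
    return reads


class TestMapReads:
    def test_exact_substring_placed(self, rng):
        ref = random_dna(rng, 400)
        idx = KmerIndex({"ref": ref}, k=21)
        result = map_reads(_reads_from(ref, [37], 100), idx)
        p = result.placements[0]
        assert (p.ref_start, p.strand) == (37, "+")
        assert p.identity_fraction == 1.0

    def test_reverse_complement_placed_minus(self, rng):
        ref = random_dna(rng, 400)
        idx = KmerIndex({"ref": ref}, k=21)
        result = map_reads(_reads_from(ref, [50], 100, strand="-"), idx)
        assert result.placements[0].strand == "-"
        assert result.placements[0].ref_start == 50

    def test_unrelated_read_unplaced(self, rng):
        ref = random_dna(rng, 400)
        idx = KmerIndex({"ref": ref}, k=21)
        result = map_reads([FastqRead("r", random_dna(rng, 100), "I" * 100)], idx)
        assert result.placements == [] and result.n_unplaced == 1

    def test_tied_placement_dropped(self, rng):
        seg = random_dna(rng, 120)
        ref = seg + random_dna(rng, 100) + seg
        idx = KmerIndex({"ref": ref}, k=21)
        result = map_reads(_reads_from(ref, [10], 80), idx)
        assert result.placements == [] and result.n_ties == 1


class TestConsensusContigs:
    def _placements(self, ref, spans, base_override=None):
        out = []
        for i, (start, end) in enumerate(spans):
            seq = ref.seq[start:end]
            if base_override:
                seq = base_override(seq, start)
            out.append(ReadPlacement(f"r{i}", ref.id, start, "+", end - start,
                                     1.0, read_seq=seq))
        return out

    def test_error_free_full_coverage_reproduces_reference(self, rng):
        ref = SequenceRecord("ref", random_dna(rng, 300))
        spans = [(i, i + 60) for i in range(0, 241, 6)] * 2  # depth >= 2 everywhere
        contigs = consensus_contigs(self._placements(ref, spans), ref)
        assert len(contigs) == 1
        assert contigs[0].seq == ref.seq
        assert contigs[0].ref_interval == (0, 300)

    def test_coverage_hole_splits_into_two_contigs(self, rng):
        ref = SequenceRecord("ref", random_dna(rng, 300))
        spans = [(0, 100), (0, 100), (150, 300), (150, 300)]
        contigs = consensus_contigs(self._placements(ref, spans), ref)
        assert [c.ref_interval for c in contigs] == [(0, 100), (150, 300)]

    def test_depth_below_min_excluded(self, rng):
        ref = SequenceRecord("ref", random_dna(rng, 200))
        contigs = consensus_contigs(self._placements(ref, [(0, 200)]), ref,
                                    min_depth=2)
        assert contigs == []

    def test_majority_beats_reference_tie_toward_reference(self):
        ref = SequenceRecord("ref", "AAAA")
        # two reads say C at position 0, one read says A: majority C
        pl = [ReadPlacement("r1", "ref", 0, "+", 4, 1.0, read_seq="CAAA"),
              ReadPlacement("r2", "ref", 0, "+", 4, 1.0, read_seq="CAAA"),
              ReadPlacement("r3", "ref", 0, "+", 4, 1.0, read_seq="AAAA")]
        contigs = consensus_contigs(pl, ref)
        assert contigs[0].seq == "CAAA"
        # 50/50 split: tie resolved toward the reference base
        pl = pl[:2] + [
            ReadPlacement("r3", "ref", 0, "+", 4, 1.0, read_seq="AAAA"),
            ReadPlacement("r4", "ref", 0, "+", 4, 1.0, read_seq="AAAA"),
        ]
        assert consensus_contigs(pl, ref)[0].seq == "AAAA"

    def test_seeded_simulation_recovers_truth(self):
        """15x coverage, 1% substitution error: consensus >= 99.5%
        identical to the truth over covered positions."""
        rng = np.random.default_rng(42)
        truth = random_dna(rng, 1200)
        cfg = SimConfig(seed=42, n_loci=1, skim_coverage=15.0, read_len=100,
                        read_error=0.01)
        reads = simulate_skim_reads({"locus": truth}, cfg, seed=99)
        idx = KmerIndex({"locus": truth}, k=21)
        result = map_reads(reads, idx)
        contigs = consensus_contigs(result.placements,
                                    SequenceRecord("locus", truth))
        covered = sum(c.ref_interval[1] - c.ref_interval[0] for c in contigs)
        matches = sum(
            sum(1 for x, y in zip(c.seq, truth[c.ref_interval[0]:c.ref_interval[1]])
                if x == y)
            for c in contigs
        )
        assert covered >= 0.95 * len(truth)
        assert matches / covered >= 0.995

    def test_flank_extension_beyond_reference(self):
        ref = SequenceRecord("ref", "ACGT" * 20)
        pl = [ReadPlacement(f"r{i}", "ref", 0, "+", 40, 1.0,
                            read_seq=ref.seq[:40], left_flank="TTTTT")
              for i in range(3)]
        contigs = consensus_contigs(pl, ref, flank_bp=10)
        assert contigs[0].left_flank == 5
        assert contigs[0].seq.startswith("TTTTT")
        assert contigs[0].ref_interval[0] == 0


class TestHybridJoin:
    def test_prefix_replacement(self, rng):
        backbone = random_dna(rng, 1000)
        contig = random_dna(rng, 400)
        tpl = hybrid_join(contig, (0, 400), backbone, "loc", "loc__t1__hybrid",
                          "contig1", "ref")
        assert len(tpl.seq) == 1000
        assert tpl.seq[:400] == contig and tpl.seq[400:] == backbone[400:]

    def test_full_cover_is_contig(self, rng):
        backbone = random_dna(rng, 500)
        contig = random_dna(rng, 500)
        tpl = hybrid_join(contig, (0, 500), backbone, "loc", "t", "c", "r")
        assert tpl.seq == contig

    def test_internal_replacement_segmentwise(self, rng):
        backbone = random_dna(rng, 1000)
        contig = random_dna(rng, 400)
        tpl = hybrid_join(contig, (300, 700), backbone, "loc", "t", "c", "r")
        assert tpl.seq == backbone[:300] + contig + backbone[700:]
        assert len(tpl.seq) == len(backbone) - 400 + len(contig)
        # provenance partitions the hybrid
        assert [iv for iv, _ in tpl.provenance] == [(0, 300), (300, 700), (700, 1000)]

    def test_interval_outside_backbone_rejected(self, rng):
        with pytest.raises(ConsistencyError):
            hybrid_join("ACGT", (0, 50), "ACGT" * 10, "loc", "t", "c", "r")

    @given(start=st.integers(0, 500), length=st.integers(1, 400))
    @settings(max_examples=50, deadline=None)
    def test_length_identity(self, start, length):
        backbone = "A" * 1000
        end = min(start + length, 1000)
        contig = "C" * 77
        tpl = hybrid_join(contig, (start, end), backbone, "l", "t", "c", "r")
        assert len(tpl.seq) == len(backbone) - (end - start) + len(contig)


def _mutated(seq, n, rng):
    out = list(seq)
    for i in rng.choice(len(seq), size=n, replace=False):
        out[i] = "ACGT"[("ACGT".index(out[i]) + 1) % 4]
    return "".join(out)


class TestSelectTemplates:
    def test_high_identity_single_template(self, rng):
        ref = random_dna(rng, 600)
        aln = {"ref": ref, "c1": _mutated(ref, 12, rng), "c2": _mutated(ref, 12, rng)}
        tpls = select_templates(aln, "ref", "loc", "markerminer")
        assert len(tpls) == 1

    def test_divergent_contigs_multiple_templates(self, rng):
        ref = random_dna(rng, 600)
        c1 = _mutated(ref, 180, rng)  # 70% identity to ref and to each other
        c2 = _mutated(ref, 180, rng)
        aln = star_align({"ref": ref, "c1": c1, "c2": c2}, "ref")
        tpls = select_templates(aln, "ref", "loc", "markerminer")
        assert len(tpls) >= 2

    def test_markerminer_no_contigs_omitted(self, rng):
        ref = random_dna(rng, 600)
        assert select_templates({"ref": ref}, "ref", "loc", "markerminer") == []

    def test_universal_no_contigs_keeps_reference(self, rng):
        ref = random_dna(rng, 600)
        tpls = select_templates({"ref": ref}, "ref", "loc", "universal")
        assert len(tpls) == 1 and tpls[0].source_class == "universal"
        assert tpls[0].seq == ref

    def test_short_contigs_reference_sole_template(self, rng):
        ref = random_dna(rng, 600)
        aln = star_align({"ref": ref, "c1": ref[100:250]}, "ref")
        tpls = select_templates(aln, "ref", "loc", "markerminer")
        assert len(tpls) == 1 and tpls[0].seq == ref

    def test_partial_contig_completed_as_hybrid(self, rng):
        ref = random_dna(rng, 1000)
        contig = _mutated(ref[:400], 80, rng)  # divergent partial contig
        aln = star_align({"ref": ref, "c1": contig}, "ref")
        tpls = select_templates(aln, "ref", "loc", "markerminer")
        classes = {t.source_class for t in tpls}
        assert "hybrid" in classes
        hybrid = next(t for t in tpls if t.source_class == "hybrid")
        assert len(hybrid.seq) >= 900  # completed to near backbone length

    def test_cap_at_max_templates(self, rng):
        ref = random_dna(rng, 600)
        rows = {"ref": ref}
        for i in range(6):
            rows[f"c{i}"] = _mutated(ref, 200 + 10 * i, rng)
        aln = star_align(rows, "ref")
        tpls = select_templates(aln, "ref", "loc", "markerminer",
                                ident_threshold=90.0, max_templates=4)
        assert 1 <= len(tpls) <= 4

    def test_missing_reference_rejected(self):
        with pytest.raises(ConsistencyError):
            select_templates({"c": "ACGT"}, "ref", "loc", "markerminer")


class TestStitchContigs:
    def _contig(self, lid, seq, interval, taxon="tx"):
        return Contig(lid, taxon, seq, interval, 5.0,
                      contig_id=f"{taxon}__{lid}__c{interval[0]}")

    def test_gaps_filled_from_backbone(self, rng):
        backbone = random_dna(rng, 500)
        c1 = self._contig("l", "A" * 100, (0, 100))
        c2 = self._contig("l", "C" * 100, (200, 300))
        seq, prov, frac = stitch_contigs([c2, c1], backbone, "row")
        assert seq == "A" * 100 + backbone[100:200] + "C" * 100 + backbone[300:]
        assert frac == pytest.approx(200 / 500)
        assert len(prov) == 4

    def test_full_cover_fraction_one(self, rng):
        backbone = random_dna(rng, 300)
        c = self._contig("l", "G" * 300, (0, 300))
        seq, _, frac = stitch_contigs([c], backbone, "row")
        assert seq == "G" * 300 and frac == 1.0


class TestOrganelleScreen:
    def _template(self, seq, tid="t1"):
        return TemplateSequence(tid, "loc", seq, "transcriptome")

    def test_planted_plastid_segment_flagged(self, rng):
        plastid = random_dna(rng, 5000)
        tpl = self._template(random_dna(rng, 400) + plastid[1000:1200]
                             + random_dna(rng, 400))
        kept, flagged = organelle_screen([tpl], plastid, None)
        assert kept == [] and flagged[0][1] == "plastid"

    def test_random_template_kept(self, rng):
        plastid = random_dna(rng, 5000)
        tpl = self._template(random_dna(rng, 800))
        kept, flagged = organelle_screen([tpl], plastid, random_dna(rng, 5000))
        assert flagged == [] and kept == [tpl]

    def test_match_below_min_len_kept(self, rng):
        plastid = random_dna(rng, 5000)
        tpl = self._template(random_dna(rng, 400) + plastid[2000:2050]
                             + random_dna(rng, 400))
        kept, flagged = organelle_screen([tpl], plastid, None, min_len=60)
        assert flagged == []
        # the same segment above min_len is caught
        tpl2 = self._template(random_dna(rng, 400) + plastid[2000:2080]
                              + random_dna(rng, 400), "t2")
        _, flagged2 = organelle_screen([tpl2], plastid, None, min_len=60)
        assert flagged2

    def test_no_references_skips_with_warning(self, caplog):
        tpl = self._template("ACGT" * 100)
        with caplog.at_level("WARNING", logger="skimprobe"):
            kept, flagged = organelle_screen([tpl], None, None)
        assert kept == [tpl] and flagged == []
        assert any("SKIPPED" in m for m in caplog.messages)

    def test_reverse_strand_contamination_flagged(self, rng):
        plastid = random_dna(rng, 5000)
        tpl = self._template(
            random_dna(rng, 300) + reverse_complement(plastid[100:300])
            + random_dna(rng, 300))
        _, flagged = organelle_screen([tpl], plastid, None)
        assert flagged


class TestFindLocalHit:
    def test_identity_threshold_respected(self, rng):
        ref = random_dna(rng, 2000)
        idx = SeedIndex(ref)
        seg = list(ref[500:700])
        for i in rng.choice(200, size=36, replace=False):  # 82% identity
            seg[i] = "ACGT"[("ACGT".index(seg[i]) + 1) % 4]
        query = random_dna(rng, 200) + "".join(seg) + random_dna(rng, 200)
        assert find_local_hit(query, idx, min_ident=0.90, min_len=60) is None
        assert find_local_hit(query, idx, min_ident=0.75, min_len=60) is not None
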