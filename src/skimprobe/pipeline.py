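"""Stage drivers: run Tier 1, Tier 2, probe construction and evaluation
over in-memory inputs. The command-line interface is a thin file-I/O
wrapper around these functions, and the test-suite smoke test and the
acceptance script call them directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import evaluate as ev
from . import probes as pb
from . import tier1, tier2
from .core_io import (
    GeneModel,
    LocusRecord,
    LocusRegistry,
    SequenceRecord,
)
from .simulate import (
    ALLOWED_TAXA,
    CLADES,
    GeneSpace,
    clade_skim_genome,
    make_capture_sample,
    simulate_skim_reads,
)

logger = logging.getLogger("skimprobe")


# ---------------------------------------------------------------------------
# Tier 1
# ---------------------------------------------------------------------------


@dataclass
class Tier1Result:
    registry: LocusRegistry
    rbh: tier1.RbhResult
    n_dropped_length: int
    n_dropped_structure: int
    unmapped_external: list[str]
    markerminer_count: int = 0


def run_tier1(
    transcriptomes: dict[str, list[SequenceRecord]],
    gene_models: dict[str, GeneModel],
    candidates: dict[str, dict[str, dict[str, str]]],
    universal: dict[str, list[tuple[str, SequenceRecord]]],
    allowed_taxa: set[str],
    published_queries: list[SequenceRecord],
    functional_queries: list[SequenceRecord],
    default_transcriptome: str = "miconia",
    genome_precedence: str = "genomeB",
    min_gene_length: int = 500,
    min_exon: int = 120,
    max_intron: int = 100,
    min_score: float = tier2.DEFAULT_MIN_SCORE,
) -> Tier1Result:
    """Select, deduplicate and merge SCN loci from all four sources."""
    seq_by_tid = {
        rec.id: rec for recs in transcriptomes.values() for rec in recs
    }

    def build_candidates(genome: str) -> list[tier1.LocusCandidate]:
        out = []
        for lid, hits in sorted(candidates.get(genome, {}).items()):
            resolved = {taxon: seq_by_tid[tid] for taxon, tid in hits.items()
                        if tid in seq_by_tid}
            if resolved:
                out.append(tier1.LocusCandidate(lid, resolved, genome))
        return out

    n_dropped_length = n_dropped_structure = 0
    per_genome_regs: dict[str, dict[str, LocusRecord]] = {}
    per_genome_sets: dict[str, dict[str, str]] = {}
    for genome in ("genomeA", "genomeB"):
        cands = build_candidates(genome)
        kept = tier1.filter_min_gene_length(cands, min_gene_length)
        n_dropped_length += len(cands) - len(kept)
        structured = []
        for cand in kept:
            passing = {
                taxon: rec for taxon, rec in cand.transcript_hits.items()
                if rec.id in gene_models
                and tier1.exon_intron_filter(gene_models[rec.id], min_exon, max_intron)
            }
            if passing:
                structured.append(tier1.LocusCandidate(cand.locus_id, passing,
                                                       cand.genome_origin))
            else:
                n_dropped_structure += 1
        reg: dict[str, LocusRecord] = {}
        seqs: dict[str, str] = {}
        for cand in structured:
            rep, source = tier1.choose_representative(cand.transcript_hits,
                                                      default_transcriptome)
            reg[cand.locus_id] = LocusRecord(
                cand.locus_id, "markerminer", genome, rep,
                representative_source=source)
            seqs[cand.locus_id] = rep.seq
        per_genome_regs[genome] = reg
        per_genome_sets[genome] = seqs
        logger.info("tier1 %s: %d candidates -> %d after filters",
                    genome, len(cands), len(structured))

    if per_genome_sets["genomeA"] and per_genome_sets["genomeB"]:
        rbh = tier1.reciprocal_best_hit_pairs(
            per_genome_sets["genomeA"], per_genome_sets["genomeB"],
            min_score=min_score)
    else:
        rbh = tier1.RbhResult([], [])
    mm_registry = tier1.dedupe_overlapping(
        per_genome_regs["genomeA"], per_genome_regs["genomeB"],
        rbh.pairs, genome_precedence)

    uni_reps = tier1.filter_universal_by_taxon(universal, allowed_taxa)
    uni_registry = LocusRegistry(
        LocusRecord(lid, "universal", "none", rec)
        for lid, rec in sorted(uni_reps.items())
    )

    def map_queries(queries: list[SequenceRecord], method: str) -> tuple[LocusRegistry, list[str]]:
        if not queries:
            return LocusRegistry(), []
        mapped, unmapped = tier1.map_external_loci(
            queries, transcriptomes, default_transcriptome, min_score=min_score)
        reg = LocusRegistry(
            LocusRecord(qid, method, "none", rec, representative_source=source)
            for qid, (rec, source) in sorted(mapped.items())
        )
        return reg, unmapped

    pub_registry, pub_unmapped = map_queries(published_queries, "published")
    fun_registry, fun_unmapped = map_queries(functional_queries, "functional")

    merged = tier1.merge_sources(mm_registry, uni_registry, pub_registry, fun_registry)
    logger.info("tier1 merged registry: %d loci (%d markerminer, %d universal, "
                "%d published, %d functional)", len(merged), len(mm_registry),
                len(uni_registry), len(pub_registry), len(fun_registry))
    return Tier1Result(merged, rbh, n_dropped_length, n_dropped_structure,
                       pub_unmapped + fun_unmapped, len(mm_registry))


# ---------------------------------------------------------------------------
# Tier 2
# ---------------------------------------------------------------------------


@dataclass
class Tier2Result:
    templates: list[tier2.TemplateSequence]
    registry: LocusRegistry
    alignments: dict[str, dict[str, str]]  # locus -> star alignment rows
    contigs: dict[str, list[tier2.Contig]]  # locus -> contigs (all skim taxa)
    flagged: list[tuple[tier2.TemplateSequence, str]]
    omitted_loci: list[str]
    mapping_stats: pd.DataFrame = field(default=None, repr=False)

    @property
    def template_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"template_id": t.template_id, "locus_id": t.locus_id,
             "source_class": t.source_class, "length": len(t.seq)}
            for t in self.templates
        ])


def run_tier2(
    registry: LocusRegistry,
    skim_reads: dict[str, list],
    taxon_clades: dict[str, str],
    plastid_ref: str | None = None,
    mito_ref: str | None = None,
    k: int = 21,
    min_identity: float = 0.80,
    min_depth: int = 2,
    flank_bp: int = 200,
    ident_threshold: float = 90.0,
    min_contig: int = 300,
    max_templates: int = 4,
    screen_min_ident: float = 0.90,
    screen_min_len: int = 60,
) -> Tier2Result:
    """Assemble skim reads against Tier-1 references and select templates."""
    refs = {rec.locus_id: rec.representative.seq for rec in registry}
    index = tier2.KmerIndex(refs, k=k)
    contigs_by_locus: dict[str, list[tier2.Contig]] = {lid: [] for lid in refs}
    contig_clade: dict[str, str] = {}
    map_rows = []
    for taxon in sorted(skim_reads):
        result = tier2.map_reads(skim_reads[taxon], index,
                                 min_identity=min_identity, flank_bp=flank_bp)
        by_ref: dict[str, list[tier2.ReadPlacement]] = {}
        for p in result.placements:
            by_ref.setdefault(p.ref_id, []).append(p)
        n_contigs = 0
        for lid, placements in by_ref.items():
            ref_rec = SequenceRecord(lid, refs[lid])
            contigs = tier2.consensus_contigs(placements, ref_rec,
                                              min_depth=min_depth,
                                              flank_bp=flank_bp,
                                              skim_taxon=taxon)
            for c in contigs:
                contig_clade[c.contig_id] = taxon_clades.get(taxon, "cladeA")
            contigs_by_locus[lid].extend(contigs)
            n_contigs += len(contigs)
        map_rows.append({"taxon": taxon, "n_reads": len(skim_reads[taxon]),
                         "n_placed": len(result.placements),
                         "n_unplaced": result.n_unplaced,
                         "n_ties": result.n_ties, "n_contigs": n_contigs})
        logger.info("tier2 %s: %d/%d reads placed, %d contigs", taxon,
                    len(result.placements), len(skim_reads[taxon]), n_contigs)

    templates: list[tier2.TemplateSequence] = []
    alignments: dict[str, dict[str, str]] = {}
    omitted: list[str] = []
    flagged: list[tuple[tier2.TemplateSequence, str]] = []
    final_registry = LocusRegistry()
    for rec in registry:
        lid = rec.locus_id
        contigs = contigs_by_locus.get(lid, [])
        row_class: dict[str, str] = {}
        row_stitch: dict[str, tuple[str, list, float]] = {}
        by_taxon: dict[str, list[tier2.Contig]] = {}
        for c in contigs:
            by_taxon.setdefault(c.skim_taxon, []).append(c)
        # per skim taxon, align its (flank-trimmed) contigs to the
        # reference and merge them into one coverage-only row; taxa with
        # no contig reaching min_contig fall through to select_templates'
        # reference-only rule
        usable = {t: cs for t, cs in by_taxon.items()
                  if any(len(c.seq) >= min_contig for c in cs)}
        cores = {}
        for taxon, cs in usable.items():
            for c in cs:
                core = c.seq[c.left_flank:len(c.seq) - c.right_flank
                             if c.right_flank else None]
                if core:
                    cores[c.contig_id] = (taxon, core)
        if cores:
            aln_all = tier2.star_align(
                {lid: refs[lid], **{cid: s for cid, (t, s) in cores.items()}}, lid)
            n_cols = len(aln_all[lid])
            aln: dict[str, str] = {lid: aln_all[lid]}
            for taxon in sorted({t for t, _ in cores.values()}):
                member_rows = [aln_all[cid] for cid, (t, _) in cores.items()
                               if t == taxon]
                merged = []
                for i in range(n_cols):
                    ch = "-"
                    for row in member_rows:
                        if row[i] != "-":
                            ch = row[i]
                            break
                    merged.append(ch)
                row_id = f"{taxon}__{lid}"
                aln[row_id] = "".join(merged)
                row_class[row_id] = "skim_cladeA" \
                    if taxon_clades.get(taxon) == "cladeA" else "skim_cladeB"
                if taxon in usable:
                    seq, provenance, skim_frac = tier2.stitch_contigs(
                        by_taxon[taxon], refs[lid], row_id)
                    row_stitch[row_id] = (seq, provenance, skim_frac)
        elif contigs:
            # only sub-min_contig fragments: keep them as individual rows so
            # the reference-only fallback fires on per-contig lengths
            aln = tier2.star_align(
                {lid: refs[lid], **{c.contig_id: c.seq for c in contigs
                                    if c.seq}}, lid)
            for c in contigs:
                row_class[c.contig_id] = "skim_cladeA" \
                    if contig_clade.get(c.contig_id) == "cladeA" else "skim_cladeB"
        else:
            aln = {lid: refs[lid]}
        alignments[lid] = aln
        locus_templates = tier2.select_templates(
            aln, lid, lid, rec.source_method, row_class, row_stitch,
            ident_threshold=ident_threshold, min_contig=min_contig,
            max_templates=max_templates)
        if not locus_templates:
            omitted.append(lid)
            continue
        kept, flagged_here = tier2.organelle_screen(
            locus_templates, plastid_ref, mito_ref,
            min_ident=screen_min_ident, min_len=screen_min_len)
        flagged.extend(flagged_here)
        if not kept:
            omitted.append(lid)
            continue
        templates.extend(kept)
        final_registry.add(LocusRecord(
            lid, rec.source_method, rec.genome_origin, rec.representative,
            template_ids=[t.template_id for t in kept],
            representative_source=rec.representative_source))
    logger.info("tier2: %d loci -> %d templates (%d loci omitted, %d templates "
                "organelle-flagged)", len(final_registry), len(templates),
                len(omitted), len(flagged))
    return Tier2Result(templates, final_registry, alignments,
                       contigs_by_locus, flagged, omitted,
                       pd.DataFrame(map_rows))


# ---------------------------------------------------------------------------
# Probes
# ---------------------------------------------------------------------------


@dataclass
class ProbesResult:
    templates: list[tier2.TemplateSequence]
    probes: list[pb.ProbeRecord]
    flagged: list[pb.ProbeRecord]
    summary: dict


def run_probes(
    tier2_result: Tier2Result,
    decoy_refs: dict[str, str] | None = None,
    probe_len: int = 120,
    tiling: int = 3,
    max_homopolymer: int = 10,
) -> ProbesResult:
    sanitized, kept, flagged = pb.build_panel(
        tier2_result.templates, tier2_result.alignments, decoy_refs,
        probe_len=probe_len, tiling=tiling, max_homopolymer=max_homopolymer)
    summary = pb.panel_summary(kept, sanitized, tier2_result.registry)
    logger.info("probes: %d probes kept, %d flagged over %d templates",
                len(kept), len(flagged), summary["n_templates"])
    return ProbesResult(sanitized, kept, flagged, summary)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluateResult:
    template_stats: pd.DataFrame
    sample_stats: pd.DataFrame
    locus_stats: pd.DataFrame
    clade_summaries: dict[str, ev.CladeSummary]
    variation: ev.VariationStats | None


def run_evaluate(
    templates: list[tier2.TemplateSequence],
    registry: LocusRegistry,
    sample_reads: dict[str, list],
    sample_clades: dict[str, str],
    k: int = 21,
    min_map_identity: float = 0.80,
    min_depth: int = 2,
    min_identity: float = 0.55,
    min_cov_fraction: float = 0.0,
    long_fraction: float = 0.85,
    compute_variation: bool = True,
) -> EvaluateResult:
    """Assemble capture reads per sample per locus and compute the
    capture-success report.

    Assembly is per locus (reads mapped against one reference per locus,
    the locus's longest template, the per-gene assembly convention);
    recovery is then assessed per template by aligning the locus's sample
    contigs to each template.
    """
    tpl_seqs = {t.template_id: t.seq for t in templates}
    template_locus = {t.template_id: t.locus_id for t in templates}
    locus_ref = {}
    for tid, lid in template_locus.items():
        if lid not in locus_ref or len(tpl_seqs[tid]) > len(tpl_seqs[locus_ref[lid]]):
            locus_ref[lid] = tid
    ref_seqs = {lid: tpl_seqs[tid] for lid, tid in locus_ref.items()}
    index = tier2.KmerIndex(ref_seqs, k=k)
    rows = []
    sample_rows = []
    recovered_seqs: dict[str, dict[str, str]] = {}  # template -> sample -> seq
    for sample_id in sorted(sample_reads):
        reads = sample_reads[sample_id]
        result = tier2.map_reads(reads, index, min_identity=min_map_identity,
                                 flank_bp=0)
        by_locus: dict[str, list[tier2.ReadPlacement]] = {}
        for p in result.placements:
            by_locus.setdefault(p.ref_id, []).append(p)
        contigs_by_locus: dict[str, list[tier2.Contig]] = {}
        for lid, placements in by_locus.items():
            contigs_by_locus[lid] = tier2.consensus_contigs(
                placements, SequenceRecord(lid, ref_seqs[lid]),
                min_depth=min_depth, flank_bp=0, skim_taxon=sample_id)
        stats_here: list[ev.CaptureStats] = []
        for tid, seq in tpl_seqs.items():
            contigs = contigs_by_locus.get(template_locus[tid], [])
            rec = ev.recovered_sequence(seq, contigs, min_identity,
                                        min_cov_fraction) if contigs else None
            stats_here.append(ev.CaptureStats(
                sample_id=sample_id, template_id=tid,
                recovered_len=rec.recovered_len if rec else 0,
                reference_len=len(seq),
                identity_pct=rec.identity_pct if rec else 0.0,
                recovered=rec is not None,
                at_50pct=bool(rec and rec.recovered_len >= 0.5 * len(seq)),
            ))
            if rec is not None:
                recovered_seqs.setdefault(tid, {})[sample_id] = rec.seq
        paralog_loci = set()
        for lid, contigs in contigs_by_locus.items():
            if contigs and ev.flag_paralogs(ref_seqs[lid], contigs, long_fraction):
                paralog_loci.add(lid)
        for s in stats_here:
            s.paralog_flag = template_locus[s.template_id] in paralog_loci
        rows.extend(vars(s) for s in stats_here)
        on_target = ev.on_target_fraction(len(result.placements), len(reads))
        recovered_lens = [s.recovered_len for s in stats_here if s.recovered]
        sample_rows.append({
            "sample_id": sample_id,
            "clade": sample_clades.get(sample_id, ""),
            "total_reads": len(reads),
            "reads_mapped": len(result.placements),
            "on_target_pct": on_target,
            "n_templates_recovered": sum(s.recovered for s in stats_here),
            "n_templates_at_50pct": ev.count_templates_at_50pct(stats_here),
            "mean_recovered_len": (sum(recovered_lens) / len(recovered_lens))
            if recovered_lens else 0.0,
            "max_recovered_len": max(recovered_lens, default=0),
            "n_paralog_loci": len(paralog_loci),
        })
        logger.info("evaluate %s: %.1f%% on-target, %d templates recovered",
                    sample_id, on_target or 0.0,
                    sum(s.recovered for s in stats_here))

    template_stats = pd.DataFrame(rows)
    sample_stats = pd.DataFrame(sample_rows)
    locus_stats = ev.locus_rollup(template_stats, template_locus)
    sample_clade_col = sample_stats.set_index("sample_id")["clade"]
    locus_counts = (
        locus_stats[locus_stats["recovered"]]
        .groupby("sample_id")["locus_id"].nunique()
    )
    sample_stats["n_loci_recovered"] = sample_stats["sample_id"].map(
        locus_counts).fillna(0).astype(int)
    clade_summaries = {
        clade: ev.clade_summary(group.drop(columns=["clade"]), clade)
        for clade, group in sample_stats.groupby("clade")
        if clade
    }
    variation = None
    if compute_variation and recovered_seqs:
        alignments = []
        for tid, by_sample in sorted(recovered_seqs.items()):
            if len(by_sample) < 2:
                continue
            seqs = {"__ref__": tpl_seqs[tid]}
            seqs.update(by_sample)
            aln = tier2.star_align(seqs, "__ref__")
            alignments.append([row for sid, row in sorted(aln.items())
                               if sid != "__ref__"])
        if alignments:
            variation = ev.alignment_variation_stats(alignments)
    return EvaluateResult(template_stats, sample_stats, locus_stats,
                          clade_summaries, variation)


# ---------------------------------------------------------------------------
# End-to-end over a synthetic gene space
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    tier1: Tier1Result
    tier2: Tier2Result
    probes: ProbesResult
    evaluation: EvaluateResult | None


def run_all(space: GeneSpace, n_samples_per_clade: int = 2,
            capture_reads_per_sample: int = 2500,
            evaluate_panel: bool = True) -> PipelineResult:
    """Run the full pipeline over a synthetic gene space: Tier 1 from its
    transcriptomes and candidate lists, Tier 2 from simulated skims of
    two taxa per clade, probe construction with decoy screening, and
    evaluation on simulated capture samples."""
    cfg = space.cfg
    t1 = run_tier1(
        space.transcriptomes, space.gene_models, space.candidates,
        space.universal, ALLOWED_TAXA, space.published_queries,
        space.functional_queries)

    skim_reads = {}
    taxon_clades = {}
    for ci, clade in enumerate(CLADES):
        genome = clade_skim_genome(space, clade)
        for ti in range(2):
            taxon = f"{clade}_skim{ti + 1}"
            skim_reads[taxon] = simulate_skim_reads(
                genome, cfg, seed=cfg.seed + 100 * ci + ti, taxon=taxon)
            taxon_clades[taxon] = clade
    t2 = run_tier2(t1.registry, skim_reads, taxon_clades,
                   plastid_ref=space.plastid, mito_ref=space.mito)

    pr = run_probes(t2, decoy_refs={
        "plastid": space.plastid, "mito": space.mito,
        "nuclear_decoy": space.nuclear_decoy,
    })

    evaluation = None
    if evaluate_panel and pr.probes:
        sample_reads, sample_clades = {}, {}
        for ci, clade in enumerate(CLADES):
            for si in range(n_samples_per_clade):
                sample_id = f"{clade}_s{si + 1}"
                reads, _ = make_capture_sample(
                    space, clade, sample_id, capture_reads_per_sample,
                    seed=cfg.seed + 1000 + 10 * ci + si)
                sample_reads[sample_id] = reads
                sample_clades[sample_id] = clade
        evaluation = run_evaluate(pr.templates, t2.registry, sample_reads,
                                  sample_clades)
    return PipelineResult(t1, t2, pr, evaluation)
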