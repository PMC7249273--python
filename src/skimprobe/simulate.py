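"""Seeded synthetic-data generator for the whole pipeline.

Emulates the structure of the study system: an ancestral gene space with
exon/intron models, two study clades diverged from it, two transcriptome
taxa near the ancestor (the Tier-1 inputs), curated single-copy candidate
lists for two reference genomes, a universal locus set with taxon-source
metadata, published/functional query loci, shallow genome-skim reads at a
configured fold coverage, organellar and decoy references with planted
contamination, and enrichment-biased capture reads. Everything is
deterministic under a fixed seed; planted filter violations, duplicate
candidates and contamination are recorded in a truth table so tests can
assert they are caught downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FastqRead, GeneModel, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")

CLADES = ("cladeA", "cladeB")
TRANSCRIPTOME_TAXA = ("miconia", "medinilla")
ALLOWED_TAXA = {"rosid_1", "rosid_2"}
UNIVERSAL_TAXA = ("rosid_1", "rosid_2", "asterid_1", "monocot_1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic gene space and read sets.

    ``clade_divergence`` is the expected pairwise substitution divergence
    between the two study clades (each clade sits at half that distance
    from the ancestor). Loci evolve at heterogeneous rates: each locus
    draws a rate factor uniform in [1 - h, 1 + h] with
    h = ``rate_heterogeneity``, so slow loci stay capturable by a single
    template while fast loci force clade-specific templates, the mix the
    two-tier design exists for. ``skim_coverage`` is mean fold coverage of the
    skims; ``enrichment_ratio`` is the on-target/off-target sampling odds
    of the capture experiment (ratio r gives an expected on-target
    fraction r/(1+r)).
    """

    seed: int = 1
    n_loci: int = 30
    n_exons_range: tuple[int, int] = (1, 4)
    exon_len_range: tuple[int, int] = (140, 450)
    intron_len_range: tuple[int, int] = (20, 95)
    frac_violations: float = 0.2
    frac_duplicates: float = 0.1
    clade_divergence: float = 0.15
    rate_heterogeneity: float = 0.6
    transcriptome_divergence: float = 0.02
    indel_rate: float = 0.003
    skim_coverage: float = 15.0
    read_len: int = 150
    read_error: float = 0.01
    organelle_len: int = 8000
    enrichment_ratio: float = 5.67
    sample_divergence: float = 0.005
    frac_organelle_planted: float = 0.07

    def __post_init__(self) -> None:
        for name in ("frac_violations", "frac_duplicates", "clade_divergence",
                     "rate_heterogeneity", "transcriptome_divergence",
                     "indel_rate", "read_error", "sample_divergence",
                     "frac_organelle_planted"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.skim_coverage <= 0:
            raise ValueError("skim_coverage must be positive")
        if self.read_len < 21:
            raise ValueError("read_len must be >= k-mer size (21)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.exon_len_range[0] < 1 or self.intron_len_range[0] < 0:
            raise ValueError("impossible exon/intron length range")
        if self.enrichment_ratio < 0:
            raise ValueError("enrichment_ratio must be >= 0")


def random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate(seq: str, sub_rate: float, indel_rate: float,
           rng: np.random.Generator) -> str:
    """Per-site Bernoulli substitutions (uniform alternative base) plus
    geometric-length indels (mean 3 bp), the simple divergence model the
    alignment and gapped-identity machinery needs to be exercised on."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    if sub_rate > 0:
        hit = rng.random(len(arr)) < sub_rate
        n = int(hit.sum())
        if n:
            shifts = rng.integers(1, 4, size=n)
            base_idx = np.searchsorted(_BASES, arr[hit])
            arr[hit] = _BASES[(base_idx + shifts) % 4]
    out = arr.tobytes().decode()
    if indel_rate > 0:
        n_indels = rng.binomial(len(out), indel_rate)
        for _ in range(n_indels):
            if len(out) < 10:
                break
            pos = int(rng.integers(1, len(out)))
            length = int(rng.geometric(1 / 3))
            if rng.random() < 0.5:
                out = out[:pos] + random_seq(rng, length) + out[pos:]
            else:
                out = out[:pos] + out[pos + length:]
    return out


@dataclass
class SimLocus:
    locus_id: str
    category: str                       # markerminer/universal/published/functional
    membership: str                     # genomeA/genomeB/both (markerminer only)
    exon_lengths: list[int]
    intron_lengths: list[int]
    violates_filter: bool
    organelle_planted: bool
    divergence_factor: float
    ancestral_transcript: str
    ancestral_genomic: str
    clade_transcript: dict[str, str]
    clade_genomic: dict[str, str]
    duplicate_of: str | None = None


@dataclass
class GeneSpace:
    cfg: SimConfig
    loci: dict[str, SimLocus]
    transcriptomes: dict[str, list[SequenceRecord]]
    gene_models: dict[str, GeneModel]
    #: per reference genome: candidate locus id -> {transcriptome: transcript_id}
    candidates: dict[str, dict[str, dict[str, str]]]
    universal: dict[str, list[tuple[str, SequenceRecord]]]
    published_queries: list[SequenceRecord]
    functional_queries: list[SequenceRecord]
    plastid: str
    mito: str
    nuclear_decoy: str
    off_target_genome: str
    truth: pd.DataFrame = field(repr=False, default=None)


def true_locus_of(registry_locus_id: str) -> str:
    """Strip source namespacing, per-genome prefixes and duplicate suffixes
    from a registry locus id, recovering the simulated locus id."""
    lid = registry_locus_id
    for method in ("markerminer", "universal", "published", "functional"):
        prefix = f"{method}__"
        if lid.startswith(prefix):
            lid = lid[len(prefix):]
    if ":" in lid:
        lid = lid.split(":", 1)[1]
    for prefix in ("pub_", "fun_"):
        if lid.startswith(prefix):
            lid = lid[len(prefix):]
    if lid.endswith("_dup"):
        lid = lid[:-4]
    return lid


def _segment_mutate(exons: list[str], introns: list[str], sub_rate: float,
                    indel_rate: float, rng: np.random.Generator):
    """Mutate exon and intron segments independently so the spliced
    transcript stays consistent with the genomic sequence."""
    mex = [mutate(e, sub_rate, indel_rate, rng) for e in exons]
    mint = [mutate(i, sub_rate, indel_rate, rng) for i in introns]
    genomic = []
    for i, e in enumerate(mex):
        genomic.append(e)
        if i < len(mint):
            genomic.append(mint[i])
    return mex, mint, "".join(mex), "".join(genomic)


ORGANELLE_SEGMENT_LEN = 200


def make_gene_space(cfg: SimConfig) -> GeneSpace:
    """Build the full synthetic input bundle deterministically from
    ``cfg.seed``. See the module docstring for what is planted."""
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_loci
    n_published = max(1, round(0.03 * n)) if n >= 8 else (1 if n >= 4 else 0)
    n_functional = max(1, round(0.02 * n)) if n >= 8 else (1 if n >= 6 else 0)
    n_universal = max(1, round(0.3 * n)) if n >= 4 else 0
    n_mm = n - n_published - n_functional - n_universal
    if n_mm < 1:
        raise ValueError("n_loci too small to populate all locus sources")
    categories = (["markerminer"] * n_mm + ["universal"] * n_universal
                  + ["published"] * n_published + ["functional"] * n_functional)

    n_violations = round(cfg.frac_violations * n_mm)
    plastid_core = random_seq(rng, cfg.organelle_len)
    # deterministic contamination quota: the screens need planted
    # positives to exist whenever the fraction is nonzero
    organelle_quota = (max(1, round(cfg.frac_organelle_planted * n))
                       if cfg.frac_organelle_planted > 0 else 0)
    n_organelle_planted = 0

    loci: dict[str, SimLocus] = {}
    for i, category in enumerate(categories):
        locus_id = f"locus{i:03d}"
        violates = category == "markerminer" and i < n_violations
        n_exons = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
        exon_lengths = [int(rng.integers(max(cfg.exon_len_range[0], 125),
                                         cfg.exon_len_range[1] + 1))
                        for _ in range(n_exons)]
        intron_lengths = [int(rng.integers(cfg.intron_len_range[0],
                                           min(cfg.intron_len_range[1], 99) + 1))
                          for _ in range(n_exons - 1)]
        while sum(exon_lengths) < 520:
            exon_lengths[-1] += 100
        if violates:
            if n_exons > 1 and rng.random() < 0.5:
                intron_lengths[int(rng.integers(0, len(intron_lengths)))] = \
                    int(rng.integers(130, 250))
            else:
                # a short exon; the locus may additionally fall below the
                # minimum gene length, either filter must exclude it
                exon_lengths[int(rng.integers(0, n_exons))] = int(rng.integers(60, 101))

        exons = [random_seq(rng, L) for L in exon_lengths]
        introns = [random_seq(rng, L) for L in intron_lengths]

        organelle_planted = False
        if (category in ("markerminer", "universal") and not violates
                and n_organelle_planted < organelle_quota
                and i >= n_violations + 1):
            target = max(range(len(exons)), key=lambda j: len(exons[j]))
            if len(exons[target]) > ORGANELLE_SEGMENT_LEN + 40:
                seg_at = int(rng.integers(0, cfg.organelle_len - ORGANELLE_SEGMENT_LEN))
                segment = plastid_core[seg_at:seg_at + ORGANELLE_SEGMENT_LEN]
                mid = len(exons[target]) // 2
                exons[target] = (exons[target][:mid] + segment
                                 + exons[target][mid + ORGANELLE_SEGMENT_LEN:]) \
                    if len(exons[target]) >= mid + ORGANELLE_SEGMENT_LEN else \
                    exons[target][:mid] + segment + exons[target][mid:]
                exon_lengths[target] = len(exons[target])
                organelle_planted = True
                n_organelle_planted += 1

        factor = float(rng.uniform(1.0 - cfg.rate_heterogeneity,
                                   1.0 + cfg.rate_heterogeneity))
        if organelle_planted:
            # contamination screens are planted positives: keep these loci
            # slow-evolving so the planted segment stays above the screen's
            # identity threshold in every derived template
            factor = min(factor, 0.4)
        half = cfg.clade_divergence * factor / 2.0
        clade_transcript, clade_genomic = {}, {}
        for clade in CLADES:
            _, _, tr, gen = _segment_mutate(exons, introns, half, cfg.indel_rate, rng)
            clade_transcript[clade] = tr
            clade_genomic[clade] = gen

        genomic = []
        for j, e in enumerate(exons):
            genomic.append(e)
            if j < len(introns):
                genomic.append(introns[j])
        membership = "none"
        if category == "markerminer":
            draw = rng.random()
            membership = "both" if draw < 0.5 else ("genomeA" if draw < 0.75 else "genomeB")
        loci[locus_id] = SimLocus(
            locus_id=locus_id, category=category, membership=membership,
            exon_lengths=list(exon_lengths), intron_lengths=list(intron_lengths),
            violates_filter=violates, organelle_planted=organelle_planted,
            divergence_factor=factor,
            ancestral_transcript="".join(exons), ancestral_genomic="".join(genomic),
            clade_transcript=clade_transcript, clade_genomic=clade_genomic,
        )

    # transcriptomes: markerminer/published/functional loci, per-taxon divergence
    transcriptomes: dict[str, list[SequenceRecord]] = {t: [] for t in TRANSCRIPTOME_TAXA}
    gene_models: dict[str, GeneModel] = {}
    locus_transcripts: dict[str, dict[str, str]] = {}
    for locus in loci.values():
        if locus.category == "universal":
            continue
        draw = rng.random()
        present = list(TRANSCRIPTOME_TAXA) if draw < 0.7 else \
            [TRANSCRIPTOME_TAXA[0]] if draw < 0.85 else [TRANSCRIPTOME_TAXA[1]]
        locus_transcripts[locus.locus_id] = {}
        exons = _split_exons(locus.ancestral_transcript, locus.exon_lengths)
        for taxon in present:
            mex = [mutate(e, cfg.transcriptome_divergence, cfg.indel_rate / 2, rng)
                   for e in exons]
            tid = f"{taxon}_{locus.locus_id}"
            seq = "".join(mex)
            transcriptomes[taxon].append(SequenceRecord(tid, seq))
            gene_models[tid] = GeneModel(tid, [len(e) for e in mex],
                                         list(locus.intron_lengths), taxon)
            locus_transcripts[locus.locus_id][taxon] = tid

    # single-copy candidate lists per reference genome, with planted duplicates
    candidates: dict[str, dict[str, dict[str, str]]] = {"genomeA": {}, "genomeB": {}}
    mm_loci = [l for l in loci.values() if l.category == "markerminer"
               and locus_transcripts.get(l.locus_id)]
    for locus in mm_loci:
        hits = locus_transcripts[locus.locus_id]
        if locus.membership in ("genomeA", "both"):
            candidates["genomeA"][f"gA:{locus.locus_id}"] = dict(hits)
        if locus.membership in ("genomeB", "both"):
            candidates["genomeB"][f"gB:{locus.locus_id}"] = dict(hits)
    # keep planted signals disjoint: a duplicated locus never reaches the
    # organelle screen (multi-mapping reads starve it of contigs)
    dup_pool = [l for l in mm_loci if l.membership == "both"
                and not l.violates_filter and not l.organelle_planted]
    n_dups = min(round(cfg.frac_duplicates * n_mm), len(dup_pool))
    for locus in dup_pool[:n_dups]:
        candidates["genomeA"][f"gA:{locus.locus_id}_dup"] = \
            dict(candidates["genomeA"][f"gA:{locus.locus_id}"])
        locus.duplicate_of = locus.locus_id

    # universal locus set with taxon-source metadata
    universal: dict[str, list[tuple[str, SequenceRecord]]] = {}
    for locus in loci.values():
        if locus.category != "universal":
            continue
        n_taxa = int(rng.integers(1, 4))
        has_rosid = rng.random() < 0.7
        taxa = []
        if has_rosid:
            taxa.append(UNIVERSAL_TAXA[int(rng.integers(0, 2))])
        while len(taxa) < n_taxa:
            taxa.append(UNIVERSAL_TAXA[int(rng.integers(0, len(UNIVERSAL_TAXA)))])
        entries = []
        for j, taxon in enumerate(dict.fromkeys(taxa)):
            seq = mutate(locus.ancestral_transcript, 0.05, cfg.indel_rate, rng)
            entries.append((taxon, SequenceRecord(f"u_{locus.locus_id}_{taxon}", seq)))
        universal[locus.locus_id] = entries

    published_queries = [
        SequenceRecord(f"pub_{l.locus_id}", mutate(l.ancestral_transcript, 0.03,
                                                   cfg.indel_rate, rng))
        for l in loci.values() if l.category == "published"
        and locus_transcripts.get(l.locus_id)
    ]
    functional_queries = [
        SequenceRecord(f"fun_{l.locus_id}", mutate(l.ancestral_transcript, 0.03,
                                                   cfg.indel_rate, rng))
        for l in loci.values() if l.category == "functional"
        and locus_transcripts.get(l.locus_id)
    ]

    mito = random_seq(rng, cfg.organelle_len)
    nuclear_decoy = random_seq(rng, cfg.organelle_len)
    off_target_genome = random_seq(rng, max(4 * cfg.read_len, 30000))

    truth = pd.DataFrame([
        {
            "locus_id": l.locus_id, "category": l.category,
            "membership": l.membership, "violates_filter": l.violates_filter,
            "duplicate_planted": l.duplicate_of is not None,
            "organelle_planted": l.organelle_planted,
            "divergence_factor": l.divergence_factor,
            "in_transcriptomes": bool(locus_transcripts.get(l.locus_id)),
            "transcript_len": len(l.ancestral_transcript),
        }
        for l in loci.values()
    ])

    return GeneSpace(
        cfg=cfg, loci=loci, transcriptomes=transcriptomes,
        gene_models=gene_models, candidates=candidates, universal=universal,
        published_queries=published_queries, functional_queries=functional_queries,
        plastid=plastid_core, mito=mito, nuclear_decoy=nuclear_decoy,
        off_target_genome=off_target_genome, truth=truth,
    )


def _split_exons(transcript: str, exon_lengths: list[int]) -> list[str]:
    out, pos = [], 0
    for L in exon_lengths:
        out.append(transcript[pos:pos + L])
        pos += L
    return out


def clade_skim_genome(space: GeneSpace, clade: str) -> dict[str, str]:
    """The clade's genomic sequences (all loci), the substrate skims sample."""
    return {lid: locus.clade_genomic[clade] for lid, locus in space.loci.items()}


def _sequencing_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n:
        shifts = rng.integers(1, 4, size=n)
        base_idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(base_idx + shifts) % 4]
    return arr.tobytes().decode()


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_skim_reads(genome: dict[str, str], cfg: SimConfig,
                        seed: int | None = None, taxon: str = "skim") -> list[FastqRead]:
    """Uniform shotgun reads over ``genome`` at ``cfg.skim_coverage`` mean
    depth, random strand, substitution errors at ``cfg.read_error``,
    constant quality. Deterministic per seed."""
    if not genome:
        raise ValueError("empty genome")
    eligible = {k: v for k, v in genome.items() if len(v) >= cfg.read_len}
    if not eligible:
        raise ValueError(f"read_len {cfg.read_len} exceeds every genome sequence")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ids = sorted(eligible)
    lengths = np.array([len(eligible[i]) for i in ids], dtype=float)
    total = lengths.sum()
    n_reads = int(round(cfg.skim_coverage * total / cfg.read_len))
    probs = lengths / total
    reads: list[FastqRead] = []
    qual = "I" * cfg.read_len
    src = rng.choice(len(ids), size=n_reads, p=probs)
    for i in range(n_reads):
        sid = ids[src[i]]
        seq = eligible[sid]
        pos = int(rng.integers(0, len(seq) - cfg.read_len + 1))
        frag = seq[pos:pos + cfg.read_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = _revcomp(frag)
        frag = _sequencing_errors(frag, cfg.read_error, rng)
        reads.append(FastqRead(f"{taxon}|{sid}|{pos}|{strand}|r{i}", frag, qual))
    return reads


def simulate_capture_reads(
    targets: dict[str, str],
    off_target_genome: str,
    cfg: SimConfig,
    n_reads: int,
    seed: int | None = None,
    sample_id: str = "sample",
) -> tuple[list[FastqRead], int]:
    """Enrichment-biased capture reads.

    Each read is drawn from the target sequences with probability
    ratio/(1+ratio) (ratio = ``cfg.enrichment_ratio``; infinite ratio
    means no off-target reads), otherwise from the off-target genome.
    Returns (reads, true on-target count).
    """
    if not targets:
        raise ValueError("simulate_capture_reads requires nonempty targets")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    p_on = 1.0 if math.isinf(cfg.enrichment_ratio) else \
        cfg.enrichment_ratio / (1.0 + cfg.enrichment_ratio)
    ids = sorted(t for t in targets if len(targets[t]) >= cfg.read_len)
    if not ids:
        raise ValueError("every target shorter than read_len")
    lengths = np.array([len(targets[i]) for i in ids], dtype=float)
    probs = lengths / lengths.sum()
    qual = "I" * cfg.read_len
    reads: list[FastqRead] = []
    n_on = 0
    for i in range(n_reads):
        on_target = rng.random() < p_on
        if on_target and ids:
            sid = ids[int(rng.choice(len(ids), p=probs))]
            seq = targets[sid]
            origin = f"on|{sid}"
            n_on += 1
        else:
            sid, seq, origin = None, off_target_genome, "off|decoy"
        pos = int(rng.integers(0, len(seq) - cfg.read_len + 1))
        frag = seq[pos:pos + cfg.read_len]
        if rng.random() < 0.5:
            frag = _revcomp(frag)
        frag = _sequencing_errors(frag, cfg.read_error, rng)
        reads.append(FastqRead(f"{sample_id}|{origin}|r{i}", frag, qual))
    return reads, n_on


def make_capture_sample(space: GeneSpace, clade: str, sample_id: str,
                        n_reads: int, seed: int) -> tuple[list[FastqRead], int]:
    """Capture reads for one individual of a clade: targets are the
    clade's genomic locus sequences mutated at the within-clade
    (sample-level) divergence."""
    rng = np.random.default_rng(seed)
    targets = {
        lid: mutate(seq, space.cfg.sample_divergence, 0.0, rng)
        for lid, seq in sorted(clade_skim_genome(space, clade).items())
    }
    return simulate_capture_reads(
        targets, space.off_target_genome, space.cfg, n_reads,
        seed=seed + 1, sample_id=sample_id,
    )
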