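"""Turn final template sequences into a screened 120-bp probe panel.

Templates are first sanitized (alignment gaps removed, IUPAC ambiguity
codes resolved to the most frequent base in the locus alignment), then
tiled into fixed-length probes at 3x coverage (step = probe length / 3),
and screened: large homopolymer runs are rejected, and probes matching
organellar genomes or a nuclear decoy genome are excluded from the panel
and reported.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .core_io import (
    ConsistencyError,
    IUPAC_AMBIGUITY,
    LocusRegistry,
    UNAMBIGUOUS,
)
from .tier2 import SeedIndex, TemplateSequence, find_local_hit

logger = logging.getLogger("skimprobe")

PROBE_FLAGS = ("homopolymer", "organelle_hit", "nuclear_decoy_hit", "terminal")


@dataclass
class ProbeRecord:
    """A fixed-length probe on template coordinates (0-based half-open)."""

    probe_id: str
    template_id: str
    start: int
    end: int
    seq: str
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ConsistencyError(f"probe {self.probe_id}: interval/sequence mismatch")
        bad = set(self.seq) - UNAMBIGUOUS
        if bad:
            raise ConsistencyError(
                f"probe {self.probe_id}: unsanitized characters {sorted(bad)}"
            )
        unknown = self.flags - set(PROBE_FLAGS)
        if unknown:
            raise ConsistencyError(f"probe {self.probe_id}: unknown flags {sorted(unknown)}")


def sanitize_template(template_row: str,
                      alignment: dict[str, str] | None = None) -> str:
    """Clean a (possibly gapped, possibly ambiguous) template for tiling.

    Alignment gaps are removed. Each IUPAC ambiguity code is replaced by
    the most frequent unambiguous base in that alignment column among the
    compatible bases (tie -> alphabetically first compatible base); with
    no alignment, or a column holding no unambiguous base, the
    alphabetically first compatible base is used (logged). Idempotent:
    output is over {A,C,G,T}.
    """
    rows = list(alignment.values()) if alignment else []
    for row in rows:
        if len(row) != len(template_row):
            raise ConsistencyError("alignment rows must match template row length")
    out = []
    for col, ch in enumerate(template_row):
        if ch == "-":
            continue
        if ch in UNAMBIGUOUS:
            out.append(ch)
            continue
        compatible = IUPAC_AMBIGUITY.get(ch)
        if compatible is None:
            raise ConsistencyError(f"invalid template character {ch!r}")
        counts = Counter(
            row[col] for row in rows
            if row[col] in UNAMBIGUOUS and row[col] in compatible
        )
        if counts:
            best = max(counts, key=lambda b: (counts[b], -ord(b)))
            # tie -> alphabetically first: max on (count, -ord) does exactly that
            out.append(best)
        else:
            logger.debug("ambiguity %r at column %d: no unambiguous base in "
                         "alignment; using %r", ch, col, sorted(compatible)[0])
            out.append(sorted(compatible)[0])
    return "".join(out)


def tile_probes(template_id: str, seq: str, probe_len: int = 120,
                tiling: int = 3) -> list[ProbeRecord]:
    """Tile a sanitized template into probes at ``tiling``-fold coverage.

    Step = probe_len / tiling (40 bp for the defaults). Probes start at
    0, step, 2*step, ... while they fit; when the template length is not
    on the tiling grid a terminal probe flagged ``terminal`` is added at
    L - probe_len so the 3' end is never uncovered. Templates shorter
    than a probe yield no probes (warning).
    """
    if probe_len % tiling != 0:
        raise ValueError(f"tiling {tiling} does not divide probe length {probe_len}")
    step = probe_len // tiling
    L = len(seq)
    if L < probe_len:
        logger.warning("template %s (%d bp) shorter than probe length %d; no probes",
                       template_id, L, probe_len)
        return []
    probes = []
    offset = 0
    while offset + probe_len <= L:
        probes.append(ProbeRecord(
            f"{template_id}|p{len(probes)}", template_id,
            offset, offset + probe_len, seq[offset:offset + probe_len]))
        offset += step
    if (L - probe_len) % step != 0:
        start = L - probe_len
        probes.append(ProbeRecord(
            f"{template_id}|p{len(probes)}", template_id,
            start, L, seq[start:], flags={"terminal"}))
    return probes


def homopolymer_filter(seq: str, max_run: int = 10) -> bool:
    """True (keep) iff no single-base run reaches ``max_run``."""
    run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run >= max_run:
            return False
    return max_run > 1


def decoy_screen(
    probes: list[ProbeRecord],
    decoy_refs: dict[str, str],
    min_ident: float = 0.90,
    min_len: int = 60,
) -> tuple[list[ProbeRecord], list[ProbeRecord]]:
    """Screen probes against decoy references.

    ``decoy_refs`` maps any subset of {plastid, mito, nuclear_decoy} to a
    reference sequence. A probe matching a decoy (local alignment with
    identity >= ``min_ident`` over >= ``min_len`` columns) is flagged
    ``organelle_hit`` (plastid/mito) or ``nuclear_decoy_hit`` and
    excluded from the panel; flags are additive across decoy classes.
    Returns (kept, flagged).
    """
    known = {"plastid", "mito", "nuclear_decoy"}
    unknown = set(decoy_refs) - known
    if unknown:
        raise ValueError(f"unknown decoy classes {sorted(unknown)}")
    if not decoy_refs:
        logger.warning("decoy screen SKIPPED: no decoy references supplied")
        return list(probes), []
    indexes = {name: SeedIndex(seq) for name, seq in decoy_refs.items()}
    kept, flagged = [], []
    for p in probes:
        for name, idx in indexes.items():
            if find_local_hit(p.seq, idx, min_ident, min_len) is not None:
                p.flags.add("organelle_hit" if name in ("plastid", "mito")
                            else "nuclear_decoy_hit")
        if p.flags & {"organelle_hit", "nuclear_decoy_hit"}:
            flagged.append(p)
        else:
            kept.append(p)
    if flagged:
        logger.info("decoy screen: %d probes flagged", len(flagged))
    return kept, flagged


def panel_summary(
    probes: list[ProbeRecord],
    templates: list[TemplateSequence],
    registry: LocusRegistry,
) -> dict:
    """Bookkeeping summary of a probe panel.

    Returns locus/template/probe counts, the probes-per-template
    distribution, flag counts by class, and the template-multiplicity
    histogram (number of loci with 1, 2, 3, 4 templates). The identity
    n_templates = sum(multiplicity * loci) always holds.
    """
    template_ids = {t.template_id for t in templates}
    template_locus = {t.template_id: t.locus_id for t in templates}
    for t in templates:
        if t.locus_id not in registry:
            raise ConsistencyError(
                f"template {t.template_id} references unknown locus {t.locus_id}")
    for p in probes:
        if p.template_id not in template_ids:
            raise ConsistencyError(f"probe {p.probe_id}: dangling template id "
                                   f"{p.template_id!r}")
    per_template = Counter(p.template_id for p in probes)
    per_locus_templates = Counter(template_locus.values())
    multiplicity = Counter(per_locus_templates.values())
    flag_counts = Counter(flag for p in probes for flag in p.flags)
    return {
        "n_loci": len(per_locus_templates),
        "n_templates": len(template_ids),
        "n_probes": len(probes),
        "probes_per_template": dict(sorted(per_template.items())),
        "template_multiplicity": dict(sorted(multiplicity.items())),
        "flag_counts": dict(sorted(flag_counts.items())),
    }


def summary_frame(summary: dict) -> pd.DataFrame:
    rows = [("loci", summary["n_loci"]),
            ("templates", summary["n_templates"]),
            ("probes", summary["n_probes"])]
    rows += [(f"loci_with_{k}_templates", v)
             for k, v in summary["template_multiplicity"].items()]
    rows += [(f"flag_{k}", v) for k, v in summary["flag_counts"].items()]
    return pd.DataFrame(rows, columns=["statistic", "value"])


def build_panel(
    templates: list[TemplateSequence],
    alignments: dict[str, dict[str, str]] | None = None,
    decoy_refs: dict[str, str] | None = None,
    probe_len: int = 120,
    tiling: int = 3,
    max_homopolymer: int = 10,
    min_decoy_ident: float = 0.90,
    min_decoy_len: int = 60,
) -> tuple[list[TemplateSequence], list[ProbeRecord], list[ProbeRecord]]:
    """Sanitize, tile and screen a full template set.

    ``alignments`` maps locus id to its star alignment (used to resolve
    ambiguity codes). Returns (sanitized templates, kept probes, flagged
    probes); flagged probes carry their screen flags and appear only in
    the report.
    """
    sanitized = []
    for tpl in templates:
        aln = (alignments or {}).get(tpl.locus_id)
        row = tpl.seq
        if aln is not None and tpl.template_id in aln:
            row = aln[tpl.template_id]
        clean = sanitize_template(row, aln if (aln and tpl.template_id in aln) else None)
        sanitized.append(TemplateSequence(tpl.template_id, tpl.locus_id, clean,
                                          tpl.source_class, tpl.provenance))
    all_probes: list[ProbeRecord] = []
    for tpl in sanitized:
        all_probes.extend(tile_probes(tpl.template_id, tpl.seq, probe_len, tiling))
    kept, flagged = [], []
    for p in all_probes:
        if homopolymer_filter(p.seq, max_homopolymer):
            kept.append(p)
        else:
            p.flags.add("homopolymer")
            flagged.append(p)
    if decoy_refs:
        kept, decoy_flagged = decoy_screen(kept, decoy_refs,
                                           min_decoy_ident, min_decoy_len)
        flagged.extend(decoy_flagged)
    else:
        logger.warning("decoy screen SKIPPED: no decoy references supplied")
    return sanitized, kept, flagged
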