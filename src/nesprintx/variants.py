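"""Enumeration and assembly of alternatively transcribed variants.

Giant genes like the nesprins carry many internal alternative transcription
start and termination sites.  Combining any compatible 5' site with any 3'
site ("mix and match"), optionally modulated by cassette-exon inclusion
patterns, yields the variant space this module enumerates.  Each variant is
assembled into an mRNA (including any retained intronic extension at an
intron-retained 3' end) and a CDS anchored at the first viable-Kozak ATG of
its first coding exon.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from .errors import InputError, NoOrfError, NotFoundError, PatternError
from .gene_model import GeneModel, parse_label
from .orf import (
    CANONICAL_POLYA,
    NONCANONICAL_POLYA,
    STOP_CODONS,
    kozak_assess,
    translate_cds,
)

__all__ = [
    "UTRSite",
    "TranscriptVariant",
    "TranscriptAssembly",
    "make_variant",
    "enumerate_variants",
    "build_transcript",
    "apply_cassette_pattern",
]


@dataclass(frozen=True)
class UTRSite:
    """A candidate alternative 5' or 3' transcript end.

    ``anchor_exon`` is the first (5' side) or last (3' side) coding exon of
    transcripts using this site.  ``site_class`` distinguishes exonic ends
    from intron-retained ones; for a retained-intron 5' site the tail of the
    upstream intron (``retained_utr_len`` nt) is carried as 5'UTR.
    """

    name: str
    side: str  # "5'" or "3'"
    anchor_exon: str
    site_class: str = "exonic"  # or "intron_retained"
    evidence: tuple[str, ...] = ()
    validated: bool | None = None
    polya_tail_evidence: bool = False
    retained_utr_len: int = 60

    def __post_init__(self):
        if self.side not in {"5'", "3'"}:
            raise InputError(f"side must be 5' or 3', got {self.side!r}")
        if self.site_class not in {"exonic", "intron_retained"}:
            raise InputError(f"bad site class {self.site_class!r}")


@dataclass
class TranscriptVariant:
    """One enumerated isoform: a start site, an end site and a cassette
    inclusion pattern, realised as ordered genomic blocks."""

    start: UTRSite
    end: UTRSite
    cassette_pattern: dict[str, bool] = field(default_factory=dict)
    blocks: list[tuple[int, int]] = field(default_factory=list)
    retained_extension: tuple[int, int] | None = None
    hypothetical: bool = False
    included_labels: tuple[str, ...] = ()

    def included_exons(self, model: GeneModel) -> tuple[str, ...]:
        return self.included_labels

    @property
    def key(self):
        pattern = tuple(sorted(self.cassette_pattern.items()))
        return (
            parse_label(self.start.anchor_exon),
            self.start.site_class,
            parse_label(self.end.anchor_exon),
            self.end.site_class,
            pattern,
        )


def _retained_extension(
    model: GeneModel, last_exon: str, polya_window: int
) -> tuple[int, int]:
    """Genomic interval of the retained intronic extension at a 3' end.

    The transcript runs into the intron up to a nominal cleavage point 15 nt
    downstream of the first polyadenylation hexamer; if no signal lies within
    the window the extension spans min(intron, window).
    """
    _, istart, iend = model.intron_after(last_exon)
    intron = model.locus_seq[istart:iend]
    signals = set(CANONICAL_POLYA) | set(NONCANONICAL_POLYA)
    cut = None
    for off in range(min(len(intron), polya_window) - 5):
        if intron[off : off + 6] in signals:
            cut = min(off + 6 + 15, len(intron))
            break
    if cut is None:
        cut = min(len(intron), polya_window)
    return istart, istart + cut


def make_variant(
    model: GeneModel,
    start: UTRSite,
    end: UTRSite,
    cassette_pattern: dict[str, bool] | None = None,
    polya_window: int = 2000,
    hypothetical_cds_len: int = 5000,
) -> TranscriptVariant:
    """Construct a variant's genomic block structure from its sites."""
    if start.side != "5'" or end.side != "3'":
        raise InputError("make_variant needs a 5' start and a 3' end")
    i0 = model.exon_index(start.anchor_exon)
    i1 = model.exon_index(end.anchor_exon)
    if i0 > i1:
        raise InputError(
            f"start exon {start.anchor_exon} downstream of end exon "
            f"{end.anchor_exon}"
        )
    pattern = dict(cassette_pattern or {})
    for lab in pattern:
        exon = model.exon(lab)  # raises NotFoundError for unknown labels
        if not exon.cassette and not pattern[lab]:
            raise PatternError(f"cannot exclude constitutive exon {lab}")

    blocks: list[tuple[int, int]] = []
    included: list[str] = []
    if start.site_class == "intron_retained":
        if i0 == 0:
            raise InputError("no upstream intron before the first exon")
        prev = model.exons[i0 - 1]
        anchor = model.exons[i0]
        utr_start = max(prev.end, anchor.start - start.retained_utr_len)
        blocks.append((utr_start, anchor.start))
    for e in model.exons[i0 : i1 + 1]:
        if not pattern.get(e.label, True):
            continue
        blocks.append((e.start, e.end))
        included.append(e.label)

    extension = None
    if end.site_class == "intron_retained":
        extension = _retained_extension(model, end.anchor_exon, polya_window)

    cds_span = sum(e - s for s, e in blocks)
    return TranscriptVariant(
        start=start,
        end=end,
        cassette_pattern=pattern,
        blocks=blocks,
        retained_extension=extension,
        hypothetical=cds_span > hypothetical_cds_len,
        included_labels=tuple(included),
    )


def apply_cassette_pattern(
    model: GeneModel, variant: TranscriptVariant, pattern: dict[str, bool]
) -> TranscriptVariant:
    """Return a new variant with the given cassette inclusion pattern.

    Keys must name cassette exons of the model; attempting to exclude a
    constitutive exon raises :class:`PatternError`.
    """
    merged = dict(variant.cassette_pattern)
    merged.update(pattern)
    return make_variant(model, variant.start, variant.end, merged)


@dataclass
class TranscriptAssembly:
    """A built transcript: mRNA, CDS placement, and translation."""

    mrna: str
    blocks: list[tuple[int, int]]
    cds_start: int
    cds: str
    protein: str
    stop_offset: int | None
    non_stop: bool
    extension_offset: int | None
    weak_start: bool
    _tx_blocks: list[tuple[int, int, int]] = field(default_factory=list)

    def junction_offset(self, genomic_pos: int) -> int:
        """Transcript offset of the junction at a genomic position that lies
        between two retained blocks (e.g. where an excluded exon sat)."""
        off = 0
        for s, e, tx in self._tx_blocks:
            if e <= genomic_pos:
                off = tx + (e - s)
        return off


def build_transcript(
    model: GeneModel, variant: TranscriptVariant
) -> TranscriptAssembly:
    """Assemble the mRNA and CDS of a variant.

    The CDS starts at the first ATG of the first coding exon whose Kozak
    context is viable (falling back to the first ATG at all, flagged as a
    weak start) and runs to the first in-frame stop; a missing stop is
    reported via ``non_stop`` rather than raised.
    """
    all_blocks = list(variant.blocks)
    ext_off = None
    if variant.retained_extension is not None:
        ext_off = sum(e - s for s, e in all_blocks)
        all_blocks.append(variant.retained_extension)
    mrna_parts = []
    tx_blocks = []
    off = 0
    for s, e in all_blocks:
        mrna_parts.append(model.sequence(s, e))
        tx_blocks.append((s, e, off))
        off += e - s
    mrna = "".join(mrna_parts)

    # Locate the first coding exon's span within the transcript.
    anchor = model.exon(variant.start.anchor_exon)
    tx_anchor = None
    for s, e, tx in tx_blocks:
        if s == anchor.start:
            tx_anchor = (tx, tx + (e - s))
            break
    if tx_anchor is None:  # pragma: no cover - guarded by make_variant
        raise NoOrfError("first coding exon absent from transcript blocks")

    first_atg = None
    viable_atg = None
    pos = tx_anchor[0]
    while True:
        pos = mrna.find("ATG", pos, tx_anchor[1] - 2)
        if pos == -1:
            break
        if first_atg is None:
            first_atg = pos
        if pos + 4 <= len(mrna) and kozak_assess(mrna, pos).viable:
            viable_atg = pos
            break
        pos += 1
    if first_atg is None:
        raise NoOrfError(
            f"no ATG in first coding exon {variant.start.anchor_exon}"
        )
    cds_start = viable_atg if viable_atg is not None else first_atg
    weak_start = viable_atg is None

    stop_offset = None
    for i in range(cds_start, len(mrna) - 2, 3):
        if mrna[i : i + 3] in STOP_CODONS:
            stop_offset = i
            break
    non_stop = stop_offset is None
    cds = mrna[cds_start : (stop_offset + 3) if stop_offset is not None else len(mrna)]
    protein = translate_cds(cds) if len(cds) >= 3 else ""

    asm = TranscriptAssembly(
        mrna=mrna,
        blocks=all_blocks,
        cds_start=cds_start,
        cds=cds,
        protein=protein,
        stop_offset=stop_offset,
        non_stop=non_stop,
        extension_offset=ext_off,
        weak_start=weak_start,
        _tx_blocks=tx_blocks,
    )
    return asm


def enumerate_variants(
    model: GeneModel,
    starts: list[UTRSite],
    ends: list[UTRSite],
    cassette_patterns: list[dict[str, bool]] | None = None,
    dedup_protein_level: bool = True,
    polya_window: int = 2000,
) -> list[TranscriptVariant]:
    """Cross product of starts x ends x cassette patterns.

    Pairs whose start lies downstream of their end are silently filtered.
    With protein-level deduplication (default), variants whose CDS strings
    are identical collapse to one representative — alternative 5'UTRs that
    encode the same protein count once, as isoform tallies do.
    """
    patterns = cassette_patterns if cassette_patterns else [{}]
    starts_sorted = sorted(starts, key=lambda s: parse_label(s.anchor_exon))
    ends_sorted = sorted(ends, key=lambda s: parse_label(s.anchor_exon))

    out: list[TranscriptVariant] = []
    seen_cds: set[str] = set()
    seen_keys: set = set()
    for start, end, pattern in itertools.product(
        starts_sorted, ends_sorted, patterns
    ):
        if parse_label(start.anchor_exon) > parse_label(end.anchor_exon):
            continue
        # Restrict the pattern to cassette exons inside the variant's span.
        lo = parse_label(start.anchor_exon)
        hi = parse_label(end.anchor_exon)
        local = {
            lab: inc
            for lab, inc in pattern.items()
            if lo <= parse_label(lab) <= hi
        }
        variant = make_variant(
            model, start, end, local, polya_window=polya_window
        )
        if variant.key in seen_keys:
            continue
        seen_keys.add(variant.key)
        if dedup_protein_level:
            try:
                cds = build_transcript(model, variant).cds
            except NoOrfError:
                cds = None
            if cds is not None:
                if cds in seen_cds:
                    continue
                seen_cds.add(cds)
        out.append(variant)
    return out
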