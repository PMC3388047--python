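"""Open-reading-frame annotation of transcript variants.

This module holds the translation-level science of the pipeline:

* retained-intron readthrough translation, which yields the short unique
  C-terminal "fingerprint" peptides that distinguish prematurely
  terminating variants from the giant isoform;
* frameshift analysis of cassette-exon exclusion, which can replace the
  canonical C-terminus (including the KASH domain) with a novel tail;
* Kozak-context scoring of candidate initiation codons and hexamer scanning
  for polyadenylation signals, the two validation rules applied to candidate
  5' and 3' UTRs;
* average molecular mass and domain composition, from which variant names
  of the form ``p53KASH^Nesp1`` are assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .errors import InputError, MassError, NotFoundError, ParameterError
from .gene_model import DomainAnnotation, GeneModel, parse_label

if TYPE_CHECKING:  # pragma: no cover
    from .variants import TranscriptVariant, UTRSite

# ---------------------------------------------------------------------------
# Genetic code and residue masses
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    a + b + c: aa
    for aa, (a, b, c) in zip(
        _AA_ORDER, ((a, b, c) for a in _BASES for b in _BASES for c in _BASES)
    )
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

#: Most-frequent human codon per residue, used to back-translate printed
#: peptides into fixture DNA.  Any synonymous choice would do; this table
#: avoids generating AAT/AAA-containing codons that could spell accidental
#: polyadenylation hexamers inside coding sequence.
PREFERRED_CODON: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

#: Average (not monoisotopic) residue masses in Da, Expasy ProtParam values.
RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: Canonical polyadenylation signal hexamers.
CANONICAL_POLYA = ("AATAAA", "ATTAAA")
#: The ten most common single-substitution human variants of AATAAA.
NONCANONICAL_POLYA = (
    "AGTAAA", "TATAAA", "CATAAA", "GATAAA", "AATATA",
    "AATACA", "AATAGA", "AAAAAG", "ACTAAA", "AATGAA",
)


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, stopping at the first stop.

    Codons containing N (or any non-ACGT base) translate to X; a trailing
    partial codon is ignored.
    """
    if len(cds) < 3:
        raise InputError(f"CDS shorter than one codon: {len(cds)} nt")
    cds = cds.upper()
    aa = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            break
        aa.append(CODON_TABLE.get(codon, "X"))
    return "".join(aa)


def back_translate(peptide: str) -> str:
    """Deterministic DNA for a peptide using the preferred-codon table."""
    try:
        return "".join(PREFERRED_CODON[aa] for aa in peptide)
    except KeyError as exc:
        raise InputError(f"cannot back-translate residue {exc}") from None


def molecular_weight(aa: str) -> float:
    """Average molecular mass of an unmodified peptide chain in Da.

    Sum of average residue masses plus one water; additive under
    concatenation up to one water per join.
    """
    if not aa:
        raise MassError("empty peptide has no mass")
    try:
        return sum(RESIDUE_MASS[r] for r in aa) + WATER_MASS
    except KeyError:
        bad = sorted(set(aa) - set(RESIDUE_MASS))
        raise MassError(f"no average mass for residue(s) {bad}") from None


# ---------------------------------------------------------------------------
# Kozak context
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KozakAssessment:
    """Scored initiation context, positions -6..+4 around an ATG.

    The score rewards matches to the gccRccATGG consensus: +3 for a purine
    at -3, +3 for G at +4, and +1 for each match to g/c/c/c/c at the five
    remaining upstream positions (maximum 11).  ``viable`` follows the
    adequate-context rule: a purine at -3 OR a G at +4 suffices.
    """

    position: int
    score: int
    viable: bool
    context: str


def kozak_assess(transcript: str, atg_offset: int) -> KozakAssessment:
    """Assess the Kozak context of the ATG at ``atg_offset``.

    The context window is the 10-mer from -6 to +4 (ATG at indices 6..8);
    windows truncated by the transcript start are padded with N, which never
    matches the consensus.
    """
    seq = transcript.upper()
    if atg_offset < 0 or atg_offset + 4 > len(seq):
        raise InputError("ATG context window extends past transcript end")
    if seq[atg_offset : atg_offset + 3] != "ATG":
        raise InputError(f"no ATG at offset {atg_offset}")
    left = seq[max(0, atg_offset - 6) : atg_offset]
    context = "N" * (6 - len(left)) + left + seq[atg_offset : atg_offset + 4]

    score = 0
    minus3, plus4 = context[3], context[9]
    purine_m3 = minus3 in "AG"
    if purine_m3:
        score += 3
    if plus4 == "G":
        score += 3
    for idx, want in ((0, "G"), (1, "C"), (2, "C"), (4, "C"), (5, "C")):
        if context[idx] == want:
            score += 1
    return KozakAssessment(
        position=atg_offset,
        score=score,
        viable=purine_m3 or plus4 == "G",
        context=context,
    )


# ---------------------------------------------------------------------------
# Polyadenylation signals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolyASignalHit:
    hexamer: str
    offset_from_stop: int
    canonical: bool


def scan_polya(
    seq_downstream_of_stop: str,
    window: int = 2000,
    noncanonical: tuple[str, ...] = NONCANONICAL_POLYA,
) -> list[PolyASignalHit]:
    """All polyadenylation-signal hexamers within ``window`` nt of the stop.

    Canonical signals are AATAAA and ATTAAA; the non-canonical set defaults
    to the ten most common human variants.  Hits are ordered by offset.
    """
    if window < 6:
        raise ParameterError("window must be at least one hexamer")
    region = seq_downstream_of_stop.upper()[:window]
    signals = {h: True for h in CANONICAL_POLYA}
    signals.update({h: False for h in noncanonical})
    hits = []
    for off in range(len(region) - 5):
        hexamer = region[off : off + 6]
        if hexamer in signals:
            hits.append(
                PolyASignalHit(
                    hexamer=hexamer,
                    offset_from_stop=off,
                    canonical=signals[hexamer],
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Readthrough fingerprints and frameshift tails
# ---------------------------------------------------------------------------


@dataclass
class ReadthroughResult:
    """Outcome of translating past the last exon into a retained intron."""

    fingerprint: str
    stop_offset: int | None  # nt from the exon/intron boundary to the stop
    non_stop: bool = False


def readthrough_translate(model: GeneModel, variant) -> ReadthroughResult:
    """Fingerprint peptide produced by reading into a retained terminal intron.

    Translation continues from the reading frame at the last coding exon's 3'
    boundary into the retained intronic extension until the first in-frame
    stop.  The fingerprint is the run of residues encoded entirely within the
    intron, e.g. the 8-residue AGAGYPHQ peptide of variants terminating in
    the intron after nesprin-1 exon 90.
    """
    from .variants import build_transcript

    if variant.end.site_class != "intron_retained":
        raise InputError("variant does not terminate in a retained intron")
    asm = build_transcript(model, variant)
    boundary = asm.extension_offset
    if boundary is None:
        raise InputError("variant has no retained intronic extension")
    if asm.non_stop or asm.stop_offset is None or asm.stop_offset < boundary:
        # No in-frame stop inside the intron (or CDS already closed upstream).
        if asm.stop_offset is not None and asm.stop_offset < boundary:
            return ReadthroughResult(fingerprint="", stop_offset=None)
        return ReadthroughResult(fingerprint="", stop_offset=None, non_stop=True)
    stop_offset = asm.stop_offset - boundary
    # Residues whose codons lie entirely within the intronic extension.
    fingerprint = []
    pos = asm.cds_start
    for res in asm.protein:
        if pos >= boundary:
            fingerprint.append(res)
        pos += 3
    return ReadthroughResult(
        fingerprint="".join(fingerprint), stop_offset=stop_offset
    )


@dataclass
class FrameshiftResult:
    """Effect of cassette-exon exclusion on the C-terminus."""

    tail: str
    frameshift: bool
    lost_domains: list[str] = field(default_factory=list)
    excluded_length: int = 0


def frameshift_tail(model: GeneModel, variant) -> FrameshiftResult:
    """C-terminal consequences of the cassette exclusions in a variant.

    A frameshift occurs iff the total excluded length is not a multiple of
    three; the tail is then the novel residue run from the shift point to the
    first new stop (e.g. VHKRWLRFLPF after excluding nesprin-1 exon 145).
    Without a frameshift the downstream residues are unchanged and the tail
    simply reports the canonical C-terminal continuation.  Domains annotated
    at or downstream of the shift point are reported lost.
    """
    from .variants import build_transcript

    excluded = [
        lab
        for lab, inc in sorted(
            variant.cassette_pattern.items(), key=lambda kv: parse_label(kv[0])
        )
        if not inc
    ]
    if not excluded:
        raise InputError("variant excludes no cassette exons")
    total = sum(model.exon(lab).length for lab in excluded)
    shift = total % 3 != 0

    # Shift point: the transcript junction left by the first exclusion that
    # breaks the frame (or by the first exclusion at all when in frame).
    cum = 0
    shift_exon = excluded[0]
    for lab in excluded:
        cum += model.exon(lab).length
        if cum % 3 != 0:
            shift_exon = lab
            break

    asm = build_transcript(model, variant)
    junction = asm.junction_offset(model.exon(shift_exon).start)
    tail = []
    pos = asm.cds_start
    for res in asm.protein:
        if pos >= junction:
            tail.append(res)
        pos += 3

    lost: list[str] = []
    if shift:
        shift_key = parse_label(shift_exon)
        for d in model.domains:
            if parse_label(d.exon_span[1]) >= shift_key:
                name = d.kind if d.sr_index is None else f"SR{d.sr_index}"
                if name not in lost:
                    lost.append(name)
    return FrameshiftResult(
        tail="".join(tail),
        frameshift=shift,
        lost_domains=lost,
        excluded_length=total,
    )


# ---------------------------------------------------------------------------
# Domain composition and nomenclature
# ---------------------------------------------------------------------------


@dataclass
class DomainComposition:
    has_CH: bool
    sr_count: int
    has_KASH: bool
    delta_KASH: bool = False
    partial: list[str] = field(default_factory=list)


def domain_composition(variant, model: GeneModel) -> DomainComposition:
    """Domains present in a variant's coding exon blocks.

    A domain counts as present iff every exon of its span is included in the
    variant; spans that are only partially covered are listed in ``partial``.
    ``delta_KASH`` is set separately from :func:`frameshift_tail` evidence.
    """
    included = set(variant.included_exons(model))
    comp = DomainComposition(has_CH=False, sr_count=0, has_KASH=False)
    for d in model.domains:
        lo, hi = parse_label(d.exon_span[0]), parse_label(d.exon_span[1])
        span = {
            e.label for e in model.exons if lo <= parse_label(e.label) <= hi
        }
        if span <= included:
            if d.kind == "CH":
                comp.has_CH = True
            elif d.kind == "SR":
                comp.sr_count += 1
            elif d.kind == "KASH":
                comp.has_KASH = True
        elif span & included:
            name = d.kind if d.sr_index is None else f"SR{d.sr_index}"
            comp.partial.append(name)
    return comp


@dataclass
class ProteinProduct:
    """A translated variant with its naming-relevant annotations."""

    sequence: str
    fingerprint: str
    mass: float
    has_CH: bool
    sr_count: int
    has_KASH: bool
    delta_KASH: bool = False
    name: str = ""
    giant_like: bool = False
    hypothetical: bool = False

    def __post_init__(self):
        if self.sequence and self.mass <= 0:
            raise MassError("non-empty product must have positive mass")
        if self.fingerprint and not self.sequence.endswith(self.fingerprint):
            raise InputError("fingerprint must be a suffix of the sequence")
        if self.delta_KASH and self.has_KASH:
            raise InputError("delta_KASH product cannot retain KASH")


def name_variant(product: ProteinProduct, gene_short: str) -> str:
    """Molecular-weight / domain-composition name, e.g. ``p53KASH^Nesp1``.

    The prefix is the average mass rounded to the nearest kDa; the tag names
    the defining domain content: CH for actin-binding variants (taking
    precedence for giant-like products that also retain KASH), KASH for
    nuclear-envelope variants, ΔKASH for variants that lost the KASH domain
    through splicing, and no tag for pure spectrin-repeat variants.
    """
    kda = round(product.mass / 1000)
    if product.has_CH:
        tag = "CH"
    elif product.delta_KASH:
        tag = "ΔKASH"
    elif product.has_KASH:
        tag = "KASH"
    else:
        tag = ""
    return f"p{kda}{tag}^{gene_short}"


def disambiguate_names(names: list[str]) -> list[str]:
    """Machine-safe names: equal names gain lowercase a/b/... suffixes."""
    from collections import Counter

    totals = Counter(names)
    seen: Counter = Counter()
    out = []
    for n in names:
        if totals[n] > 1:
            suffix = chr(ord("a") + seen[n])
            seen[n] += 1
            out.append(f"{n}{suffix}")
        else:
            out.append(n)
    return out


# ---------------------------------------------------------------------------
# UTR validation
# ---------------------------------------------------------------------------


def validate_utr(site, model: GeneModel, polya_window: int = 2000):
    """Apply the discovery validation rules to a candidate UTR site.

    A 5' site is accepted when the first ATG of its first coding exon has a
    viable Kozak context (assessed in genomic context).  A 3' site is
    accepted when its evidence already includes a poly(A) tail, or when at
    least one polyadenylation-signal hexamer lies within ``polya_window`` nt
    downstream of the reading frame's stop codon (located by assembling a
    minimal transcript ending at the site; if no frame can be anchored, the
    scan starts at the anchor exon's end instead).  Returns a copy with
    ``validated`` set.
    """
    from dataclasses import replace

    from .errors import NoOrfError
    from .variants import UTRSite, build_transcript, make_variant

    exon = model.exon(site.anchor_exon)
    if site.side == "5'":
        seq = model.locus_seq
        off = seq.find("ATG", exon.start, exon.end - 3)
        ok = False
        if off != -1 and off + 4 <= len(seq):
            ok = kozak_assess(seq, off).viable
        return replace(site, validated=ok)
    if site.side == "3'":
        if site.polya_tail_evidence:
            return replace(site, validated=True)
        scan_from = exon.end
        try:
            first = model.exons[0]
            start = UTRSite("_tmp", "5'", first.label, "exonic")
            asm = build_transcript(
                model,
                make_variant(model, start, site, polya_window=polya_window),
            )
            if asm.stop_offset is not None:
                # Map the transcript offset just past the stop codon back to
                # a genomic position within its block.
                tx = asm.stop_offset + 3
                for s, e, t in asm._tx_blocks:
                    if t <= tx <= t + (e - s):
                        scan_from = s + (tx - t)
        except (NoOrfError, NotFoundError):
            pass
        downstream = model.locus_seq[scan_from : scan_from + polya_window]
        return replace(site, validated=bool(scan_polya(downstream, polya_window)))
    raise NotFoundError(f"unknown UTR side {site.side!r}")
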