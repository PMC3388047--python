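"""Genome-anchored gene models for giant multi-exon genes.

A :class:`GeneModel` holds the ordered, numbered exons of one gene together
with sequence access in *transcription orientation*: minus-strand genes are
normalised at load time so that every downstream stage (EST mapping, variant
assembly, translation) sees a single forward coordinate system.

Coordinate conventions
----------------------
Internally all coordinates are 0-based half-open offsets into the
transcription-oriented locus sequence.  GFF3 input/output uses the standard
1-based inclusive coordinates on the reference strand.

Exon labels follow the community numbering style of the nesprin genes:
integer ranks ("93") optionally primed ("6'") for cassette exons that sit
between two constitutive exons.  Introns are addressed by the labels of
their flanking exons, e.g. "14/15".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    BoundsError,
    ModelError,
    NotFoundError,
    OrientationError,
    ParameterError,
)

_PRIME_CHARS = "'′"  # ASCII apostrophe and typographic prime
_LABEL_RE = re.compile(r"^(\d+)(['′]?)$")

PRIME = "'"
_FIVE = "5′"
_THREE = "3′"


def parse_label(label: str) -> tuple[int, int]:
    """Return the sort key ``(rank, primed)`` of an exon label.

    Primed exons sort immediately after their unprimed rank, matching the
    genomic placement of cassette exons such as 6' between exons 6 and 7.
    """
    m = _LABEL_RE.match(label)
    if not m:
        raise NotFoundError(f"malformed exon label: {label!r}")
    return int(m.group(1)), 1 if m.group(2) else 0


def normalize_label(label: str) -> str:
    """Canonicalise the prime character of an exon label to ASCII ``'``."""
    rank, primed = parse_label(label)
    return f"{rank}{PRIME if primed else ''}"


@dataclass(frozen=True)
class Exon:
    """One exon in transcription orientation (local 0-based half-open)."""

    label: str
    start: int
    end: int
    cassette: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ModelError(
                f"exon {self.label}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein domain mapped to an inclusive exon range.

    kind is one of CH (paired calponin-homology actin-binding domains),
    SR (one spectrin repeat of the central rod) or KASH (the C-terminal
    nuclear-envelope targeting domain).
    """

    kind: str
    exon_span: tuple[str, str]
    sr_index: int | None = None

    def __post_init__(self):
        if self.kind not in {"CH", "SR", "KASH"}:
            raise ModelError(f"unknown domain kind {self.kind!r}")


@dataclass
class GeneModel:
    """A gene locus with ordered exons and transcription-oriented sequence."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon]
    locus_seq: str
    domains: list[DomainAnnotation] = field(default_factory=list)
    contig_len: int = 0  # reference contig length, for GFF round-trip

    def __post_init__(self):
        if self.strand not in "+-":
            raise ModelError(f"bad strand {self.strand!r}")
        if not self.contig_len:
            self.contig_len = len(self.locus_seq)
        self.locus_seq = self.locus_seq.upper()
        if set(self.locus_seq) - set("ACGTN"):
            raise ModelError("locus sequence contains non-ACGTN characters")
        self._check_exons()
        self._exon_by_label = {e.label: e for e in self.exons}
        self._check_domains()
        # canonical domain order so constructed and loaded models compare equal
        self.domains = sorted(
            self.domains, key=lambda d: (d.kind, d.sr_index or 0)
        )

    # -- validation --------------------------------------------------------

    def _check_exons(self):
        labels = [e.label for e in self.exons]
        if len(set(labels)) != len(labels):
            raise ModelError("duplicate exon labels")
        keys = [parse_label(lab) for lab in labels]
        if keys != sorted(keys):
            raise ModelError("exon labels not in transcription order")
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise ModelError(f"exon {e.label} overlaps its predecessor")
            if e.start == prev_end and prev_end >= 0:
                raise ModelError(f"zero-length intron before exon {e.label}")
            if e.end > len(self.locus_seq):
                raise BoundsError(
                    f"exon {e.label} end {e.end} beyond locus length "
                    f"{len(self.locus_seq)}"
                )
            prev_end = e.end

    def _check_domains(self):
        sr_domains = []
        for d in self.domains:
            for lab in d.exon_span:
                if lab not in self._exon_by_label:
                    raise ModelError(
                        f"domain {d.kind} references unknown exon {lab!r}"
                    )
            if parse_label(d.exon_span[0]) > parse_label(d.exon_span[1]):
                raise ModelError(f"domain {d.kind} span reversed")
            if d.kind == "SR":
                if d.sr_index is None:
                    raise ModelError("SR domain without sr_index")
                sr_domains.append(d)
            if d.kind == "KASH":
                if d.exon_span[1] != self.exons[-1].label:
                    raise ModelError("KASH domain span must be terminal")
        # SR indices must strictly increase in genomic span order
        sr_domains.sort(key=lambda d: parse_label(d.exon_span[0]))
        sr_indices = [d.sr_index for d in sr_domains]
        if sr_indices != sorted(set(sr_indices)):
            raise ModelError("SR indices must strictly increase along the gene")

    # -- queries -----------------------------------------------------------

    @property
    def exon_labels(self) -> list[str]:
        return [e.label for e in self.exons]

    def exon(self, label: str) -> Exon:
        try:
            return self._exon_by_label[normalize_label(label)]
        except KeyError:
            raise NotFoundError(f"no exon labelled {label!r}") from None

    def exon_index(self, label: str) -> int:
        lab = normalize_label(label)
        for i, e in enumerate(self.exons):
            if e.label == lab:
                return i
        raise NotFoundError(f"no exon labelled {label!r}")

    def introns(self) -> list[tuple[str, int, int]]:
        """All introns as ``(label, start, end)`` with labels like ``"14/15"``."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append((f"{a.label}/{b.label}", a.end, b.start))
        return out

    def intron(self, label: str) -> tuple[int, int]:
        want = "/".join(normalize_label(p) for p in label.split("/"))
        for lab, s, e in self.introns():
            if lab == want:
                return s, e
        raise NotFoundError(f"no intron labelled {label!r}")

    def intron_after(self, exon_label: str) -> tuple[str, int, int]:
        """The intron immediately downstream of the given exon."""
        i = self.exon_index(exon_label)
        if i == len(self.exons) - 1:
            raise NotFoundError(f"exon {exon_label!r} is terminal; no intron")
        lab = f"{self.exons[i].label}/{self.exons[i + 1].label}"
        return lab, self.exons[i].end, self.exons[i + 1].start

    def sequence(self, start: int, end: int) -> str:
        if start < 0 or end > len(self.locus_seq) or start > end:
            raise BoundsError(f"interval [{start}, {end}) outside locus")
        return self.locus_seq[start:end]

    def exon_seq(self, label: str) -> str:
        e = self.exon(label)
        return self.locus_seq[e.start : e.end]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def segment_sequence(model: GeneModel, kind: str, label: str) -> str:
    """Sequence of one exon or intron, in transcription orientation."""
    if kind == "exon":
        return model.exon_seq(label)
    if kind == "intron":
        s, e = model.intron(label)
        return model.locus_seq[s:e]
    raise ParameterError(f"kind must be 'exon' or 'intron', got {kind!r}")


def tile_queries(
    sequence: str, window: int = 1000, step: int = 500
) -> list[tuple[int, int, str]]:
    """Overlapping query windows covering a sequence.

    Consecutive windows overlap by ``window - step``; when the sequence length
    is not a multiple of the step the final window is shifted left so that the
    union of windows covers [0, L) exactly.  Sequences shorter than one window
    yield a single full-length window.
    """
    if window <= step or step <= 0:
        raise ParameterError(f"require window > step > 0, got {window}, {step}")
    L = len(sequence)
    if L < 1:
        raise ParameterError("sequence must be non-empty")
    if L <= window:
        return [(0, L, sequence[:L])]
    starts = list(range(0, L - window + 1, step))
    if starts[-1] + window < L:
        starts.append(L - window)
    return [(s, s + window, sequence[s : s + window]) for s in starts]


def format_utr_name(gene_short: str, side: str, anchor: str) -> str:
    """Paper-convention UTR name, e.g. ``N1-5'I14/15`` or ``N1-3'E62``.

    side accepts "5'"/"3'" in ASCII or typographic-prime form; the returned
    name uses the typographic prime.  Intron anchors use the ``a/b`` form
    between flanking exon ranks.
    """
    side_norm = side.replace("′", "'").replace("p", "'")
    if side_norm not in {"5'", "3'"}:
        raise ParameterError(f"side must be 5' or 3', got {side!r}")
    side_out = _FIVE if side_norm == "5'" else _THREE
    if "/" in anchor:
        parts = [normalize_label(p) for p in anchor.split("/")]
        return f"{gene_short}-{side_out}I{'/'.join(parts)}"
    return f"{gene_short}-{side_out}E{normalize_label(anchor)}"


def primer_pair_spans_intron(
    model: GeneModel, fwd: tuple[int, int], rev: tuple[int, int]
) -> bool:
    """True iff at least one annotated intron lies strictly between primers.

    Intron-spanning primer pairs distinguish cDNA amplicons from genomic DNA
    contamination; both primer intervals are local transcription-oriented
    coordinates and the forward primer must precede the reverse one.
    """
    for name, iv in (("fwd", fwd), ("rev", rev)):
        if iv[0] < 0 or iv[1] > len(model.locus_seq) or iv[0] >= iv[1]:
            raise BoundsError(f"{name} primer interval {iv} outside locus")
    if rev[0] < fwd[1]:
        raise OrientationError(
            "reverse primer does not lie downstream of forward primer"
        )
    gap = (fwd[1], rev[0])
    for _, s, e in model.introns():
        if s >= gap[0] and e <= gap[1]:
            return True
    return False


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O
# ---------------------------------------------------------------------------


def load_gene(gff_path: str, fasta_path: str, gene_id: str) -> GeneModel:
    """Load one gene from GFF3 + genome FASTA.

    Exon features must carry an ``exon_label`` attribute; optional ``domain``
    features carry ``kind``, ``exon_span`` (``a-b``) and ``sr_index``.
    Minus-strand genes are normalised: the contig is reverse-complemented and
    coordinates mirrored so the model reads in transcription orientation.
    """
    import gffutils

    db = gffutils.create_db(
        gff_path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    try:
        gene = db[gene_id]
    except Exception:
        raise NotFoundError(f"gene {gene_id!r} not found in {gff_path}") from None

    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    if gene.seqid not in contigs:
        raise NotFoundError(f"contig {gene.seqid!r} not in {fasta_path}")
    contig = contigs[gene.seqid]
    L = len(contig)
    strand = gene.strand if gene.strand in "+-" else "+"

    raw_exons = []
    for feat in db.children(gene, featuretype="exon"):
        label = feat.attributes.get("exon_label", [None])[0]
        if label is None:
            raise ModelError(f"exon at {feat.start}-{feat.end} lacks exon_label")
        start0, end0 = feat.start - 1, feat.end  # GFF3 1-based inclusive
        if start0 < 0 or end0 > L:
            raise BoundsError(
                f"exon {label} [{feat.start}, {feat.end}] outside contig of "
                f"length {L}"
            )
        cassette = feat.attributes.get("cassette", ["false"])[0].lower() == "true"
        raw_exons.append((start0, end0, normalize_label(label), cassette))

    domains = []
    for feat in db.children(gene, featuretype="domain"):
        kind = feat.attributes.get("kind", [None])[0]
        span = feat.attributes.get("exon_span", [None])[0]
        if kind is None or span is None:
            raise ModelError("domain feature lacks kind/exon_span attributes")
        a, b = span.split("-")
        sr = feat.attributes.get("sr_index", [None])[0]
        domains.append(
            DomainAnnotation(
                kind=kind,
                exon_span=(normalize_label(a), normalize_label(b)),
                sr_index=int(sr) if sr is not None else None,
            )
        )

    if strand == "+":
        locus = contig
        exons = [
            Exon(label=lab, start=s, end=e, cassette=c)
            for s, e, lab, c in sorted(raw_exons)
        ]
    else:
        locus = str(Seq(contig).reverse_complement())
        exons = [
            Exon(label=lab, start=L - e, end=L - s, cassette=c)
            for s, e, lab, c in sorted(raw_exons, reverse=True)
        ]
    domains.sort(key=lambda d: (d.kind, d.sr_index or 0))

    return GeneModel(
        gene_id=gene_id,
        chrom=gene.seqid,
        strand=strand,
        exons=exons,
        locus_seq=locus,
        domains=domains,
        contig_len=L,
    )


def gff_string(model: GeneModel) -> str:
    """GFF3 text for a model.

    Output is deterministic: exons in reference-strand coordinate order,
    domains sorted by kind then SR index.  Round-trips with :func:`load_gene`.
    """
    L = model.contig_len

    def to_ref(start: int, end: int) -> tuple[int, int]:
        if model.strand == "+":
            return start + 1, end
        return L - end + 1, L - start

    gene_start = min(e.start for e in model.exons)
    gene_end = max(e.end for e in model.exons)
    g1, g2 = to_ref(gene_start, gene_end)

    lines = ["##gff-version 3"]
    lines.append(
        "\t".join(
            [
                model.chrom,
                "nesprintx",
                "gene",
                str(g1),
                str(g2),
                ".",
                model.strand,
                ".",
                f"ID={model.gene_id}",
            ]
        )
    )
    mrna_id = f"{model.gene_id}.mRNA"
    lines.append(
        "\t".join(
            [
                model.chrom,
                "nesprintx",
                "mRNA",
                str(g1),
                str(g2),
                ".",
                model.strand,
                ".",
                f"ID={mrna_id};Parent={model.gene_id}",
            ]
        )
    )
    rows = []
    for e in model.exons:
        r1, r2 = to_ref(e.start, e.end)
        attrs = (
            f"ID={model.gene_id}.exon.{e.label};Parent={mrna_id};"
            f"exon_label={e.label};cassette={'true' if e.cassette else 'false'}"
        )
        rows.append((r1, r2, attrs))
    for r1, r2, attrs in sorted(rows):
        lines.append(
            "\t".join(
                [
                    model.chrom,
                    "nesprintx",
                    "exon",
                    str(r1),
                    str(r2),
                    ".",
                    model.strand,
                    ".",
                    attrs,
                ]
            )
        )
    for i, d in enumerate(
        sorted(model.domains, key=lambda d: (d.kind, d.sr_index or 0))
    ):
        a = model.exon(d.exon_span[0])
        b = model.exon(d.exon_span[1])
        r1, r2 = to_ref(min(a.start, b.start), max(a.end, b.end))
        attrs = (
            f"ID={model.gene_id}.domain.{i};Parent={model.gene_id};"
            f"kind={d.kind};exon_span={d.exon_span[0]}-{d.exon_span[1]}"
        )
        if d.sr_index is not None:
            attrs += f";sr_index={d.sr_index}"
        lines.append(
            "\t".join(
                [
                    model.chrom,
                    "nesprintx",
                    "domain",
                    str(r1),
                    str(r2),
                    ".",
                    model.strand,
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def fasta_string(model: GeneModel) -> str:
    """Reference-strand contig FASTA text for a model."""
    contig = (
        model.locus_seq
        if model.strand == "+"
        else str(Seq(model.locus_seq).reverse_complement())
    )
    lines = [f">{model.chrom}"]
    for i in range(0, len(contig), 70):
        lines.append(contig[i : i + 70])
    return "\n".join(lines) + "\n"


def write_gff(model: GeneModel, gff_path: str, fasta_path: str | None = None):
    """Write a model to a GFF3 file (and optionally the contig FASTA)."""
    with open(gff_path, "w") as fh:
        fh.write(gff_string(model))
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            fh.write(fasta_string(model))
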