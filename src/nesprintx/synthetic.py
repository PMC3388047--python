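"""Synthetic gene models with planted alternative-transcription features.

Every downstream stage of the pipeline is exercised against genes built
here: a random generator (:func:`make_gene`) plants alternative start sites
with graded Kozak contexts, intron-retained terminators carrying in-frame
fingerprint codons followed by a stop and a polyadenylation signal, and
cassette exons of frame-preserving and frame-shifting lengths; EST-like
one-shot reads are then sampled from the implied variant transcripts.

The hand-built "mini-nesprin" fixtures encode the published landmark
peptides of the nesprin-1 and nesprin-2 genes — the AGAGYPHQ retained-intron
fingerprint, the VHKRWLRFLPF and GIAGHSATPPA frameshift tails produced by
cassette-exon exclusion around the KASH domain, the cassette-exon inserts
SMHRGSP (exon 6'), the 47-residue exon-93 insert and the 23-residue exon
107' insert, and the canonical KASH tails RYTNGPPPL / YPMLRYTNGPPPT — in a
compact, fully synthetic exon/intron scaffold.  The genomic codons are
back-translations (most-frequent human codons), not the true genomic
sequence, so tests compare amino acids, never nucleotides, against the
published values.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .gene_model import DomainAnnotation, Exon, GeneModel, fasta_string, gff_string
from .orf import (
    CANONICAL_POLYA,
    NONCANONICAL_POLYA,
    back_translate,
    translate_cds,
)
from .variants import TranscriptVariant, UTRSite, build_transcript, make_variant

# ---------------------------------------------------------------------------
# Published landmark peptides (compared by tests as amino-acid strings)
# ---------------------------------------------------------------------------

FINGERPRINT_E90 = "AGAGYPHQ"  # retained intron after nesprin-1 exon 90
TAIL_DELTA_KASH_NESP1 = "VHKRWLRFLPF"  # exon-145 exclusion frameshift tail
TAIL_KASH_NESP1 = "RYTNGPPPL"  # canonical nesprin-1 KASH C-terminus
TAIL_DELTA_KASH_NESP2 = "GIAGHSATPPA"  # exons-110-113 exclusion tail
TAIL_KASH_NESP2 = "YPMLRYTNGPPPT"  # canonical nesprin-2 KASH C-terminus
CASSETTE_6P = "SMHRGSP"
CASSETTE_93 = "MTAGRCHTLLSPVTEESGEEGTNSEISSPPACRSPSPVANTDASVNQ"
CASSETTE_107P = "DVEIPENPEAYLKMTTKTLKASS"

# Invented fixture fingerprints for terminators the published text does not
# spell out (only their existence); any peptide would do.
FINGERPRINT_E14_FIXTURE = "GQSLVRT"
FINGERPRINT_E7_NESP2_FIXTURE = "SPQLRTE"

_ALL_POLYA = tuple(CANONICAL_POLYA) + tuple(NONCANONICAL_POLYA)

_KOZAK_CONTEXT = {
    # -6..-1 context planted ahead of an ATG; viability per the adequate rule
    "strong": "GCCACC",  # purine at -3 and (with GCC-starting filler) G at +4
    "adequate": "TTTACC",  # purine at -3 only
    "weak": "TTTTTT",  # neither; fails validation
}

_FILL_CYCLE = "ASLDKEVQRGT"  # no Met, no stop-prone codon junctions


def _fill(n: int, phase: int = 0) -> str:
    """Deterministic filler peptide of n residues."""
    cyc = _FILL_CYCLE
    return "".join(cyc[(phase + i) % len(cyc)] for i in range(n))


def _spacer(n: int, rng: np.random.Generator) -> str:
    """Random non-coding DNA scrubbed of polyadenylation hexamers, ATGs and
    A-runs, so planted signals stay unique."""
    bases = "ACGT"
    seq = "".join(bases[i] for i in rng.integers(0, 4, size=n))
    bad = _ALL_POLYA + ("ATG", "AAAA")
    for _ in range(100):
        dirty = False
        for motif in bad:
            pos = seq.find(motif)
            while pos != -1:
                dirty = True
                repl = "".join(
                    bases[i] for i in rng.integers(0, 4, size=len(motif))
                )
                seq = seq[:pos] + repl + seq[pos + len(motif) :]
                pos = seq.find(motif)
        if not dirty:
            return seq
    raise ConfigError("could not scrub spacer sequence")  # pragma: no cover


def _terminator_intron(
    fingerprint: str, rng: np.random.Generator, total_len: int | None = None
) -> str:
    """An intron whose retention terminates translation.

    Layout: in-frame fingerprint codons, a TAA stop, a 20-nt spacer, an
    AATAAA polyadenylation signal, then intron filler.
    """
    core = back_translate(fingerprint) + "TAA" + _spacer(20, rng) + "AATAAA"
    pad = (total_len - len(core)) if total_len else 80
    if pad < 40:
        pad = 40
    return core + _spacer(pad, rng)


def _dual_frame_terminal_exon(
    shifted_tail: str,
    linker: str,
    canonical_tail: str,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Terminal-exon coding region read in two frames.

    Entered one nucleotide out of frame (cassette included, cassette length
    = 1 mod 3) the exon encodes junk-then-``linker + canonical_tail`` and a
    TGA stop; entered in frame (cassette excluded) it encodes
    ``shifted_tail`` then an immediate TAA — the novel C-terminal tail.
    Returns ``(coding_dna, canonical_peptide_of_region)``.

    The preferred-codon table contains no codon ending in T, so the
    out-of-frame reading can never spell a stop inside the tail region; this
    is asserted.
    """
    dual = back_translate(shifted_tail) + "TAA"
    coding = dual + "GC" + back_translate(linker + canonical_tail) + "TGA"
    canonical_pep = translate_cds(coding[2:])
    if not canonical_pep.endswith(canonical_tail):
        raise ConfigError("dual-frame design hit a premature stop")
    return coding, canonical_pep


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    site: UTRSite
    kozak: str | None = None  # strong / adequate / weak, 5' sites only
    fingerprint: str | None = None  # retained-intron peptide, 3' sites only
    expected_valid: bool = True
    discoverable: bool = True  # recoverable from EST structure (not canonical)


@dataclass(frozen=True)
class PlantedCassette:
    label: str
    length: int
    peptide: str | None = None  # insert peptide when frame-preserving
    default_include: bool = False


@dataclass(frozen=True)
class VariantSpec:
    name: str
    start_name: str
    end_name: str
    pattern: tuple[tuple[str, bool], ...] = ()

    @property
    def pattern_dict(self) -> dict[str, bool]:
        return dict(self.pattern)


@dataclass
class TruthSet:
    """Planted ground truth for one synthetic gene."""

    gene_short: str
    sites: list[PlantedSite]
    cassettes: list[PlantedCassette]
    variants: list[VariantSpec]
    fingerprints: dict[str, str] = field(default_factory=dict)
    variant_cds: dict[str, str] = field(default_factory=dict)
    canonical_tail: str = ""

    def site(self, name: str) -> UTRSite:
        for p in self.sites:
            if p.site.name == name:
                return p.site
        raise InputError(f"no planted site named {name!r}")

    def variant_spec(self, name: str) -> VariantSpec:
        for v in self.variants:
            if v.name == name:
                return v
        raise InputError(f"no planted variant named {name!r}")

    def make_variant(self, model: GeneModel, name: str) -> TranscriptVariant:
        spec = self.variant_spec(name)
        return make_variant(
            model,
            self.site(spec.start_name),
            self.site(spec.end_name),
            spec.pattern_dict,
        )

    def discoverable_sites(self) -> list[PlantedSite]:
        return [p for p in self.sites if p.discoverable and p.expected_valid]


# ---------------------------------------------------------------------------
# Mini-nesprin fixtures
# ---------------------------------------------------------------------------


def _utr5(rng: np.random.Generator) -> str:
    return _spacer(24, rng) + "GCCACC"


def _build_mini_nesp1() -> tuple[GeneModel, TruthSet]:
    rng = np.random.default_rng(20120702)

    # Solve filler sizes so the stand-in variants hit the published masses:
    # the CH-domain variant (giant start, terminator after the exon-14
    # analogue) is 56 kDa and the KASH variant (exon-138 analogue start,
    # canonical end) is 53 kDa.
    from .orf import molecular_weight

    dual_coding, _ = _dual_frame_terminal_exon(
        TAIL_DELTA_KASH_NESP1, _fill(20), TAIL_KASH_NESP1, rng
    )
    e145_coding = back_translate(_fill(7)) + "G"  # 22 nt: 1 mod 3

    def p56_protein(n14: int) -> str:
        return "M" + _fill(129) + _fill(130) + _fill(130) + _fill(n14) + (
            FINGERPRINT_E14_FIXTURE
        )

    def p53_protein(n138: int) -> str:
        cds = (
            "ATG"
            + back_translate(_fill(n138))
            + back_translate(_fill(200))
            + e145_coding
            + dual_coding
        )
        return translate_cds(cds)

    n14 = next(
        n
        for n in range(60, 400)
        if round(molecular_weight(p56_protein(n)) / 1000) == 56
    )
    n138 = next(
        n
        for n in range(60, 500)
        if round(molecular_weight(p53_protein(n)) / 1000) == 53
    )

    exon_coding = {
        "1": "ATG" + back_translate(_fill(129)),
        "2": back_translate(_fill(130)),
        "6'": back_translate(CASSETTE_6P),
        "7": back_translate(_fill(130)),
        "14": back_translate(_fill(n14)),
        "15": back_translate(_fill(100)),
        "89": back_translate(_fill(100)),
        "90": back_translate(_fill(120)),
        "91": "GCCACC" + "ATG" + back_translate(_fill(120)),
        "93": back_translate(CASSETTE_93),
        "94": back_translate(_fill(100)),
        "138": "GCCACC" + "ATG" + back_translate(_fill(n138)),
        "144": back_translate(_fill(200)),
        "145": e145_coding,
        "146": dual_coding,
    }
    exon_seqs = dict(exon_coding)
    exon_seqs["1"] = _utr5(rng) + exon_coding["1"]
    exon_seqs["146"] = exon_coding["146"] + _spacer(30, rng) + "AATAAA" + _spacer(40, rng)

    order = list(exon_seqs)
    introns = {}
    for a, b in zip(order, order[1:]):
        introns[(a, b)] = _spacer(100, rng)
    introns[("14", "15")] = _terminator_intron(FINGERPRINT_E14_FIXTURE, rng, 160)
    introns[("90", "91")] = _terminator_intron(FINGERPRINT_E90, rng, 160)
    # Decoy signal and weak ATG, away from any planted site.
    introns[("2", "6'")] = (
        _spacer(40, rng) + "AATAAA" + _spacer(20, rng) + "TTTTATGTT" + _spacer(31, rng)
    )

    cassette_labels = {"6'", "93", "145"}
    model = _assemble(
        "mini_nesp1", "chrM1", order, exon_seqs, introns, cassette_labels, rng,
        domains=[
            DomainAnnotation("CH", ("1", "2")),
            DomainAnnotation("SR", ("7", "14"), sr_index=1),
            DomainAnnotation("SR", ("15", "89"), sr_index=2),
            DomainAnnotation("SR", ("90", "91"), sr_index=3),
            DomainAnnotation("SR", ("94", "94"), sr_index=4),
            DomainAnnotation("SR", ("138", "144"), sr_index=5),
            DomainAnnotation("KASH", ("145", "146")),
        ],
    )

    s5e1 = UTRSite("N1-5′E1", "5'", "1", "exonic")
    s5e91 = UTRSite("N1-5′E91", "5'", "91", "exonic")
    s5e138 = UTRSite("N1-5′E138", "5'", "138", "exonic")
    s3e14 = UTRSite("N1-3′E14", "3'", "14", "intron_retained")
    s3e90 = UTRSite("N1-3′E90", "3'", "90", "intron_retained")
    s3e146 = UTRSite("N1-3′E146", "3'", "146", "exonic")

    truth = TruthSet(
        gene_short="Nesp1",
        sites=[
            PlantedSite(s5e1, kozak="strong", discoverable=False),
            PlantedSite(s5e91, kozak="strong", discoverable=False),
            PlantedSite(s5e138, kozak="strong", discoverable=False),
            PlantedSite(s3e14, fingerprint=FINGERPRINT_E14_FIXTURE),
            PlantedSite(s3e90, fingerprint=FINGERPRINT_E90),
            PlantedSite(s3e146, discoverable=False),
        ],
        cassettes=[
            PlantedCassette("6'", 21, CASSETTE_6P),
            PlantedCassette("93", 141, CASSETTE_93),
            PlantedCassette("145", 22, None, default_include=True),
        ],
        variants=[
            VariantSpec("p56CH", "N1-5′E1", "N1-3′E14", (("6'", False),)),
            VariantSpec("p53KASH", "N1-5′E138", "N1-3′E146", (("145", True),)),
            VariantSpec("p53dKASH", "N1-5′E138", "N1-3′E146", (("145", False),)),
            VariantSpec(
                "giant",
                "N1-5′E1",
                "N1-3′E146",
                (("6'", False), ("93", False), ("145", True)),
            ),
            VariantSpec("fp90", "N1-5′E1", "N1-3′E90", (("6'", False), ("93", False))),
            VariantSpec("rod93", "N1-5′E91", "N1-3′E146", (("93", True), ("145", True))),
        ],
        fingerprints={
            "N1-3′E14": FINGERPRINT_E14_FIXTURE,
            "N1-3′E90": FINGERPRINT_E90,
        },
        variant_cds={
            "p56CH_protein": p56_protein(n14),
            "p53KASH_protein": p53_protein(n138),
        },
        canonical_tail=TAIL_KASH_NESP1,
    )
    return model, truth


def _build_mini_nesp2() -> tuple[GeneModel, TruthSet]:
    rng = np.random.default_rng(20120703)

    dual_coding, _ = _dual_frame_terminal_exon(
        TAIL_DELTA_KASH_NESP2, _fill(15), TAIL_KASH_NESP2, rng
    )
    # Cassette block 110-113: one dual-frame-safe coding run of 112 nt
    # (37 codons + 1 nt; total length = 1 mod 3 so removal shifts frame),
    # split across the four exons.
    block = back_translate(_fill(37)) + "G"
    cuts = [0, 28, 55, 82, 112]
    block_parts = {
        lab: block[a:b]
        for lab, a, b in zip(
            ("110", "111", "112", "113"), cuts[:-1], cuts[1:]
        )
    }

    exon_seqs = {
        "1": _utr5(rng) + "ATG" + back_translate(_fill(100)),
        "2": back_translate(_fill(100)),
        "7": back_translate(_fill(80)),
        "100": back_translate(_fill(100)),
        "101": back_translate(_fill(100)),
        "107'": back_translate(CASSETTE_107P),
        "108": back_translate(_fill(80)),
        "109": back_translate(_fill(80)),
        **block_parts,
        "114": dual_coding + _spacer(30, rng) + "AATAAA" + _spacer(40, rng),
    }
    order = list(exon_seqs)
    introns = {(a, b): _spacer(100, rng) for a, b in zip(order, order[1:])}
    introns[("7", "100")] = _terminator_intron(
        FINGERPRINT_E7_NESP2_FIXTURE, rng, 160
    )

    cassette_labels = {"107'", "110", "111", "112", "113"}
    model = _assemble(
        "mini_nesp2", "chrM2", order, exon_seqs, introns, cassette_labels, rng,
        domains=[
            DomainAnnotation("CH", ("1", "2")),
            DomainAnnotation("SR", ("100", "101"), sr_index=1),
            DomainAnnotation("SR", ("108", "109"), sr_index=2),
            DomainAnnotation("KASH", ("113", "114")),
        ],
    )

    s5e1 = UTRSite("N2-5′E1", "5'", "1", "exonic")
    s3e7 = UTRSite("N2-3′E7", "3'", "7", "intron_retained")
    s3e114 = UTRSite("N2-3′E114", "3'", "114", "exonic")

    include_all = tuple((lab, True) for lab in ("110", "111", "112", "113"))
    exclude_all = tuple((lab, False) for lab in ("110", "111", "112", "113"))
    truth = TruthSet(
        gene_short="Nesp2",
        sites=[
            PlantedSite(s5e1, kozak="strong", discoverable=False),
            PlantedSite(s3e7, fingerprint=FINGERPRINT_E7_NESP2_FIXTURE),
            PlantedSite(s3e114, discoverable=False),
        ],
        cassettes=[
            PlantedCassette("107'", 69, CASSETTE_107P),
            PlantedCassette("110", 28, None, default_include=True),
            PlantedCassette("111", 27, None, default_include=True),
            PlantedCassette("112", 27, None, default_include=True),
            PlantedCassette("113", 30, None, default_include=True),
        ],
        variants=[
            VariantSpec(
                "giant", "N2-5′E1", "N2-3′E114", (("107'", False),) + include_all
            ),
            VariantSpec(
                "dkash1", "N2-5′E1", "N2-3′E114", (("107'", False),) + exclude_all
            ),
            VariantSpec("p32CH", "N2-5′E1", "N2-3′E7", ()),
        ],
        fingerprints={"N2-3′E7": FINGERPRINT_E7_NESP2_FIXTURE},
        canonical_tail=TAIL_KASH_NESP2,
    )
    return model, truth


def _assemble(
    gene_id: str,
    chrom: str,
    order: list[str],
    exon_seqs: dict[str, str],
    introns: dict[tuple[str, str], str],
    cassette_labels: set[str],
    rng: np.random.Generator,
    domains: list[DomainAnnotation],
) -> GeneModel:
    """Concatenate flank + exons + introns into a locus and build the model."""
    parts = [_spacer(50, rng)]
    pos = len(parts[0])
    exons = []
    for i, lab in enumerate(order):
        seq = exon_seqs[lab]
        exons.append(
            Exon(
                label=lab,
                start=pos,
                end=pos + len(seq),
                cassette=lab in cassette_labels,
            )
        )
        parts.append(seq)
        pos += len(seq)
        if i < len(order) - 1:
            iseq = introns[(lab, order[i + 1])]
            parts.append(iseq)
            pos += len(iseq)
    parts.append(_spacer(50, rng))
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        exons=exons,
        locus_seq="".join(parts),
        domains=domains,
    )


@functools.lru_cache(maxsize=None)
def mini_nesprin_fixture(gene: str = "nesp1") -> tuple[GeneModel, TruthSet]:
    """The deterministic mini-nesprin fixture.

    ``gene`` selects the nesprin-1-like scaffold (retained-intron AGAGYPHQ
    terminator, cassettes 6'/93/145, RYTNGPPPL canonical KASH tail) or the
    nesprin-2-like one (cassette 107', frame-shifting 110-113 block,
    YPMLRYTNGPPPT canonical tail).
    """
    if gene == "nesp1":
        return _build_mini_nesp1()
    if gene == "nesp2":
        return _build_mini_nesp2()
    raise InputError(f"unknown fixture gene {gene!r}")


# ---------------------------------------------------------------------------
# Random planted genes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the random planted-gene simulator.

    Defaults describe a compact locus that still exhibits every evidence
    structure the screen must detect: a dozen exons, two alternative start
    sites of graded Kozak strength retained from upstream introns, two
    intron-retained terminators with fingerprint codons and an AATAAA within
    ``polya_window``, one cassette exon, and one-shot EST reads of a few
    hundred nucleotides with a 0.5% substitution error rate.
    """

    n_exons: int = 12
    exon_len_range: tuple[int, int] = (150, 300)
    intron_len_range: tuple[int, int] = (150, 260)
    n_alt_starts: int = 2
    n_alt_ends: int = 2
    n_cassettes: int = 1
    kozak_strengths: tuple[str, ...] = ("strong", "adequate")
    polya_window: int = 2000
    est_error_rate: float = 0.005
    est_indel_rate: float = 0.0
    est_len_range: tuple[int, int] = (150, 500)
    retained_utr_len: int = 60
    seed: int = 0
    fingerprint_peptides: tuple[str, ...] | None = None

    def validate(self):
        if self.n_exons < 4:
            raise ConfigError("need at least 4 exons")
        if not (0 <= self.est_error_rate < 0.1):
            raise ConfigError("est_error_rate must be in [0, 0.1)")
        if not (0 <= self.est_indel_rate < 0.1):
            raise ConfigError("est_indel_rate must be in [0, 0.1)")
        for name in ("exon_len_range", "intron_len_range", "est_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ConfigError(f"empty range {name}")
        if self.exon_len_range[0] < 30:
            raise ConfigError("exons too short for planted start contexts")
        if self.intron_len_range[0] < self.retained_utr_len + 60:
            raise ConfigError("introns too short for planted terminators")
        if min(self.n_alt_starts, self.n_alt_ends, self.n_cassettes) < 0:
            raise ConfigError("counts must be non-negative")
        n_internal = self.n_exons - 2
        if self.n_alt_starts + self.n_alt_ends + self.n_cassettes > n_internal:
            raise ConfigError("more planted features than internal exons")


def make_gene(
    config: SimConfig,
) -> tuple[GeneModel, TruthSet, str, str]:
    """Generate a planted gene; returns (model, truth, fasta_text, gff_text).

    Deterministic for a fixed config (seed included).  Alternative 5' sites
    are intron-retained: the transcript keeps the last ``retained_utr_len``
    nt of the upstream intron and initiates at a planted ATG at the start of
    the anchor exon, with Kozak context cycled through
    ``kozak_strengths``.  Terminators follow the fingerprint/stop/AATAAA
    layout.  A decoy AATAAA and a decoy ATG are planted in an unused intron.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_short = "S1"

    n = config.n_exons
    internal = list(range(1, n - 1))
    picks = rng.permutation(internal)
    alt_start_exons = sorted(int(x) for x in picks[: config.n_alt_starts])
    alt_end_exons = sorted(
        int(x)
        for x in picks[config.n_alt_starts : config.n_alt_starts + config.n_alt_ends]
    )
    cassette_exons = sorted(
        int(x)
        for x in picks[
            config.n_alt_starts
            + config.n_alt_ends : config.n_alt_starts
            + config.n_alt_ends
            + config.n_cassettes
        ]
    )

    aa_alphabet = "ASLDKEVQRGTFINH"

    def rand_fill(n_res: int) -> str:
        return "".join(
            aa_alphabet[i] for i in rng.integers(0, len(aa_alphabet), size=n_res)
        )

    def coding_len() -> int:
        lo, hi = config.exon_len_range
        return 3 * int(rng.integers(lo // 3, hi // 3 + 1))

    exon_seqs: dict[str, str] = {}
    cassettes: list[PlantedCassette] = []
    kozak_cycle = list(config.kozak_strengths) or ["strong"]
    site_kozak: dict[int, str] = {}
    for j, idx in enumerate(alt_start_exons):
        site_kozak[idx] = kozak_cycle[j % len(kozak_cycle)]

    for idx in range(n):
        label = str(idx + 1)
        if idx == 0:
            seq = _utr5(rng) + "ATG" + back_translate(rand_fill(coding_len() // 3))
        elif idx == n - 1:
            seq = (
                back_translate(rand_fill(coding_len() // 3))
                + "TGA"
                + _spacer(25, rng)
                + "AATAAA"
                + _spacer(30, rng)
            )
        elif idx in site_kozak:
            strength = site_kozak[idx]
            first = "A" if strength != "weak" else "F"  # F codon TTC: +4 = T
            pep = first + rand_fill(coding_len() // 3 - 1)
            seq = _KOZAK_CONTEXT[strength] + "ATG" + back_translate(pep)
        elif idx in cassette_exons:
            n_res = coding_len() // 3
            preserve = (idx % 2) == 0
            seq = back_translate(rand_fill(n_res))
            if not preserve:
                seq += "G"  # frame-shifting length (1 mod 3)
            cassettes.append(
                PlantedCassette(
                    label,
                    len(seq),
                    peptide=None,
                    default_include=preserve,
                )
            )
            exon_seqs[label] = seq
            continue
        else:
            seq = back_translate(rand_fill(coding_len() // 3))
        exon_seqs[label] = seq

    def intron_len() -> int:
        lo, hi = config.intron_len_range
        return int(rng.integers(lo, hi + 1))

    fingerprints_cfg = list(config.fingerprint_peptides or [])
    fingerprints: dict[str, str] = {}
    introns: dict[tuple[str, str], str] = {}
    decoy_done = False
    for idx in range(n - 1):
        a, b = str(idx + 1), str(idx + 2)
        if (idx + 1) in alt_end_exons:
            if fingerprints_cfg:
                fp = fingerprints_cfg.pop(0)
            else:
                fp = rand_fill(int(rng.integers(6, 11)))
            fingerprints[f"{gene_short}-3′E{a}"] = fp
            introns[(a, b)] = _terminator_intron(fp, rng, intron_len())
        elif (
            not decoy_done
            and (idx + 2) not in alt_start_exons
            and (idx + 1) not in alt_start_exons
        ):
            decoy_done = True
            L = intron_len()
            introns[(a, b)] = (
                _spacer(L // 2, rng)
                + "AATAAA"
                + "TTTATGT"
                + _spacer(L - L // 2 - 13, rng)
            )
        else:
            introns[(a, b)] = _spacer(intron_len(), rng)

    order = [str(i + 1) for i in range(n)]
    model = _assemble(
        f"sim_{config.seed}",
        "chrS",
        order,
        exon_seqs,
        introns,
        {str(i + 1) for i in cassette_exons},
        rng,
        domains=[],
    )

    sites: list[PlantedSite] = []
    canon5 = UTRSite(f"{gene_short}-5′E1", "5'", "1", "exonic")
    sites.append(PlantedSite(canon5, kozak="strong", discoverable=False))
    for idx in alt_start_exons:
        anchor = str(idx + 1)
        prev = str(idx)
        strength = site_kozak[idx]
        site = UTRSite(
            f"{gene_short}-5′I{prev}/{anchor}",
            "5'",
            anchor,
            "intron_retained",
            retained_utr_len=config.retained_utr_len,
        )
        sites.append(
            PlantedSite(site, kozak=strength, expected_valid=strength != "weak")
        )
    for idx in alt_end_exons:
        anchor = str(idx)
        site = UTRSite(f"{gene_short}-3′E{anchor}", "3'", anchor, "intron_retained")
        sites.append(
            PlantedSite(site, fingerprint=fingerprints[f"{gene_short}-3′E{anchor}"])
        )
    canon3 = UTRSite(f"{gene_short}-3′E{n}", "3'", str(n), "exonic")
    sites.append(PlantedSite(canon3, discoverable=False))

    default_pattern = tuple(
        (c.label, c.default_include) for c in cassettes
    )
    variants = [VariantSpec("canonical", canon5.name, canon3.name, default_pattern)]
    for p in sites:
        if not p.discoverable:
            continue
        if p.site.side == "5'":
            variants.append(
                VariantSpec(f"alt_start_{p.site.anchor_exon}", p.site.name,
                            canon3.name, default_pattern)
            )
        else:
            local = tuple(
                (lab, inc)
                for lab, inc in default_pattern
                if int(lab) <= int(p.site.anchor_exon)
            )
            variants.append(
                VariantSpec(f"alt_end_{p.site.anchor_exon}", canon5.name,
                            p.site.name, local)
            )
    for c in cassettes:
        toggled = tuple(
            (lab, (not inc) if lab == c.label else inc)
            for lab, inc in default_pattern
        )
        variants.append(
            VariantSpec(f"cassette_{c.label}", canon5.name, canon3.name, toggled)
        )

    truth = TruthSet(
        gene_short=gene_short,
        sites=sites,
        cassettes=cassettes,
        variants=variants,
        fingerprints=fingerprints,
    )
    return model, truth, fasta_string(model), gff_string(model)


# ---------------------------------------------------------------------------
# EST read simulation
# ---------------------------------------------------------------------------


def simulate_ests(
    model: GeneModel,
    truth: TruthSet,
    n: int,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample one-shot EST-like reads from the planted variant transcripts.

    Each read is a 5'- or 3'-anchored truncation of one variant's mRNA with
    per-base substitution errors at ``config.est_error_rate`` (plus, when
    ``config.est_indel_rate`` is non-zero, single-base insertions/deletions
    at that per-base rate); 3'-anchored reads from polyadenylated
    transcripts carry a 15-nt poly(A) tail, the classic evidence for a
    genuine termination site.  Returns the reads and a truth-label table
    (read id, source variant, anchored side).
    """
    if n < 1:
        raise ConfigError("need at least one read")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    transcripts = {}
    for spec in truth.variants:
        asm = build_transcript(model, truth.make_variant(model, spec.name))
        transcripts[spec.name] = asm.mrna
    names = sorted(transcripts)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    reads: list[tuple[str, str]] = []
    labels = []
    for i in range(n):
        name = names[i % len(names)]
        mrna = transcripts[name]
        side = "5'" if rng.random() < 0.5 else "3'"
        lo, hi = config.est_len_range
        L = min(int(rng.integers(lo, hi + 1)), len(mrna))
        seq = mrna[:L] if side == "5'" else mrna[-L:]
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        errs = np.flatnonzero(rng.random(len(arr)) < config.est_error_rate)
        for pos in errs:
            choices = bases[bases != arr[pos]]
            arr[pos] = choices[rng.integers(0, 3)]
        seq = arr.tobytes().decode()
        n_indels = 0
        if config.est_indel_rate > 0:
            chars = list(seq)
            # iterate right-to-left so earlier positions stay valid
            for pos in range(len(chars) - 1, -1, -1):
                if rng.random() >= config.est_indel_rate:
                    continue
                n_indels += 1
                if rng.random() < 0.5:
                    del chars[pos]
                else:
                    chars.insert(pos, "ACGT"[rng.integers(0, 4)])
            seq = "".join(chars)
        if side == "3'":
            seq += "A" * 15
        rid = f"est{i:05d}"
        reads.append((rid, seq))
        labels.append(
            {"read_id": rid, "variant": name, "side": side,
             "n_errors": int(len(errs)), "n_indels": n_indels, "length": L}
        )
    return reads, pd.DataFrame(labels)


# ---------------------------------------------------------------------------
# Ct table simulation
# ---------------------------------------------------------------------------


def simulate_ct_table(
    fold_changes: dict[str, float],
    ct_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    base_ct: float = 22.0,
    reference_ct: float = 16.0,
    target: str = "target",
    reference_target: str = "GAPDH",
    control_condition: str = "control",
) -> pd.DataFrame:
    """Simulated qPCR Ct table under known fold changes.

    The target amplifies ``base_ct`` cycles in the control; a condition with
    fold change f shifts its Ct by -log2(f) (knockdown raises Ct).  The
    reference gene is flat across conditions.  Gaussian cycle noise with sd
    ``ct_sd`` is added independently to every well.
    """
    for cond, f in fold_changes.items():
        if f <= 0:
            raise InputError(f"fold change for {cond!r} must be positive")
    rng = np.random.default_rng(seed)
    conditions = {control_condition: 1.0, **fold_changes}
    rows = []
    for cond, fold in conditions.items():
        for rep in range(n_replicates):
            sample = f"{cond}_r{rep + 1}"
            rows.append(
                {
                    "sample": sample,
                    "condition": cond,
                    "target": target,
                    "ct": base_ct - np.log2(fold) + rng.normal(0, ct_sd),
                    "replicate": rep + 1,
                }
            )
            rows.append(
                {
                    "sample": sample,
                    "condition": cond,
                    "target": reference_target,
                    "ct": reference_ct + rng.normal(0, ct_sd),
                    "replicate": rep + 1,
                }
            )
    return pd.DataFrame(rows)


def reads_to_fasta(reads: list[tuple[str, str]]) -> str:
    lines = []
    for rid, seq in reads:
        lines.append(f">{rid}")
        for i in range(0, len(seq), 70):
            lines.append(seq[i : i + 70])
    return "\n".join(lines) + "\n"
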