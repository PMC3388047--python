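"""End-to-end orchestration: simulate, screen, enumerate, annotate, quantify.

A single :func:`run_pipeline` call exercises every stage against one planted
gene: generate the locus, sample EST reads, map them and call candidate UTR
sites, enumerate mix-and-match variants from the discovered plus canonical
sites, annotate each variant's protein product, simulate and analyse a
knockdown Ct table, and emit a deterministic manifest plus a human-readable
report.  All artifacts are plain text; the manifest carries sha256 digests
of each one so reruns are byte-verifiable.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError, NoOrfError
from .est_screen import (
    UTRCandidate,
    call_utr_candidates,
    classify_events,
    evaluate_recovery,
    screen_ests,
)
from .gene_model import GeneModel
from .orf import (
    ProteinProduct,
    disambiguate_names,
    domain_composition,
    frameshift_tail,
    molecular_weight,
    name_variant,
    readthrough_translate,
)
from .quantify import DeltaDeltaCt
from .synthetic import (
    SimConfig,
    TruthSet,
    make_gene,
    reads_to_fasta,
    simulate_ct_table,
    simulate_ests,
)
from .variants import (
    TranscriptVariant,
    UTRSite,
    build_transcript,
    enumerate_variants,
)

__all__ = [
    "PipelineConfig",
    "AnnotatedVariant",
    "annotate_variants",
    "variants_gff_string",
    "run_pipeline",
    "write_report",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs, serialisable to/from YAML."""

    seed: int = 0
    n_reads: int = 400
    min_support: int = 1
    polya_window: int = 2000
    max_cassette_patterns: int = 16
    knockdown_folds: dict = field(
        default_factory=lambda: {"kd_isoform": 0.25}
    )
    ct_sd: float = 0.1
    ct_replicates: int = 6
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("pipeline config must be a YAML mapping")
        sim_raw = raw.pop("sim", {})
        known_sim = set(SimConfig.__dataclass_fields__)
        bad = set(sim_raw) - known_sim
        if bad:
            raise ConfigError(f"unknown sim keys: {sorted(bad)}")
        known = set(cls.__dataclass_fields__) - {"sim"}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown pipeline keys: {sorted(bad)}")
        for tup_key in ("exon_len_range", "intron_len_range", "est_len_range",
                        "kozak_strengths", "fingerprint_peptides"):
            if tup_key in sim_raw and sim_raw[tup_key] is not None:
                sim_raw[tup_key] = tuple(sim_raw[tup_key])
        return cls(sim=SimConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class AnnotatedVariant:
    """One enumerated variant with its protein-level annotation."""

    variant: TranscriptVariant
    product: ProteinProduct
    tail: str = ""
    lost_domains: tuple[str, ...] = ()

    def row(self) -> dict:
        v = self.variant
        p = self.product
        return {
            "name": p.name,
            "start": v.start.name,
            "end": v.end.name,
            "pattern": json.dumps(dict(sorted(v.cassette_pattern.items()))),
            "n_exons": len(v.included_labels),
            "protein_len": len(p.sequence),
            "mass_kda": round(p.mass / 1000, 2),
            "CH": p.has_CH,
            "SR": p.sr_count,
            "KASH": p.has_KASH,
            "dKASH": p.delta_KASH,
            "fingerprint": p.fingerprint,
            "tail": self.tail,
            "hypothetical": p.hypothetical,
        }


def _span_reaches_kash(model: GeneModel, variant: TranscriptVariant) -> bool:
    from .gene_model import parse_label

    end_key = parse_label(variant.end.anchor_exon)
    return any(
        d.kind == "KASH" and parse_label(d.exon_span[0]) <= end_key
        for d in model.domains
    )


def annotate_variants(
    model: GeneModel,
    variants: list[TranscriptVariant],
    gene_short: str,
) -> list[AnnotatedVariant]:
    """Translate and annotate variants; assign disambiguated names.

    Variants without a usable start codon are skipped.  KASH loss through a
    frameshifting cassette exclusion overrides the inclusion-based domain
    composition: the exons are present but the reading frame never reaches
    them.
    """
    annotated: list[AnnotatedVariant] = []
    for v in variants:
        try:
            asm = build_transcript(model, v)
        except NoOrfError:
            continue
        comp = domain_composition(v, model)
        has_kash, delta_kash = comp.has_KASH, False
        tail = ""
        lost: tuple[str, ...] = ()
        if any(not inc for inc in v.cassette_pattern.values()):
            fs = frameshift_tail(model, v)
            if fs.frameshift:
                tail = fs.tail
                lost = tuple(fs.lost_domains)
                if "KASH" in fs.lost_domains and _span_reaches_kash(model, v):
                    has_kash = False
                    delta_kash = True
        fingerprint = ""
        if v.end.site_class == "intron_retained":
            fingerprint = readthrough_translate(model, v).fingerprint
        protein = asm.protein
        product = ProteinProduct(
            sequence=protein,
            fingerprint=fingerprint,
            mass=molecular_weight(protein) if protein else 0.0,
            has_CH=comp.has_CH,
            sr_count=comp.sr_count,
            has_KASH=has_kash,
            delta_KASH=delta_kash,
            giant_like=comp.has_CH and has_kash,
            hypothetical=v.hypothetical,
        )
        annotated.append(AnnotatedVariant(v, product, tail=tail, lost_domains=lost))

    names = disambiguate_names(
        [name_variant(a.product, gene_short) for a in annotated]
    )
    for a, name in zip(annotated, names):
        a.product.name = name
    return annotated


def _sha(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage; return results and optionally write artifacts.

    Deterministic for a fixed config.  The returned dict holds the model,
    truth, alignments, events, candidates, recovery stats, annotated
    variants, quantification results, the report text and the manifest.
    """
    sim = replace(config.sim, seed=config.seed)
    model, truth, fasta_text, gff_text = make_gene(sim)
    reads, read_truth = simulate_ests(model, truth, config.n_reads, sim)

    alignments = screen_ests(model, reads)
    events = [
        ev for aln in alignments for ev in classify_events(model, aln)
    ]
    candidates = call_utr_candidates(
        model,
        events,
        truth.gene_short,
        min_support=config.min_support,
        polya_window=config.polya_window,
    )
    recovery = evaluate_recovery(truth, candidates)

    # Site set for enumeration: canonical ends plus validated discoveries.
    first, last = model.exons[0], model.exons[-1]
    starts = [UTRSite(f"{truth.gene_short}-5′E{first.label}", "5'",
                      first.label, "exonic")]
    ends = [UTRSite(f"{truth.gene_short}-3′E{last.label}", "3'",
                    last.label, "exonic")]
    for c in candidates:
        if not c.site.validated:
            continue
        (starts if c.site.side == "5'" else ends).append(c.site)

    cassette_labels = sorted(
        (e.label for e in model.exons if e.cassette),
        key=lambda lab: model.exon_index(lab),
    )
    patterns: list[dict[str, bool]] = [{}]
    if cassette_labels:
        combos = list(itertools.product([True, False], repeat=len(cassette_labels)))
        if len(combos) <= config.max_cassette_patterns:
            patterns = [dict(zip(cassette_labels, c)) for c in combos]
    variants = enumerate_variants(
        model, starts, ends, patterns, polya_window=config.polya_window
    )
    annotated = annotate_variants(model, variants, truth.gene_short)

    ct_table = simulate_ct_table(
        config.knockdown_folds,
        ct_sd=config.ct_sd,
        seed=config.seed + 7,
        n_replicates=config.ct_replicates,
    )
    ddct = DeltaDeltaCt(ct_table, "GAPDH", "control").fit()

    results = {
        "config": config,
        "model": model,
        "truth": truth,
        "reads": reads,
        "read_truth": read_truth,
        "alignments": alignments,
        "events": events,
        "candidates": candidates,
        "recovery": recovery,
        "variants": annotated,
        "ddct": ddct,
    }
    report = write_report(results)
    results["report"] = report

    variants_tsv = _variants_tsv(annotated)
    variants_gff = variants_gff_string(model, annotated)
    transcripts_fa, proteins_fa = _sequences_fasta(model, annotated)
    candidates_json = _candidates_json(candidates)
    reads_fa = reads_to_fasta(reads)
    ct_csv = ct_table.to_csv(index=False)
    manifest = {
        "tool": "nesprintx",
        "config": config.to_dict(),
        "gene_id": model.gene_id,
        "n_reads": len(reads),
        "n_alignments": len(alignments),
        "n_events": len(events),
        "n_candidates": len(candidates),
        "n_variants": len(annotated),
        "recovery": {
            "precision": recovery["precision"],
            "recall": recovery["recall"],
        },
        "artifacts": {
            "gene.fasta": _sha(fasta_text),
            "gene.gff3": _sha(gff_text),
            "reads.fasta": _sha(reads_fa),
            "candidates.json": _sha(candidates_json),
            "variants.tsv": _sha(variants_tsv),
            "variants.gff3": _sha(variants_gff),
            "transcripts.fasta": _sha(transcripts_fa),
            "proteins.fasta": _sha(proteins_fa),
            "ct_table.csv": _sha(ct_csv),
            "report.txt": _sha(report),
        },
    }
    results["manifest"] = manifest

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "gene.fasta").write_text(fasta_text)
        (out / "gene.gff3").write_text(gff_text)
        (out / "reads.fasta").write_text(reads_fa)
        (out / "candidates.json").write_text(candidates_json)
        (out / "variants.tsv").write_text(variants_tsv)
        (out / "variants.gff3").write_text(variants_gff)
        (out / "transcripts.fasta").write_text(transcripts_fa)
        (out / "proteins.fasta").write_text(proteins_fa)
        (out / "ct_table.csv").write_text(ct_csv)
        (out / "report.txt").write_text(report)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return results


def _candidates_json(candidates: list[UTRCandidate]) -> str:
    rows = []
    for c in candidates:
        rows.append(
            {
                "name": c.site.name,
                "side": c.site.side,
                "anchor_exon": c.site.anchor_exon,
                "site_class": c.site.site_class,
                "evidence": list(c.site.evidence),
                "validated": c.site.validated,
                "support": c.support,
            }
        )
    return json.dumps(rows, indent=2, sort_keys=True) + "\n"


def variants_gff_string(model: GeneModel, annotated: list[AnnotatedVariant]) -> str:
    """GFF3 text for enumerated variants: one mRNA per variant with exon
    children; intron-retained 3' extensions carry a ``retained_extension``
    attribute (genomic span, 1-based inclusive)."""
    L = model.contig_len

    def to_ref(start: int, end: int) -> tuple[int, int]:
        if model.strand == "+":
            return start + 1, end
        return L - end + 1, L - start

    lines = ["##gff-version 3"]
    for idx, a in enumerate(annotated):
        v = a.variant
        blocks = list(v.blocks)
        if v.retained_extension is not None:
            blocks.append(v.retained_extension)
        g1 = min(to_ref(s, e)[0] for s, e in blocks)
        g2 = max(to_ref(s, e)[1] for s, e in blocks)
        vid = f"{model.gene_id}.variant.{idx}"
        attrs = f"ID={vid};Parent={model.gene_id};name={a.product.name}"
        if v.retained_extension is not None:
            r1, r2 = to_ref(*v.retained_extension)
            attrs += f";retained_extension={r1}-{r2}"
        lines.append(
            "\t".join(
                [model.chrom, "nesprintx", "mRNA", str(g1), str(g2),
                 ".", model.strand, ".", attrs]
            )
        )
        for j, (s, e) in enumerate(sorted(to_ref(s, e) for s, e in blocks)):
            lines.append(
                "\t".join(
                    [model.chrom, "nesprintx", "exon", str(s), str(e),
                     ".", model.strand, ".",
                     f"ID={vid}.exon.{j};Parent={vid}"]
                )
            )
    return "\n".join(lines) + "\n"


def _sequences_fasta(
    model: GeneModel, annotated: list[AnnotatedVariant]
) -> tuple[str, str]:
    """Transcript and protein FASTA texts for the annotated variants."""
    tx_lines: list[str] = []
    prot_lines: list[str] = []
    for a in annotated:
        asm = build_transcript(model, a.variant)
        header = (
            f">{a.product.name} start={a.variant.start.name} "
            f"end={a.variant.end.name} mass_kda={a.product.mass / 1000:.2f}"
        )
        tx_lines.append(header)
        tx_lines.extend(
            asm.mrna[i : i + 70] for i in range(0, len(asm.mrna), 70)
        )
        prot_lines.append(header)
        prot_lines.extend(
            asm.protein[i : i + 70] for i in range(0, len(asm.protein), 70)
        )
    return "\n".join(tx_lines) + "\n", "\n".join(prot_lines) + "\n"


def _variants_tsv(annotated: list[AnnotatedVariant]) -> str:
    if not annotated:
        return ""
    rows = [a.row() for a in annotated]
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    return "\n".join(lines) + "\n"


def write_report(results: dict) -> str:
    """Human-readable run summary."""
    model: GeneModel = results["model"]
    truth: TruthSet = results["truth"]
    rec = results["recovery"]
    lines = [
        f"nesprintx report — gene {model.gene_id} ({truth.gene_short})",
        "",
        f"Locus: {len(model.locus_seq)} nt, {len(model.exons)} exons, "
        f"{sum(1 for e in model.exons if e.cassette)} cassette exon(s)",
        f"Reads: {len(results['reads'])} simulated, "
        f"{len(results['alignments'])} aligned, "
        f"{len(results['events'])} events",
        "",
        "UTR candidates:",
    ]
    for c in results["candidates"]:
        flag = "validated" if c.site.validated else "rejected"
        lines.append(
            f"  {c.site.name:<16} {c.site.side} {c.site.site_class:<16} "
            f"support={c.support:<4d} {flag}"
        )
    lines += [
        "",
        f"Recovery vs planted truth: precision={rec['precision']:.3f} "
        f"recall={rec['recall']:.3f} "
        f"(planted={rec['n_planted']}, called={rec['n_called']})",
    ]
    if rec["spurious"]:
        lines.append(f"  spurious: {', '.join(rec['spurious'])}")
    if rec["missed"]:
        lines.append(f"  missed:   {', '.join(rec['missed'])}")
    lines += ["", "Variants:"]
    for a in results["variants"]:
        p = a.product
        extras = []
        if p.fingerprint:
            extras.append(f"fingerprint={p.fingerprint}")
        if a.tail:
            extras.append(f"tail={a.tail}")
        if p.hypothetical:
            extras.append("hypothetical")
        lines.append(
            f"  {p.name:<16} {a.variant.start.name} → {a.variant.end.name}  "
            f"{len(p.sequence)} aa, {p.mass / 1000:.1f} kDa"
            + ("  " + "; ".join(extras) if extras else "")
        )
    lines += ["", "Relative expression:", results["ddct"].summary(), ""]
    return "\n".join(lines)
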