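# Methods

This document describes the computational conventions and algorithms used
by `nesprintx`.

## Gene models and coordinates

Internally every gene is represented in **transcription orientation** with
0-based half-open coordinates into the locus sequence. Minus-strand genes
are normalised at load time: the contig is reverse-complemented and exon
coordinates mirrored, so downstream stages never branch on strand. GFF3
input/output uses standard 1-based inclusive reference-strand coordinates
with the conventional gene → mRNA → exon feature hierarchy;
exon features carry `exon_label` and `cassette` attributes and optional
`domain` features carry `kind` (CH/SR/KASH), `exon_span` and `sr_index`.
Exon labels follow community numbering: integer ranks with an optional
prime (`6'`) for cassette exons inserted between constitutive neighbours;
primed labels sort immediately after their unprimed rank. Introns are
addressed by their flanking exon labels (`14/15`).

Model invariants are validated at construction: unique ordered labels,
non-overlapping exons with non-empty introns, ACGTN-only sequence,
KASH domains terminal, and spectrin-repeat indices strictly increasing
along the gene.

For screening a large locus in fixed-size jobs, `tile_queries` cuts the
sequence into 1 kb windows at a 500 bp step; the final window is shifted
left so the union of windows covers the sequence exactly.

Candidate transcript ends are named `"{gene}-5′I{a}/{b}"` (a start inside
intron a/b) or `"{gene}-3′E{n}"` (an end anchored at exon n).

`primer_pair_spans_intron` reports whether at least one annotated intron
lies strictly between a forward and reverse primer, the standard control
for distinguishing cDNA amplicons from genomic contamination.

## EST screening

EST-like reads are aligned with a deliberately small seed–chain–extend
aligner standing in for a BLAST-style local aligner:

1. exact k-mer seeds (k = 21) against a position index of the locus;
2. seed hits grouped by diagonal and merged into clusters, then extended
   gaplessly in both directions with an X-drop rule (+1 match, −2
   mismatch, drop limit 8);
3. the best colinear chain of extended segments is selected by dynamic
   programming on total match count, ties broken toward the leftmost
   genomic placement;
4. alignments below 90 % identity or 50 % read coverage are discarded.

A terminal adenine run of at least 8 nt is trimmed before alignment and
recorded as poly(A)-tail evidence.

An unmapped read yields an *empty* alignment value, not an error; empty
alignments are dropped before classification (classifying one violates a
precondition).

The classifier converts block structure into events, requiring a
12 nt overhang on each side of any junction so extension jitter from
sequencing errors cannot flip a call:

- **`novel_5p_start`** — first block starts ≥ 12 nt inside an intron and
  crosses ≥ 12 nt into the downstream exon;
- **`novel_3p_end`** — last block ends ≥ 12 nt inside an intron, supported
  by a trimmed poly(A) tail or by a polyadenylation hexamer within the
  retained portion. Tails are rejected as internal priming when ≥ 13 of
  the 20 genomic nt downstream of the alignment end are adenines. A tailed
  read ending mid-exon away from the annotated terminus yields an exonic
  novel end;
- **`retained_intron`** — any other block covering an exon/intron
  junction;
- **`cassette_skip` / `cassette_include`** — splice gaps exactly spanning
  cassette exons, or blocks covering a cassette exon.

Events pool by side and anchor into UTR-site candidates (minimum support
configurable; the permissive default of 1 read accepts single-EST
candidates, as curated EST catalogues routinely do), which are then
validated: a 5′ site needs a viable
Kozak context at the first ATG of its anchor exon; a 3′ site needs
poly(A)-tail evidence or a polyadenylation hexamer within 2 kb downstream
of the reading frame's stop codon.

## Variant enumeration and transcript assembly

Variants are the cross product of candidate 5′ sites × 3′ sites × cassette
inclusion patterns, filtered to colinear pairs. An intron-retained 5′ site
contributes the last 60 nt of the upstream intron as 5′UTR; an
intron-retained 3′ site appends a retained intronic extension running to a
nominal cleavage point 15 nt past the first polyadenylation hexamer. The
CDS starts at the first ATG of the first coding exon with a viable Kozak
context (falling back to the first ATG, flagged as a weak start) and runs
to the first in-frame stop. Variants with identical CDS collapse to one
representative. Variants whose coding span exceeds 5 kb are flagged
hypothetical. The pipeline exports enumerated variants as GFF3 (one mRNA
feature per variant with exon children and, for intron-retained ends, a
`retained_extension` attribute) alongside transcript and protein FASTA.

## Protein annotation

- **Kozak scoring** over the −6..+4 context: +3 for a purine at −3, +3 for
  G at +4, +1 per match to g/c/c/c/c at the remaining upstream positions
  (maximum 11). Viability follows the adequate-context rule: purine at −3
  **or** G at +4.
- **Polyadenylation signals**: canonical AATAAA/ATTAAA plus the ten most
  common single-substitution variants (AGTAAA, TATAAA, CATAAA, GATAAA,
  AATATA, AATACA, AATAGA, AAAAAG, ACTAAA, AATGAA).
- **Readthrough fingerprints**: translation continuing from the last
  coding exon's frame into a retained terminal intron until the first
  in-frame stop; the fingerprint is the residue run encoded entirely
  within the intron.
- **Frameshift tails**: a cassette exclusion shifts the frame iff the
  total excluded length is not a multiple of three; the tail is the novel
  residue run from the shift junction to the new stop, and domains at or
  downstream of the shift point are reported lost.
- **Mass**: sum of Expasy average residue masses plus one water
  (18.0153 Da); additive under concatenation up to one water per join.
- **Naming**: `p{kDa}{tag}^{gene}` with the mass rounded to the nearest
  kilodalton and the tag chosen by precedence CH > ΔKASH > KASH > none;
  name collisions gain lowercase a/b suffixes.

## Quantification

Relative expression uses the comparative-Ct method: per-sample
ΔCt = Ct(target) − Ct(reference), per-condition
ΔΔCt = mean ΔCt(condition) − mean ΔCt(control), fold = 2^−ΔΔCt. The
control fold is exactly 1.0 by construction. Confidence intervals use the
t distribution on per-replicate ΔCt values with Welch pooling of the
condition and control variances. Samples lacking target or reference
wells are dropped with a warning; a condition left with zero usable
replicates is an input error. The crosstalk report classifies per-target
fold changes qualitatively as up / down / unchanged at a configurable
fold threshold (default 1.5×); read across knockdown conditions it
exposes suppression of unintended targets.

## Synthetic truth

The random generator plants, in a single locus: alternative start sites
retained 60 nt into their upstream introns with Kozak contexts cycled
through configurable strengths; terminator introns carrying in-frame
fingerprint codons, a stop, and an AATAAA hexamer; frame-preserving and
frame-shifting cassette exons; and decoy AATAAA/ATG motifs in an unused
intron. Non-coding filler is scrubbed of polyadenylation hexamers, ATGs
and adenine runs so planted signals stay unique. Coding filler is
back-translated with a most-frequent-codon table, which provably cannot
spell a polyadenylation hexamer or an in-frame stop at codon boundaries.

The two mini-nesprin fixtures additionally use a dual-frame terminal-exon
construction: entered in frame (cassette excluded) the exon encodes the
novel frameshift tail followed by an immediate stop; entered one
nucleotide out of frame (cassette included, cassette length ≡ 1 mod 3) it
encodes the canonical KASH tail. EST simulation samples 5′- or 3′-anchored
truncations of the planted variants' mRNAs with configurable substitution
error rates (substitution-only by default; single-base indels behind the
`est_indel_rate` flag), appending 15-nt poly(A) tails to 3′-anchored
reads. Ct-table
simulation shifts the target's threshold cycle by −log₂(fold) per
condition and adds Gaussian cycle noise.

All generators are deterministic for a fixed seed; pipeline manifests
record sha256 digests of every text artifact.
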