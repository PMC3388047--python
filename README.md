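# nesprintx

Alternative-transcription variant discovery for giant multi-exon genes.

Very large spliced genes (the nesprins, titin, dystrophin, ...) produce many
more proteins than their canonical full-length transcripts: internal
promoters start transcription mid-gene, internal polyadenylation sites
terminate it early, and cassette exons reshuffle the middle. `nesprintx` is
a small, fully tested pipeline that finds and characterises such variants:

- **`gene_model`** — genome-anchored gene models with community-style exon
  numbering (including primed cassette labels like `6'`), GFF3/FASTA I/O
  with minus-strand normalisation, tiling query windows, UTR-site
  nomenclature, and intron-spanning primer checks.
- **`est_screen`** — a seed–chain–extend aligner for one-shot EST-like
  reads plus an event classifier that converts alignment block structure
  into `novel_5p_start`, `novel_3p_end`, `retained_intron`,
  `cassette_skip` and `cassette_include` calls, and aggregates them into
  validated UTR-site candidates.
- **`variants`** — mix-and-match enumeration of 5′ × 3′ × cassette-pattern
  combinations, transcript/CDS assembly (including retained intronic
  extensions), and protein-level deduplication.
- **`orf`** — translation, Kozak-context scoring, polyadenylation-signal
  scanning, retained-intron readthrough fingerprints, cassette-exclusion
  frameshift tails, domain composition (CH / spectrin repeats / KASH),
  average molecular mass and `p{kDa}{tag}^{gene}` naming.
- **`quantify`** — comparative-Ct (ΔΔCt) relative expression with
  t-distribution confidence intervals and a knockdown crosstalk report,
  in a statsmodels-style `DeltaDeltaCt(...).fit().summary()` shape.
- **`synthetic`** — deterministic planted-truth generators: a random gene
  simulator with graded Kozak contexts and fingerprinted terminators, two
  hand-built "mini-nesprin" fixtures encoding published landmark peptides,
  and EST/Ct-table simulators.
- **`pipeline` / `cli`** — end-to-end orchestration with a deterministic
  sha256 manifest and a `nesprintx` command-line interface.

## Quick start

```sh
# full pipeline on a planted gene: simulate, screen, enumerate, annotate,
# quantify; writes gene.fasta/gff3, reads, candidates, variants
# (tsv + gff3 + transcript/protein fasta), ct table, report,
# and a deterministic manifest
nesprintx run --seed 1 --out runs/demo
nesprintx report runs/demo

# or stage by stage
nesprintx simulate --seed 3 --n-reads 400 --out runs/sim
nesprintx screen --gff runs/sim/gene.gff3 --fasta runs/sim/gene.fasta \
    --gene-id sim_3 --reads runs/sim/reads.fasta --out candidates.json
nesprintx annotate --gff runs/sim/gene.gff3 --fasta runs/sim/gene.fasta \
    --gene-id sim_3 --candidates candidates.json --out variants.tsv
nesprintx quantify --ct-table runs/demo/ct_table.csv
```

From Python:

```python
import nesprintx as nx

model, truth = nx.mini_nesprin_fixture("nesp1")
variant = truth.make_variant(model, "fp90")
print(nx.readthrough_translate(model, variant).fingerprint)  # AGAGYPHQ
```

## Testing

```sh
python -m pytest             # unit + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the headline quantities (landmark
peptides, stand-in masses, motif-scanner oracle agreement, EST screen
precision/recall over seeded replicates, ΔΔCt fold recovery) and writes
them as JSON `{name: {"value": ..., "n": ...}}`.

See `docs/methods.md` for the algorithms and conventions.
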