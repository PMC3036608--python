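# phytoscan

Tools for a plant regulatory-genomics workflow in three parts:

1. **Promoter screening** — parse pre-extracted upstream-sequence FASTA
   files (TAIR dialect) or extract fixed-length upstream windows from a
   genome FASTA + GFF3, then scan them for IUPAC degenerate motifs
   (default: the PHR1-binding element `GNATATNC`). Hits are reported in
   "bp upstream of the start codon" coordinates; the genome-wide screen
   counts models with at least one site.
2. **qPCR quantification** — comparative-CT relative expression normalized
   to a reference gene (default `UBQ10`) against a per-tissue calibrator
   condition, reported as log2 values with SD over biological replicates,
   plus a dilution-series amplification-efficiency QC (pass at >= 1.85).
3. **Physiology statistics** — radiotracer shoot/root transfer percentages,
   anion-concentration summaries, fold changes, and group comparison via
   one-way ANOVA + Tukey HSD with mutants flagged against wild type.

A `synthetic` module generates promoter sets with planted motif sites, CT
tables with known log2 effects, and group/tracer datasets from stated
means/SDs — all seeded and shipped with their ground truth, so every stage
is testable without downloads.

## CLI

```bash
phytoscan screen  --fasta upstream.fasta --pattern GNATATNC --out out/
phytoscan scan    --fasta upstream.fasta --out out/          # per-hit TSV/BED
phytoscan extract --genome genome.fa --gff ann.gff3 --window 500 --out out/
phytoscan qpcr    --ct-table ct.tsv --target-gene SULTR1;3 \
                  --calibrator WT,complete --out out/
phytoscan physiology --tracer tracer.tsv --reference WT --alpha 0.05 --out out/
phytoscan simulate --kind promoters --seed 1 --n 1000 --planted 250 --out out/
phytoscan all     --seed 1 --out out/    # simulate + run every stage
```

Every run writes a JSON manifest (parameters, versions, counts, output
files) and a plain-text log next to its results; validation problems exit
nonzero with a diagnostic.

## Layout

- `src/phytoscan/promoters.py` — upstream FASTA parsing, GFF3-based extraction
- `src/phytoscan/motif.py` — IUPAC pattern compilation, strand-aware scanning, screen
- `src/phytoscan/qpcr.py` — comparative-CT quantification and efficiency QC
- `src/phytoscan/physiology.py` — transfer percentages, ANOVA + Tukey, fold changes
- `src/phytoscan/synthetic.py` — seeded generators with ground truth
- `src/phytoscan/cli.py` — `phytoscan` entry point
- `tests/` — unit, property (hypothesis) and acceptance suites; independent
  oracles (naive window scanner, exact hit-probability DP) live in
  `tests/conftest.py`
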