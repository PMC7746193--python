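# waldscan

Toolkit for asking whether a multidomain protein's variant spectrum is shaped
by survivorship bias: the domain whose damaging variants are mostly *unseen*
(because they are not tolerated) shows a lower observed/expected variant
ratio, higher sequence conservation, more disease-propensity hotspots and
lower dN/dS. `waldscan` computes all four signals from standard inputs,
compares two domains statistically, and issues a composite verdict.

## What it computes

Given an ortholog protein MSA, the in-frame coding sequence, a gnomAD-style
population variant table, a 0–100 saturation pathogenicity score matrix and a
domain annotation, the pipeline produces:

- **Conservation profile** — per-residue weighted-entropy conservation scores
  with position-based (Henikoff-style) sequence weights, binned into the
  familiar 1–9 grades (9 = most conserved), plus a grade-homogeneity
  chi-squared between the two domains. This is a tree-free approximation of
  empirical-Bayes conservation rates.
- **Tolerance landscape** — per-residue dN/dS: observed missense:synonymous
  SNVs normalized by the possible missense:synonymous ratio from exhaustive
  codon SNV enumeration, smoothed over a sliding window (default 21 codons,
  pseudocount 0.5; window 1 gives raw values). Domains are compared by
  Kolmogorov–Smirnov and Mann–Whitney tests.
- **Disease-propensity hotspots** — per-position mean of the 19 substitution
  scores, a percentile critical value (default 95th), and maximal runs of at
  least `min_run` consecutive positions strictly above it.
- **Variant-rate test** — per-domain observed missense counts against equal,
  length-proportional or opportunity-proportional expectations.
- **Verdict** — the domain winning at least 3 of the 4 criteria (lower O/E,
  higher mean grade, more hotspot positions, lower mean dN/dS); otherwise
  "inconclusive".

A synthetic-data module generates complete input bundles with configurable
site-rate heterogeneity, per-domain purifying selection and planted
functional stretches, plus a ground-truth file, for calibration and
parameter-recovery testing.

## CLI

Generate a synthetic bundle and analyze it:

```sh
waldscan simulate --seed 42 --out bundle/
waldscan run \
  --msa bundle/msa.fasta --cds bundle/cds.fasta \
  --variants bundle/variants.tsv --scores bundle/scores.tsv \
  --domains bundle/domains.json \
  --domain-a D1 --domain-b D2 --out results/
```

`waldscan run` writes `conservation.tsv`, `landscape.tsv`, `hotspots.tsv`,
`report.json` and `summary.txt`; identical inputs give byte-identical
outputs. Tunables: `--window`, `--pseudocount`, `--percentile`, `--min-run`,
`--dps-cutoff`, `--gof-model {equal,length,possible}`, `--dnds-stride`.
`waldscan simulate` accepts a YAML config mirroring `SyntheticConfig`.
Exit code 2 signals an input error.

## File formats

- **MSA / CDS**: FASTA. MSA rows must be equal length over the 20 amino
  acids plus `-` (gap) and `X` (unknown, never counted as a match); the CDS
  is a single in-frame record without stop codons.
- **Variants**: TSV with columns `cds_pos, ref_nt, alt_nt, allele_count,
  hom_count` (optional `consequence`; recomputed from the CDS when given).
  Multi-allelic sites are separate rows. Rows contradicting the CDS are
  dropped and counted.
- **Scores**: TSV with a `pos` column and one column per amino acid; the
  reference residue's cell is `NA` (or dropped on read). Scores in [0, 100].
- **Domains**: JSON `{"protein_id": ..., "length": ...,
  "domains": [{"name": ..., "start": ..., "end": ...}]}` with 1-based
  inclusive protein coordinates.

All coordinates are 1-based inclusive; codon *i* covers CDS nucleotides
3*i*−2..3*i*.

## Python API

```python
import waldscan as ws

dataset = ws.simulate_dataset(ws.SyntheticConfig(seed=42))
report, profile, landscape, hotspot_set = ws.analyze(
    dataset.alignment, dataset.cds, dataset.variants,
    dataset.matrix, dataset.annotation, "D1", "D2",
)
print(report.verdict["walds_domain"])
```
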