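# codonuse

Codon usage bias analysis of coding sequences, built around virus–host
codon co-adaptation:

- **Composition indices**: nucleotide and third-position percentages, GC1/GC2/GC3
  (plus synonymous GC3), GC12, Gravy, Aromo, per record and summarized as
  mean ± SE per subgroup.
- **ENc**: Wright's effective number of codons, with the expected ENc–GC3
  curve and plot data.
- **Neutrality regression**: OLS of GC12 on GC3 with Pearson r and p.
- **RSCU and high-frequency codons**: pooled per-subgroup RSCU; codons with
  RSCU ≥ 1.05 are high-frequency. Each virus high-frequency codon is
  classified against a host codon-usage reference as host-coincident
  (`HFC_H`, host RSCU ≥ threshold too) or virus-specific (`HFC_V`, host RSCU
  below threshold), with conversion analysis between subgroup
  classifications. *Note:* the H/V rule is inferred from the published
  table highlighting; it reproduces every published count.
- **CHFC**: the per-amino-acid contribution of a high-frequency codon
  subset, computed by both the RSCU formula route and direct counting
  (the two are algebraically identical; the package verifies this on every
  call).
- **CAI**: Sharp–Li codon adaptation index with RSCU-ratio relative
  adaptiveness and a 0.5 pseudo-count for zero host counts.
- **Correspondence analysis** of the records × 59-codon RSCU matrix.
- **Correlation matrix** (Pearson, Spearman optional) and one-way ANOVA.
- **Synthetic generator**: coding sequences under target-RSCU,
  mutation-pressure, or third-position-selection models, plus synthetic
  host tables — so the whole pipeline is testable offline.

A published 61-codon RSCU reference table (three virus subgroups —
Ca-CTV/Cr-CTV/Cs-CTV — and their three citrus hosts) is packaged at
`src/codonuse/data/ctv_citrus_rscu.tsv` and drives the fixture-mode
classification.

**Not computed**: CBI and Fop — their optimal-codon set was never published,
so any value would be arbitrary.

## CLI

```sh
# full pipeline on your data (hosts may be plain-tsv counts, kazusa-style,
# or rscu-direct tables)
codonuse run --fasta cds.fasta --groups groups.tsv \
    --host-table "C.reticulata=cr_counts.tsv" --out results/

# synthetic emulation preset (122 records, 3 subgroups, 223 codons each)
codonuse run --out results/ --seed 1

# classify the packaged published RSCU table only
codonuse hfc --fixture --out results/
```

Stage subcommands: `composition`, `rscu`, `hfc`, `chfc`, `cai`,
`neutrality`, `enc-gc3`, `coa`, `anova`, `simulate`, `run`. Inputs are
FASTA (DNA or RNA; T is normalized to U, terminal stops stripped and
flagged) and a `id<TAB>subgroup<TAB>host` group map. Outputs are TSV files
(floats at 6 significant digits) plus a JSON manifest; repeated runs on
identical inputs are byte-identical. Exit codes: 0 success, 2 validation
error, 3 computation error.

## Conventions and caveats

- Standard nuclear genetic code throughout; internal stop codons are a
  hard error (`--drop-invalid` demotes to a warning plus record exclusion);
  codons containing IUPAC ambiguity codes are excluded from all statistics.
- Subgroup RSCU is computed from pooled codon counts, not averaged
  per-record RSCU.
- The high-frequency threshold comparison is inclusive (≥ 1.05).
- ENc values above 61 (a finite-sample artifact of Wright's estimator) are
  reported with a warning, never clamped. An absent Ile class is imputed as
  the mean of the 2- and 4-fold class homozygosities; an absent 2-, 4- or
  6-fold class is an error.
- Table-style GC3/third-position percentages include Met and Trp; the
  ENc–GC3 plot uses synonymous GC3 (`GC3s`, Met/Trp excluded).
- Correspondence analysis runs on the RSCU matrix per subgroup by default;
  axis signs are fixed by making the largest-magnitude codon coordinate on
  each axis positive.
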