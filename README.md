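# srnacount

Hierarchical, rule-driven counting of small RNA-seq reads with
single-nucleotide precision.

Small RNA libraries mix miRNAs, siRNAs, piRNAs and decay fragments of longer
RNAs, often produced from the same locus and differing by as little as one
nucleotide. General-purpose counters cannot tell a 5'-shifted isomiR from its
parent miRNA, or an antisense 22G siRNA from a sense rRNA fragment over the
same interval. `srnacount` classifies and quantifies SAM alignments against
annotated features using a table of user-defined **selection rules** with
exact control over positional overlap, 5' nucleotide, read length, strand and
mismatch count, resolving ambiguity by per-rule hierarchy values.

## The selection scheme

Counting proceeds in three stages:

1. **Feature retrieval** — features are selected from a GFF3 annotation by
   source (column 2), type (column 3), or any column-9 attribute. Without a
   GFF, every reference sequence in the SAM header is one full-length feature
   and this stage is skipped (direct alignment to hairpin/transcript
   references).
2. **Positional selection** — each rule requires `Partial`, `Nested`,
   `Exact`, `5' anchored` or `3' anchored` overlap between alignment and
   feature, with signed nucleotide shifts expressed in the feature's
   orientation (negative = toward the feature's 5' end). Anchored modes
   require the read's 5' (or 3') end to coincide with the shifted feature
   end, with bounded slack at the other end. A mismatch (NM) range may also
   be required.
3. **Read matching and hierarchy** — read length, 5' nt and strandedness
   relative to the feature are tested; among all passing (feature, rule)
   pairs at a locus, only those with the **minimum hierarchy value** receive
   counts.

A sequence with *n* reads and *m* genomic alignments contributes
**(n/m)/k** to each of the *k* features passing selection at a locus; the
*m* and *k* divisors are independently optional. Library-level normalisation
is reads per million mapped (rpm) or a per-library custom factor from the
sample sheet.

Collapsed SAM input is supported: read tallies embedded in identifiers as
`<id>_count=N` / `seq<i>_xN` (format `count`) or `<id>-N` (format `fastx`)
are extracted, so one record can stand for thousands of reads.

## Worked example

Generate a synthetic miRNA/isomiR dataset (one annotated miRNA per strand,
reads with 5' offsets -1/0/+1 and 3' extensions up to 4 nt) and count it:

```sh
srnacount fixtures make mirna_isomir --seed 7 --out fx
cat > config.yml <<EOF
samples: fx/samples.csv
rules: fx/rules.csv
gff: fx/features.gff3
out_dir: out
collapsed_format: count
timestamp: false
EOF
srnacount count --config config.yml
```

The rule table holds three mutually exclusive 5'-anchored rules:

```
Select for...,with value...,Classify as...,Hierarchy,Strand,5' nt,Length,Overlap,Mismatches
Type,miRNA,isomiR_minus1,1,Sense,Any,16-28,"5' anchored, -1, 4",Any
Type,miRNA,miRNA,1,Sense,Any,16-28,"5' anchored, 0, 4",Any
Type,miRNA,isomiR_plus1,1,Sense,Any,16-28,"5' anchored, 1, 4",Any
```

`out/feature_counts.csv` lists one row per feature-classifier pair — the
same miRNA locus is subclassified by rule:

```
Feature ID,Classifier,lib1,lib2
mir-1,isomiR_minus1,41.000000,0.000000
mir-1,isomiR_plus1,51.000000,0.000000
mir-1,miRNA,43.000000,0.000000
mir-2,isomiR_minus1,0.000000,64.000000
mir-2,isomiR_plus1,0.000000,80.000000
mir-2,miRNA,0.000000,26.000000
```

Reads whose 5' end matches the annotated miRNA start exactly count as
`miRNA` (43 reads in lib1); reads shifted 1 nt upstream/downstream count as
`isomiR_minus1`/`isomiR_plus1`. `summary_stats.csv` accounts for every read:

```
Statistic,lib1,lib2
Total Reads,140,174
Mapped Reads,140,174
Assigned Reads,135.0,170.0
Unassigned Mapped Reads,5.0,4.0
```

The 5 unassigned lib1 reads are a decoy with a 3-nt 5' offset outside all
three anchored rules. The run directory also contains `rule_totals.csv`,
`class_totals.csv`, per-library `nt_len_<lib>.csv` 5' nt x length matrices,
`run.log` and `config.effective.yml` for reproducibility.

Other built-in scenarios: `rrna_vs_sirna` (hierarchy routing of sense
fragments vs antisense siRNAs), `g22_g26` (nematode 22G/26G classes),
`promoter` (upstream-shifted nested windows), `multimapper` ((n/m)/k
splitting), `gffless` (direct alignment to reference sequences). Each ships
with a brute-force-derived `truth.tsv`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates every built-in scenario from the given seed and runs the full
pipeline (SAM/GFF parsing, rule evaluation, index construction, counting and
output writing) end to end, writing the results JSON to `--out`.
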