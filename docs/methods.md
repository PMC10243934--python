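# Methods

## Model

`srnacount` treats counting as staged filtering over (alignment, feature,
rule) triples followed by hierarchical mass splitting.

**Coordinates.** All intervals are 0-based half-open internally. GFF3's
1-based closed coordinates are converted once at parse time
(`start-1, end`); SAM positions come from the alignment records directly.
Alignments are assumed ungapped and end-to-end (Bowtie v1-style), so aligned
length equals the reference span; soft/hard clips, indels, paired-end reads
and BAM/CRAM input are out of scope.

**Read attributes.** SAM stores the sequence in reference orientation. The
read's own 5' nucleotide is therefore the first stored base on '+' and the
complement of the last stored base on '-'; it is a property of the read, so
every alignment of a multi-mapping sequence reports the same value. The
ambiguity code N never satisfies a concrete 5' nt selector (a wildcard
selector accepts it). Mismatch counts come from the NM tag; an absent tag
means 0 with a one-per-file warning, matching pipelines that align with zero
mismatches. The alignment multiplicity *m* comes from the NH tag when
present, otherwise from a grouping pre-pass over read identifiers, keeping
the tool aligner-agnostic.

**Collapsed reads.** Read tallies embedded in identifiers are parsed per the
`collapsed_format` setting: `count` accepts `<id>_count=N` and `seq<i>_xN`;
`fastx` accepts `<id>-N`; `auto` probes up to 100 distinct ids and requires
a consistent match, else falls back to one read per record with a warning.
An explicitly requested format that fails to parse is a hard error naming
the offending identifier.

## Overlap selectors

Shifts are signed nucleotide offsets in the **feature's** orientation:
negative toward the feature's 5' side, positive toward its 3' side. For
'-'-strand features this reverses genomic direction, which is the only
reading under which an upstream promoter window (`Nested, -1000, 0`) or a
-1 isomiR offset behaves identically on both strands.

- `Partial`: >=1 nt intersection with the feature interval. No shifts.
- `Nested`: the alignment interval is contained in the shifted window.
- `Exact`: alignment equals the unshifted feature interval; the parser
  rejects shifts (they are never combined in practice).
- `5' anchored, s5, s3`: the alignment's strand-aware 5' end must equal the
  feature's 5' end shifted by `s5`; the alignment may extend at most `s3` nt
  beyond the feature's 3' end (negative `s3`: must stop short). There is no
  lower bound on the 3' side — minimum read length is governed by the Length
  selector. `3' anchored` is the mirror image.

Anchored rules differing only in `s5` are mutually exclusive by
construction, so isomiR classes need no hierarchy separation.

For indexing, each (feature, rule) pair contributes its shifted window to a
per-reference **step vector**: a canonical partition of [0, L) into steps
carrying frozen candidate sets, built by a boundary sweep (hence
insertion-order independent) with equal adjacent steps merged. Queries union
the sets of overlapped steps. Windows are clamped to the axis at build time;
out-of-axis queries are clamped with a warning since reads may overhang
contig ends. Strand is deliberately not an index dimension — strand
incompatibility is a rule failure, not an index miss, and must be visible to
diagnostics.

## Hierarchy and mass splitting

Among all (feature, rule) pairs passing stages 2-3 at a locus, only those
with the minimum hierarchy value count. A sequence with *n* reads and *m*
alignments contributes `(n/m)/k` to each of the *k* distinct winning
features; disabling the optional *m* or *k* divisor substitutes 1. When one
feature wins through several equal-hierarchy rules, its `(n/m)/k` share is
split evenly across those rules, so feature-level totals are invariant under
splitting one rule into mutually exclusive subrules — counts are conserved
whichever way the rule table is factored. Hierarchy is resolved
independently per alignment locus; the per-locus *k* makes any other reading
incoherent.

Features with undefined strand ('.') fail both `Sense` and `Antisense`
rules rather than matching both (conservative; logged). Their window
geometry is oriented like '+'.

**Bookkeeping.** Assigned/unassigned statistics are tracked in
read-equivalents using the true `n/m` regardless of the optional divisors,
so `assigned + unassigned = mapped reads` always holds (checked to 1e-9
relative tolerance). The 5' nt x length distribution tallies raw read counts
(*n*), not normalised weights, over sequences with at least one assigned
alignment; `all_mapped_distributions` widens it to all mapped sequences.
The rpm denominator counts each sequence once (sum of *n* over sequences
with >=1 alignment), the conventional reading of "per million mapped
reads"; when both rpm and a custom factor are configured, rpm wins with a
warning. Fractional counts are written at fixed 6-decimal precision.

## Synthetic data

The fixture generator states a small, fully controlled world: random
uniform-base genomes of a few kilobases, features placed at known
coordinates, reads derived from the genome (reverse-complemented for
antisense reads, with 5' bases forced where a scenario needs a specific
5' nt), copy counts of 1-50 per unique sequence, constant quality strings
and NM/NH tags written explicitly. Each library is emitted both collapsed
(`seq<i>_x<n>` ids) and expanded (one record per read copy) to exercise both
parsing paths; one scenario includes an unmapped record. Scenario sizes
(10-30 unique sequences; 200 reads, 20 features, 6 rules for randomized
scenarios) are chosen to keep the quadratic oracle exact and fast while
covering every selector mode, both strands, multi-mappers and decoys.

What the generator does **not** emulate: sequencing error and quality
variation, adapter remnants, realistic length/abundance distributions,
gapped alignments, or genuinely ambiguous annotation. A green suite
establishes that the engine implements the stated selection semantics
exactly — it does not validate biological annotation quality or aligner
behaviour upstream.

`brute_force_assign` is the independent oracle: a quadratic all-pairs
evaluator with no interval index and no staging, written longhand per
strand case. Engine results must match it exactly (byte-for-byte after
6-decimal formatting) on all named scenarios and on randomized ones.

## Numerical and design choices

- Weights are IEEE doubles; conservation assertions use 1e-9 relative
  tolerance, final tables fixed 6-decimal text.
- Determinism: outputs are independent of SAM record order and (given
  distinct hierarchies) rule order; candidate sets are frozensets and all
  output rows are sorted before writing.
- Empty shifted windows (a selector shrinking a short feature away) drop
  the candidate with a log note rather than erroring, since the same rule
  may be valid for longer features.
- The run directory gets a `YYYY-mm-dd_HH-MM-SS` suffix (disable with
  `timestamp: false` for scripted use) and contains `run.log` and
  `config.effective.yml`, so a run is reproducible from its outputs alone.
- `validate` parses every input and reports problems without writing
  anything; exit codes are 0 / 1 (user error) / 2 (internal error).

## Known limitations

- Ungapped single-end alignments only; no BAM/CRAM, no GTF dialect.
- No probabilistic multi-mapper rescue — only the even `(n/m)/k` split.
- No differential expression or plotting; counts tables are the interface
  to downstream tools.
- Runtime is linear in alignments times overlapped candidates; no
  C-level optimisation of the step vector is attempted, correctness and
  asymptotics being the contract here.
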