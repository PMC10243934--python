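"""Deterministic synthetic data with known ground truth.

Generates genomes, GFF3 annotations, rule tables, sample sheets and SAM
libraries for the canonical small-RNA counting scenarios (miRNA/isomiR
anchored selection, rRNA-fragment vs siRNA hierarchy, nematode 22G/26G
classes, promoter-derived reads, multi-mapping splits and GFF-less direct
alignment), plus fully randomised scenarios for property testing.

``brute_force_assign`` is an independent quadratic oracle: it evaluates every
(alignment, feature, rule) triple monolithically, with no interval index and
no staging, and is what the production engine is tested against.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .formats_io import RULES_COLUMNS, Alignment, FeatureRecord, write_gff
from .rule_engine import OverlapMode, SelectionRule, parse_rule_row

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Scenario model
# ---------------------------------------------------------------------------

@dataclass
class ReadSpec:
    """One unique sequence with its copy count and genomic alignments."""

    idx: int
    seq: str                       # read orientation
    copies: int
    # (ref, start, strand, mismatches) per genomic alignment
    alignments: list[tuple[str, int, str, int]]
    lib: int = 1
    note: str = ""                 # intended classifier, for inspection only
    mapped: bool = True

    @property
    def collapsed_id(self) -> str:
        return f"seq{self.idx}_x{self.copies}"


@dataclass
class Scenario:
    name: str
    seed: int
    genome: dict[str, str]
    features: list[FeatureRecord]
    rules_rows: list[dict[str, str]]
    reads: list[ReadSpec]
    gffless: bool = False

    @property
    def rules(self) -> list[SelectionRule]:
        return [parse_rule_row(row, index=i)
                for i, row in enumerate(self.rules_rows)]

    @property
    def axis_lengths(self) -> dict[str, int]:
        return {ref: len(seq) for ref, seq in self.genome.items()}

    def alignments(self, libs: Iterable[int] | None = None) -> list[Alignment]:
        """Materialise Alignment objects straight from the read specs."""
        out = []
        for r in self.reads:
            if not r.mapped or (libs is not None and r.lib not in libs):
                continue
            for ref, start, strand, nm in r.alignments:
                out.append(Alignment(
                    read_id=r.collapsed_id,
                    seq_count=r.copies,
                    ref_name=ref,
                    start=start,
                    end=start + len(r.seq),
                    strand=strand,
                    five_prime_nt=r.seq[0],
                    length=len(r.seq),
                    mismatches=nm,
                    n_alignments=len(r.alignments),
                ))
        return out


SCENARIO_NAMES = ("mirna_isomir", "rrna_vs_sirna", "g22_g26", "promoter",
                  "multimapper", "gffless")


def _rule_row(select_for: str = "", value: str = "", classify: str = "",
              hierarchy: int = 1, strand: str = "Any", nt5: str = "Any",
              length: str = "Any", overlap: str = "Partial",
              mismatches: str = "Any") -> dict[str, str]:
    return dict(zip(RULES_COLUMNS, [
        select_for, value, classify, str(hierarchy), strand, nt5, length,
        overlap, mismatches]))


def _random_genome(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=length))


def _feature(fid: str, ref: str, start: int, end: int, strand: str,
             ftype: str, source: str = "synthfix") -> FeatureRecord:
    return FeatureRecord(feature_id=fid, source=source, type=ftype,
                         ref_name=ref, start=start, end=end, strand=strand,
                         attributes={"ID": [fid]})


def _read_seq(genome: dict[str, list[str]], ref: str, start: int, length: int,
              strand: str) -> str:
    s = "".join(genome[ref][start:start + length])
    return s if strand == "+" else revcomp(s)


def _force_5p(genome: dict[str, list[str]], ref: str, start: int, length: int,
              strand: str, base: str) -> None:
    """Force the genome so a read at (start, length, strand) begins with base."""
    if strand == "+":
        genome[ref][start] = base
    else:
        genome[ref][start + length - 1] = revcomp(base)


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

def _sc_mirna_isomir(rng: np.random.Generator, seed: int) -> Scenario:
    genome = {"chrI": _random_genome(rng, 400)}
    features = [
        _feature("mir-1", "chrI", 100, 122, "+", "miRNA"),
        _feature("mir-2", "chrI", 200, 222, "-", "miRNA"),
    ]
    rules = [
        _rule_row("Type", "miRNA", "isomiR_minus1", 1, "Sense", "Any",
                  "16-28", "5' anchored, -1, 4"),
        _rule_row("Type", "miRNA", "miRNA", 1, "Sense", "Any",
                  "16-28", "5' anchored, 0, 4"),
        _rule_row("Type", "miRNA", "isomiR_plus1", 1, "Sense", "Any",
                  "16-28", "5' anchored, 1, 4"),
    ]
    reads: list[ReadSpec] = []
    idx = 0
    for offset in (-1, 0, 1):
        for ext in (0, 2, 4):
            # plus-strand miRNA: 5' anchor at 100+offset, 3' slack to the right
            start = 100 + offset
            length = 22 - offset + ext
            reads.append(ReadSpec(idx, _read_seq(genome, "chrI", start, length, "+"),
                                  int(rng.integers(1, 31)),
                                  [("chrI", start, "+", 0)], lib=1 + idx % 2))
            idx += 1
            # minus-strand miRNA: anchor at 221-offset, slack leftward
            end = 222 - offset
            start2 = 200 - ext
            reads.append(ReadSpec(idx, _read_seq(genome, "chrI", start2, end - start2, "-"),
                                  int(rng.integers(1, 31)),
                                  [("chrI", start2, "-", 0)], lib=1 + idx % 2))
            idx += 1
    # decoys: 5' offset outside all three anchored rules; antisense read
    reads.append(ReadSpec(idx, _read_seq(genome, "chrI", 97, 25, "+"), 5,
                          [("chrI", 97, "+", 0)], lib=1, note="unassigned"))
    idx += 1
    reads.append(ReadSpec(idx, _read_seq(genome, "chrI", 100, 22, "-"), 4,
                          [("chrI", 100, "-", 0)], lib=2, note="unassigned"))
    return Scenario("mirna_isomir", seed, {r: "".join(v) for r, v in genome.items()},
                    features, rules, reads)


def _sc_rrna_vs_sirna(rng: np.random.Generator, seed: int) -> Scenario:
    genome = {"chrI": _random_genome(rng, 2000)}
    features = [_feature("rrn-1", "chrI", 300, 1400, "+", "rRNA")]
    rules = [
        _rule_row("Type", "rRNA", "rRNA", 1, "Sense", "Any", "Any", "Partial"),
        _rule_row("Type", "rRNA", "siRNA", 7, "Any", "Any", "18-30", "Partial"),
    ]
    reads: list[ReadSpec] = []
    for i in range(12):  # sense rRNA decay fragments: match both rules
        start = int(rng.integers(300, 1360))
        length = int(rng.integers(18, 31))
        reads.append(ReadSpec(i, _read_seq(genome, "chrI", start, length, "+"),
                              int(rng.integers(1, 50)),
                              [("chrI", start, "+", 0)], lib=1 + i % 2,
                              note="rRNA"))
    for i in range(12, 22):  # antisense siRNAs: strand-incompatible with rule 1
        start = int(rng.integers(300, 1370))
        length = int(rng.integers(20, 24))
        reads.append(ReadSpec(i, _read_seq(genome, "chrI", start, length, "-"),
                              int(rng.integers(1, 50)),
                              [("chrI", start, "-", 0)], lib=1 + i % 2,
                              note="siRNA"))
    # a read outside the feature: unassigned
    reads.append(ReadSpec(22, _read_seq(genome, "chrI", 1500, 22, "+"), 7,
                          [("chrI", 1500, "+", 0)], lib=1, note="unassigned"))
    # an unmapped record: tallied in totals, never assigned
    reads.append(ReadSpec(23, "".join(rng.choice(list("ACGT"), size=21)), 3,
                          [], lib=1, note="unmapped", mapped=False))
    return Scenario("rrna_vs_sirna", seed, {r: "".join(v) for r, v in genome.items()},
                    features, rules, reads)


def _sc_g22_g26(rng: np.random.Generator, seed: int) -> Scenario:
    genome = {"chrI": _random_genome(rng, 2000)}
    features = [
        _feature("gene-1", "chrI", 100, 700, "+", "gene"),
        _feature("gene-2", "chrI", 900, 1600, "-", "gene"),
    ]
    rules = [
        _rule_row("Type", "gene", "22G", 1, "Antisense", "G", "22", "Nested"),
        _rule_row("Type", "gene", "26G", 1, "Antisense", "G", "26", "Nested"),
    ]
    reads: list[ReadSpec] = []
    idx = 0
    for feat, anti in ((features[0], "-"), (features[1], "+")):
        for length in (22, 26, 22, 26):
            start = int(rng.integers(feat.start, feat.end - length))
            _force_5p(genome, "chrI", start, length, anti, "G")
            reads.append(ReadSpec(idx, _read_seq(genome, "chrI", start, length, anti),
                                  int(rng.integers(1, 40)),
                                  [("chrI", start, anti, 0)], lib=1 + idx % 2,
                                  note=f"{length}G"))
            idx += 1
    # decoys: wrong length / wrong strand / wrong 5' nt
    _force_5p(genome, "chrI", 150, 24, "-", "G")
    reads.append(ReadSpec(idx, _read_seq(genome, "chrI", 150, 24, "-"), 5,
                          [("chrI", 150, "-", 0)], lib=1, note="unassigned"))
    idx += 1
    _force_5p(genome, "chrI", 200, 22, "+", "G")
    reads.append(ReadSpec(idx, _read_seq(genome, "chrI", 200, 22, "+"), 5,
                          [("chrI", 200, "+", 0)], lib=2, note="unassigned"))
    idx += 1
    _force_5p(genome, "chrI", 250, 22, "-", "A")
    reads.append(ReadSpec(idx, _read_seq(genome, "chrI", 250, 22, "-"), 5,
                          [("chrI", 250, "-", 0)], lib=1, note="unassigned"))
    return Scenario("g22_g26", seed, {r: "".join(v) for r, v in genome.items()},
                    features, rules, reads)


def _sc_promoter(rng: np.random.Generator, seed: int) -> Scenario:
    genome = {"chrI": _random_genome(rng, 6000)}
    features = [
        _feature("gene-1", "chrI", 1200, 2000, "+", "gene"),
        _feature("gene-2", "chrI", 3500, 4300, "-", "gene"),
    ]
    rules = [
        _rule_row("Type", "gene", "gene_body", 1, "Any", "Any", "Any",
                  "Nested, 0, 0"),
        _rule_row("Type", "gene", "promoter", 2, "Any", "Any", "Any",
                  "Nested, -1000, 0"),
    ]
    reads: list[ReadSpec] = []
    idx = 0
    for feat, upstream in ((features[0], (200, 1170)), (features[1], (4300, 5270))):
        for _ in range(5):  # body reads -> hierarchy-1 gene_body rule
            length = int(rng.integers(18, 27))
            start = int(rng.integers(feat.start, feat.end - length))
            reads.append(ReadSpec(idx, _read_seq(genome, "chrI", start, length, "+"),
                                  int(rng.integers(1, 30)),
                                  [("chrI", start, "+", 0)], lib=1 + idx % 2,
                                  note="gene_body"))
            idx += 1
        for _ in range(5):  # upstream reads -> promoter rule
            length = int(rng.integers(18, 27))
            start = int(rng.integers(upstream[0], upstream[1] - length))
            reads.append(ReadSpec(idx, _read_seq(genome, "chrI", start, length, "+"),
                                  int(rng.integers(1, 30)),
                                  [("chrI", start, "+", 0)], lib=1 + idx % 2,
                                  note="promoter"))
            idx += 1
    # straddles the gene-1 5' boundary: nested only in the promoter window
    reads.append(ReadSpec(idx, _read_seq(genome, "chrI", 1190, 22, "+"), 6,
                          [("chrI", 1190, "+", 0)], lib=1, note="promoter"))
    idx += 1
    # more than 1000 nt upstream of gene-1: unassigned
    reads.append(ReadSpec(idx, _read_seq(genome, "chrI", 150, 22, "+"), 4,
                          [("chrI", 150, "+", 0)], lib=2, note="unassigned"))
    return Scenario("promoter", seed, {r: "".join(v) for r, v in genome.items()},
                    features, rules, reads)


def _sc_multimapper(rng: np.random.Generator, seed: int) -> Scenario:
    genome = {"chrI": _random_genome(rng, 1000)}
    cassette = list(rng.choice(list("ACGT"), size=100))
    genome["chrI"][100:200] = cassette
    genome["chrI"][600:700] = cassette
    features = [
        _feature("locA", "chrI", 100, 200, "+", "repeat"),
        _feature("locB", "chrI", 600, 700, "+", "repeat"),
        _feature("locC", "chrI", 590, 690, "+", "repeat"),  # overlaps locB
    ]
    rules = [
        _rule_row("Type", "repeat", "repeat", 1, "Sense", "Any", "Any", "Nested"),
    ]
    reads = [
        # n=4, m=2; locus1 k=1, locus2 nested in locB and locC -> k=2
        ReadSpec(0, _read_seq(genome, "chrI", 120, 25, "+"), 4,
                 [("chrI", 120, "+", 0), ("chrI", 620, "+", 0)], lib=1),
        # n=6, m=2; second alignment hits no feature -> half the mass unassigned
        ReadSpec(1, _read_seq(genome, "chrI", 150, 25, "+"), 6,
                 [("chrI", 150, "+", 0), ("chrI", 300, "+", 0)], lib=1),
        # single mapper for baseline
        ReadSpec(2, _read_seq(genome, "chrI", 610, 20, "+"), 3,
                 [("chrI", 610, "+", 0)], lib=2),
    ]
    return Scenario("multimapper", seed, {r: "".join(v) for r, v in genome.items()},
                    features, rules, reads)


def _sc_gffless(rng: np.random.Generator, seed: int) -> Scenario:
    genome = {
        "mir-52": "".join(rng.choice(list("ACGT"), size=22)),
        "mir-53": "".join(rng.choice(list("ACGT"), size=24)),
        "let-7": "".join(rng.choice(list("ACGT"), size=22)),
    }
    rules = [_rule_row("", "", "miRNA", 1, "Sense", "Any", "16-30", "Partial")]
    g = {r: list(s) for r, s in genome.items()}
    reads = [
        ReadSpec(0, _read_seq(g, "mir-52", 0, 22, "+"), 11,
                 [("mir-52", 0, "+", 0)], lib=1),
        ReadSpec(1, _read_seq(g, "mir-53", 0, 21, "+"), 7,
                 [("mir-53", 0, "+", 0)], lib=1),
        ReadSpec(2, _read_seq(g, "let-7", 2, 20, "+"), 5,
                 [("let-7", 2, "+", 0)], lib=2),
        # aligned to two references: m=2, half a read-equivalent each (n=1)
        ReadSpec(3, _read_seq(g, "mir-52", 0, 20, "+"), 9,
                 [("mir-52", 0, "+", 0), ("let-7", 0, "+", 2)], lib=2),
    ]
    return Scenario("gffless", seed, genome, [], rules, reads, gffless=True)


def make_random_scenario(seed: int, n_reads: int = 200, n_features: int = 20,
                         n_rules: int = 6) -> Scenario:
    """Fully randomised scenario for property testing (no files written)."""
    rng = np.random.default_rng(seed)
    refs = {"chrI": 3000, "chrII": 2500}
    genome = {r: _random_genome(rng, n) for r, n in refs.items()}
    types = ["miRNA", "gene", "rRNA", "repeat"]
    features = []
    for i in range(n_features):
        ref = str(rng.choice(list(refs)))
        length = int(rng.integers(50, 400))
        start = int(rng.integers(0, refs[ref] - length))
        strand = str(rng.choice(["+", "-", "."], p=[0.45, 0.45, 0.1]))
        features.append(_feature(f"feat{i}", ref, start, start + length,
                                 strand, str(rng.choice(types))))
    rows = []
    for i in range(n_rules):
        mode = str(rng.choice(["Partial", "Nested", "Exact", "5' anchored",
                               "3' anchored"]))
        if mode in ("Partial", "Exact"):
            overlap = mode
        elif mode == "Nested":
            overlap = f"Nested, {int(rng.integers(-50, 5))}, {int(rng.integers(-5, 50))}"
        else:
            overlap = f"{mode}, {int(rng.integers(-2, 3))}, {int(rng.integers(0, 6))}"
        length = str(rng.choice(["Any", "18-30", "20-26", "22", "22,26"]))
        nt5 = str(rng.choice(["Any", "G", "A,G", "C,T"]))
        strand = str(rng.choice(["Sense", "Antisense", "Any"]))
        mm = str(rng.choice(["Any", "0", "0-1"]))
        sel = str(rng.choice(["Type", "Any"]))
        val = str(rng.choice(types)) if sel != "Any" else ""
        rows.append(_rule_row(sel, val, f"class{i}", int(rng.integers(1, 5)),
                              strand, nt5, length, overlap, mm))
    reads: list[ReadSpec] = []
    for i in range(n_reads):
        length = int(rng.integers(18, 31))
        if features and rng.random() < 0.7:  # feature-derived with jitter
            f = features[int(rng.integers(len(features)))]
            jitter = int(rng.integers(-4, 5))
            start = min(max(0, f.start + jitter), refs[f.ref_name] - length)
            ref = f.ref_name
            strand = str(rng.choice(["+", "-"]))
        else:
            ref = str(rng.choice(list(refs)))
            start = int(rng.integers(0, refs[ref] - length))
            strand = str(rng.choice(["+", "-"]))
        nm = int(rng.choice([0, 0, 0, 1, 2]))
        alns = [(ref, start, strand, nm)]
        if rng.random() < 0.25:  # multi-mapper
            ref2 = str(rng.choice(list(refs)))
            start2 = int(rng.integers(0, refs[ref2] - length))
            alns.append((ref2, start2, str(rng.choice(["+", "-"])), nm))
        reads.append(ReadSpec(i, _read_seq(genome, ref, start, length, strand),
                              int(rng.integers(1, 21)), alns,
                              lib=1 + i % 2))
    return Scenario(f"random{seed}", seed,
                    {r: "".join(v) for r, v in genome.items()},
                    features, rows, reads)


_BUILDERS = {
    "mirna_isomir": _sc_mirna_isomir,
    "rrna_vs_sirna": _sc_rrna_vs_sirna,
    "g22_g26": _sc_g22_g26,
    "promoter": _sc_promoter,
    "multimapper": _sc_multimapper,
    "gffless": _sc_gffless,
}


def make_scenario(name: str, seed: int,
                  out_dir: str | Path | None = None
                  ) -> tuple[Scenario, dict[str, Path]]:
    """Build a named scenario; write its files when out_dir is given."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")
    rng = np.random.default_rng(seed)
    scenario = _BUILDERS[name](rng, seed)
    paths: dict[str, Path] = {}
    if out_dir is not None:
        paths = write_scenario(scenario, out_dir)
    return scenario, paths


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def _write_fasta(genome: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for ref, seq in genome.items():
            fh.write(f">{ref}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _sam_records(reads: Sequence[ReadSpec], collapsed: bool):
    for r in reads:
        ids = ([r.collapsed_id] if collapsed
               else [f"read{r.idx}.{j}" for j in range(r.copies)])
        for rid in ids:
            if not r.mapped:
                yield (rid, 4, "*", 0, "*", r.seq, 255, None, None)
                continue
            m = len(r.alignments)
            for ref, start, strand, nm in r.alignments:
                flag = 16 if strand == "-" else 0
                stored = r.seq if strand == "+" else revcomp(r.seq)
                yield (rid, flag, ref, start + 1, f"{len(r.seq)}M", stored,
                       255, nm, m)


def _write_sam(reads: Sequence[ReadSpec], refs: dict[str, int], path: Path,
               collapsed: bool) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref, length in refs.items():
            fh.write(f"@SQ\tSN:{ref}\tLN:{length}\n")
        for rid, flag, ref, pos, cigar, seq, mapq, nm, nh in _sam_records(
                reads, collapsed):
            fields = [rid, str(flag), ref, str(pos), str(mapq), cigar, "*",
                      "0", "0", seq, "I" * len(seq)]
            if nm is not None:
                fields.append(f"NM:i:{nm}")
            if nh is not None:
                fields.append(f"NH:i:{nh}")
            fh.write("\t".join(fields) + "\n")


def write_scenario(scenario: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Write all scenario files; returns a name -> path map.

    Each library is written twice — collapsed ids (`seq<i>_x<n>`) and one
    record per read copy — referenced by samples.csv and
    samples_expanded.csv respectively.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = out / "genome.fa"
    _write_fasta(scenario.genome, paths["genome"])
    if not scenario.gffless:
        paths["gff"] = out / "features.gff3"
        write_gff(scenario.features, paths["gff"])
    paths["rules"] = out / "rules.csv"
    with open(paths["rules"], "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=RULES_COLUMNS)
        writer.writeheader()
        writer.writerows(scenario.rules_rows)
    refs = scenario.axis_lengths
    libs = sorted({r.lib for r in scenario.reads}) or [1]
    sheet_rows, sheet_rows_exp = [], []
    for lib in libs:
        lib_reads = [r for r in scenario.reads if r.lib == lib]
        for collapsed, suffix, rows in ((True, "collapsed", sheet_rows),
                                        (False, "expanded", sheet_rows_exp)):
            sam = out / f"lib{lib}_{suffix}.sam"
            _write_sam(lib_reads, refs, sam, collapsed)
            paths[f"lib{lib}_{suffix}"] = sam
            rows.append({"file": sam.name, "name": f"lib{lib}"})
    for fname, rows in (("samples.csv", sheet_rows),
                        ("samples_expanded.csv", sheet_rows_exp)):
        p = out / fname
        with open(p, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["file", "name", "norm_factor"])
            writer.writeheader()
            writer.writerows(rows)
        paths[fname.removesuffix(".csv")] = p
    paths["truth"] = out / "truth.tsv"
    _write_truth(scenario, paths["truth"])
    return paths


def _write_truth(scenario: Scenario, path: Path) -> None:
    result = brute_force_assign(scenario)
    with open(path, "w") as fh:
        fh.write("read_id\tfeature\tclassifier\texpected_weight\n")
        for r in scenario.reads:
            rows = result.per_read.get(r.collapsed_id, {})
            for (fid, cls), w in sorted(rows.items()):
                fh.write(f"{r.collapsed_id}\t{fid}\t{cls}\t{w:.6f}\n")
            leftover = result.unassigned_per_read.get(r.collapsed_id, 0.0)
            if leftover > 1e-12 or not rows:
                fh.write(f"{r.collapsed_id}\t-\tunassigned\t{leftover:.6f}\n")


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

@dataclass
class BruteForceResult:
    counts: dict[tuple[str, str], float] = field(default_factory=dict)
    rule_counts: dict[tuple[str, int], float] = field(default_factory=dict)
    class_totals: dict[str, float] = field(default_factory=dict)
    per_read: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    unassigned_per_read: dict[str, float] = field(default_factory=dict)
    assigned_mass: float = 0.0
    unassigned_mass: float = 0.0


def _bf_stage1(feat: FeatureRecord, rule: SelectionRule) -> bool:
    for fname, value in rule.stage1_filters:
        if fname == "source":
            got = [feat.source]
        elif fname == "type":
            got = [feat.type]
        else:
            got = feat.attributes.get(fname.split(":", 1)[1], [])
        if value not in got:
            return False
    return True


def _bf_positional(aln: Alignment, feat: FeatureRecord,
                   rule: SelectionRule) -> bool:
    """Monolithic positional predicate, written longhand per strand case."""
    sel = rule.overlap
    fs, fe = feat.start, feat.end
    if sel.mode is OverlapMode.PARTIAL:
        return len(set(range(aln.start, aln.end)) & set(range(fs, fe))) >= 1
    if sel.mode is OverlapMode.EXACT:
        return aln.start == fs and aln.end == fe
    if sel.mode is OverlapMode.NESTED:
        if feat.strand == "-":
            lo, hi = fs - sel.shift3, fe - sel.shift5
        else:
            lo, hi = fs + sel.shift5, fe + sel.shift3
        pos = set(range(aln.start, aln.end))
        return bool(pos) and pos <= set(range(lo, hi))
    # anchored modes
    if aln.strand == "+":
        a5, a3 = aln.start, aln.end - 1
    else:
        a5, a3 = aln.end - 1, aln.start
    if sel.mode is OverlapMode.ANCHORED5:
        if feat.strand == "-":
            return a5 == (fe - 1) - sel.shift5 and aln.start >= fs - sel.shift3
        return a5 == fs + sel.shift5 and aln.end - 1 <= (fe - 1) + sel.shift3
    if feat.strand == "-":
        return a3 == fs - sel.shift3 and aln.end - 1 <= (fe - 1) - sel.shift5
    return a3 == (fe - 1) + sel.shift3 and aln.start >= fs + sel.shift5


def _bf_read_attrs(aln: Alignment, feat: FeatureRecord,
                   rule: SelectionRule) -> bool:
    if rule.mismatch_range is not None:
        lo, hi = rule.mismatch_range
        if not lo <= aln.mismatches <= hi:
            return False
    if rule.length_set is not None and aln.length not in rule.length_set:
        return False
    if rule.nt5 is not None and aln.five_prime_nt not in rule.nt5:
        return False
    if rule.strand == "Sense":
        return feat.strand in "+-" and aln.strand == feat.strand
    if rule.strand == "Antisense":
        return feat.strand in "+-" and aln.strand != feat.strand
    return True


def brute_force_assign(scenario: Scenario,
                       normalize_by_alignments: bool = True,
                       normalize_by_features: bool = True,
                       libs: Iterable[int] | None = None) -> BruteForceResult:
    """Exhaustive per-(alignment, feature, rule) reference assigner.

    Evaluates every predicate monolithically with no interval index and no
    staging; the production engine must reproduce these numbers exactly.
    """
    rules = scenario.rules
    features = scenario.features
    if scenario.gffless:
        features = [
            FeatureRecord(feature_id=ref, source=".", type=".", ref_name=ref,
                          start=0, end=len(seq), strand="+")
            for ref, seq in scenario.genome.items()]
    res = BruteForceResult()
    for aln in scenario.alignments(libs=libs):
        passing = []
        for feat in features:
            if feat.ref_name != aln.ref_name:
                continue
            for rule in rules:
                if not scenario.gffless and not _bf_stage1(feat, rule):
                    continue
                if not _bf_positional(aln, feat, rule):
                    continue
                if not _bf_read_attrs(aln, feat, rule):
                    continue
                passing.append((feat.feature_id, rule))
        share = aln.seq_count / aln.n_alignments
        if not passing:
            res.unassigned_mass += share
            res.unassigned_per_read[aln.read_id] = \
                res.unassigned_per_read.get(aln.read_id, 0.0) + share
            continue
        res.assigned_mass += share
        h_min = min(r.hierarchy for _, r in passing)
        winners = [(fid, r) for fid, r in passing if r.hierarchy == h_min]
        k = len({fid for fid, _ in winners})
        n = aln.seq_count
        m = aln.n_alignments if normalize_by_alignments else 1
        k_eff = k if normalize_by_features else 1
        per_feat: dict[str, int] = {}
        for fid, _ in winners:
            per_feat[fid] = per_feat.get(fid, 0) + 1
        for fid, rule in winners:
            w = (n / m) / k_eff / per_feat[fid]
            res.counts[(fid, rule.classifier)] = \
                res.counts.get((fid, rule.classifier), 0.0) + w
            res.rule_counts[(fid, rule.index)] = \
                res.rule_counts.get((fid, rule.index), 0.0) + w
            res.class_totals[rule.classifier] = \
                res.class_totals.get(rule.classifier, 0.0) + w
            res.per_read.setdefault(aln.read_id, {})
            key = (fid, rule.classifier)
            res.per_read[aln.read_id][key] = \
                res.per_read[aln.read_id].get(key, 0.0) + w
    return res
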