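"""Readers and writers for every external format the counter touches.

Inputs: SAM alignments (optionally with collapsed-read counts embedded in the
read identifiers), GFF3 feature annotations, the selection-rule CSV, the
sample sheet CSV and the YAML run configuration.  Outputs: the feature counts
table, rule/class totals, summary statistics and per-library 5' nt x length
distributions.

All genomic coordinates are 0-based half-open inside the package; conversion
from GFF's 1-based closed convention happens here and nowhere else.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
import yaml
from gffutils.feature import feature_from_line

logger = logging.getLogger("srnacount")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: recognised collapsed-read identifier styles
COLLAPSED_FORMATS = ("auto", "count", "fastx", "none")

# `<anything>_count=N` or `seq<i>_xN` — collapser tools that append the tally
_COUNT_EQ_RE = re.compile(r"^.+_count=(\d+)$")
_SEQ_X_RE = re.compile(r"^seq\d+_x(\d+)$")
# FASTX-Toolkit collapser: `<id>-N`
_FASTX_RE = re.compile(r"^.+-(\d+)$")


class InputError(Exception):
    """A problem with user-supplied input files or configuration."""


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """One mapped SAM record, normalised to a strand-aware genomic interval.

    ``seq_count`` is n, the number of reads this (possibly collapsed) record
    represents; ``n_alignments`` is m, the number of genomic alignments
    reported for the sequence.
    """

    read_id: str
    seq_count: int
    ref_name: str
    start: int          # 0-based inclusive
    end: int            # 0-based exclusive
    strand: str         # '+' or '-'
    five_prime_nt: str  # in read orientation, one of A/C/G/T/N
    length: int         # aligned length in nt (== end - start, ungapped)
    mismatches: int     # NM edit distance
    n_alignments: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty alignment interval for {self.read_id}")
        if self.seq_count < 1 or self.n_alignments < 1:
            raise ValueError(f"non-positive count fields for {self.read_id}")


@dataclass
class FeatureRecord:
    """One annotated feature, coordinates 0-based half-open."""

    feature_id: str
    source: str
    type: str
    ref_name: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    attributes: dict[str, list[str]] = field(default_factory=dict)
    classifier: str | None = None

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise ValueError("feature_id must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"feature {self.feature_id}: end <= start")


@dataclass
class SampleEntry:
    path: str
    name: str
    norm_factor: float | None = None


@dataclass
class LibraryTotals:
    """Per-file tallies gathered while reading a SAM file."""

    total_sequences: int = 0   # unique read ids, mapped or not
    total_reads: int = 0       # sum of seq_count over unique read ids
    mapped_sequences: int = 0
    mapped_reads: int = 0      # sum of seq_count over ids with >=1 alignment
    alignment_records: int = 0


@dataclass
class RunConfig:
    """Validated YAML run configuration."""

    samples: str
    rules: str
    out_dir: str
    gff: str | None = None
    normalize_by_alignments: bool = True
    normalize_by_features: bool = True
    rpm: bool = False
    collapsed_format: str = "auto"
    all_mapped_distributions: bool = False
    trace: bool = False
    timestamp: bool = True
    feature_id_attribute: str | None = None


# ---------------------------------------------------------------------------
# Collapsed read-identifier parsing
# ---------------------------------------------------------------------------

def parse_collapsed_id(read_id: str, collapsed_format: str) -> int | None:
    """Extract the read tally embedded in a collapsed read identifier.

    Returns None when the id does not match the requested grammar.
    """
    if collapsed_format == "count":
        m = _COUNT_EQ_RE.match(read_id) or _SEQ_X_RE.match(read_id)
    elif collapsed_format == "fastx":
        m = _FASTX_RE.match(read_id)
    else:
        raise ValueError(f"not a concrete collapsed format: {collapsed_format}")
    return int(m.group(1)) if m else None


def _detect_collapsed_format(read_ids: Sequence[str]) -> str:
    """Try the `count` then `fastx` grammars on a sample of read ids.

    A format is accepted only if every sampled id parses; otherwise counts
    default to 1 (format 'none') with a logged warning.
    """
    if not read_ids:
        return "none"
    for fmt in ("count", "fastx"):
        if all(parse_collapsed_id(r, fmt) is not None for r in read_ids):
            return fmt
    logger.warning(
        "read ids do not match any collapsed-id grammar; treating every "
        "record as one read (example id: %r)", read_ids[0])
    return "none"


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam(path: str | Path,
             collapsed_format: str = "auto",
             ) -> tuple[list[Alignment], LibraryTotals]:
    """Parse a SAM file into :class:`Alignment` records plus library totals.

    ``seq_count`` comes from the read identifier when ``collapsed_format`` is
    not ``none`` (``auto`` probes the first 100 ids).  ``n_alignments`` comes
    from the NH tag when present, otherwise from grouping records by read id.
    Unmapped records are tallied in the totals but never emitted.
    """
    if collapsed_format not in COLLAPSED_FORMATS:
        raise InputError(f"unknown collapsed_format {collapsed_format!r}")
    path = str(path)
    raw: list[tuple] = []   # (read_id, flag-strand, ref, start, end, nt5, nm, nh)
    unmapped_ids: list[str] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as af:
        header = af.header.to_dict()
        if not header.get("SQ"):
            raise InputError(f"{path}: SAM header with @SQ lines is required")
        missing_nm_warned = False
        for rec in af:
            if rec.is_unmapped:
                unmapped_ids.append(rec.query_name)
                continue
            seq = rec.query_sequence or ""
            start = rec.reference_start
            end = rec.reference_end
            if end is None:  # CIGAR '*': assume ungapped end-to-end
                end = start + len(seq)
            strand = "-" if rec.is_reverse else "+"
            # SAM stores SEQ in reference orientation: the read's own first
            # base is SEQ[0] on '+' and the complement of SEQ[-1] on '-'.
            if seq:
                nt5 = seq[0].upper() if strand == "+" else complement(seq[-1]).upper()
            else:
                nt5 = "N"
            if nt5 not in "ACGT":
                nt5 = "N"
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                nm = 0
                if not missing_nm_warned:
                    logger.warning("%s: NM tag absent; assuming 0 mismatches", path)
                    missing_nm_warned = True
            nh = int(rec.get_tag("NH")) if rec.has_tag("NH") else None
            raw.append((rec.query_name, strand, rec.reference_name, start, end, nt5, nm, nh))

    # n_alignments fallback: group mapped records by read id
    per_id_records: dict[str, int] = {}
    for r in raw:
        per_id_records[r[0]] = per_id_records.get(r[0], 0) + 1

    mapped_ids = [r[0] for r in raw]
    if collapsed_format == "auto":
        fmt = _detect_collapsed_format(sorted(set(mapped_ids))[:100])
    else:
        fmt = collapsed_format

    def seq_count_of(read_id: str) -> int:
        if fmt == "none":
            return 1
        n = parse_collapsed_id(read_id, fmt)
        if n is None:
            raise InputError(
                f"{path}: read id {read_id!r} does not match collapsed "
                f"format {fmt!r}")
        return n

    alignments = []
    for read_id, strand, ref, start, end, nt5, nm, nh in raw:
        alignments.append(Alignment(
            read_id=read_id,
            seq_count=seq_count_of(read_id),
            ref_name=ref,
            start=start,
            end=end,
            strand=strand,
            five_prime_nt=nt5,
            length=end - start,
            mismatches=nm,
            n_alignments=nh if nh is not None else per_id_records[read_id],
        ))

    totals = LibraryTotals()
    seen: dict[str, int] = {}
    for rid in mapped_ids:
        if rid not in seen:
            seen[rid] = seq_count_of(rid)
    totals.mapped_sequences = len(seen)
    totals.mapped_reads = sum(seen.values())
    for rid in unmapped_ids:
        if rid not in seen:
            seen[rid] = seq_count_of(rid)
    totals.total_sequences = len(seen)
    totals.total_reads = sum(seen.values())
    totals.alignment_records = len(raw)
    return alignments, totals


def read_sam_references(path: str | Path) -> dict[str, int]:
    """Reference name -> length map from the @SQ header lines."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        header = af.header.to_dict()
    refs: dict[str, int] = {}
    for sq in header.get("SQ", []):
        if "LN" not in sq:
            raise InputError(f"{path}: @SQ line for {sq.get('SN')} lacks LN")
        refs[sq["SN"]] = int(sq["LN"])
    if not refs:
        raise InputError(f"{path}: SAM header with @SQ lines is required")
    return refs


def features_from_sam_header(path: str | Path) -> list[FeatureRecord]:
    """GFF-less mode: each reference sequence becomes one full-length feature.

    Stage 1 attribute filtering is bypassed for these features.
    """
    refs = read_sam_references(path)
    return [
        FeatureRecord(feature_id=name, source=".", type=".",
                      ref_name=name, start=0, end=length, strand="+")
        for name, length in refs.items()
    ]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | Path, id_attribute: str | None = None) -> list[FeatureRecord]:
    """Read a GFF3 file into FeatureRecords (0-based half-open coordinates).

    feature_id is the ``ID`` attribute, falling back to ``id_attribute`` when
    given, else ``<ref>:<start>-<end>:<strand>``.
    """
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise InputError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}")
            try:
                feat = feature_from_line(line)
                start_1based, end = int(cols[3]), int(cols[4])
            except Exception as exc:
                raise InputError(f"{path}:{lineno}: unparseable GFF line: {exc}") from exc
            if end < start_1based:
                raise InputError(f"{path}:{lineno}: end < start")
            attributes = {k: list(v) for k, v in feat.attributes.items()}
            fid = None
            for key in filter(None, ("ID", id_attribute)):
                if attributes.get(key):
                    fid = attributes[key][0]
                    break
            if fid is None:
                fid = f"{cols[0]}:{start_1based - 1}-{end}:{cols[6]}"
            records.append(FeatureRecord(
                feature_id=fid,
                source=cols[1],
                type=cols[2],
                ref_name=cols[0],
                start=start_1based - 1,
                end=end,
                strand=cols[6] if cols[6] in "+-" else ".",
                attributes=attributes,
            ))
    return records


def write_gff(features: Iterable[FeatureRecord], path: str | Path) -> None:
    """Write FeatureRecords back to GFF3 (used by the fixture generator)."""
    def esc(v: str) -> str:
        return v.replace("%", "%25").replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            attrs.setdefault("ID", [f.feature_id])
            col9 = ";".join(
                f"{k}={','.join(esc(v) for v in vs)}" for k, vs in attrs.items())
            fh.write("\t".join([
                f.ref_name, f.source or ".", f.type or ".",
                str(f.start + 1), str(f.end), ".", f.strand, ".", col9,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Rules CSV and sample sheet
# ---------------------------------------------------------------------------

RULES_COLUMNS = [
    "Select for...", "with value...", "Classify as...", "Hierarchy",
    "Strand", "5' nt", "Length", "Overlap", "Mismatches",
]


def read_rules(path: str | Path):
    """Parse the selection-rule CSV into an ordered list of SelectionRules."""
    from .rule_engine import parse_rule_row  # deferred: avoids import cycle

    rules = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise InputError(f"{path}: empty rules file; at least one rule required")
        fields = {f.strip() for f in reader.fieldnames}
        missing = [c for c in RULES_COLUMNS if c not in fields]
        if missing:
            raise InputError(f"{path}: missing rules columns: {missing}")
        for i, row in enumerate(reader):
            row = {(k or "").strip(): (v or "").strip() for k, v in row.items()}
            try:
                rules.append(parse_rule_row(row, index=i))
            except ValueError as exc:
                raise InputError(f"{path}: rule row {i + 1}: {exc}") from exc
    if not rules:
        raise InputError(f"{path}: at least one rule required")
    return rules


def read_samples(path: str | Path) -> list[SampleEntry]:
    """Parse the sample sheet CSV (columns: file, name, norm_factor)."""
    entries: list[SampleEntry] = []
    base = Path(path).parent
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "file" not in reader.fieldnames \
                or "name" not in reader.fieldnames:
            raise InputError(f"{path}: sample sheet needs 'file' and 'name' columns")
        for i, row in enumerate(reader, start=1):
            fpath = (row.get("file") or "").strip()
            name = (row.get("name") or "").strip()
            if not fpath or not name:
                raise InputError(f"{path}: row {i}: file and name are required")
            factor_s = (row.get("norm_factor") or "").strip()
            factor = None
            if factor_s:
                try:
                    factor = float(factor_s)
                except ValueError:
                    raise InputError(f"{path}: row {i}: bad norm_factor {factor_s!r}")
                if factor <= 0:
                    raise InputError(f"{path}: row {i}: norm_factor must be > 0")
            if not Path(fpath).is_absolute():
                fpath = str(base / fpath)
            entries.append(SampleEntry(path=fpath, name=name, norm_factor=factor))
    if not entries:
        raise InputError(f"{path}: sample sheet lists no libraries")
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise InputError(f"{path}: display names must be unique")
    return entries


# ---------------------------------------------------------------------------
# YAML run configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError(f"{path}: configuration must be a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise InputError(f"{path}: unknown configuration keys: {sorted(unknown)}")
    for req in ("samples", "rules", "out_dir"):
        if req not in data:
            raise InputError(f"{path}: missing required key {req!r}")
    cfg = RunConfig(**data)
    if cfg.collapsed_format not in COLLAPSED_FORMATS:
        raise InputError(
            f"{path}: collapsed_format must be one of {COLLAPSED_FORMATS}")
    base = Path(path).parent
    for attr in ("samples", "rules", "gff"):
        val = getattr(cfg, attr)
        if val is not None and not Path(val).is_absolute():
            setattr(cfg, attr, str(base / val))
    for attr in ("samples", "rules", "gff"):
        val = getattr(cfg, attr)
        if val is not None and not Path(val).exists():
            raise InputError(f"{path}: {attr} file not found: {val}")
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: getattr(cfg, k) for k in RunConfig.__dataclass_fields__},
                       fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------

def write_outputs(counts: pd.DataFrame,
                  rule_totals: pd.DataFrame,
                  class_totals: pd.DataFrame,
                  stats: pd.DataFrame,
                  nt_len_tables: Mapping[str, pd.DataFrame],
                  out_dir: str | Path) -> list[Path]:
    """Write all CSV outputs; fractional values at fixed 6-decimal precision."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str, **kw) -> None:
        p = out_dir / name
        df.to_csv(p, float_format="%.6f", **kw)
        written.append(p)

    _write(counts, "feature_counts.csv")
    _write(rule_totals, "rule_totals.csv")
    _write(class_totals, "class_totals.csv")
    _write(stats, "summary_stats.csv")
    for lib, table in nt_len_tables.items():
        safe = re.sub(r"[^\w.-]", "_", lib)
        _write(table, f"nt_len_{safe}.csv")
    return written
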