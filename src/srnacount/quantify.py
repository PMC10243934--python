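"""Per-library counting driver.

Routes every alignment through the interval index and the three-stage rule
engine, applies the (n/m)/k multi-mapping split and library-level
normalisation, and accumulates the counts matrix, rule/class totals, summary
statistics and 5' nt x length distributions.

A sequence with n reads and m genomic alignments contributes (n/m)/k to each
of the k features passing selection at a locus; m and k are independently
optional.  Mass bookkeeping (assigned vs unassigned read-equivalents) always
uses the true n/m so that assigned + unassigned equals the mapped-read total
regardless of the optional factors.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import formats_io, interval_index, rule_engine
from .formats_io import (Alignment, InputError, LibraryTotals, RunConfig,
                         SampleEntry)
from .interval_index import StepVector
from .rule_engine import SelectionRule

logger = logging.getLogger("srnacount")

NT_ROWS = ("A", "C", "G", "T", "N")


@dataclass
class LibraryStats:
    """Summary statistics for one library."""

    name: str
    total_reads: float = 0.0
    mapped_reads: float = 0.0
    mapped_sequences: int = 0
    assigned_reads: float = 0.0            # read-equivalents (true n/m)
    unassigned_mapped_reads: float = 0.0
    class_totals: dict[str, float] = field(default_factory=dict)
    normalize_by_alignments: bool = True
    normalize_by_features: bool = True
    rpm: bool = False
    rpm_denominator: float | None = None
    custom_factor: float | None = None


def assign_alignment(aln: Alignment,
                     index: Mapping[str, StepVector],
                     rules: Sequence[SelectionRule],
                     normalize_by_alignments: bool = True,
                     normalize_by_features: bool = True,
                     ) -> list[tuple[str, int, float]]:
    """Assign one alignment, returning (feature_id, rule_index, weight) rows.

    weight = (n/m)/k x 1/r where r is the number of minimum-hierarchy rules
    the feature passed; an empty list means unassigned at this locus.
    """
    sv = index.get(aln.ref_name)
    if sv is None:
        return []
    candidates = sv.query(aln.start, aln.end)
    passing: list[tuple[str, int, int]] = []
    hits_by_key: dict[tuple[str, int], interval_index.CandidateHit] = {}
    for hit in candidates:
        rule = rules[hit.rule_index]
        if rule_engine.stage2_match(aln, hit, rule) and \
                rule_engine.stage3_match(aln, hit, rule):
            passing.append((hit.feature_id, hit.rule_index, rule.hierarchy))
            hits_by_key[(hit.feature_id, hit.rule_index)] = hit
    winners, k = rule_engine.resolve_hierarchy(passing)
    if not winners:
        return []
    n = aln.seq_count
    m = aln.n_alignments if normalize_by_alignments else 1
    k_eff = k if normalize_by_features else 1
    rules_per_feature: dict[str, int] = {}
    for fid, _, _ in winners:
        rules_per_feature[fid] = rules_per_feature.get(fid, 0) + 1
    return [
        (fid, ridx, (n / m) / k_eff / rules_per_feature[fid])
        for fid, ridx, _ in winners
    ]


def count_library(sam_path: str | Path,
                  index: Mapping[str, StepVector],
                  rules: Sequence[SelectionRule],
                  sample_entry: SampleEntry,
                  config: RunConfig,
                  ) -> tuple[dict[tuple[str, int], float], LibraryStats,
                             dict[tuple[str, int], int], list[tuple]]:
    """Count one library.

    Returns per-(feature, rule) weights, library statistics, the raw-read
    (5' nt, length) tally over assigned sequences, and trace rows (empty
    unless ``config.trace``).
    """
    alignments, totals = formats_io.read_sam(
        sam_path, collapsed_format=config.collapsed_format)
    counts: dict[tuple[str, int], float] = {}
    assigned_mass = 0.0
    read_attrs: dict[str, tuple[str, int, int]] = {}  # id -> (nt5, len, n)
    assigned_ids: set[str] = set()
    trace: list[tuple] = []
    for aln in alignments:
        read_attrs.setdefault(
            aln.read_id, (aln.five_prime_nt, aln.length, aln.seq_count))
        rows = assign_alignment(
            aln, index, rules,
            normalize_by_alignments=config.normalize_by_alignments,
            normalize_by_features=config.normalize_by_features)
        share = aln.seq_count / aln.n_alignments  # true per-locus mass
        if rows:
            assigned_mass += share
            assigned_ids.add(aln.read_id)
            for fid, ridx, weight in rows:
                counts[(fid, ridx)] = counts.get((fid, ridx), 0.0) + weight
                if config.trace:
                    trace.append((aln.read_id, fid, ridx, "assigned"))
        elif config.trace:
            trace.append((aln.read_id, "-", "-", "unassigned"))

    tally_ids = set(read_attrs) if config.all_mapped_distributions else assigned_ids
    nt_len: dict[tuple[str, int], int] = {}
    for rid in tally_ids:
        nt5, length, n = read_attrs[rid]
        nt_len[(nt5, length)] = nt_len.get((nt5, length), 0) + n

    stats = LibraryStats(
        name=sample_entry.name,
        total_reads=totals.total_reads,
        mapped_reads=totals.mapped_reads,
        mapped_sequences=totals.mapped_sequences,
        assigned_reads=assigned_mass,
        unassigned_mapped_reads=totals.mapped_reads - assigned_mass,
        normalize_by_alignments=config.normalize_by_alignments,
        normalize_by_features=config.normalize_by_features,
        rpm=config.rpm,
        rpm_denominator=totals.mapped_reads if config.rpm else None,
        custom_factor=sample_entry.norm_factor,
    )
    class_totals: dict[str, float] = {}
    for (fid, ridx), w in counts.items():
        cls = rules[ridx].classifier
        class_totals[cls] = class_totals.get(cls, 0.0) + w
    stats.class_totals = class_totals
    return counts, stats, nt_len, trace


def normalize_library(column: pd.Series, stats: LibraryStats,
                      mode: str = "none") -> pd.Series:
    """Apply library-level normalisation: 'none', 'rpm' or 'custom'.

    rpm scales by 1e6 / mapped reads (mapped = sum of read tallies over
    sequences with at least one alignment); 'custom' multiplies by the sample
    sheet factor.
    """
    if mode == "none":
        return column
    if mode == "rpm":
        if not stats.mapped_reads:
            raise InputError(
                f"library {stats.name}: rpm normalisation with zero mapped reads")
        return column * (1e6 / stats.mapped_reads)
    if mode == "custom":
        if stats.custom_factor is None:
            raise InputError(
                f"library {stats.name}: no norm_factor in the sample sheet")
        return column * stats.custom_factor
    raise ValueError(f"unknown normalisation mode {mode!r}")


def _norm_mode(config: RunConfig, entry: SampleEntry) -> str:
    if config.rpm:
        if entry.norm_factor is not None:
            logger.warning("library %s: rpm requested; custom factor ignored",
                           entry.name)
        return "rpm"
    if entry.norm_factor is not None:
        return "custom"
    return "none"


def nt_len_frame(nt_len: Mapping[tuple[str, int], int]) -> pd.DataFrame:
    """5' nt x length matrix (rows A/C/G/T/N, one column per observed length)."""
    lengths = sorted({ln for _, ln in nt_len}) or []
    df = pd.DataFrame(0, index=list(NT_ROWS), columns=lengths, dtype=int)
    for (nt, ln), n in nt_len.items():
        df.loc[nt, ln] = n
    df.index.name = "5p_nt"
    return df


def load_features(config: RunConfig,
                  axis_lengths: Mapping[str, int]) -> tuple[list, bool]:
    """Features from the GFF, or one per reference sequence when absent."""
    if config.gff:
        features = formats_io.read_gff(config.gff, config.feature_id_attribute)
        kept = []
        for f in features:
            if f.ref_name not in axis_lengths:
                logger.warning("feature %s on unknown reference %s dropped",
                               f.feature_id, f.ref_name)
                continue
            kept.append(f)
        return kept, False
    return [
        formats_io.FeatureRecord(feature_id=name, source=".", type=".",
                                 ref_name=name, start=0, end=length, strand="+")
        for name, length in axis_lengths.items()
    ], True


def run(config: RunConfig) -> Path:
    """Execute a full counting run; returns the output directory."""
    out_dir = Path(config.out_dir)
    if config.timestamp:
        stamp = _dt.datetime.now().strftime("%Y-%m-%d_%H-%M-%S")
        out_dir = Path(f"{out_dir}_{stamp}")
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory {out_dir} is not writable: {exc}")

    log_handler = logging.FileHandler(out_dir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        samples = formats_io.read_samples(config.samples)
        rules = formats_io.read_rules(config.rules)

        axis_lengths: dict[str, int] = {}
        for entry in samples:
            for ref, length in formats_io.read_sam_references(entry.path).items():
                if axis_lengths.get(ref, length) != length:
                    raise InputError(
                        f"reference {ref} has conflicting lengths across libraries")
                axis_lengths[ref] = length

        features, gffless = load_features(config, axis_lengths)
        candidates = rule_engine.stage1_select(features, rules,
                                               bypass_filters=gffless)
        index = interval_index.build_index(candidates, axis_lengths)

        row_keys = sorted({(c.feature_id, rules[c.rule_index].classifier)
                           for c in candidates})
        columns: dict[str, pd.Series] = {}
        all_stats: list[LibraryStats] = []
        nt_len_tables: dict[str, pd.DataFrame] = {}
        rule_cols: dict[str, pd.Series] = {}
        for entry in samples:
            logger.info("counting library %s (%s)", entry.name, entry.path)
            counts, stats, nt_len, trace = count_library(
                entry.path, index, rules, entry, config)
            col = pd.Series(0.0, index=pd.MultiIndex.from_tuples(
                row_keys or [("", "")], names=["Feature ID", "Classifier"]))
            for (fid, ridx), w in counts.items():
                col.loc[(fid, rules[ridx].classifier)] += w
            rcol = pd.Series(0.0, index=range(len(rules)))
            for (fid, ridx), w in counts.items():
                rcol.loc[ridx] += w
            mode = _norm_mode(config, entry)
            columns[entry.name] = normalize_library(col, stats, mode)
            rule_cols[entry.name] = normalize_library(rcol, stats, mode)
            all_stats.append(stats)
            nt_len_tables[entry.name] = nt_len_frame(nt_len)
            if config.trace:
                with open(out_dir / f"trace_{entry.name}.tsv", "w") as fh:
                    fh.write("read_id\tfeature\trule\tstage\n")
                    for row in trace:
                        fh.write("\t".join(map(str, row)) + "\n")

        counts_df = pd.DataFrame(columns)
        if not row_keys:
            counts_df = counts_df.iloc[0:0]
        rule_meta = pd.DataFrame({
            "Classifier": [r.classifier for r in rules],
            "Hierarchy": [r.hierarchy for r in rules],
        }, index=pd.Index(range(len(rules)), name="Rule"))
        rule_totals = pd.concat([rule_meta, pd.DataFrame(rule_cols)], axis=1)
        class_totals = rule_totals.groupby("Classifier")[
            [e.name for e in samples]].sum()
        stats_df = summary_frame(all_stats)
        formats_io.write_outputs(counts_df, rule_totals, class_totals,
                                 stats_df, nt_len_tables, out_dir)
        formats_io.dump_config(config, out_dir / "config.effective.yml")
        logger.info("run complete: %s", out_dir)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
    return out_dir


def summary_frame(all_stats: Sequence[LibraryStats]) -> pd.DataFrame:
    rows = [
        "Total Reads", "Mapped Reads", "Mapped Sequences", "Assigned Reads",
        "Unassigned Mapped Reads", "Normalized by Alignments",
        "Normalized by Features", "RPM Denominator", "Custom Factor",
    ]
    data = {}
    for s in all_stats:
        data[s.name] = [
            s.total_reads, s.mapped_reads, s.mapped_sequences,
            s.assigned_reads, s.unassigned_mapped_reads,
            int(s.normalize_by_alignments), int(s.normalize_by_features),
            s.rpm_denominator if s.rpm_denominator is not None else "",
            s.custom_factor if s.custom_factor is not None else "",
        ]
    df = pd.DataFrame(data, index=rows)
    df.index.name = "Statistic"
    return df
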