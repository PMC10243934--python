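"""Three-stage selection: feature retrieval, positional overlap, read matching.

Stage 1 pairs features with rules whose GFF-attribute filters they satisfy and
precomputes each pair's positional match window.  Stage 2 tests an alignment's
positional overlap (partial / nested / exact / 5'- or 3'-anchored, with signed
offsets) and its mismatch count.  Stage 3 tests read attributes (5' nt,
length, strand relative to the feature) and resolves ties by hierarchy.

Offset sign convention: shifts are expressed in the FEATURE's orientation —
negative values move toward the feature's 5' side (upstream), positive toward
its 3' side.  For '-'-strand features this reverses genomic direction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Sequence

from .interval_index import CandidateHit

if TYPE_CHECKING:  # only for annotations; avoids an import cycle
    from .formats_io import Alignment, FeatureRecord

logger = logging.getLogger("srnacount")

WILDCARD = None  # wildcard fields are represented as None throughout


class OverlapMode(Enum):
    PARTIAL = "partial"
    NESTED = "nested"
    EXACT = "exact"
    ANCHORED5 = "5' anchored"
    ANCHORED3 = "3' anchored"


@dataclass(frozen=True)
class OverlapSelector:
    """Positional overlap requirement with signed nt shifts.

    ``shift5`` moves the 5' boundary/anchor, ``shift3`` the 3' one, both in
    the feature's orientation.  Partial and Exact take no shifts.
    """

    mode: OverlapMode
    shift5: int = 0
    shift3: int = 0

    def __post_init__(self) -> None:
        if self.mode in (OverlapMode.PARTIAL, OverlapMode.EXACT) and (
                self.shift5 or self.shift3):
            raise ValueError(f"{self.mode.value} overlap does not accept shifts")


@dataclass
class SelectionRule:
    """One row of the rules CSV, parsed to structured form.

    Wildcard ("Any") fields are None.  ``stage1_filters`` holds (field, value)
    pairs where field is 'source', 'type' or 'attribute:<key>'.
    """

    index: int
    overlap: OverlapSelector
    hierarchy: int
    classifier: str
    stage1_filters: list[tuple[str, str]] = field(default_factory=list)
    mismatch_range: tuple[int, int] | None = WILDCARD
    nt5: frozenset[str] | None = WILDCARD
    length_set: frozenset[int] | None = WILDCARD
    strand: str = "Any"  # Sense | Antisense | Any

    def __post_init__(self) -> None:
        if self.hierarchy < 1:
            raise ValueError("hierarchy must be a positive integer")
        if self.length_set is not None and not self.length_set:
            raise ValueError("length set must be non-empty")
        if self.mismatch_range is not None and self.mismatch_range[0] < 0:
            raise ValueError("mismatch range lower bound must be >= 0")


# ---------------------------------------------------------------------------
# Rule-field grammar
# ---------------------------------------------------------------------------

_PRIMES = str.maketrans({"′": "'", "’": "'"})


def _norm(text: str) -> str:
    return " ".join(text.translate(_PRIMES).split()).lower()


def _is_wild(text: str) -> bool:
    return _norm(text) in ("", "any", "all", "*")


def parse_overlap(text: str) -> OverlapSelector:
    """Parse an Overlap cell, e.g. ``5' anchored, 0, 4`` or ``Nested``."""
    parts = [p.strip() for p in text.split(",")]
    keyword = _norm(parts[0])
    modes = {
        "partial": OverlapMode.PARTIAL,
        "nested": OverlapMode.NESTED,
        "exact": OverlapMode.EXACT,
        "5' anchored": OverlapMode.ANCHORED5,
        "5'anchored": OverlapMode.ANCHORED5,
        "3' anchored": OverlapMode.ANCHORED3,
        "3'anchored": OverlapMode.ANCHORED3,
    }
    if keyword not in modes:
        raise ValueError(f"unknown overlap keyword {parts[0]!r}")
    shifts = parts[1:]
    if len(shifts) not in (0, 2):
        raise ValueError(f"overlap {text!r}: expected 'mode' or 'mode, shift5, shift3'")
    try:
        shift5, shift3 = (int(shifts[0]), int(shifts[1])) if shifts else (0, 0)
    except ValueError:
        raise ValueError(f"overlap {text!r}: shifts must be integers")
    return OverlapSelector(modes[keyword], shift5, shift3)


def parse_length(text: str) -> frozenset[int] | None:
    """Parse a Length cell: single values, A-B ranges, comma lists, or Any."""
    if _is_wild(text):
        return WILDCARD
    values: set[int] = set()
    for token in text.split(","):
        token = token.strip()
        m = re.fullmatch(r"(\d+)\s*[-–]\s*(\d+)", token)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if hi < lo:
                raise ValueError(f"bad length range {token!r}")
            values.update(range(lo, hi + 1))
        elif token.isdigit() and int(token) > 0:
            values.add(int(token))
        else:
            raise ValueError(f"malformed length token {token!r}")
    if not values:
        raise ValueError("empty length list")
    return frozenset(values)


def parse_nt5(text: str) -> frozenset[str] | None:
    if _is_wild(text):
        return WILDCARD
    bases = {t.strip().upper() for t in text.split(",") if t.strip()}
    if not bases or not bases <= set("ACGT"):
        raise ValueError(f"malformed 5' nt list {text!r} (allowed: A,C,G,T or Any)")
    return frozenset(bases)


def parse_mismatches(text: str) -> tuple[int, int] | None:
    if _is_wild(text):
        return WILDCARD
    m = re.fullmatch(r"(\d+)(?:\s*[-–]\s*(\d+))?", text.strip())
    if not m:
        raise ValueError(f"malformed mismatch range {text!r}")
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) else lo
    if hi < lo:
        raise ValueError(f"bad mismatch range {text!r}")
    return (lo, hi)


def parse_strand(text: str) -> str:
    norm = _norm(text)
    if norm in ("", "any"):
        return "Any"
    if norm == "sense":
        return "Sense"
    if norm == "antisense":
        return "Antisense"
    raise ValueError(f"strand must be Sense, Antisense or Any, got {text!r}")


def parse_rule_row(row: dict[str, str], index: int) -> SelectionRule:
    """Build a SelectionRule from one (stripped) rules-CSV row."""
    filters: list[tuple[str, str]] = []
    sel_field = row.get("Select for...", "")
    sel_value = row.get("with value...", "")
    if not _is_wild(sel_field) and not _is_wild(sel_value):
        norm_field = _norm(sel_field)
        if norm_field in ("source", "type"):
            filters.append((norm_field, sel_value))
        else:
            filters.append((f"attribute:{sel_field}", sel_value))
    hier_s = row.get("Hierarchy", "")
    if not hier_s.isdigit() or int(hier_s) < 1:
        raise ValueError(f"hierarchy must be a positive integer, got {hier_s!r}")
    classifier = row.get("Classify as...", "") or f"rule{index + 1}"
    return SelectionRule(
        index=index,
        overlap=parse_overlap(row.get("Overlap", "Partial") or "Partial"),
        hierarchy=int(hier_s),
        classifier=classifier,
        stage1_filters=filters,
        mismatch_range=parse_mismatches(row.get("Mismatches", "")),
        nt5=parse_nt5(row.get("5' nt", "")),
        length_set=parse_length(row.get("Length", "")),
        strand=parse_strand(row.get("Strand", "")),
    )


# ---------------------------------------------------------------------------
# Strand-aware geometry helpers
# ---------------------------------------------------------------------------

def feature_ends(start: int, end: int, strand: str) -> tuple[int, int]:
    """(5' base coordinate, 3' base coordinate) of an interval on a strand.

    Undefined strand '.' is oriented like '+' for window geometry.
    """
    if strand == "-":
        return end - 1, start
    return start, end - 1


def match_window(feature: "FeatureRecord", selector: OverlapSelector) -> tuple[int, int]:
    """Unclamped genomic match window for one (feature, rule) pair.

    For anchored modes the window spans the shifted anchor to the shifted
    slack boundary, guaranteeing every alignment that can pass Stage 2
    overlaps it; precise anchoring is re-checked in Stage 2.
    """
    fs, fe = feature.start, feature.end
    s5, s3 = selector.shift5, selector.shift3
    minus = feature.strand == "-"
    mode = selector.mode
    if mode in (OverlapMode.PARTIAL, OverlapMode.EXACT):
        return fs, fe
    if mode is OverlapMode.NESTED:
        return (fs - s3, fe - s5) if minus else (fs + s5, fe + s3)
    p5, p3 = feature_ends(fs, fe, feature.strand)
    if mode is OverlapMode.ANCHORED5:
        anchor = p5 - s5 if minus else p5 + s5
        if minus:
            left = min(fs - s3, anchor)
            return left, anchor + 1
        right = max(fe + s3, anchor + 1)
        return anchor, right
    # ANCHORED3
    anchor = p3 - s3 if minus else p3 + s3
    if minus:
        right = max(fe - s5, anchor + 1)
        return anchor, right
    left = min(fs + s5, anchor)
    return left, anchor + 1


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------

def _stage1_filter_passes(feature: "FeatureRecord", field_name: str, value: str) -> bool:
    if field_name == "source":
        return feature.source == value
    if field_name == "type":
        return feature.type == value
    key = field_name.split(":", 1)[1]
    return value in feature.attributes.get(key, [])


def stage1_select(features: Sequence["FeatureRecord"],
                  rules: Sequence[SelectionRule],
                  bypass_filters: bool = False) -> list[CandidateHit]:
    """Pair features with rules whose attribute filters they satisfy.

    In GFF-less mode (``bypass_filters``) every feature pairs with every rule.
    Pairs whose shifted window is empty are dropped with a log note.
    """
    hits: list[CandidateHit] = []
    for rule in rules:
        for feat in features:
            if not bypass_filters and not all(
                    _stage1_filter_passes(feat, f, v)
                    for f, v in rule.stage1_filters):
                continue
            win = match_window(feat, rule.overlap)
            if win[1] <= win[0]:
                logger.info("feature %s rule %d: empty match window, skipped",
                            feat.feature_id, rule.index)
                continue
            hits.append(CandidateHit(
                feature_id=feat.feature_id,
                rule_index=rule.index,
                match_window=win,
                feature_strand=feat.strand,
                ref_name=feat.ref_name,
                feature_start=feat.start,
                feature_end=feat.end,
            ))
    if not hits:
        logger.info("Stage 1 produced no (feature, rule) candidates")
    return hits


# ---------------------------------------------------------------------------
# Stage 2
# ---------------------------------------------------------------------------

def stage2_match(aln: "Alignment", hit: CandidateHit, rule: SelectionRule) -> bool:
    """Positional-overlap and mismatch test for one candidate."""
    mm = rule.mismatch_range
    if mm is not None and not mm[0] <= aln.mismatches <= mm[1]:
        return False
    mode = rule.overlap.mode
    ws, we = hit.match_window
    if mode is OverlapMode.PARTIAL:
        return aln.start < we and ws < aln.end
    if mode is OverlapMode.NESTED:
        return ws <= aln.start and aln.end <= we
    if mode is OverlapMode.EXACT:
        return aln.start == hit.feature_start and aln.end == hit.feature_end
    fs, fe = hit.feature_start, hit.feature_end
    minus = hit.feature_strand == "-"
    f5, f3 = feature_ends(fs, fe, hit.feature_strand)
    a5, a3 = feature_ends(aln.start, aln.end, aln.strand)
    s5, s3 = rule.overlap.shift5, rule.overlap.shift3
    if mode is OverlapMode.ANCHORED5:
        anchor = f5 - s5 if minus else f5 + s5
        if a5 != anchor:
            return False
        # 3' slack: read extent may pass the feature 3' end by at most shift3
        # nt (negative shift3: must stop short), measured on the genome.
        if minus:
            return aln.start >= fs - s3
        return aln.end - 1 <= fe - 1 + s3
    # ANCHORED3: anchor equality at the 3' end, slack at the 5' side
    anchor = f3 - s3 if minus else f3 + s3
    if a3 != anchor:
        return False
    if minus:
        return aln.end - 1 <= fe - 1 - s5
    return aln.start >= fs + s5


# ---------------------------------------------------------------------------
# Stage 3
# ---------------------------------------------------------------------------

def stage3_match(aln: "Alignment", hit: CandidateHit, rule: SelectionRule) -> bool:
    """Read-attribute test: length, 5' nt and strand relative to the feature.

    The ambiguity code N never satisfies a concrete nt selector; features with
    undefined strand '.' match only rules with strand Any.
    """
    if rule.length_set is not None and aln.length not in rule.length_set:
        return False
    if rule.nt5 is not None and aln.five_prime_nt not in rule.nt5:
        return False
    if rule.strand == "Any":
        return True
    if hit.feature_strand == ".":
        return False
    if rule.strand == "Sense":
        return aln.strand == hit.feature_strand
    return aln.strand != hit.feature_strand


# ---------------------------------------------------------------------------
# Hierarchy resolution
# ---------------------------------------------------------------------------

def resolve_hierarchy(passing: Iterable[tuple[str, int, int]]
                      ) -> tuple[list[tuple[str, int, int]], int]:
    """Keep only minimum-hierarchy entries; return them with k.

    ``passing`` holds (feature_id, rule_index, hierarchy) triples; k is the
    number of distinct feature ids among the winners.
    """
    passing = list(passing)
    if not passing:
        return [], 0
    h_min = min(h for _, _, h in passing)
    winners = [p for p in passing if p[2] == h_min]
    k = len({fid for fid, _, _ in winners})
    return winners, k
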