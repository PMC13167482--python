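"""Allele-aware cfDNA fragment-size analysis.

Read pairs overlapping a variant locus are classified as mutant or
non-mutant by positional CIGAR pattern matching (SNVs require the projected
base to equal the alt allele; indels require an I/D operation of exactly the
right length at exactly the right junction).  Per-fragment insert sizes are
then taken from the SAM template-length field and summarized per allele
class: sub-threshold fractions (default < 150 bp) and mono-/di-nucleosome
window statistics (50-220 bp and 221-400 bp), plus a one-sided rank-sum
test for a mutant-vs-non-mutant size shift.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import VariantSpec
from .stats import rank_sum_less, round_half_away

log = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "AlleleCall",
    "InsertSizeStats",
    "project_locus",
    "classify_read",
    "classify_fragments",
    "fragment_sizes",
    "size_summary",
    "rank_sum_less",
    "read_sam",
    "write_split_sam",
    "analyze_locus",
]

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

MUTANT = "mutant"
NON_MUTANT = "non_mutant"
OTHER_ALLELE = "other_allele"
NOT_COVERED = "not_covered"
AMBIGUOUS = "ambiguous"

FRAGMENT_LABELS = (MUTANT, NON_MUTANT, OTHER_ALLELE, AMBIGUOUS, NOT_COVERED)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_ALIGNED_OPS = set("M=X")


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read (SAM semantics, 1-based leftmost position)."""

    query_name: str
    flags: int
    chrom: str
    pos: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    tlen: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.seq and self.seq != "*":
            qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
            if qlen != len(self.seq):
                raise ValueError(
                    f"{self.query_name}: CIGAR query length {qlen} != seq length {len(self.seq)}"
                )

    @property
    def is_primary(self) -> bool:
        return not self.flags & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY | FLAG_UNMAPPED)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flags & FLAG_DUPLICATE)

    @classmethod
    def from_sam_line(cls, line: str) -> "AlignmentRecord":
        f = line.rstrip("\n").split("\t")
        if len(f) < 11:
            raise ValueError(f"malformed SAM line ({len(f)} fields): {line[:80]}")
        return cls(
            query_name=f[0],
            flags=int(f[1]),
            chrom=f[2],
            pos=int(f[3]),
            mapq=int(f[4]),
            cigar=parse_cigar(f[5]),
            seq=f[9],
            tlen=int(f[8]),
        )

    def to_sam_line(self, rnext: str = "=") -> str:
        cig = "".join(f"{n}{op}" for op, n in self.cigar) or "*"
        mate_pos = self.pos + self.tlen - _query_ref_span(self.cigar) if self.tlen > 0 else 1
        # pnext is informational only for our single-locus SAMs; recompute lazily
        return "\t".join(
            [
                self.query_name,
                str(self.flags),
                self.chrom,
                str(self.pos),
                str(self.mapq),
                cig,
                rnext,
                str(max(1, mate_pos)),
                str(self.tlen),
                self.seq,
                "*",
            ]
        )


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    """Parse a CIGAR string into ((op, length), ...); '*' -> empty tuple."""
    if cigar == "*" or not cigar:
        return ()
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return tuple((op, int(n)) for n, op in ops)


def _query_ref_span(cigar: Sequence[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in _REF_OPS)


@dataclass(frozen=True)
class AlleleCall:
    """Allele assignment of one read or fragment at one variant locus."""

    label: str
    evidence: tuple[str, ...] = ()


@dataclass
class InsertSizeStats:
    """Summary of one size window (mono / di / all)."""

    window: str
    n: int
    mean: Optional[float]
    median: Optional[float]
    fraction_below_threshold: Optional[float]
    histogram: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "n": self.n,
            "mean": self.mean,
            "median": self.median,
            "fraction_below_threshold": self.fraction_below_threshold,
        }


@dataclass
class _CigarWalk:
    """Reference-coordinate view of one alignment."""

    aligned: dict[int, int]                 # ref pos (1-based) -> query offset
    insertions: dict[int, tuple[int, int]]  # ref pos before I -> (query offset, length)
    deletions: list[tuple[int, int]]        # (ref start, ref end) 1-based inclusive


def _walk_cigar(record: AlignmentRecord) -> _CigarWalk:
    aligned: dict[int, int] = {}
    insertions: dict[int, tuple[int, int]] = {}
    deletions: list[tuple[int, int]] = []
    ref = record.pos  # next reference position to consume
    query = 0
    for op, n in record.cigar:
        if op in _ALIGNED_OPS:
            for i in range(n):
                aligned[ref + i] = query + i
            ref += n
            query += n
        elif op == "I":
            insertions[ref - 1] = (query, n)
            query += n
        elif op == "S":
            query += n
        elif op in "DN":
            if op == "D":
                deletions.append((ref, ref + n - 1))
            ref += n
        elif op in "HP":
            pass
        else:  # pragma: no cover - parse_cigar restricts the alphabet
            raise ValueError(f"unsupported CIGAR op {op!r}")
    return _CigarWalk(aligned, insertions, deletions)


def project_locus(
    record: AlignmentRecord, ref_pos: int
) -> tuple[Optional[int], Optional[str]]:
    """Project a 1-based reference position onto the read.

    Returns ``(query_offset, op)`` where op is the covering aligned CIGAR
    operation, or ``(None, None)`` if the position is not covered by an
    aligned base (including positions inside D/N operations or outside the
    read span).
    """
    ref = record.pos
    query = 0
    for op, n in record.cigar:
        if op in _ALIGNED_OPS:
            if ref <= ref_pos < ref + n:
                return query + (ref_pos - ref), op
            ref += n
            query += n
        elif op in ("I", "S"):
            query += n
        elif op in "DN":
            if ref <= ref_pos < ref + n:
                return None, None  # position deleted / skipped in this read
            ref += n
        # H and P consume nothing
    return None, None


def _has_anchor(walk: _CigarWalk, left_of: int, right_of: int, min_anchor: int) -> bool:
    """True if >= min_anchor aligned bases exist at positions <= left_of and
    >= right_of contiguously adjacent to the event."""
    for i in range(min_anchor):
        if (left_of - i) not in walk.aligned:
            return False
        if (right_of + i) not in walk.aligned:
            return False
    return True


def classify_read(
    record: AlignmentRecord, variant: VariantSpec, min_anchor: int = 1
) -> AlleleCall:
    """Classify one primary read at a variant locus by CIGAR pattern matching.

    SNV: the projected base must equal alt (mutant) or ref (non-mutant);
    any other base is ``other_allele``.  Insertion: an I operation of exactly
    the inserted length at the anchor junction, with the inserted read bases
    equal to the inserted sequence, is mutant; a junction spanned by aligned
    bases with no insertion is non-mutant.  Deletion: a D operation exactly
    covering the deleted span is mutant; a fully aligned span is non-mutant.
    In every case ``min_anchor`` aligned bases are required on both sides,
    otherwise ``not_covered``.
    """
    if record.chrom != variant.chrom:
        return AlleleCall(NOT_COVERED, (record.query_name,))
    walk = _walk_cigar(record)
    ev = (record.query_name,)

    if variant.kind == "SNV":
        pos = variant.pos
        if pos not in walk.aligned or not _has_anchor(walk, pos - 1, pos + 1, min_anchor):
            return AlleleCall(NOT_COVERED, ev)
        base = record.seq[walk.aligned[pos]]
        if base == variant.alt_allele:
            return AlleleCall(MUTANT, ev)
        if base == variant.ref_allele:
            return AlleleCall(NON_MUTANT, ev)
        return AlleleCall(OTHER_ALLELE, ev)

    anchor_pos = variant.pos
    if variant.kind == "insertion":
        inserted = variant.alt_allele[1:]
        # anchors: aligned bases at the anchor position and the next ref base
        if not _has_anchor(walk, anchor_pos, anchor_pos + 1, min_anchor):
            return AlleleCall(NOT_COVERED, ev)
        ins = walk.insertions.get(anchor_pos)
        if ins is None:
            return AlleleCall(NON_MUTANT, ev)
        qoff, length = ins
        if length == len(inserted) and record.seq[qoff : qoff + length] == inserted:
            return AlleleCall(MUTANT, ev)
        return AlleleCall(OTHER_ALLELE, ev)

    if variant.kind == "deletion":
        d = len(variant.ref_allele) - 1
        del_span = (anchor_pos + 1, anchor_pos + d)
        has_anchor = _has_anchor(walk, anchor_pos, anchor_pos + d + 1, min_anchor)
        if has_anchor and del_span in walk.deletions:
            return AlleleCall(MUTANT, ev)
        if has_anchor and all(
            p in walk.aligned for p in range(del_span[0], del_span[1] + 1)
        ):
            # fully aligned across the would-be deletion; also require no
            # insertion at the junction (that would be a different allele)
            if anchor_pos in walk.insertions:
                return AlleleCall(OTHER_ALLELE, ev)
            return AlleleCall(NON_MUTANT, ev)
        # a read whose reference extent spans the deleted region but shows a
        # different pattern (offset/partial deletion) carries another allele
        ref_end = record.pos + sum(n for op, n in record.cigar if op in _REF_OPS) - 1
        if record.pos <= anchor_pos and ref_end >= anchor_pos + d + 1:
            return AlleleCall(OTHER_ALLELE, ev)
        return AlleleCall(NOT_COVERED, ev)

    raise ValueError(f"unknown variant kind {variant.kind!r}")


_INFORMATIVE = {MUTANT, NON_MUTANT, OTHER_ALLELE}


def classify_fragments(
    records: Iterable[AlignmentRecord],
    variant: VariantSpec,
    min_mapq: int = 20,
    min_anchor: int = 1,
) -> dict[str, AlleleCall]:
    """Fragment-level allele calls, one per query name.

    Mates below ``min_mapq`` or flagged duplicate are uninformative.  Two
    informative mates that agree give their shared label; conflicting mates
    are excluded as ``ambiguous``; a single informative mate decides alone;
    otherwise the fragment is ``not_covered``.  Order of records never
    affects the result.
    """
    by_name: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        if not rec.is_primary:
            continue
        by_name.setdefault(rec.query_name, []).append(rec)

    calls: dict[str, AlleleCall] = {}
    for name, mates in by_name.items():
        if len(mates) > 2:
            raise ValueError(f"{name}: {len(mates)} primary records (expected <= 2)")
        labels = set()
        evidence: list[str] = []
        for rec in sorted(mates, key=lambda r: (r.pos, r.flags)):
            if rec.mapq < min_mapq or rec.is_duplicate:
                continue
            call = classify_read(rec, variant, min_anchor)
            if call.label in _INFORMATIVE:
                labels.add(call.label)
                evidence.append(f"mate@{rec.pos}:{call.label}")
        if not labels:
            calls[name] = AlleleCall(NOT_COVERED, tuple(evidence))
        elif len(labels) == 1:
            calls[name] = AlleleCall(labels.pop(), tuple(evidence))
        else:
            calls[name] = AlleleCall(AMBIGUOUS, tuple(evidence))
    return calls


def fragment_sizes(
    fragments: dict[str, AlleleCall],
    records: Iterable[AlignmentRecord],
    max_size: int = 1000,
) -> tuple[dict[str, list[int]], dict[str, int]]:
    """Per-label insert-size lists, one size per fragment.

    The size is |TLEN| from the mate with positive TLEN.  Fragments with
    TLEN 0, |TLEN| beyond ``max_size``, or inconsistent mate TLENs are
    excluded and tallied.
    """
    tlens: dict[str, list[int]] = {}
    for rec in records:
        if rec.is_primary:
            tlens.setdefault(rec.query_name, []).append(rec.tlen)

    sizes: dict[str, list[int]] = {label: [] for label in FRAGMENT_LABELS}
    excluded = {"tlen_zero": 0, "tlen_too_large": 0, "tlen_inconsistent": 0, "no_records": 0}
    for name, call in fragments.items():
        ts = tlens.get(name, [])
        if not ts:
            excluded["no_records"] += 1
            continue
        if len(ts) == 2 and ts[0] != -ts[1]:
            log.warning("fragment %s: mate TLENs %s are not negations; excluded", name, ts)
            excluded["tlen_inconsistent"] += 1
            continue
        size = max(ts) if len(ts) == 2 else abs(ts[0])
        if size == 0:
            excluded["tlen_zero"] += 1
            continue
        if size > max_size:
            excluded["tlen_too_large"] += 1
            continue
        sizes[call.label].append(size)
    return sizes, excluded


def size_summary(
    sizes: Sequence[int],
    threshold: int = 150,
    mono: tuple[int, int] = (50, 220),
    di: tuple[int, int] = (221, 400),
    bin_width: int = 10,
) -> dict[str, InsertSizeStats]:
    """Insert-size statistics overall and within the mono-/di-nucleosome windows.

    ``fraction_below_threshold`` uses strict ``< threshold``; window
    membership is inclusive of both endpoints.
    """
    arr = np.asarray(sizes, dtype=float)
    if np.any(arr < 0):
        raise ValueError("insert sizes must be nonnegative")
    out = {}
    for window, bounds in (("all", None), ("mono", mono), ("di", di)):
        sel = arr if bounds is None else arr[(arr >= bounds[0]) & (arr <= bounds[1])]
        n = int(sel.size)
        if n == 0:
            out[window] = InsertSizeStats(window, 0, None, None, None, [])
            continue
        frac = float(np.count_nonzero(sel < threshold) / n)
        hist = _histogram(sel, bin_width)
        out[window] = InsertSizeStats(
            window=window,
            n=n,
            mean=float(sel.mean()),
            median=float(np.median(sel)),
            fraction_below_threshold=frac,
            histogram=hist,
        )
    return out


def _histogram(arr: np.ndarray, bin_width: int) -> list[tuple[int, int]]:
    bins = (arr // bin_width).astype(int) * bin_width
    vals, counts = np.unique(bins, return_counts=True)
    return [(int(v), int(c)) for v, c in zip(vals, counts)]


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read all alignment records from a SAM text file."""
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            records.append(AlignmentRecord.from_sam_line(line))
    return records


def write_split_sam(
    records: Sequence[AlignmentRecord],
    fragments: dict[str, AlleleCall],
    out_dir: str | Path,
    header_lines: Sequence[str] = (),
) -> dict[str, Path]:
    """Write mutant-supporting and non-mutant-supporting records to separate
    SAM files; every written record belongs to a fragment with that label."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label in (MUTANT, NON_MUTANT):
        path = out_dir / f"{label}.sam"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(line.rstrip("\n") + "\n")
            for rec in records:
                if fragments.get(rec.query_name, AlleleCall(NOT_COVERED)).label == label:
                    fh.write(rec.to_sam_line() + "\n")
        paths[label] = path
    return paths


def analyze_locus(
    records: Sequence[AlignmentRecord],
    variant: VariantSpec,
    min_mapq: int = 20,
    min_anchor: int = 1,
    threshold: int = 150,
    max_size: int = 1000,
    mono: tuple[int, int] = (50, 220),
    di: tuple[int, int] = (221, 400),
) -> dict:
    """Full per-locus analysis: classify fragments, collect sizes, summarize,
    and test for a mutant-shorter size shift.  Returns a JSON-able dict."""
    fragments = classify_fragments(records, variant, min_mapq, min_anchor)
    sizes, excluded = fragment_sizes(fragments, records, max_size)
    label_counts = {label: 0 for label in FRAGMENT_LABELS}
    for call in fragments.values():
        label_counts[call.label] += 1

    summaries = {
        label: {w: s.to_dict() for w, s in size_summary(
            sizes[label], threshold, mono, di).items()}
        for label in (MUTANT, NON_MUTANT)
    }
    report = {
        "variant": variant.to_dict(),
        "fragment_counts": label_counts,
        "size_exclusions": excluded,
        "threshold_bp": threshold,
        "summaries": summaries,
    }
    for label in (MUTANT, NON_MUTANT):
        frac = summaries[label]["all"]["fraction_below_threshold"]
        report[f"{label}_percent_below_threshold"] = (
            None if frac is None else round_half_away(100.0 * frac, 1)
        )
    if sizes[MUTANT] and sizes[NON_MUTANT]:
        p, u = rank_sum_less(sizes[MUTANT], sizes[NON_MUTANT])
        report["rank_sum_less"] = {"p_value": p, "u_statistic": u}
    else:
        report["rank_sum_less"] = None
    return report


def calls_to_frame(
    fragments: dict[str, AlleleCall], sizes: dict[str, list[int]] | None = None
) -> pd.DataFrame:
    """Tabulate fragment calls (and per-label sizes when provided)."""
    rows = [
        {"fragment": name, "label": call.label, "evidence": ";".join(call.evidence)}
        for name, call in sorted(fragments.items())
    ]
    return pd.DataFrame(rows, columns=["fragment", "label", "evidence"])
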