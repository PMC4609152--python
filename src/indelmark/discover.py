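"""InDel extraction from alignment blocks and the four-condition filter
cascade used for marker development.

The cascade retains an InDel only when (a) both aligned segments of its
source block exceed a minimum length (default 1 kb), (b) its length lies
within a window (default 2-100 bp), (c) the block identity exceeds a
floor (default 95 %), and (d) it lies more than a minimum distance
(default 1 kb) from the nearest retained InDel on the same contig.
Conditions (a)-(c) are order-independent per-variant predicates; (d) is
resolved by a greedy left-to-right scan and is applied last.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

from .align import AlignmentBlock
from .io import AnchorMap

__all__ = [
    "InDelVariant",
    "FilterConfig",
    "LENGTH_CLASSES",
    "extract_indels",
    "filter_indels",
    "classify_lengths",
    "select_by_density",
    "normalize_left",
]

log = logging.getLogger(__name__)


@dataclass
class InDelVariant:
    """One insertion/deletion event on reference coordinates.

    ``ref_pos`` is the 0-based offset of the first affected reference base
    (for an insertion: the offset of the base before which the inserted
    sequence sits).  Exactly one of ref_len / qry_len is zero.
    """

    ref_contig_id: str
    ref_pos: int
    ref_len: int
    qry_len: int
    kind: str  # "insertion" | "deletion" (relative to the reference)
    block_ref: str
    ref_seq: str = ""
    qry_seq: str = ""

    def __post_init__(self) -> None:
        if (self.ref_len == 0) == (self.qry_len == 0):
            raise ValueError(
                f"pure indel needs exactly one zero allele length, got "
                f"ref_len={self.ref_len}, qry_len={self.qry_len}"
            )
        if self.kind not in {"insertion", "deletion"}:
            raise ValueError(f"unknown indel kind {self.kind!r}")

    @property
    def indel_len(self) -> int:
        return abs(self.ref_len - self.qry_len)

    @property
    def ref_end(self) -> int:
        return self.ref_pos + self.ref_len


@dataclass
class FilterConfig:
    """Thresholds of the marker filter cascade.

    Defaults follow the published barley pipeline: aligning segments
    > 1 kb, InDel lengths 2-100 bp, identity > 95 %, spacing > 1 kb.
    """

    min_segment_len: int = 1000
    min_indel_len: int = 2
    max_indel_len: int = 100
    min_identity: float = 0.95
    min_spacing: int = 1000

    def __post_init__(self) -> None:
        if not (1 <= self.min_indel_len <= self.max_indel_len):
            raise ValueError("need 1 <= min_indel_len <= max_indel_len")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_segment_len < 0 or self.min_spacing < 0:
            raise ValueError("lengths must be non-negative")


def normalize_left(seq: str, pos: int, allele: str) -> int:
    """Shift an indel allele leftward to its canonical position.

    ``seq`` is the sequence the allele is placed on (reference for a
    deletion, i.e. the allele is seq[pos:pos+len]; for an insertion the
    allele sits between seq[pos-1] and seq[pos]).  Standard VCF-style
    left-alignment: while the base left of the event equals the last base
    of the allele, rotate the allele right and shift left.
    """
    if not allele:
        return pos
    allele = list(allele)
    while pos > 0 and seq[pos - 1] == allele[-1]:
        allele.insert(0, allele.pop())
        pos -= 1
    return pos


def extract_indels(block: AlignmentBlock) -> list[InDelVariant]:
    """One variant per maximal gap run in either gapped row.

    Gap runs separated by at least one match/mismatch column are distinct
    variants.  Positions are reported on reference coordinates and
    left-normalised; a gap run bordered by mismatches is still a pure
    indel (mismatches are never absorbed into the allele).
    """
    variants: list[InDelVariant] = []
    ref_cursor = block.ref_start
    qry_cursor = block.qry_start
    i = 0
    rrow, qrow = block.ref_row, block.qry_row
    n = len(rrow)
    ref_seq_cache: list[str] = []
    while i < n:
        a, b = rrow[i], qrow[i]
        if a == "-" and b == "-":
            raise ValueError("column gapped in both rows")
        if b == "-":  # deletion relative to reference (query lacks bases)
            j = i
            while j < n and qrow[j] == "-":
                j += 1
            allele = rrow[i:j]
            variants.append(
                InDelVariant(
                    ref_contig_id=block.ref_contig_id,
                    ref_pos=ref_cursor,
                    ref_len=len(allele),
                    qry_len=0,
                    kind="deletion",
                    block_ref=block.id,
                    ref_seq=allele,
                )
            )
            ref_cursor += len(allele)
            i = j
        elif a == "-":  # insertion relative to reference
            j = i
            while j < n and rrow[j] == "-":
                j += 1
            allele = qrow[i:j]
            variants.append(
                InDelVariant(
                    ref_contig_id=block.ref_contig_id,
                    ref_pos=ref_cursor,
                    ref_len=0,
                    qry_len=len(allele),
                    kind="insertion",
                    block_ref=block.id,
                    qry_seq=allele,
                )
            )
            qry_cursor += len(allele)
            i = j
        else:
            ref_cursor += 1
            qry_cursor += 1
            i += 1

    # Left-normalise against the ungapped reference slice of the block.
    ref_ungapped = rrow.replace("-", "")
    offset = block.ref_start
    for v in variants:
        allele = v.ref_seq if v.kind == "deletion" else v.qry_seq
        v.ref_pos = offset + normalize_left(ref_ungapped, v.ref_pos - offset, allele)
    variants.sort(key=lambda v: v.ref_pos)
    return variants


def filter_indels(
    variants: list[InDelVariant],
    blocks: list[AlignmentBlock],
    cfg: FilterConfig = FilterConfig(),
    report: dict | None = None,
) -> list[InDelVariant]:
    """Apply the four filter conditions; returns the surviving variants.

    ``report``, if given, is filled with the attrition funnel: counts
    after the segment-length, indel-length, identity and spacing stages.
    """
    by_id = {b.id: b for b in blocks}
    for v in variants:
        if v.block_ref not in by_id:
            raise KeyError(f"variant references unknown block {v.block_ref!r}")

    def seg_ok(v: InDelVariant) -> bool:
        b = by_id[v.block_ref]
        return (
            b.ref_segment_len > cfg.min_segment_len
            and b.qry_segment_len > cfg.min_segment_len
        )

    def len_ok(v: InDelVariant) -> bool:
        return cfg.min_indel_len <= v.indel_len <= cfg.max_indel_len

    def ident_ok(v: InDelVariant) -> bool:
        return by_id[v.block_ref].identity > cfg.min_identity

    stage = [v for v in variants if seg_ok(v)]
    n_seg = len(stage)
    stage = [v for v in stage if len_ok(v)]
    n_len = len(stage)
    stage = [v for v in stage if ident_ok(v)]
    n_ident = len(stage)

    # Spacing, greedy left-to-right per contig: keep a variant only when
    # its position is more than min_spacing past the last kept one.
    kept: list[InDelVariant] = []
    last_kept: dict[str, int] = {}
    for v in sorted(stage, key=lambda v: (v.ref_contig_id, v.ref_pos)):
        last = last_kept.get(v.ref_contig_id)
        if last is None or v.ref_pos - last > cfg.min_spacing:
            kept.append(v)
            last_kept[v.ref_contig_id] = v.ref_pos
    if report is not None:
        report.update(
            raw=len(variants),
            after_segment_filter=n_seg,
            after_length_filter=n_len,
            after_identity_filter=n_ident,
            after_spacing=len(kept),
        )
    return kept


LENGTH_CLASSES: list[tuple[str, int, int]] = [
    ("1-2", 1, 2),
    ("3-10", 3, 10),
    ("11-20", 11, 20),
    ("21-30", 21, 30),
    ("31-40", 31, 40),
    ("41-50", 41, 50),
    (">50", 51, 10**9),
]


def classify_lengths(variants: list[InDelVariant]) -> dict[str, int]:
    """Histogram of indel lengths over the standard reporting classes
    (1-2, 3-10, 11-20, 21-30, 31-40, 41-50, >50 bp; bounds inclusive)."""
    hist = {name: 0 for name, _, _ in LENGTH_CLASSES}
    for v in variants:
        for name, lo, hi in LENGTH_CLASSES:
            if lo <= v.indel_len <= hi:
                hist[name] += 1
                break
    return hist


def select_by_density(
    variants: list[InDelVariant],
    anchors: AnchorMap,
    target_per_cm: float = 1.0,
) -> list[InDelVariant]:
    """Even-density selection: at most one variant per cM bin.

    The cM axis of each chromosome is partitioned into bins of width
    1/target_per_cm; within a bin the variant with the largest indel
    length wins (ties: smallest contig id, then smallest ref_pos).
    Variants on unanchored contigs are skipped with a logged count.
    """
    if target_per_cm <= 0:
        raise ValueError("target_per_cm must be positive")
    width = 1.0 / target_per_cm
    best: dict[tuple[str, int], InDelVariant] = {}
    skipped = 0
    for v in sorted(variants, key=lambda v: (v.ref_contig_id, v.ref_pos)):
        pos = anchors.position(v.ref_contig_id)
        if pos is None:
            skipped += 1
            continue
        chrom, cm = pos
        key = (chrom, int(cm / width))
        cur = best.get(key)
        if cur is None or (
            (-v.indel_len, v.ref_contig_id, v.ref_pos)
            < (-cur.indel_len, cur.ref_contig_id, cur.ref_pos)
        ):
            best[key] = v
    if skipped:
        log.info("select_by_density: skipped %d variants on unanchored contigs", skipped)
    return [best[k] for k in sorted(best)]
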