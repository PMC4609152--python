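"""Desk-scale pairwise alignment of contig pairs.

Replaces the BWA + LASTZ step of genome-scale marker pipelines with an
in-process seed-chain-extend aligner: unique shared k-mers seed the
alignment, the longest colinear chain is kept, and inter-anchor gaps are
filled by affine-gap global alignment (match +1, mismatch -2, gap open -4,
gap extend -1).  Forward strand only: cultivar assemblies / fixtures are
assumed co-oriented.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

from Bio import Align

from .io import Contig

__all__ = [
    "AlignmentBlock",
    "AlignScores",
    "seed_anchors",
    "chain_anchors",
    "align_block",
    "align_pair",
    "compute_identity",
    "pair_contigs",
]

MAX_SEGMENT = 20_000  # inter-anchor segments beyond this split the block


@dataclass(frozen=True)
class AlignScores:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1


@dataclass
class AlignmentBlock:
    """A gapped pairwise alignment between one reference segment and one
    query segment; coordinates 0-based half-open on the ungapped sequences."""

    ref_contig_id: str
    qry_contig_id: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    ref_row: str
    qry_row: str
    identity: float = 0.0

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.qry_row):
            raise ValueError("gapped rows differ in length")

    @property
    def id(self) -> str:
        return (
            f"{self.ref_contig_id}:{self.ref_start}-{self.ref_end}"
            f"|{self.qry_contig_id}:{self.qry_start}-{self.qry_end}"
        )

    @property
    def ref_segment_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_segment_len(self) -> int:
        return self.qry_end - self.qry_start


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in counts:
            counts[kmer] = -1  # repeated: poisoned
        else:
            counts[kmer] = i
    return {kmer: pos for kmer, pos in counts.items() if pos >= 0 and "N" not in kmer}


def seed_anchors(ref: Contig, qry: Contig, k: int = 21) -> list[tuple[int, int]]:
    """Positions of k-mers occurring exactly once in each sequence and
    shared by both, sorted by reference position.  Requires k >= 8."""
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    ref_u = _unique_kmers(ref.sequence, k)
    qry_u = _unique_kmers(qry.sequence, k)
    anchors = [
        (rpos, qry_u[kmer]) for kmer, rpos in ref_u.items() if kmer in qry_u
    ]
    anchors.sort()
    return anchors


def chain_anchors(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain strictly increasing in both coordinates.

    Anchors must be sorted by ref position (seed_anchors guarantees unique
    ref positions, so this reduces to a longest strictly increasing
    subsequence on the query coordinate).  Patience algorithm, O(n log n),
    with a deterministic smallest-tail tie rule.
    """
    if not anchors:
        return []
    # Sort ties on ref descending in qry so a strictly-increasing qry
    # subsequence is automatically strictly increasing in ref as well.
    anchors = sorted(anchors, key=lambda a: (a[0], -a[1]))
    qs = [q for _, q in anchors]
    tails: list[int] = []          # smallest tail q for each chain length
    tails_idx: list[int] = []
    prev = [-1] * len(qs)
    for i, q in enumerate(qs):
        j = bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tails_idx.append(i)
        else:
            tails[j] = q
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain: list[tuple[int, int]] = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(anchors[i])
        i = prev[i]
    chain.reverse()
    return chain


def _aligner(scores: AlignScores) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scores.match
    a.mismatch_score = scores.mismatch
    a.open_gap_score = scores.gap_open
    a.extend_gap_score = scores.gap_extend
    return a


def _align_segment(a: str, b: str, scores: AlignScores) -> tuple[str, str]:
    """Affine-gap global alignment of two (possibly empty) segments."""
    if not a and not b:
        return "", ""
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    aln = _aligner(scores).align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _merge_diagonal_runs(
    chain: list[tuple[int, int]], k: int
) -> list[tuple[int, int, int]]:
    """Collapse overlapping same-diagonal anchors into maximal exact-match
    runs (ref_start, qry_start, length)."""
    runs: list[tuple[int, int, int]] = []
    for r, q in chain:
        if runs:
            r0, q0, ln = runs[-1]
            if r - q == r0 - q0 and r <= r0 + ln:  # same diagonal, contiguous
                runs[-1] = (r0, q0, r + k - r0)
                continue
            if r < r0 + ln or q < q0 + ln:  # off-diagonal overlap: drop anchor
                continue
        runs.append((r, q, k))
    return runs


def align_block(
    ref: Contig,
    qry: Contig,
    chain: list[tuple[int, int]],
    k: int = 21,
    scores: AlignScores = AlignScores(),
    end_extension_min_identity: float = 0.9,
) -> AlignmentBlock:
    """Build one gapped alignment block from a colinear anchor chain.

    Inter-anchor gaps are filled by affine-gap global alignment; the block
    is extended to the sequence ends when the identity of the extension is
    at least ``end_extension_min_identity``.  Inter-anchor segments longer
    than 20 kb are refused (callers split the chain; see align_pair).
    """
    if not chain:
        raise ValueError("empty anchor chain")
    runs = _merge_diagonal_runs(chain, k)
    ref_rows: list[str] = []
    qry_rows: list[str] = []
    r_cur, q_cur = runs[0][0], runs[0][1]
    ref_start, qry_start = r_cur, q_cur
    for r, q, ln in runs:
        seg_r = ref.sequence[r_cur:r]
        seg_q = qry.sequence[q_cur:q]
        if len(seg_r) > MAX_SEGMENT or len(seg_q) > MAX_SEGMENT:
            raise ValueError(
                f"inter-anchor segment of {max(len(seg_r), len(seg_q))} bp "
                f"exceeds {MAX_SEGMENT} bp; split the chain"
            )
        rr, qq = _align_segment(seg_r, seg_q, scores)
        ref_rows.append(rr)
        qry_rows.append(qq)
        match = ref.sequence[r : r + ln]
        ref_rows.append(match)
        qry_rows.append(match)
        r_cur, q_cur = r + ln, q + ln
    ref_end, qry_end = r_cur, q_cur

    # End extension: include flanks when they still look homologous.
    left_r, left_q = ref.sequence[:ref_start], qry.sequence[:qry_start]
    if left_r and left_q and min(len(left_r), len(left_q)) <= MAX_SEGMENT:
        rr, qq = _align_segment(left_r, left_q, scores)
        if _rows_identity(rr, qq) >= end_extension_min_identity:
            ref_rows.insert(0, rr)
            qry_rows.insert(0, qq)
            ref_start, qry_start = 0, 0
    right_r = ref.sequence[ref_end:]
    right_q = qry.sequence[qry_end:]
    if right_r and right_q and min(len(right_r), len(right_q)) <= MAX_SEGMENT:
        rr, qq = _align_segment(right_r, right_q, scores)
        if _rows_identity(rr, qq) >= end_extension_min_identity:
            ref_rows.append(rr)
            qry_rows.append(qq)
            ref_end, qry_end = len(ref.sequence), len(qry.sequence)

    block = AlignmentBlock(
        ref_contig_id=ref.id,
        qry_contig_id=qry.id,
        ref_start=ref_start,
        ref_end=ref_end,
        qry_start=qry_start,
        qry_end=qry_end,
        ref_row="".join(ref_rows),
        qry_row="".join(qry_rows),
    )
    block.identity = compute_identity(block)
    return block


def _rows_identity(ref_row: str, qry_row: str) -> float:
    matches = mismatches = 0
    for a, b in zip(ref_row, qry_row):
        if a == "-" or b == "-" or a == "N" or b == "N":
            continue
        if a == b:
            matches += 1
        else:
            mismatches += 1
    if matches + mismatches == 0:
        return 0.0
    return matches / (matches + mismatches)


def compute_identity(block: AlignmentBlock) -> float:
    """Identity = matches / (matches + mismatches).

    Gap columns are excluded from the denominator (LASTZ-style identity),
    as are columns containing N.  A block with zero non-gap columns has no
    defined identity and raises.
    """
    matches = mismatches = 0
    for a, b in zip(block.ref_row, block.qry_row):
        if a == "-" or b == "-" or a == "N" or b == "N":
            continue
        if a == b:
            matches += 1
        else:
            mismatches += 1
    total = matches + mismatches
    if total == 0:
        raise ValueError("identity undefined: block has no aligned base columns")
    return matches / total


def _split_chain(chain: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    parts: list[list[tuple[int, int]]] = [[chain[0]]]
    for (r0, q0), (r1, q1) in zip(chain, chain[1:]):
        if r1 - r0 > MAX_SEGMENT or q1 - q0 > MAX_SEGMENT:
            parts.append([])
        parts[-1].append((r1, q1))
    return parts


def align_pair(
    ref: Contig,
    qry: Contig,
    k: int = 21,
    scores: AlignScores = AlignScores(),
) -> list[AlignmentBlock]:
    """Seed, chain and align one contig pair; returns zero or more blocks.

    Chains whose inter-anchor distance exceeds 20 kb are split into
    separate blocks to bound the global-alignment problem size.
    """
    anchors = seed_anchors(ref, qry, k)
    chain = chain_anchors(anchors)
    if not chain:
        return []
    blocks = []
    for part in _split_chain(chain):
        blocks.append(align_block(ref, qry, part, k=k, scores=scores))
    return blocks


def pair_contigs(
    ref_contigs: list[Contig], qry_contigs: list[Contig], k: int = 21, min_shared: int = 5
) -> list[tuple[Contig, Contig]]:
    """Pair each query contig with the reference contig sharing the most
    unique k-mers (the stand-in for read-mapping-based contig pairing).

    Pairs sharing fewer than ``min_shared`` unique k-mers are dropped.
    """
    index: dict[str, str] = {}
    counts_per_ref: dict[str, dict[str, int]] = {}
    for rc in ref_contigs:
        for kmer in _unique_kmers(rc.sequence, k):
            if kmer in index:
                index[kmer] = ""  # shared between ref contigs: ambiguous
            else:
                index[kmer] = rc.id
    ref_by_id = {c.id: c for c in ref_contigs}
    pairs: list[tuple[Contig, Contig]] = []
    for qc in qry_contigs:
        votes: dict[str, int] = {}
        for kmer in _unique_kmers(qc.sequence, k):
            rid = index.get(kmer, "")
            if rid:
                votes[rid] = votes.get(rid, 0) + 1
        if not votes:
            continue
        best = max(sorted(votes), key=lambda rid: votes[rid])
        if votes[best] >= min_shared:
            pairs.append((ref_by_id[best], qc))
    return pairs
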