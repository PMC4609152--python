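"""Anchoring of heterogeneous marker panels and single-map integration.

SSR primer pairs and DArT/SNP/InDel reference sequences are anchored to
the reference assembly by a k-mer-seeded local alignment (the desk-scale
stand-in for a BLAST search); hits are ranked by score, which plays the
role of ascending E-value — the ordering is what matters, not the E-value
magnitude.  Anchored markers inherit the genetic (cM) position of their
contig from the anchor map; markers on unanchored contigs, or with tied
best hits (ambiguous placement), are removed.  Markers sharing a genetic
position are collapsed to one locus for map drawing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .align import AlignScores
from .io import AnchorMap, Contig, MarkerRecord

__all__ = [
    "AnchorHit",
    "GenomeIndex",
    "SSRAnchor",
    "SSRRejection",
    "IntegratedMap",
    "MapSummary",
    "anchor_sequence",
    "anchor_ssr",
    "assign_genetic_position",
    "dedup_loci",
    "summarize",
    "build_integrated_map",
]


@dataclass(frozen=True)
class AnchorHit:
    query_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    score: float
    evalue_rank: int = 0


class GenomeIndex:
    """k-mer index over an assembly for seeded local-alignment search."""

    def __init__(self, contigs: list[Contig], k: int = 13,
                 scores: AlignScores = AlignScores()):
        self.contigs = {c.id: c for c in contigs}
        self.k = k
        self.scores = scores
        self._index: dict[str, list[tuple[str, int]]] = {}
        for c in contigs:
            seq = c.sequence
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self._index.setdefault(kmer, []).append((c.id, i))
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.match_score = scores.match
        self._aligner.mismatch_score = scores.mismatch
        self._aligner.open_gap_score = scores.gap_open
        self._aligner.extend_gap_score = scores.gap_extend

    def _candidate_windows(self, query: str) -> set[tuple[str, int]]:
        """Candidate (contig, diagonal-origin) placements from seed votes."""
        k = self.k
        cands: set[tuple[str, int]] = set()
        for qpos in range(len(query) - k + 1):
            for contig_id, gpos in self._index.get(query[qpos : qpos + k], ()):
                cands.add((contig_id, gpos - qpos))
        return cands

    def search(self, query_id: str, query: str, min_score: float) -> list[AnchorHit]:
        hits: dict[tuple[str, int, str], AnchorHit] = {}
        margin = max(10, len(query) // 5)
        for strand, q in (("+", query), ("-", _revcomp(query))):
            for contig_id, diag in self._candidate_windows(q):
                contig = self.contigs[contig_id]
                w0 = max(0, diag - margin)
                w1 = min(len(contig.sequence), diag + len(q) + margin)
                window = contig.sequence[w0:w1]
                alns = self._aligner.align(window, q)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                score = float(aln.score)
                if score < min_score:
                    continue
                g0 = w0 + int(aln.aligned[0][0][0])
                g1 = w0 + int(aln.aligned[0][-1][1])
                key = (contig_id, g0 // 10, strand)  # merge near-identical placements
                cur = hits.get(key)
                if cur is None or score > cur.score:
                    hits[key] = AnchorHit(
                        query_id=query_id, contig_id=contig_id,
                        start=g0, end=g1, strand=strand, score=score,
                    )
        ranked = sorted(hits.values(), key=lambda h: (-h.score, h.contig_id, h.start))
        return [
            AnchorHit(h.query_id, h.contig_id, h.start, h.end, h.strand,
                      h.score, rank)
            for rank, h in enumerate(ranked, start=1)
        ]


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def anchor_sequence(
    query: str,
    genome: GenomeIndex,
    query_id: str = "query",
    min_score_frac: float = 0.9,
    min_len: int = 20,
) -> list[AnchorHit]:
    """Anchor a marker reference sequence in the assembly.

    Returns hits ranked by descending alignment score (rank 1 plays the
    role of the lowest E-value); empty when nothing reaches
    ``min_score_frac`` of the maximum possible score.
    """
    if len(query) < min_len:
        raise ValueError(f"query of {len(query)} bp below minimum {min_len}")
    min_score = min_score_frac * len(query) * genome.scores.match
    return genome.search(query_id, query.upper(), min_score)


@dataclass(frozen=True)
class SSRAnchor:
    contig_id: str
    position: int  # midpoint of the implied amplicon, 0-based
    product_len: int
    f_hit: AnchorHit
    r_hit: AnchorHit


@dataclass(frozen=True)
class SSRRejection:
    reason: str  # "no hit" | "different contigs" | "orientation" | "product too large"


def anchor_ssr(
    forward: str,
    reverse: str,
    genome: GenomeIndex,
    max_product: int = 1000,
    min_score_frac: float = 0.9,
) -> SSRAnchor | SSRRejection:
    """Anchor an SSR marker by its primer pair.

    Both primers are placed independently; the marker is accepted only
    when the best hits fall on the same contig, convergently oriented,
    with an implied product no larger than ``max_product``.
    """
    if len(forward) < 18 or len(reverse) < 18:
        raise ValueError("SSR primers must be >= 18 bp")
    fh = anchor_sequence(forward, genome, "F", min_score_frac, min_len=18)
    rh = anchor_sequence(reverse, genome, "R", min_score_frac, min_len=18)
    if not fh or not rh:
        return SSRRejection("no hit")
    f, r = fh[0], rh[0]
    if f.contig_id != r.contig_id:
        return SSRRejection("different contigs")
    # Convergent: the plus-strand primer upstream of the minus-strand one.
    if f.strand == "+" and r.strand == "-" and f.start < r.start:
        left, right = f, r
    elif f.strand == "-" and r.strand == "+" and r.start < f.start:
        left, right = r, f
    else:
        return SSRRejection("orientation")
    product = right.end - left.start
    if product > max_product:
        return SSRRejection("product too large")
    return SSRAnchor(
        contig_id=f.contig_id,
        position=(left.start + right.end) // 2,
        product_len=product,
        f_hit=f,
        r_hit=r,
    )


def assign_genetic_position(
    hit: AnchorHit, anchors: AnchorMap
) -> tuple[str, float] | None:
    """(chromosome, cm) inherited from the hit's contig; None = unplaced."""
    return anchors.position(hit.contig_id)


def dedup_loci(markers: list[MarkerRecord]) -> tuple[list[MarkerRecord], int]:
    """Collapse markers sharing an identical (chromosome, cm) position to
    one locus, keeping the lexicographically smallest marker id."""
    best: dict[tuple[str, float], MarkerRecord] = {}
    for m in markers:
        key = (m.chromosome, m.cm)
        cur = best.get(key)
        if cur is None or m.marker_id < cur.marker_id:
            best[key] = m
    loci = sorted(best.values(), key=lambda m: (m.chromosome, m.cm, m.marker_id))
    return loci, len(markers) - len(loci)


@dataclass
class IntegratedMap:
    """The single merged map of SSR/DArT/SNP/InDel markers."""

    markers: list[MarkerRecord]
    unplaced: int = 0
    ambiguous: int = 0

    def __post_init__(self) -> None:
        self.markers = sorted(
            self.markers, key=lambda m: (m.chromosome, m.cm, m.marker_id)
        )


@dataclass
class MapSummary:
    counts: pd.DataFrame      # chromosomes x marker types (+ Total row/col)
    lengths_cm: pd.Series     # per-chromosome map length (max cM)
    density: pd.DataFrame     # per-type markers per cM, 1 decimal


def summarize(
    markers: list[MarkerRecord],
    lengths_cm: dict[str, float] | None = None,
) -> MapSummary:
    """Per-chromosome, per-type marker counts, map lengths and densities.

    Chromosome length defaults to the maximum cM among its markers;
    density = count / length rounded to 1 decimal.  Totals are sums, and
    the total density uses the summed length.
    """
    if not markers:
        raise ValueError("cannot summarise an empty map")
    df = pd.DataFrame(
        {
            "chromosome": [m.chromosome for m in markers],
            "type": [m.marker_type for m in markers],
            "cm": [m.cm for m in markers],
        }
    )
    counts = (
        df.pivot_table(index="chromosome", columns="type", values="cm",
                       aggfunc="count", fill_value=0)
        .astype(int)
        .sort_index()
    )
    counts["Total"] = counts.sum(axis=1)
    counts.loc["Total"] = counts.sum(axis=0)
    if lengths_cm is None:
        lengths = df.groupby("chromosome")["cm"].max().sort_index()
    else:
        lengths = pd.Series(lengths_cm).sort_index()
    lengths.loc["Total"] = lengths.drop("Total", errors="ignore").sum()
    density = counts.div(lengths, axis=0).round(1)
    return MapSummary(counts=counts, lengths_cm=lengths, density=density)


def build_integrated_map(
    indel_markers: list[MarkerRecord],
    panels: dict[str, list[tuple[str, str]]],
    ssr_panel: list[tuple[str, str, str]],
    genome: GenomeIndex,
    anchors: AnchorMap,
    max_product: int = 1000,
    min_score_frac: float = 0.9,
) -> IntegratedMap:
    """Anchor every panel and merge with the InDel markers into one map.

    ``panels`` maps a marker type ("SNP"/"DArT") to (marker_id, sequence)
    tag lists; ``ssr_panel`` rows are (marker_id, forward, reverse).
    Markers without a hit, with score-tied best hits (ambiguous), on
    unanchored contigs, or failing the SSR consistency check are dropped
    and counted.
    """
    placed: list[MarkerRecord] = list(indel_markers)
    unplaced = ambiguous = 0
    for mtype, entries in panels.items():
        for marker_id, seq in entries:
            hits = anchor_sequence(seq, genome, marker_id, min_score_frac)
            if not hits:
                unplaced += 1
                continue
            if len(hits) > 1 and hits[0].score == hits[1].score:
                ambiguous += 1
                continue
            pos = assign_genetic_position(hits[0], anchors)
            if pos is None:
                unplaced += 1
                continue
            chrom, cm = pos
            placed.append(
                MarkerRecord(
                    marker_id=marker_id, marker_type=mtype,
                    chromosome=chrom, cm=cm,
                    contig_id=hits[0].contig_id,
                    start=hits[0].start, end=hits[0].end,
                )
            )
    for marker_id, fwd, rev in ssr_panel:
        res = anchor_ssr(fwd, rev, genome, max_product, min_score_frac)
        if isinstance(res, SSRRejection):
            unplaced += 1
            continue
        pos = anchors.position(res.contig_id)
        if pos is None:
            unplaced += 1
            continue
        chrom, cm = pos
        placed.append(
            MarkerRecord(
                marker_id=marker_id, marker_type="SSR",
                chromosome=chrom, cm=cm,
                contig_id=res.contig_id,
                start=res.position, end=res.position + 1,
                primer_f=fwd, primer_r=rev,
            )
        )
    return IntegratedMap(markers=placed, unplaced=unplaced, ambiguous=ambiguous)
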