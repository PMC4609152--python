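"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open.  Conversion to 1-based
happens only inside the VCF and MapChart writers.  Lowercase (soft-masked)
bases are uppercased on read; ``U`` is normalised to ``T``; ``N`` is kept.
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "AnchorEntry",
    "AnchorMap",
    "MarkerRecord",
    "FastaParseError",
    "DuplicateIdError",
    "read_fasta",
    "write_fasta",
    "read_anchor_map",
    "write_anchor_map",
    "write_vcf",
    "write_bed",
    "write_mapchart",
    "write_marker_table",
    "read_marker_table",
]

_ALPHABET = set("ACGTN")


class FastaParseError(ValueError):
    """Structural problem in a FASTA file; the message names the line."""


class DuplicateIdError(ValueError):
    """Two records share an identifier that must be unique."""


@dataclass
class Contig:
    """A named cultivar sequence: the unit of alignment and anchoring."""

    id: str
    sequence: str
    cultivar: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        seq = self.sequence.upper().replace("U", "T")
        if len(seq) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnchorEntry:
    contig_id: str
    chromosome: str
    cm: float


class AnchorMap:
    """Physical-to-genetic anchoring: contig id -> (chromosome, cM).

    Emulates a population-sequencing (POPSEQ-style) genetic map in which
    every assembly contig carries one genetic position.  Entries are kept
    sorted by (chromosome, cm); each contig appears at most once.
    """

    def __init__(self, entries: Iterable[AnchorEntry] = ()) -> None:
        entries = list(entries)
        seen: set[str] = set()
        for e in entries:
            if e.cm < 0:
                raise ValueError(f"negative cM for contig {e.contig_id!r}: {e.cm}")
            if e.contig_id in seen:
                raise DuplicateIdError(f"contig {e.contig_id!r} anchored twice")
            seen.add(e.contig_id)
        self.entries: list[AnchorEntry] = sorted(
            entries, key=lambda e: (e.chromosome, e.cm, e.contig_id)
        )
        self._by_contig = {e.contig_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._by_contig

    def position(self, contig_id: str) -> tuple[str, float] | None:
        """Return (chromosome, cm) for a contig, or None when unanchored."""
        e = self._by_contig.get(contig_id)
        return None if e is None else (e.chromosome, e.cm)

    def chromosomes(self) -> list[str]:
        return sorted({e.chromosome for e in self.entries})


@dataclass
class MarkerRecord:
    """One row of the merged marker map.

    Primer and melting fields are empty/None for anchored-only markers
    (SSR / DArT / SNP panels carry no designed amplicon here).
    """

    marker_id: str
    marker_type: str  # InDel | SSR | SNP | DArT
    chromosome: str
    cm: float
    contig_id: str
    start: int
    end: int
    ref_allele_len: int = 0
    alt_allele_len: int = 0
    primer_f: str = ""
    primer_r: str = ""
    amplicon_ref_len: int | None = None
    amplicon_alt_len: int | None = None
    tm_amplicon_ref: float | None = None
    tm_amplicon_alt: float | None = None
    delta_tm: float | None = None
    hrm_genotypable: bool | None = None

    def __post_init__(self) -> None:
        if self.marker_type not in {"InDel", "SSR", "SNP", "DArT"}:
            raise ValueError(f"unknown marker type {self.marker_type!r}")
        if not self.start < self.end:
            raise ValueError(
                f"marker {self.marker_id!r}: start {self.start} !< end {self.end}"
            )


def read_fasta(path: str | Path, cultivar: str = "") -> list[Contig]:
    """Read a multi-FASTA file into a list of :class:`Contig`.

    Sequences are uppercased and U->T normalised; record order is kept.
    Raises :class:`FastaParseError` (naming the offending line) for a file
    that does not start with a header or contains an empty record, and
    :class:`DuplicateIdError` for repeated identifiers.
    """
    path = Path(path)
    # Structural pre-check so errors can carry line numbers; the actual
    # record parsing is delegated to Bio.SeqIO below.
    last_header_line = 0
    seen_seq = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if not seen_seq:
                    raise FastaParseError(
                        f"{path.name}:{last_header_line}: record with no sequence"
                    )
                if len(line) == 1:
                    raise FastaParseError(f"{path.name}:{lineno}: empty FASTA header")
                last_header_line = lineno
                seen_seq = False
            else:
                if last_header_line == 0:
                    raise FastaParseError(
                        f"{path.name}:{lineno}: sequence before any '>' header"
                    )
                seen_seq = True
    if last_header_line and not seen_seq:
        raise FastaParseError(
            f"{path.name}:{last_header_line}: record with no sequence"
        )

    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"{path.name}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        contigs.append(Contig(id=rec.id, sequence=str(rec.seq), cultivar=cultivar))
    return contigs


def write_fasta(contigs: Sequence[Contig], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_anchor_map(path: str | Path) -> AnchorMap:
    """Read a contig anchor table: TSV with contig_id, chromosome, cm.

    Lines starting with ``#`` are comments.  An empty file yields an empty
    map (downstream anchoring then places zero markers).
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1, 2],
            names=["contig_id", "chromosome", "cm"],
            dtype={"contig_id": str, "chromosome": str, "cm": float},
        )
    except pd.errors.EmptyDataError:
        return AnchorMap([])
    entries = [
        AnchorEntry(r.contig_id, r.chromosome, float(r.cm))
        for r in df.itertuples(index=False)
    ]
    return AnchorMap(entries)


def write_anchor_map(anchors: AnchorMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig_id\tchromosome\tcm\n")
        for e in anchors.entries:
            fh.write(f"{e.contig_id}\t{e.chromosome}\t{e.cm:.4f}\n")


# ---------------------------------------------------------------------------
# VCF


def write_vcf(variants, assembly: Sequence[Contig], path: str | Path) -> None:
    """Write indels as VCF 4.2 using the left-anchor-base convention.

    POS is the 1-based position of the shared anchor base immediately left
    of the event; REF and ALT both start with that base.  INFO carries
    SVLEN (negative for deletions) and the provenance alignment-block id.
    """
    by_id = {c.id: c for c in assembly}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Alt minus ref allele length">',
        '##INFO=<ID=BLOCK,Number=1,Type=String,Description="Source alignment block">',
    ]
    for c in assembly:
        lines.append(f"##contig=<ID={c.id},length={len(c)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    def sort_key(v):
        return (v.ref_contig_id, v.ref_pos)

    for v in sorted(variants, key=sort_key):
        contig = by_id.get(v.ref_contig_id)
        if contig is None:
            raise KeyError(f"variant references unknown contig {v.ref_contig_id!r}")
        seq = contig.sequence
        if v.ref_pos < 0 or v.ref_pos + v.ref_len > len(seq):
            raise IndexError(
                f"variant at {v.ref_contig_id}:{v.ref_pos} outside contig "
                f"(len {len(seq)})"
            )
        svlen = v.qry_len - v.ref_len
        if v.ref_pos >= 1:
            anchor = seq[v.ref_pos - 1]
            if v.kind == "deletion":
                ref_allele = anchor + seq[v.ref_pos : v.ref_pos + v.ref_len]
                alt_allele = anchor
            else:
                ref_allele = anchor
                alt_allele = anchor + v.qry_seq
        else:
            # Event at the very start of the contig: anchor on the right.
            anchor = seq[v.ref_len]
            if v.kind == "deletion":
                ref_allele = seq[v.ref_pos : v.ref_pos + v.ref_len] + anchor
                alt_allele = anchor
            else:
                anchor = seq[0]
                ref_allele = anchor
                alt_allele = v.qry_seq + anchor
        pos_out = v.ref_pos if v.ref_pos >= 1 else 1
        vid = getattr(v, "id", None) or f"{v.ref_contig_id}_{v.ref_pos}"
        info = f"SVLEN={svlen};BLOCK={v.block_ref}"
        lines.append(
            f"{v.ref_contig_id}\t{pos_out}\t{vid}\t{ref_allele}\t{alt_allele}"
            f"\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(markers: Sequence[MarkerRecord], path: str | Path) -> None:
    """BED6: contig, 0-based half-open interval, marker id, score 0, strand +."""
    with open(path, "w") as fh:
        for m in sorted(markers, key=lambda m: (m.contig_id, m.start, m.marker_id)):
            fh.write(f"{m.contig_id}\t{m.start}\t{m.end}\t{m.marker_id}\t0\t+\n")


def write_mapchart(markers: Sequence[MarkerRecord], path: str | Path) -> None:
    """MapChart data-area text: one ``group`` block per chromosome.

    Within a block, ``name\\tcM`` lines sorted ascending by cM; ties broken
    by marker name so the output is byte-stable across runs.
    """
    for m in markers:
        if m.cm is None or m.chromosome is None:
            raise ValueError(
                f"marker {m.marker_id!r} lacks a genetic position; "
                "unplaced markers must be filtered before writing"
            )
    out: list[str] = []
    by_chrom: dict[str, list[MarkerRecord]] = {}
    for m in markers:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom in sorted(by_chrom):
        out.append(f"group {chrom}")
        for m in sorted(by_chrom[chrom], key=lambda m: (m.cm, m.marker_id)):
            out.append(f"{m.marker_id}\t{m.cm:.3f}")
        out.append("")
    Path(path).write_text("\n".join(out))


_MARKER_COLUMNS = [
    "marker_id", "marker_type", "chromosome", "cm", "contig_id", "start",
    "end", "ref_allele_len", "alt_allele_len", "primer_f", "primer_r",
    "amplicon_ref_len", "amplicon_alt_len", "tm_amplicon_ref",
    "tm_amplicon_alt", "delta_tm", "hrm_genotypable",
]


def write_marker_table(markers: Sequence[MarkerRecord], path: str | Path) -> None:
    """TSV marker table with one row per MarkerRecord (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_MARKER_COLUMNS) + "\n")
        for m in markers:
            row = []
            for col in _MARKER_COLUMNS:
                v = getattr(m, col)
                if v is None:
                    row.append(".")
                elif isinstance(v, bool):
                    row.append("1" if v else "0")
                elif isinstance(v, float):
                    row.append(f"{v:.4f}")
                else:
                    row.append(str(v))
            fh.write("\t".join(row) + "\n")


def read_marker_table(path: str | Path) -> list[MarkerRecord]:
    markers: list[MarkerRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            vals = dict(zip(_MARKER_COLUMNS, line.split("\t")))
            def _f(key, cast):
                v = vals[key]
                return None if v == "." else cast(v)
            markers.append(
                MarkerRecord(
                    marker_id=vals["marker_id"],
                    marker_type=vals["marker_type"],
                    chromosome=vals["chromosome"],
                    cm=float(vals["cm"]),
                    contig_id=vals["contig_id"],
                    start=int(vals["start"]),
                    end=int(vals["end"]),
                    ref_allele_len=int(vals["ref_allele_len"]),
                    alt_allele_len=int(vals["alt_allele_len"]),
                    primer_f="" if vals["primer_f"] == "." else vals["primer_f"],
                    primer_r="" if vals["primer_r"] == "." else vals["primer_r"],
                    amplicon_ref_len=_f("amplicon_ref_len", int),
                    amplicon_alt_len=_f("amplicon_alt_len", int),
                    tm_amplicon_ref=_f("tm_amplicon_ref", float),
                    tm_amplicon_alt=_f("tm_amplicon_alt", float),
                    delta_tm=_f("delta_tm", float),
                    hrm_genotypable=_f(
                        "hrm_genotypable", lambda s: bool(int(s))
                    ),
                )
            )
    return markers
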