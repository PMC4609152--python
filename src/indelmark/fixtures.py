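"""Synthetic cultivar-pair generator with planted variation and truth set.

Emulates, at desk scale, a pair of diverged barley-like cultivar
assemblies: a reference assembly of i.i.d. uniform-base contigs with a
POPSEQ-style anchor map, a derived assembly carrying planted SNPs and
InDels, and marker panels (SSR primer pairs, SNP/DArT sequence tags)
extracted from the reference.  Every planted event is recorded in a
truth set verifiable by direct string comparison, so recall and
precision are computable for every pipeline stage.  All randomness flows
from one explicit seed; given the seed, output is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .discover import normalize_left
from .io import AnchorEntry, AnchorMap, Contig

__all__ = [
    "SimulationConfig",
    "PlantedVariant",
    "PanelOrigin",
    "TruthSet",
    "simulate_reference",
    "mutate",
    "make_marker_panels",
    "plant_duplication",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cultivar pair.

    Defaults emulate two closely related cultivars at desk scale: a 2-Mb
    assembly (100 x 20 kb contigs over 7 chromosomes), 0.5 % SNP
    divergence, and planted InDels (geometric lengths, mean 8 bp,
    truncated at 120 bp so both sides of the 2-100 bp marker window are
    exercised) separated by at least 2 kb.
    """

    n_contigs: int = 100
    contig_len: int = 20_000
    snp_rate: float = 0.005
    indel_rate: float = 5e-5
    indel_len_mean: float = 8.0
    indel_len_min: int = 1
    indel_len_max: int = 120
    min_planted_spacing: int = 2000
    cm_per_contig: float = 1.0
    chromosomes: tuple[str, ...] = ("1H", "2H", "3H", "4H", "5H", "6H", "7H")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.snp_rate <= 0.1 and 0 <= self.indel_rate <= 0.1):
            raise ValueError("rates must lie in [0, 0.1]")
        if self.min_planted_spacing < 0:
            raise ValueError("spacing must be non-negative")
        if self.n_contigs < 1 or self.contig_len < 1:
            raise ValueError("need at least one contig of positive length")


@dataclass(frozen=True)
class PlantedVariant:
    contig_id: str
    pos: int           # 0-based on the reference contig, left-normalised
    kind: str          # "snp" | "insertion" | "deletion"
    ref_seq: str       # reference allele ("" for insertion)
    alt_seq: str       # derived allele ("" for deletion)

    @property
    def indel_len(self) -> int:
        return abs(len(self.ref_seq) - len(self.alt_seq))


@dataclass(frozen=True)
class PanelOrigin:
    marker_id: str
    panel: str         # "SNP" | "DArT" | "SSR"
    contig_id: str
    start: int
    end: int


@dataclass
class TruthSet:
    variants: list[PlantedVariant] = field(default_factory=list)
    duplications: list[tuple[str, int, int, str, int]] = field(default_factory=list)
    panel_origins: list[PanelOrigin] = field(default_factory=list)

    def indels(self) -> list[PlantedVariant]:
        return [v for v in self.variants if v.kind != "snp"]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def simulate_reference(cfg: SimulationConfig) -> tuple[list[Contig], AnchorMap]:
    """Reference assembly plus its anchor map.

    Contigs are split over the configured chromosomes in consecutive
    blocks; within a chromosome, contig i sits at i * cm_per_contig cM.
    """
    rng = np.random.default_rng(cfg.seed)
    contigs: list[Contig] = []
    entries: list[AnchorEntry] = []
    per_chrom = -(-cfg.n_contigs // len(cfg.chromosomes))  # ceil
    width = len(str(cfg.n_contigs))
    for i in range(cfg.n_contigs):
        cid = f"contig{i:0{width}d}"
        contigs.append(
            Contig(id=cid, sequence=_random_seq(rng, cfg.contig_len), cultivar="ref")
        )
        chrom = cfg.chromosomes[i // per_chrom]
        entries.append(AnchorEntry(cid, chrom, (i % per_chrom) * cfg.cm_per_contig))
    return contigs, AnchorMap(entries)


def _sample_indel_len(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    p = 1.0 / cfg.indel_len_mean
    while True:
        n = int(rng.geometric(p))
        if cfg.indel_len_min <= n <= cfg.indel_len_max:
            return n


def mutate(
    assembly: list[Contig], cfg: SimulationConfig
) -> tuple[list[Contig], TruthSet]:
    """Derive a diverged assembly by planting SNPs and InDels.

    InDels are planted left-to-right with rejection sampling so that
    consecutive InDels are at least ``min_planted_spacing`` apart and no
    two events overlap; SNPs avoid InDel footprints but are otherwise
    unconstrained.  Truth positions are left-normalised so they are
    directly comparable with alignment-derived calls.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    derived: list[Contig] = []
    truth = TruthSet()
    for contig in assembly:
        seq = contig.sequence
        L = len(seq)
        # --- indels, left to right with spacing
        events: list[PlantedVariant] = []
        n_indels = rng.binomial(L, cfg.indel_rate)
        positions = np.sort(rng.integers(1, L - 1, size=n_indels))
        last_end = -(10**9)
        occupied: list[tuple[int, int]] = []
        for pos in positions:
            pos = int(pos)
            if pos - last_end <= cfg.min_planted_spacing:
                continue  # rejection: too close to the previous event
            ln = _sample_indel_len(rng, cfg)
            if rng.random() < 0.5 and pos + ln < L - 1:
                ref_allele, alt_allele = seq[pos : pos + ln], ""
                kind = "deletion"
                end = pos + ln
            else:
                ref_allele, alt_allele = "", _random_seq(rng, ln)
                kind = "insertion"
                end = pos
            events.append(PlantedVariant(contig.id, pos, kind, ref_allele, alt_allele))
            occupied.append((pos, max(end, pos + 1)))
            last_end = end
        # --- SNPs anywhere outside indel footprints
        # SNPs stay >= 8 bp clear of indel boundaries: a substitution inside
        # an indel's alignment-shift neighbourhood would make the truth
        # coordinate ambiguous (the aligner could absorb it into an
        # equally-scoring alternative gap placement).
        n_snps = rng.binomial(L, cfg.snp_rate)
        snp_pos = np.unique(rng.integers(0, L, size=n_snps))
        footprint = np.zeros(L, dtype=bool)
        margin = 8
        for s, e in occupied:
            footprint[max(0, s - margin) : min(L, e + margin)] = True
        snp_events: list[PlantedVariant] = []
        for pos in snp_pos:
            pos = int(pos)
            if footprint[pos]:
                continue
            old = seq[pos]
            new = "ACGT"[(("ACGT".index(old)) + int(rng.integers(1, 4))) % 4]
            snp_events.append(PlantedVariant(contig.id, pos, "snp", old, new))

        # Apply right-to-left so earlier coordinates stay valid.
        out = seq
        for v in sorted(events + snp_events, key=lambda v: -v.pos):
            if v.kind == "snp":
                out = out[: v.pos] + v.alt_seq + out[v.pos + 1 :]
            elif v.kind == "deletion":
                out = out[: v.pos] + out[v.pos + len(v.ref_seq) :]
            else:
                out = out[: v.pos] + v.alt_seq + out[v.pos :]
        derived.append(Contig(id=contig.id + "_d", sequence=out, cultivar="derived"))

        for v in events:
            allele = v.ref_seq if v.kind == "deletion" else v.alt_seq
            npos = normalize_left(seq, v.pos, allele)
            truth.variants.append(replace(v, pos=npos))
        truth.variants.extend(snp_events)
    return derived, truth


def plant_duplication(
    assembly: list[Contig],
    src_contig: str,
    start: int,
    length: int,
    dest_contig: str,
    dest_pos: int,
    truth: TruthSet | None = None,
) -> list[Contig]:
    """Copy a segment to a second location (for specificity-screen tests).

    Returns a new assembly in which ``dest_contig`` carries a verbatim
    copy of assembly[src_contig][start:start+length] at ``dest_pos``.
    """
    by_id = {c.id: c for c in assembly}
    segment = by_id[src_contig].sequence[start : start + length]
    out: list[Contig] = []
    for c in assembly:
        if c.id == dest_contig:
            seq = c.sequence[:dest_pos] + segment + c.sequence[dest_pos + length :]
            out.append(Contig(id=c.id, sequence=seq, cultivar=c.cultivar))
        else:
            out.append(c)
    if truth is not None:
        truth.duplications.append((src_contig, start, length, dest_contig, dest_pos))
    return out


def make_marker_panels(
    assembly: list[Contig],
    truth: TruthSet,
    n_snp: int = 30,
    n_dart: int = 20,
    n_ssr: int = 10,
    tag_len: int = 80,
    ssr_product: int = 200,
    primer_len: int = 20,
    seed: int = 12345,
) -> tuple[list[tuple[str, str, str]], dict[str, list[tuple[str, str]]]]:
    """Extract SSR primer pairs and SNP/DArT sequence tags from the
    assembly, recording true origins in the truth set.

    Tags are verbatim subsequences; SSR primer pairs flank a segment of
    ``ssr_product`` bp (product length includes both primers).  Returns
    (ssr_panel, {"SNP": [...], "DArT": [...]}).
    """
    rng = np.random.default_rng(seed)
    n_contigs = len(assembly)
    panels: dict[str, list[tuple[str, str]]] = {"SNP": [], "DArT": []}
    for panel, count in (("SNP", n_snp), ("DArT", n_dart)):
        for i in range(count):
            c = assembly[int(rng.integers(0, n_contigs))]
            start = int(rng.integers(0, len(c.sequence) - tag_len))
            marker_id = f"{panel.lower()}{i:04d}"
            panels[panel].append((marker_id, c.sequence[start : start + tag_len]))
            truth.panel_origins.append(
                PanelOrigin(marker_id, panel, c.id, start, start + tag_len)
            )
    ssr_panel: list[tuple[str, str, str]] = []
    from Bio.Seq import Seq

    for i in range(n_ssr):
        c = assembly[int(rng.integers(0, n_contigs))]
        start = int(rng.integers(0, len(c.sequence) - ssr_product))
        fwd = c.sequence[start : start + primer_len]
        rev = str(
            Seq(c.sequence[start + ssr_product - primer_len : start + ssr_product])
            .reverse_complement()
        )
        marker_id = f"ssr{i:04d}"
        ssr_panel.append((marker_id, fwd, rev))
        truth.panel_origins.append(
            PanelOrigin(marker_id, "SSR", c.id, start, start + ssr_product)
        )
    return ssr_panel, panels
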