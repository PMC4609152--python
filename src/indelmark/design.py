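"""Primer design across InDels, amplicon derivation and specificity screen.

Primer melting temperatures use the SantaLucia (1998) unified
nearest-neighbor parameters with the entropy salt correction at 50 mM
monovalent cation and 250 nM primer, which is the standard model for
short-oligo Tm prediction.  The specificity screen is a desk-scale
surrogate for a BLAST search: a primer "targets" a genomic region when it
matches over its full length with at most ``max_mismatches`` mismatches
on either strand; a marker is removed only when BOTH primers target two
or more regions (one unique primer rescues the marker).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

from .discover import InDelVariant
from .io import Contig

__all__ = [
    "PrimerPair",
    "DesignConfig",
    "DesignRejection",
    "DesignSkip",
    "primer_tm",
    "design_primer_pair",
    "amplicon_alleles",
    "specificity_screen",
    "count_primer_sites",
    "ScreenedMarker",
]


class DesignSkip(ValueError):
    """Sequence cannot be used for design (e.g. contains N)."""


@dataclass(frozen=True)
class PrimerPair:
    """A designed primer pair on the reference allele.

    ``reverse`` is given 5'->3' on the minus strand; ``r_start`` is the
    0-based reference offset of its binding site (its leftmost base on the
    plus strand).
    """

    forward: str
    reverse: str
    f_tm: float
    r_tm: float
    f_start: int
    r_start: int

    @property
    def f_end(self) -> int:
        return self.f_start + len(self.forward)

    @property
    def r_end(self) -> int:
        return self.r_start + len(self.reverse)

    @property
    def product_len_ref(self) -> int:
        return self.r_end - self.f_start


@dataclass(frozen=True)
class DesignRejection:
    """Machine-readable reason why no primer pair could be designed."""

    reason: str


@dataclass
class DesignConfig:
    """Primer/amplicon design constraints.

    Amplicons run 80-250 bp by default; when the InDel itself is larger
    than ``large_indel_len`` the upper bound is relaxed by the InDel
    length so big events remain amplifiable.
    """

    amplicon_min: int = 80
    amplicon_max: int = 250
    primer_len_min: int = 18
    primer_len_max: int = 27
    tm_min: float = 57.0
    tm_max: float = 63.0
    gc_min: float = 30.0
    gc_max: float = 70.0
    max_homopolymer: int = 4
    large_indel_len: int = 50

    def __post_init__(self) -> None:
        if not self.amplicon_min <= self.amplicon_max:
            raise ValueError("amplicon_min must be <= amplicon_max")
        if not self.tm_min < self.tm_max:
            raise ValueError("empty primer Tm range")
        if not (8 <= self.primer_len_min <= self.primer_len_max <= 40):
            raise ValueError("primer length bounds out of range")


def primer_tm(seq: str, na_mm: float = 50.0, primer_nm: float = 250.0) -> float:
    """Nearest-neighbor melting temperature of a primer, in deg C.

    SantaLucia-1998 unified dH/dS parameters, entropy-based monovalent
    salt correction (``na_mm`` in mM), primer concentration ``primer_nm``
    in nM with the template assumed in excess deficit (standard primer
    asymmetry).  Length must be 8-40 nt; N bases are not designable.
    """
    seq = seq.upper()
    if not (8 <= len(seq) <= 40):
        raise ValueError(f"primer length {len(seq)} outside 8-40 nt")
    if "N" in seq:
        raise DesignSkip("primer window contains N")
    return float(
        _mt.Tm_NN(
            Seq(seq),
            nn_table=_mt.DNA_NN3,
            Na=na_mm,
            K=0, Tris=0, Mg=0, dNTPs=0,
            dnac1=primer_nm,
            dnac2=0,
            saltcorr=5,
        )
    )


def _gc_percent(seq: str) -> float:
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _feasible(seq: str, cfg: DesignConfig) -> float | None:
    """Return the primer Tm when a window passes all per-primer constraints."""
    if "N" in seq:
        return None
    if not (cfg.gc_min <= _gc_percent(seq) <= cfg.gc_max):
        return None
    if _max_run(seq) > cfg.max_homopolymer:
        return None
    tm = primer_tm(seq)
    if not (cfg.tm_min <= tm <= cfg.tm_max):
        return None
    return tm


def design_primer_pair(
    contig: Contig,
    variant: InDelVariant,
    cfg: DesignConfig = DesignConfig(),
) -> PrimerPair | DesignRejection:
    """Design the Tm-balanced primer pair flanking an InDel.

    Scans all candidate forward windows left of the event and reverse
    windows right of it, keeps windows passing Tm/GC/homopolymer rules,
    and among product-length-feasible pairs returns the one minimising
    |f_tm - r_tm| (ties: smaller product, then leftmost positions).
    Returns a :class:`DesignRejection` with a machine-readable reason when
    no pair exists.
    """
    seq = contig.sequence
    var_start, var_end = variant.ref_pos, variant.ref_end
    if var_start < cfg.amplicon_max or len(seq) - var_end < cfg.amplicon_max:
        return DesignRejection("insufficient flank")
    amp_max = cfg.amplicon_max
    if variant.indel_len > cfg.large_indel_len:
        amp_max += variant.indel_len

    fwd: list[tuple[int, int, float]] = []  # (start, length, tm)
    lo = max(0, var_end + cfg.primer_len_min - amp_max)
    for fs in range(lo, var_start - cfg.primer_len_min + 1):
        for ln in range(cfg.primer_len_min, cfg.primer_len_max + 1):
            if fs + ln > var_start:  # 3' end must stay left of the InDel
                break
            tm = _feasible(seq[fs : fs + ln], cfg)
            if tm is not None:
                fwd.append((fs, ln, tm))
    if not fwd:
        return DesignRejection("no feasible forward primer")

    rev: list[tuple[int, int, float]] = []
    hi = min(len(seq), var_start + amp_max)
    for rs in range(var_end, hi - cfg.primer_len_min + 1):
        for ln in range(cfg.primer_len_min, cfg.primer_len_max + 1):
            if rs + ln > len(seq):
                break
            tm = _feasible(_revcomp(seq[rs : rs + ln]), cfg)
            if tm is not None:
                rev.append((rs, ln, tm))
    if not rev:
        return DesignRejection("no feasible reverse primer")

    best: tuple[float, int, int, int] | None = None
    best_pair: tuple[int, int, float, int, int, float] | None = None
    for fs, fl, ftm in fwd:
        for rs, rl, rtm in rev:
            product = rs + rl - fs
            if not (cfg.amplicon_min <= product <= amp_max):
                continue
            key = (abs(ftm - rtm), product, fs, rs)
            if best is None or key < best:
                best = key
                best_pair = (fs, fl, ftm, rs, rl, rtm)
    if best_pair is None:
        return DesignRejection("no feasible pair in amplicon window")
    fs, fl, ftm, rs, rl, rtm = best_pair
    return PrimerPair(
        forward=seq[fs : fs + fl],
        reverse=_revcomp(seq[rs : rs + rl]),
        f_tm=ftm,
        r_tm=rtm,
        f_start=fs,
        r_start=rs,
    )


def amplicon_alleles(
    pair: PrimerPair,
    variant: InDelVariant,
    ref: Contig,
    qry_allele: str | None = None,
) -> tuple[str, str]:
    """Reference and alternate amplicon sequences for a designed marker.

    The alternate amplicon is the reference amplicon with the InDel
    applied; the two lengths differ by exactly ``variant.indel_len``.
    """
    if variant.indel_len == 0:
        raise ValueError("degenerate variant with indel_len == 0 is not an InDel")
    if not (pair.f_end <= variant.ref_pos and variant.ref_end <= pair.r_start):
        raise ValueError("variant not strictly inside the primer interval")
    ref_amp = ref.sequence[pair.f_start : pair.r_end]
    off = variant.ref_pos - pair.f_start
    if variant.kind == "deletion":
        alt_amp = ref_amp[:off] + ref_amp[off + variant.ref_len :]
    else:
        ins = qry_allele if qry_allele is not None else variant.qry_seq
        if len(ins) != variant.qry_len:
            raise ValueError("insertion allele length disagrees with variant")
        alt_amp = ref_amp[:off] + ins + ref_amp[off:]
    return ref_amp, alt_amp


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _concat_genome(genome: list[Contig], sep_len: int) -> np.ndarray:
    """Concatenate contigs with an X spacer so windows never span two."""
    sep = np.full(sep_len, ord("X"), dtype=np.uint8)
    parts: list[np.ndarray] = []
    for contig in genome:
        parts.append(_encode(contig.sequence))
        parts.append(sep)
    return np.concatenate(parts[:-1]) if parts else np.zeros(0, dtype=np.uint8)


def _count_sites_encoded(pat: str, g: np.ndarray, max_mismatches: int) -> int:
    p = _encode(pat)
    m = len(p)
    n = len(g) - m + 1
    if n <= 0:
        return 0
    mism = np.zeros(n, dtype=np.int32)
    for k in range(m):
        mism += g[k : k + n] != p[k]
    return int(np.count_nonzero(mism <= max_mismatches))


def count_primer_sites(
    primer: str, genome: list[Contig], max_mismatches: int = 2
) -> int:
    """Count genomic sites (both strands) matching the primer over its
    full length with at most ``max_mismatches`` mismatches."""
    g = _concat_genome(genome, len(primer))
    total = 0
    for pat in {primer, _revcomp(primer)}:
        total += _count_sites_encoded(pat, g, max_mismatches)
    return total


@dataclass(frozen=True)
class ScreenedMarker:
    marker: object
    pair: PrimerPair
    f_hits: int
    r_hits: int


def specificity_screen(
    pairs: list[tuple[object, PrimerPair]],
    genome: list[Contig],
    max_mismatches: int = 2,
) -> list[ScreenedMarker]:
    """Remove markers whose forward AND reverse primers each target two or
    more genomic regions; retained markers carry per-primer hit counts."""
    retained: list[ScreenedMarker] = []
    max_len = max(
        (max(len(p.forward), len(p.reverse)) for _, p in pairs), default=1
    )
    g = _concat_genome(genome, max_len)
    def hits(primer: str) -> int:
        return sum(
            _count_sites_encoded(pat, g, max_mismatches)
            for pat in {primer, _revcomp(primer)}
        )
    for marker, pair in pairs:
        f_hits = hits(pair.forward)
        r_hits = hits(pair.reverse)
        if f_hits >= 2 and r_hits >= 2:
            continue
        retained.append(ScreenedMarker(marker, pair, f_hits, r_hits))
    return retained
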