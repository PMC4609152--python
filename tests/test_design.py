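import math

import numpy as np
import pytest

from indelmark.design import (
    DesignConfig,
    DesignRejection,
    DesignSkip,
    amplicon_alleles,
    count_primer_sites,
    design_primer_pair,
    primer_tm,
    specificity_screen,
)
from indelmark.discover import InDelVariant
from indelmark.fixtures import plant_duplication
from indelmark.io import Contig

from conftest import random_seq


# --- independent nearest-neighbor oracle (SantaLucia 1998 unified set),
# hand-coded from the published dH (kcal/mol) / dS (cal/mol K) table.
_DH = {"AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2, "CA": -8.5, "TG": -8.5,
       "GT": -8.4, "AC": -8.4, "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
       "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0}
_DS = {"AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3, "CA": -22.7,
       "TG": -22.7, "GT": -22.4, "AC": -22.4, "CT": -21.0, "AG": -21.0,
       "GA": -22.2, "TC": -22.2, "CG": -27.2, "GC": -24.4, "GG": -19.9,
       "CC": -19.9}


def _oracle_nn_tm(seq, na_mm=50.0, primer_nm=250.0):
    dh = ds = 0.0
    for end in (seq[0], seq[-1]):
        if end in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    for i in range(len(seq) - 1):
        dh += _DH[seq[i : i + 2]]
        ds += _DS[seq[i : i + 2]]
    ds += 0.368 * (len(seq) - 1) * math.log(na_mm / 1000.0)
    return dh * 1000.0 / (ds + 1.987 * math.log(primer_nm * 1e-9)) - 273.15


class TestPrimerTm:
    # values frozen from the hand-summed oracle above before wiring
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGTACGTACGTACGTACGT", 57.07),
            ("ATATATATATATATATATAT", 28.23),
            ("GCGCGCGCGCGCGCGCGCGC", 80.99),
            ("AGTCCGTAAGGTCAATTCGC", 56.36),
        ],
    )
    def test_matches_frozen_nn_oracle(self, seq, expected):
        assert primer_tm(seq) == pytest.approx(expected, abs=0.1)
        assert primer_tm(seq) == pytest.approx(_oracle_nn_tm(seq), abs=0.1)

    def test_gc_rich_melts_higher_than_at_rich(self):
        assert primer_tm("G" * 10 + "C" * 10) > primer_tm("A" * 10 + "T" * 10)

    def test_duplex_symmetry(self):
        seq = "AGTCCGTAAGGTCAATTCGC"
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert primer_tm(seq) == pytest.approx(primer_tm(rc), abs=1e-9)

    def test_length_out_of_range(self):
        with pytest.raises(ValueError):
            primer_tm("ACGTACG")
        with pytest.raises(ValueError):
            primer_tm("A" * 41)

    def test_n_raises_design_skip(self):
        with pytest.raises(DesignSkip):
            primer_tm("ACGTNACGTACGT")


def _deletion(contig_id, pos, length, seq):
    return InDelVariant(contig_id, pos, length, 0, "deletion", "b",
                        ref_seq=seq[pos : pos + length])


WIDE = DesignConfig(tm_min=45.0, tm_max=75.0, gc_min=20.0, gc_max=80.0)


def _constraint_check(pair, variant, contig, cfg):
    """Independent re-check of every design constraint."""
    seq = contig.sequence
    assert seq[pair.f_start : pair.f_end] == pair.forward
    rc = pair.reverse.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    assert seq[pair.r_start : pair.r_end] == rc
    assert pair.f_end <= variant.ref_pos
    assert variant.ref_end <= pair.r_start
    amp_max = cfg.amplicon_max + (
        variant.indel_len if variant.indel_len > cfg.large_indel_len else 0
    )
    assert cfg.amplicon_min <= pair.product_len_ref <= amp_max
    for primer, tm in ((pair.forward, pair.f_tm), (pair.reverse, pair.r_tm)):
        assert cfg.primer_len_min <= len(primer) <= cfg.primer_len_max
        gc = 100.0 * sum(b in "GC" for b in primer) / len(primer)
        assert cfg.gc_min <= gc <= cfg.gc_max
        assert cfg.tm_min <= tm <= cfg.tm_max
        assert max(
            len(run) for run in
            __import__("re").findall(r"(?:A+|C+|G+|T+)", primer)
        ) <= cfg.max_homopolymer
        assert primer_tm(primer) == pytest.approx(tm)


class TestDesignPrimerPair:
    def test_clean_flanks_feasible_and_tm_balanced(self):
        rng = np.random.default_rng(42)
        seq = random_seq(rng, 800)
        contig = Contig("c", seq)
        v = _deletion("c", 390, 12, seq)
        pair = design_primer_pair(contig, v, WIDE)
        assert not isinstance(pair, DesignRejection)
        _constraint_check(pair, v, contig, WIDE)
        # exhaustive oracle: no feasible pair has a smaller Tm imbalance
        best = _exhaustive_best_imbalance(contig, v, WIDE)
        assert abs(pair.f_tm - pair.r_tm) == pytest.approx(best, abs=1e-9)

    def test_variant_near_contig_end_rejected(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 500)
        v = _deletion("c", len(seq) - 35, 5, seq)
        out = design_primer_pair(Contig("c", seq), v, WIDE)
        assert isinstance(out, DesignRejection)
        assert out.reason == "insufficient flank"

    def test_all_n_flank_rejected(self):
        seq = "N" * 300 + "ACGTACGTAC" + "N" * 300
        v = InDelVariant("c", 302, 3, 0, "deletion", "b", ref_seq="NNN")
        out = design_primer_pair(Contig("c", seq), v, WIDE)
        assert isinstance(out, DesignRejection)

    def test_large_indel_relaxes_amplicon_upper_bound(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 900)
        v = _deletion("c", 400, 80, seq)  # > large_indel_len
        pair = design_primer_pair(Contig("c", seq), v, WIDE)
        if not isinstance(pair, DesignRejection):
            assert pair.product_len_ref <= WIDE.amplicon_max + 80


def _exhaustive_best_imbalance(contig, variant, cfg):
    """Brute-force enumeration of every feasible primer pair."""
    import re
    seq = contig.sequence
    amp_max = cfg.amplicon_max + (
        variant.indel_len if variant.indel_len > cfg.large_indel_len else 0
    )
    def ok(p):
        if "N" in p:
            return None
        gc = 100.0 * sum(b in "GC" for b in p) / len(p)
        if not (cfg.gc_min <= gc <= cfg.gc_max):
            return None
        if max(len(r) for r in re.findall(r"(?:A+|C+|G+|T+)", p)) > cfg.max_homopolymer:
            return None
        tm = primer_tm(p)
        return tm if cfg.tm_min <= tm <= cfg.tm_max else None
    rc = str.maketrans("ACGT", "TGCA")
    fwd = []
    for fs in range(0, variant.ref_pos):
        for fl in range(cfg.primer_len_min, cfg.primer_len_max + 1):
            if fs + fl > variant.ref_pos:
                break
            ftm = ok(seq[fs : fs + fl])
            if ftm is not None:
                fwd.append((fs, fl, ftm))
    rev = []
    for rs in range(variant.ref_end, len(seq)):
        for rl in range(cfg.primer_len_min, cfg.primer_len_max + 1):
            if rs + rl > len(seq):
                break
            rtm = ok(seq[rs : rs + rl].translate(rc)[::-1])
            if rtm is not None:
                rev.append((rs, rl, rtm))
    best = None
    for fs, fl, ftm in fwd:
        for rs, rl, rtm in rev:
            product = rs + rl - fs
            if not (cfg.amplicon_min <= product <= amp_max):
                continue
            d = abs(ftm - rtm)
            if best is None or d < best:
                best = d
    return best


class TestAmpliconAlleles:
    def _fig1_case(self):
        # planted 33-bp deletion with the amplicon window pinned to 129 bp
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 800)
        contig = Contig("c", seq)
        v = _deletion("c", 395, 33, seq)
        cfg = DesignConfig(amplicon_min=129, amplicon_max=129, tm_min=40.0,
                           tm_max=80.0, gc_min=10.0, gc_max=90.0)
        pair = design_primer_pair(contig, v, cfg)
        assert not isinstance(pair, DesignRejection)
        return pair, v, contig

    def test_33bp_deletion_gives_129_and_96bp_amplicons(self):
        pair, v, contig = self._fig1_case()
        ref_amp, alt_amp = amplicon_alleles(pair, v, contig)
        assert (len(ref_amp), len(alt_amp)) == (129, 96)
        assert ref_amp == contig.sequence[pair.f_start : pair.r_end]

    def test_length_difference_equals_indel_len(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 700)
        contig = Contig("c", seq)
        for ln in (2, 7, 21, 48):
            v = _deletion("c", 330, ln, seq)
            pair = design_primer_pair(contig, v, WIDE)
            if isinstance(pair, DesignRejection):
                continue
            ref_amp, alt_amp = amplicon_alleles(pair, v, contig)
            assert len(ref_amp) - len(alt_amp) == ln
            # InDel strictly inside the amplicon, between the primers
            assert pair.f_end <= v.ref_pos and v.ref_end <= pair.r_start

    def test_insertion_allele_applied(self):
        rng = np.random.default_rng(9)
        seq = random_seq(rng, 700)
        contig = Contig("c", seq)
        ins = "TTGACCA"
        v = InDelVariant("c", 350, 0, len(ins), "insertion", "b", qry_seq=ins)
        pair = design_primer_pair(contig, v, WIDE)
        assert not isinstance(pair, DesignRejection)
        ref_amp, alt_amp = amplicon_alleles(pair, v, contig)
        assert len(alt_amp) - len(ref_amp) == len(ins)
        off = v.ref_pos - pair.f_start
        assert alt_amp[off : off + len(ins)] == ins

    def test_degenerate_variant_rejected(self):
        rng = np.random.default_rng(11)
        seq = random_seq(rng, 700)
        contig = Contig("c", seq)
        v = _deletion("c", 330, 5, seq)
        pair = design_primer_pair(contig, v, WIDE)
        bogus = InDelVariant("c", 330, 5, 0, "deletion", "b", ref_seq=seq[330:335])
        bogus.ref_len = 0  # degrade to a zero-length event post-validation
        with pytest.raises(ValueError, match="not an InDel|indel_len"):
            amplicon_alleles(pair, bogus, contig)


class TestSpecificityScreen:
    def _designed(self, seed=21):
        rng = np.random.default_rng(seed)
        genome = [Contig(f"g{i}", random_seq(rng, 3000)) for i in range(3)]
        v = _deletion("g0", 1500, 10, genome[0].sequence)
        pair = design_primer_pair(genome[0], v, WIDE)
        assert not isinstance(pair, DesignRejection)
        return genome, v, pair

    def test_unique_primers_retained_on_duplication_free_genome(self):
        genome, v, pair = self._designed()
        out = specificity_screen([(v, pair)], genome)
        assert len(out) == 1
        assert out[0].f_hits == 1 and out[0].r_hits == 1

    def test_one_unique_primer_rescues_marker(self):
        genome, v, pair = self._designed()
        # duplicate only the reverse-primer site onto another contig
        genome2 = plant_duplication(
            genome, "g0", pair.r_start, len(pair.reverse), "g1", 200
        )
        out = specificity_screen([(v, pair)], genome2)
        assert len(out) == 1
        assert out[0].f_hits == 1 and out[0].r_hits == 2

    def test_both_primers_multimapping_removed(self):
        genome, v, pair = self._designed()
        length = pair.r_end - pair.f_start
        genome2 = plant_duplication(genome, "g0", pair.f_start, length, "g2", 500)
        out = specificity_screen([(v, pair)], genome2)
        assert out == []

    @pytest.mark.parametrize("max_mm", [0, 2])
    def test_site_counts_match_exhaustive_scan(self, max_mm):
        rng = np.random.default_rng(33)
        genome = [Contig("g", random_seq(rng, 2000))]
        primer = genome[0].sequence[700:720]
        got = count_primer_sites(primer, genome, max_mismatches=max_mm)
        # brute force over both strands
        rc = primer.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        n = 0
        for pat in {primer, rc}:
            for i in range(len(genome[0].sequence) - len(pat) + 1):
                window = genome[0].sequence[i : i + len(pat)]
                if sum(a != b for a, b in zip(window, pat)) <= max_mm:
                    n += 1
        assert got == n
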