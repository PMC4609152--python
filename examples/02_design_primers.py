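"""Design a primer pair across a planted 33-bp InDel and derive the two
allele amplicons (the classic 129 / 96 bp marker geometry).

The designer scans every candidate window flanking the event, keeps
primers passing Tm / GC / homopolymer rules, and returns the pair with
the best-balanced melting temperatures.
"""

import numpy as np

from indelmark.design import DesignConfig, amplicon_alleles, design_primer_pair
from indelmark.discover import InDelVariant
from indelmark.io import Contig

rng = np.random.default_rng(3)
seq = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, 800)].tobytes().decode()
contig = Contig("c", seq)
variant = InDelVariant("c", 395, 33, 0, "deletion", "demo", ref_seq=seq[395:428])

cfg = DesignConfig(amplicon_min=129, amplicon_max=129, tm_min=40.0, tm_max=80.0,
                   gc_min=10.0, gc_max=90.0)
pair = design_primer_pair(contig, variant, cfg)
ref_amp, alt_amp = amplicon_alleles(pair, variant, contig)

print(f"forward primer  {pair.forward}  (Tm {pair.f_tm:.2f} C)")
print(f"reverse primer  {pair.reverse}  (Tm {pair.r_tm:.2f} C)")
print(f"amplicon sizes: {len(ref_amp)} bp (reference) vs {len(alt_amp)} bp (alternate)")
print(f"size difference = {len(ref_amp) - len(alt_amp)} bp = the InDel length")
# A codominant InDel marker: the two alleles amplify products whose
# length difference equals the InDel, scorable on a gel or by melting.
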