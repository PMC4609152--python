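# Methods

This note records the models, parameter choices and numerical
conventions behind `indelmark`, and what the synthetic-data tests do and
do not demonstrate about real assemblies.

## Coordinates and normalisation

All internal coordinates are 0-based half-open; 1-based conversion
happens only in the VCF and MapChart writers. InDels are
left-normalised (VCF-style: the event is shifted left while the base
preceding it equals the last base of the allele), and the synthetic
truth set is normalised with the same convention, so an alignment-derived
call and a planted event are comparable by `(contig, position, kind,
length)`. Lowercase bases are uppercased on read, `U` becomes `T`, and
`N` is retained but never appears inside a reported allele.

## Pairwise alignment

Contigs are paired by shared unique *k*-mer count (*k* = 21 by default;
ties resolved deterministically), standing in for read-mapping-based
pairing. Within a pair, unique shared *k*-mers seed the alignment; the
longest chain strictly increasing in both coordinates is found by an
O(n log n) patience pass with a deterministic smallest-tail tie rule.
Overlapping same-diagonal anchors merge into exact-match runs;
inter-anchor gaps are filled by affine-gap global alignment with
match +1, mismatch −2, gap open −4, gap extend −1 (Biopython's
`PairwiseAligner`; the scheme is pinned for reproducibility — any
sensible scoring is admissible for this step). Blocks extend to the
sequence ends when the extension alignment reaches ≥ 0.9 identity, and
chains are split when an inter-anchor segment exceeds 20 kb, bounding
the quadratic alignment problem.

Identity is matches / (matches + mismatches): gap columns and columns
containing `N` are excluded from the denominator (LASTZ-style). This
choice matters at the 95 % filter threshold and is therefore explicit
and tested at the boundary.

Limitations: forward strand only (assemblies are assumed co-oriented;
the simulator never inverts), no inversions/translocations, no repeat
masking.

## Filter cascade

Defaults: segments > 1000 bp (both sides, ungapped lengths), InDel
length in [2, 100] bp (inclusive), identity > 0.95, spacing > 1000 bp.
All four comparisons at a threshold are strict except the inclusive
length window, and the boundary behavior (999/1000/1001,
0.949/0.95/0.951, 1/2/100/101) is pinned by tests. Conditions (a)–(c)
are order-independent per-variant predicates; spacing is resolved last
by a greedy left-to-right scan (keep a variant iff its position exceeds
the last kept position by more than the minimum), which is deterministic
and order-stable. Density selection partitions each chromosome's cM
axis into bins of width 1/target (default one marker per cM) and keeps
the longest InDel per bin (ties: smallest contig id, then position).

## Primer design and thermodynamics

Primer Tm uses the SantaLucia (1998) unified nearest-neighbor
parameters with the entropic salt correction at 50 mM monovalent cation
and 250 nM primer (template in excess); the implementation delegates to
Biopython's `MeltingTemp.Tm_NN` and is cross-checked against an
independently hand-summed NN table in the tests (agreement to
< 0.1 °C). Design constraints: primers 18–27 nt, Tm 57–63 °C, GC
30–70 %, no single-base run ≥ 5, 3′ ends outside the InDel, amplicon
80–250 bp with the upper bound relaxed by the InDel length when the
InDel exceeds 50 bp (so large events remain amplifiable). Among
feasible pairs the design minimises |Tm_f − Tm_r| with deterministic
tie-breaks (smaller product, then leftmost positions). Dimer/hairpin
screening and multiplexing are out of scope.

The specificity screen is a desk-scale surrogate for a BLAST search: a
primer targets a site when it matches over its full length with ≤ 2
mismatches on either strand, and a marker is removed only when both
primers target ≥ 2 sites — the literal "both primers multi-map" rule,
under which one unique primer rescues the marker. A strict mode is a
one-line change (remove when either primer multi-maps) but is not the
default.

## HRM model

Amplicon melt temperatures use the classical empirical long-duplex
formula `81.5 + 16.6·log₁₀[Na⁺] + 0.41·%GC − 675/N` at 50 mM Na⁺ (the
default); sequences under 50 bp route to the nearest-neighbor model.
This is a stated approximation standing in for an instrument-measured
melt curve: it lets the genotypability classifier and population caller
run end-to-end on synthetic data, and both accept measured temperatures
directly. A marker is genotypable iff ΔTm > 0.3 °C, strictly — exactly
0.3 fails, which the tests pin.

The population caller assigns a line to the nearer parental Tm and
abstains ("unresolved") when the line is farther than threshold/2 from
both parents or exactly midway; the margin is this package's choice.
Under the simulated study conditions (360 doubled-haploid lines,
parental ΔTm 0.6 °C, Gaussian noise σ = 0.05 °C) the margin sits at 3σ,
so ≈ 0.3 % of lines abstain in expectation. Accuracy is reported over
resolved calls (an abstention is a deliberate no-call, not a miscall)
together with the call rate; wrong calls require a 6σ noise excursion
and essentially never occur.

No claim is made that predicted ΔTm correlates with InDel length — on
measured data that correlation is known to be near zero (R² ≈ 0.04),
and the only model-level property asserted is the formula identity that
ΔTm between same-GC alleles is monotone in |1/N₁ − 1/N₂|.

## Panel anchoring and map integration

Marker tags anchor by *k*-mer-seeded (k = 13) local alignment with the
same scoring as the genome aligner; hits rank by descending score with
(contig, start) tie-breaking. Score order substitutes for ascending
E-value order — the ordering is all that is used downstream, and
database-size-dependent E-value statistics are meaningless at desk
scale. A query is placed when its best hit reaches 90 % of the maximum
possible score; rank-1/rank-2 score ties mark a marker ambiguous and
remove it. SSR markers are accepted only when both primers' best hits
are on one contig, convergently oriented, with an implied product
≤ 1000 bp (configurable; no published bound exists); the marker position
is the amplicon midpoint. Placed markers inherit `(chromosome, cM)`
from their contig's anchor entry; markers on unanchored contigs are
removed and counted. Deduplication collapses identical
`(chromosome, cM)` positions to one locus (lexicographically smallest
id), by default within the InDel set only (for map drawing), with a
flag to extend to all types. Summaries report per-chromosome,
per-type counts, map length (max cM unless given explicitly) and
density rounded to one decimal.

## Synthetic data

The generator emulates two closely related cultivars: i.i.d.
uniform-base contigs (default 100 × 20 kb over seven chromosomes,
cM = index × 1.0 within a chromosome), 0.5 % SNP divergence, and
planted InDels at 5 × 10⁻⁵ per bp with geometric lengths (mean 8 bp,
truncated to [1, 120] so both sides of the 2–100 bp window are
exercised) and ≥ 2 kb spacing, planted left-to-right with rejection
sampling. SNPs are kept ≥ 8 bp clear of InDel boundaries: a
substitution inside an InDel's alignment-shift neighbourhood would make
the truth coordinate ambiguous (two equally scoring gap placements).
All randomness flows from one explicit seed; reruns are byte-identical.

What the generator does *not* emulate: repeat structure, transposons,
GC heterogeneity, assembly errors, strand flips, or recombination.
Passing tests therefore demonstrate algorithmic correctness on
well-behaved homologous sequence, not robustness to repeat-rich plant
genomes — on real assemblies the unique-*k*-mer seeding and the
specificity screen do real work that the fixtures only spot-check via
explicitly planted duplications.

## Problem sizes

The test suite and the acceptance script run the full cascade on a
2-Mb simulated pair (100 × 20 kb contigs), which exercises every stage
in a few seconds per run while keeping planted-truth comparisons exact;
the pipeline itself has no hard-coded size assumptions beyond the 20-kb
inter-anchor split.

## Published worked examples

`indelmark.barley` bundles the published per-chromosome summary tables
of the barley InDel marker panel this pipeline emulates (1140 InDel
markers, 6976 integrated markers, 998.4 cM). They are inputs to the
summary machinery, reproducing the printed densities (e.g. 187/142.2 →
1.3 markers/cM on 1H), the 75 % share of 3–20 bp markers, the
704-locus deduplication and the assay success rates exactly; the
per-chromosome cM lengths sum to 998.5 while the printed total is
998.4, a rounding discrepancy this package does not resolve (totals use
the summed lengths).
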