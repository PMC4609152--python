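"""End-to-end orchestration: simulate -> align -> discover -> design ->
HRM -> integrate, with a machine-readable attrition report.

Every stage is the library function; this module only wires them, applies
the configured thresholds, and writes the standard outputs (VCF, marker
table, BED, MapChart text, summary TSV, attrition JSON).  All randomness
flows from the single seed in :class:`PipelineConfig`; reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as mio
from .align import align_pair, pair_contigs
from .design import (
    DesignConfig,
    DesignRejection,
    amplicon_alleles,
    design_primer_pair,
    specificity_screen,
)
from .discover import (
    FilterConfig,
    classify_lengths,
    extract_indels,
    filter_indels,
    select_by_density,
)
from .fixtures import SimulationConfig, make_marker_panels, mutate, simulate_reference
from .hrm import DEFAULT_DELTA_TM_THRESHOLD, amplicon_tm, classify_hrm
from .integrate import GenomeIndex, build_integrated_map, dedup_loci, summarize

__all__ = ["PipelineConfig", "run_all", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage configurations plus paths and the single seed.

    Defaults equal the published pipeline's thresholds where it states
    one (segments > 1 kb, InDels 2-100 bp, identity > 95 %, spacing
    > 1 kb, one marker per cM, amplicons 80-250 bp, delta-Tm > 0.3 C).
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    hrm_threshold: float = DEFAULT_DELTA_TM_THRESHOLD
    na_molar: float = 0.05
    target_per_cm: float = 1.0
    k: int = 21
    max_mismatches: int = 2
    ssr_max_product: int = 1000
    min_score_frac: float = 0.9
    panel_sizes: tuple[int, int, int] = (30, 20, 10)  # SNP, DArT, SSR
    seed: int = 0

    def __post_init__(self) -> None:
        # One seed governs everything, including the simulator.
        self.sim = dataclasses.replace(self.sim, seed=self.seed)


_SECTION_TYPES = {"sim": SimulationConfig, "filter": FilterConfig, "design": DesignConfig}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus overrides.

    Precedence: overrides (CLI flags) > file > documented defaults.
    Unknown keys are rejected.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            data.update(loaded)
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if "." in key:
            section, sub = key.split(".", 1)
            data.setdefault(section, {})[sub] = val
        else:
            data[key] = val

    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    kwargs: dict = {}
    for key, val in data.items():
        if key not in top_fields:
            raise ValueError(f"unknown configuration key {key!r}")
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            unknown = set(val) - sub_fields
            if unknown:
                raise ValueError(f"unknown {key} keys: {sorted(unknown)}")
            if key == "sim" and "chromosomes" in val:
                val["chromosomes"] = tuple(val["chromosomes"])
            kwargs[key] = cls(**val)
        elif key == "panel_sizes":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return PipelineConfig(**kwargs)


def run_all(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run the whole pipeline into ``outdir``; returns the run report.

    The report carries the attrition funnel raw InDels -> segment filter
    -> length filter -> identity filter -> spacing -> density selection
    -> primer design -> specificity screen, plus integration counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "parameters": _cfg_dict(cfg)}

    # --- simulate the cultivar pair
    ref, anchors = simulate_reference(cfg.sim)
    qry, truth = mutate(ref, cfg.sim)
    mio.write_fasta(ref, outdir / "reference.fasta")
    mio.write_fasta(qry, outdir / "derived.fasta")
    mio.write_anchor_map(anchors, outdir / "anchors.tsv")
    report["n_contigs"] = len(ref)
    report["n_planted_indels"] = len(truth.indels())

    # --- align and discover
    pairs = pair_contigs(ref, qry, k=cfg.k)
    blocks = []
    for rc, qc in pairs:
        blocks.extend(align_pair(rc, qc, k=cfg.k))
    variants = [v for b in blocks for v in extract_indels(b)]
    funnel: dict = {}
    kept = filter_indels(variants, blocks, cfg.filter, report=funnel)
    selected = select_by_density(kept, anchors, cfg.target_per_cm)
    funnel["after_density_selection"] = len(selected)
    mio.write_vcf(kept, ref, outdir / "indels.vcf")
    report["length_class_histogram"] = classify_lengths(kept)

    # --- primer design + HRM prediction
    ref_by_id = {c.id: c for c in ref}
    designed = []
    rejections: dict[str, int] = {}
    for v in selected:
        res = design_primer_pair(ref_by_id[v.ref_contig_id], v, cfg.design)
        if isinstance(res, DesignRejection):
            rejections[res.reason] = rejections.get(res.reason, 0) + 1
            continue
        designed.append((v, res))
    funnel["after_primer_design"] = len(designed)
    screened = specificity_screen(designed, ref, cfg.max_mismatches)
    funnel["after_specificity"] = len(screened)
    report["design_rejections"] = rejections
    report["attrition"] = funnel

    markers: list[mio.MarkerRecord] = []
    for sm in screened:
        v = sm.marker
        chrom_cm = anchors.position(v.ref_contig_id)
        if chrom_cm is None:
            continue
        chrom, cm = chrom_cm
        ref_amp, alt_amp = amplicon_alleles(sm.pair, v, ref_by_id[v.ref_contig_id])
        res = classify_hrm(
            amplicon_tm(ref_amp, cfg.na_molar),
            amplicon_tm(alt_amp, cfg.na_molar),
            threshold=cfg.hrm_threshold,
        )
        markers.append(
            mio.MarkerRecord(
                marker_id=f"indel_{v.ref_contig_id}_{v.ref_pos}",
                marker_type="InDel",
                chromosome=chrom,
                cm=cm,
                contig_id=v.ref_contig_id,
                start=v.ref_pos,
                end=max(v.ref_end, v.ref_pos + 1),
                ref_allele_len=v.ref_len,
                alt_allele_len=v.qry_len,
                primer_f=sm.pair.forward,
                primer_r=sm.pair.reverse,
                amplicon_ref_len=len(ref_amp),
                amplicon_alt_len=len(alt_amp),
                tm_amplicon_ref=res.tm_ref,
                tm_amplicon_alt=res.tm_alt,
                delta_tm=res.delta_tm,
                hrm_genotypable=res.genotypable,
            )
        )
    report["n_markers"] = len(markers)
    report["n_hrm_genotypable"] = sum(1 for m in markers if m.hrm_genotypable)

    # --- panels and integration
    n_snp, n_dart, n_ssr = cfg.panel_sizes
    ssr_panel, panels = make_marker_panels(
        ref, truth, n_snp=n_snp, n_dart=n_dart, n_ssr=n_ssr, seed=cfg.seed + 7
    )
    genome = GenomeIndex(ref)
    imap = build_integrated_map(
        markers, panels, ssr_panel, genome, anchors,
        max_product=cfg.ssr_max_product, min_score_frac=cfg.min_score_frac,
    )
    report["integrated_markers"] = len(imap.markers)
    report["unplaced_markers"] = imap.unplaced
    report["ambiguous_markers"] = imap.ambiguous

    indel_only = [m for m in imap.markers if m.marker_type == "InDel"]
    loci, removed = dedup_loci(indel_only)
    report["indel_loci"] = len(loci)
    report["duplicate_position_removed"] = removed

    mio.write_marker_table(imap.markers, outdir / "map.tsv")
    mio.write_bed(imap.markers, outdir / "markers.bed")
    drawn = loci + [m for m in imap.markers if m.marker_type != "InDel"]
    mio.write_mapchart(drawn, outdir / "mapchart.txt")
    if imap.markers:
        summary = summarize(imap.markers)
        summary.counts.to_csv(outdir / "summary.tsv", sep="\t")
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _cfg_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["sim"]["chromosomes"] = list(d["sim"]["chromosomes"])
    d["panel_sizes"] = list(d["panel_sizes"])
    return d
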