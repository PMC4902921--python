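"""Pipeline orchestration: from a declarative config to the locus map report.

Stages run in a fixed order — ingest, CpG islands, methylation depletion,
miRNA sites, region calling, variant calling, prioritisation, strain
concordance — and every stage can also be run standalone through the library
modules.  The report is a plain JSON-serialisable dict whose every number is
recomputable from the bundled inputs plus the recorded parameters; no
timestamps, so identical configs give identical reports.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import __version__
from . import cpg as _cpg
from . import integrate as _integrate
from . import methylation as _meth
from . import mirna as _mirna
from . import strains as _strains
from . import variants as _variants
from .intervals import GeneModel, GenomicInterval, classify_region
from .io import (
    FeatureTrack,
    read_bed,
    read_fasta,
    read_gene_model,
    read_methylation,
    read_mirna_predictions,
    read_strain_table,
)

log = logging.getLogger("regmap")

DEFAULT_PARAMETERS = {
    "region_window": 500,
    "region_merge_gap": 200,
    "cluster_gap": 10,
    "seed_positions": [2, 8],
    "seed_max_mismatches": 1,
    "methylation_segment": None,
    "methylation_alpha": 0.01,
    "yates": False,
    "align_band": None,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh)
    config["_base_dir"] = str(path.parent)
    return config


def _resolve(config: Mapping, key_path: str) -> Path:
    return Path(config.get("_base_dir", ".")) / key_path


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("[%s] start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config) -> dict:
    """Execute the full analysis and return the map report dict.

    ``config`` is a dict (or a path to a YAML file) naming the input files
    (relative to the config location) and the parameters; defaults are
    echoed into the report for provenance.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    params = {**DEFAULT_PARAMETERS, **(config.get("parameters") or {})}

    # ---- ingest ----------------------------------------------------------
    @_stage("ingest")
    def ingest():
        seqs = read_fasta(_resolve(config, config["sequences"]))
        ref_name = config.get("reference_name", "ref")
        if ref_name not in seqs:
            raise ValueError(f"reference {ref_name!r} not in FASTA")
        gm = read_gene_model(_resolve(config, config["gene_model"]))
        tracks: dict[str, FeatureTrack] = {}
        track_files = config.get("tracks") or {}
        if "constrained" not in track_files:
            raise ValueError("criterion (a) cannot be evaluated: no constrained track configured")
        for ftype, rel in track_files.items():
            tracks[ftype] = read_bed(_resolve(config, rel), ftype)
        if "methylation" in config:
            tracks["methylation"] = read_methylation(_resolve(config, config["methylation"]))
        predictions = None
        mirna_seqs: dict[str, str] = {}
        if "mirna_predictions" in config:
            predictions = read_mirna_predictions(_resolve(config, config["mirna_predictions"]))
            mirna_seqs = read_fasta(_resolve(config, config["mirna_sequences"]))
        table = None
        line_names = tuple(config.get("line_names", ("F", "L")))
        if "strain_table" in config:
            table = read_strain_table(_resolve(config, config["strain_table"]), line_names)
        return seqs, ref_name, gm, tracks, predictions, mirna_seqs, table, line_names

    seqs, ref_name, gm, tracks, predictions, mirna_seqs, table, line_names = ingest()
    ref = seqs[ref_name]

    # ---- CpG islands -----------------------------------------------------
    @_stage("cpg_islands")
    def stage_cpg():
        islands = _cpg.find_cpg_islands(ref, seq_id=gm.seq_id)
        return islands, _cpg.islands_to_track(islands)

    islands, island_track = stage_cpg()

    # ---- methylation depletion ------------------------------------------
    @_stage("methylation")
    def stage_meth():
        seg = params.get("methylation_segment")
        if seg is None or "methylation" not in tracks:
            return None, None
        segment = GenomicInterval(gm.seq_id, int(seg[0]), int(seg[1]))
        rest = _meth.subtract(gm.intron, segment)
        report = _meth.depletion_test(tracks["methylation"], segment, rest,
                                      yates=bool(params["yates"]))
        evidence = None
        if report.direction == "depleted" and report.p_value < params["methylation_alpha"]:
            evidence = FeatureTrack("methylation", [segment], source="depletion-test")
        return report, evidence

    meth_report, meth_evidence = stage_meth()

    # ---- miRNA sites -----------------------------------------------------
    @_stage("mirna_sites")
    def stage_mirna():
        if predictions is None:
            return [], [], None, ""
        mrna = gm.mrna_sequence(ref)
        clusters = _mirna.cluster_predictions(predictions, gm, gap=int(params["cluster_gap"]))
        seed_pos = tuple(params["seed_positions"])
        max_mm = int(params["seed_max_mismatches"])
        sites: list[_mirna.MiRNASite] = []
        for mirna_id, group in predictions.groupby("mirna_id"):
            if mirna_id not in mirna_seqs:
                raise ValueError(f"no sequence for predicted miRNA {mirna_id!r}")
            merged = _merge_mrna_intervals(group)
            for lo, hi in merged:
                site = _mirna.MiRNASite(
                    mirna_id,
                    target=GenomicInterval("mRNA", lo, hi),
                    predicting_tools=set(group["tool"]),
                )
                window = _best_seed_window(mirna_seqs[mirna_id], mrna, lo, hi, seed_pos, max_mm)
                if window is not None:
                    site.seed_window = GenomicInterval("mRNA", window, window + (seed_pos[1] - seed_pos[0] + 1))
                site.context = _mirna.site_context(site, gm, mrna)
                sites.append(site)
        track = _mirna.predictions_to_genomic_track(predictions, gm)
        return clusters, sites, track, mrna

    clusters, mirna_sites, mirna_track, mrna_seq = stage_mirna()

    # ---- region calling --------------------------------------------------
    @_stage("region_calling")
    def stage_regions():
        evidence = [t for k, t in tracks.items() if k not in ("methylation", "strain_snp")]
        evidence.append(island_track)
        if mirna_track is not None:
            evidence.append(mirna_track)
        if meth_evidence is not None:
            evidence.append(meth_evidence)
        regions = _integrate.call_high_priority_regions(
            evidence,
            window=int(params["region_window"]),
            merge_gap=int(params["region_merge_gap"]),
            gene_model=gm,
        )
        return regions, evidence

    regions, evidence_tracks = stage_regions()

    # ---- variant calling -------------------------------------------------
    @_stage("variant_calling")
    def stage_variants():
        lines = {name: seqs[name] for name in line_names if name in seqs}
        if not lines:
            return [], []
        band = params.get("align_band")
        kwargs = {"band": int(band)} if band else {}
        called = _variants.call_line_variants(ref, lines, seq_id=gm.seq_id, **kwargs)
        between = [
            v for v in called
            if len({v.line_alleles[n] for n in lines}) > 1
        ]
        # attach ids from the strain table where positions coincide
        if table is not None:
            by_pos = dict(zip(table.positions, table.variant_ids))
            between = [
                _variants.Variant(v.position, v.ref_allele, v.alt_allele,
                                  v.line_alleles, by_pos.get(v.position), v.seq_id)
                for v in between
            ]
        return called, between

    called_all, fl_variants = stage_variants()

    # ---- allele effects + prioritisation --------------------------------
    @_stage("prioritisation")
    def stage_prioritise():
        allele_effects = []
        for site in mirna_sites:
            if site.seed_window is None:
                continue
            for v in fl_variants:
                if v.vtype != "snp":
                    continue
                try:
                    pos_mrna = gm.genomic_to_mrna(v.position)
                except ValueError:
                    continue
                if not site.seed_window.contains_point(pos_mrna):
                    continue
                effect = _mirna.allele_effect(
                    site, mirna_seqs[site.mirna_id], mrna_seq, pos_mrna,
                    v.line_alleles, tuple(params["seed_positions"]),
                )
                if effect.applicable:
                    site.seed_mismatches = effect.mismatches
                    allele_effects.append((site, v, effect))
        tiers = _integrate.prioritise_variants(
            fl_variants, regions, tracks["constrained"], mirna_sites, gm,
            feature_tracks=evidence_tracks, line_names=line_names,
        )
        return tiers, allele_effects

    tiers, allele_effects = stage_prioritise()

    # ---- strain SNP classification + concordance ------------------------
    @_stage("strains")
    def stage_strains():
        snp_summary = None
        if "strain_snp" in tracks and gm.core_promoter is not None:
            _, counts = _integrate.classify_strain_snps(
                tracks["strain_snp"], tracks["constrained"], gm.core_promoter
            )
            snp_summary = dict(counts)
        origin = {}
        concordances = {}
        if table is not None:
            classes = config.get("strain_classes") or {}
            for line in line_names:
                rep = _strains.concordance(table, line)
                concordances[line] = rep
                origin[line] = _strains.origin_call(rep, classes) if classes else None
        return snp_summary, concordances, origin

    snp_summary, concordances, origin = stage_strains()

    # ---- report ----------------------------------------------------------
    return _build_report(
        config, params, gm, tracks, islands, meth_report, clusters, mirna_sites,
        regions, fl_variants, tiers, allele_effects, snp_summary, concordances,
        origin, line_names,
    )


def _merge_mrna_intervals(group) -> list[tuple[int, int]]:
    spans = sorted((int(r["mrna_start"]), int(r["mrna_end"])) for _, r in group.iterrows())
    out = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [tuple(x) for x in out]


def _best_seed_window(mirna_seq: str, mrna: str, lo: int, hi: int,
                      seed_pos: tuple[int, int], max_mm: int) -> Optional[int]:
    """Leftmost minimal-mismatch seed window fully inside [lo, hi), or None."""
    k = seed_pos[1] - seed_pos[0] + 1
    best: Optional[tuple[int, int]] = None
    matches = _mirna.seed_match(mirna_seq, mrna[lo:hi], seed_pos, max_mm)
    for start, mm in matches:
        if best is None or mm < best[0]:
            best = (mm, lo + start)
    return None if best is None else best[1]


def _iv_dict(iv: GenomicInterval) -> dict:
    return {"seq_id": iv.seq_id, "start": iv.start, "end": iv.end}


def _build_report(config, params, gm, tracks, islands, meth_report, clusters,
                  mirna_sites, regions, fl_variants, tiers, allele_effects,
                  snp_summary, concordances, origin, line_names) -> dict:
    from .io import gene_model_to_dict

    report = {
        "schema_version": 1,
        "provenance": {
            "regmap_version": __version__,
            "parameters": {k: v for k, v in params.items()},
            "inputs": {
                k: v for k, v in config.items()
                if isinstance(v, str) and not k.startswith("_")
            },
            "seed": config.get("seed"),
        },
        "locus": {
            "seq_id": gm.seq_id,
            "gene_model": gene_model_to_dict(gm),
            "gene_length": gm.gene_interval.length,
            "mrna_length": gm.mrna_length,
        },
        "tracks": {
            name: {"n_intervals": len(t), "source": t.source}
            for name, t in tracks.items()
        },
        "cpg_islands": [
            {**_iv_dict(i.interval), "gc": round(i.gc_fraction, 4),
             "obs_exp": round(i.obs_exp, 4), "n_cpg": i.n_cpg}
            for i in islands
        ],
        "methylation_test": meth_report.to_dict() if meth_report else None,
        "mirna": {
            "clusters": [
                {**_iv_dict(c.interval), "context": c.context_label.value,
                 "n_mirnas": c.n_mirnas, "n_tools": c.n_tools,
                 "mirnas": sorted(c.mirna_ids)}
                for c in clusters
            ],
            "n_sites": len(mirna_sites),
            "allele_effects": [
                {"mirna_id": site.mirna_id, "variant_position": v.position,
                 "variant_id": v.id, "mismatches": effect.mismatches,
                 "seed_disruptive": effect.seed_disruptive}
                for site, v, effect in allele_effects
            ],
        },
        "regions": [
            {**_iv_dict(r.interval),
             "context": [c.value for c in r.context],
             "n_anchor_elements": len(r.anchor_elements),
             "supporting_types": sorted(r.supporting_types)}
            for r in regions
        ],
        "variants": {
            "n_between_lines": len(fl_variants),
            "by_type": dict(Counter(v.vtype for v in fl_variants)),
            "records": [
                {"position": v.position, "id": v.id, "ref": v.ref_allele,
                 "alt": v.alt_allele, "type": v.vtype,
                 "alleles": dict(v.line_alleles)}
                for v in fl_variants
            ],
            "density_bp_per_variant": (
                round(_variants.variant_density(len(fl_variants), gm.gene_interval.length +
                                                gm.upstream_flank + gm.downstream_flank), 1)
                if fl_variants else None
            ),
            "genome_wide_bp_per_variant": _variants.GENOME_WIDE_BP_PER_VARIANT,
        },
        "prioritisation": [
            {"position": pv.variant.position, "id": pv.variant.id,
             "type": pv.variant.vtype, "tier": pv.tier, "evidence": pv.evidence}
            for pv in tiers
        ],
        "strain_snps": snp_summary,
        "strain_concordance": {
            line: {
                "n_variants": rep.n_variants,
                "per_strain_shared": dict(sorted(rep.per_strain_shared.items())),
                "exact_match_strains": rep.exact_match_strains,
                "n_exact_match": len(rep.exact_match_strains),
                "origin": origin.get(line),
            }
            for line, rep in concordances.items()
        },
    }
    return report
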