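"""End-to-end orchestration of the meta-QTL candidate-gene pipeline.

Stages checkpoint to disk so later stages can consume earlier outputs:

    simulate -> consensus -> project -> colocalize -> meta -> anchor
             -> integrate

Each stage is deterministic given (inputs, config, seed); a run manifest
records the configuration hash and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import io as mio
from .anchor import (anchor_metaqtls, build_anchor_set, genes_in_interval,
                     read_gff_genes, write_bed)
from .colocalization import find_colocated, prune_redundant
from .consensus import (build_consensus, drop_unlinked_groups,
                        map_order_correlation, orient_groups,
                        resolve_inversions)
from .expression import (REGULATORY_GO_SLIM, filter_expressed_atlas,
                         filter_fpkm_expressed, find_onset_interval,
                         funnel_counts, go_slim_filter, intersect_candidates,
                         read_atlas_calls, read_expression,
                         select_transcriptomic_candidates)
from .meta import run_meta_analysis
from .models import ConsensusMap, GeneticMap, MetaQTL, ProjectedQTL
from .projection import project_all

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

STAGES = ("simulate", "consensus", "project", "colocalize", "meta",
          "anchor", "integrate")


@dataclass
class PipelineConfig:
    """All thresholds and paths, serializable to/from YAML."""

    input_dir: str = "."
    out_dir: str = "out"
    focal_trait: str = "ver"
    phenology_traits: Optional[list[str]] = None  # None = all other traits
    min_scale: float = 0.25
    max_scale: Optional[float] = None
    ci_width_constant: float = 530.0
    bin_cm: float = 5.0
    k_max: int = 10
    restarts: int = 10
    tol: float = 1e-8
    fpkm_threshold: float = 1.0
    min_reps: int = 2
    lfc_threshold: float = 1.0
    pseudocount: float = 1.0
    min_years: int = 2
    organs: list[str] = field(default_factory=lambda: ["berry", "rachis", "seed"])
    go_slim: Optional[list[str]] = None  # None = built-in regulatory slim set
    seed: int = 17
    meta_mode: str = "auto"  # single-trait | cross-trait | auto

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# -------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig, sim_cfg=None) -> Path:
    from .simulate import SimulationConfig, simulate_all, write_bundle

    sim_cfg = sim_cfg or SimulationConfig(seed=cfg.seed)
    bundle = simulate_all(sim_cfg)
    return write_bundle(bundle, cfg.input_dir)


def load_component_maps(input_dir: PathLike) -> list[GeneticMap]:
    maps_dir = Path(input_dir) / "maps"
    if not maps_dir.is_dir():
        raise FileNotFoundError(
            f"{maps_dir} missing; run the 'simulate' stage or point "
            "input_dir at a prepared bundle")
    return [mio.read_genetic_map(p) for p in sorted(maps_dir.glob("*.tsv"))]


def stage_consensus(cfg: PipelineConfig) -> ConsensusMap:
    """Normalize, orient, de-conflict and merge the component maps."""
    inp, out = Path(cfg.input_dir), Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps = load_component_maps(inp)
    syn_path = inp / "synonyms.tsv"
    if syn_path.exists():
        syn = mio.read_synonym_table(syn_path)
        maps = [mio.normalize_marker_names(g, syn) for g in maps]
    reference = max(maps, key=lambda g: (g.n_markers(), g.map_id))
    oriented = []
    for g in maps:
        g2, unorientable = orient_groups(g, reference)
        if unorientable:
            logger.info("map %s: un-orientable groups %s", g.map_id,
                        unorientable)
        oriented.append(g2)
    linked, removed = drop_unlinked_groups(oriented)
    lgs = sorted({lg for g in linked for lg in g.lgs}, key=lambda s: (len(s), s))
    removed_markers = {}
    for lg in lgs:
        linked, dropped = resolve_inversions(linked, lg)
        if dropped:
            removed_markers[lg] = dropped
    consensus = build_consensus(linked, lgs)
    mio.write_consensus_map(consensus, out / "consensus_map.tsv")
    pd.DataFrame(consensus.summary()).to_csv(out / "consensus_summary.tsv",
                                             sep="\t", index=False)
    corr_rows = []
    for g in linked:
        for lg, val in map_order_correlation(g, consensus).items():
            if lg == "overall" or val is None:
                continue
            corr_rows.append({"map_id": g.map_id, "lg": lg,
                              "spearman_rho": round(val[0], 4),
                              "n_shared": val[1]})
    pd.DataFrame(corr_rows).to_csv(out / "order_correlations.tsv", sep="\t",
                                   index=False)
    report = {"removed_groups": removed, "removed_markers": removed_markers}
    (out / "consensus_report.json").write_text(json.dumps(report, indent=1))
    return consensus


def _reload_consensus(cfg: PipelineConfig) -> ConsensusMap:
    path = Path(cfg.out_dir) / "consensus_map.tsv"
    if not path.exists():
        raise FileNotFoundError(f"{path} missing; run the 'consensus' stage first")
    return mio.read_consensus_map(path)


def stage_project(cfg: PipelineConfig,
                  consensus: Optional[ConsensusMap] = None
                  ) -> list[ProjectedQTL]:
    inp, out = Path(cfg.input_dir), Path(cfg.out_dir)
    consensus = consensus or _reload_consensus(cfg)
    qtls = mio.read_qtl_table(inp / "qtls.tsv")
    maps = {g.map_id: g for g in load_component_maps(inp)}
    syn_path = inp / "synonyms.tsv"
    if syn_path.exists():
        syn = mio.read_synonym_table(syn_path)
        maps = {k: mio.normalize_marker_names(g, syn) for k, g in maps.items()}
    projected, report = project_all(
        qtls, maps, consensus, min_scale=cfg.min_scale,
        max_scale=cfg.max_scale, ci_width_constant=cfg.ci_width_constant)
    mio.write_projected_qtls(projected, out / "projected_qtls.tsv")
    for trait in sorted({q.record.trait for q in projected}):
        mio.write_projected_qtls(
            [q for q in projected if q.record.trait == trait],
            out / f"consensus_qtls_{trait}.tsv")
    (out / "projection_report.json").write_text(json.dumps(
        {"n_total": report.n_total, "n_projected": report.n_projected,
         "rejections": report.rejections,
         "per_trait": report.per_trait,
         "per_category": report.per_category}, indent=1))
    return projected


def _reload_projected(cfg: PipelineConfig) -> list[ProjectedQTL]:
    """Rebuild projected QTLs from the checkpoint by re-running projection."""
    return stage_project(cfg)


def stage_colocalize(cfg: PipelineConfig,
                     projected: Optional[list[ProjectedQTL]] = None
                     ) -> list:
    out = Path(cfg.out_dir)
    projected = projected if projected is not None else _reload_projected(cfg)
    rows = []
    for scope in ("within-trait", "cross-trait"):
        for c in find_colocated(projected, scope=scope):
            rows.append({
                "scope": scope, "cluster_id": c.cluster_id, "lg": c.lg,
                "traits": ",".join(c.traits),
                "members": ",".join(c.member_ids),
                "n_populations": c.n_populations,
                "confirmed": int(c.confirmed),
                "span_start_cm": round(c.span_start_cm, 2),
                "span_end_cm": round(c.span_end_cm, 2),
            })
    pd.DataFrame(rows).to_csv(out / "colocated.tsv", sep="\t", index=False)
    return rows


def stage_meta(cfg: PipelineConfig,
               projected: Optional[list[ProjectedQTL]] = None
               ) -> list[MetaQTL]:
    """Two-round meta-analysis: single-trait where the focal trait has
    overlapping QTLs, cross-trait pooling elsewhere (``meta_mode=auto``)."""
    out = Path(cfg.out_dir)
    projected = projected if projected is not None else _reload_projected(cfg)
    focal_lgs = sorted({
        q.record.lg for q in projected
        if q.projected and q.record.trait == cfg.focal_trait
    }, key=lambda s: (len(s), s))
    other = set(cfg.phenology_traits) if cfg.phenology_traits else None
    metaqtls: list[MetaQTL] = []
    for lg in focal_lgs:
        found: list[MetaQTL] = []
        if cfg.meta_mode in ("single-trait", "auto"):
            found = run_meta_analysis(
                projected, cfg.focal_trait, lg, mode="single-trait",
                k_max=cfg.k_max, restarts=cfg.restarts, tol=cfg.tol,
                seed=cfg.seed)
        if cfg.meta_mode == "cross-trait" or (cfg.meta_mode == "auto"
                                              and not found):
            found = run_meta_analysis(
                projected, cfg.focal_trait, lg, mode="cross-trait",
                other_traits=other, k_max=cfg.k_max, restarts=cfg.restarts,
                tol=cfg.tol, seed=cfg.seed)
        metaqtls.extend(found)
    mio.write_metaqtls(metaqtls, out / "metaqtls.tsv")
    return metaqtls


def _reload_metaqtls(cfg: PipelineConfig) -> list[MetaQTL]:
    path = Path(cfg.out_dir) / "metaqtls.tsv"
    if not path.exists():
        raise FileNotFoundError(f"{path} missing; run the 'meta' stage first")
    df = pd.read_csv(path, sep="\t", dtype={"lg": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(MetaQTL(
            name=row.name, lg=str(row.lg), peak_cm=float(row.peak_cm),
            ci_start_cm=float(row.start_cm), ci_end_cm=float(row.end_cm),
            mean_r2=None if pd.isna(row.mean_r2) else float(row.mean_r2),
            member_ids=str(row.member_qtl_ids).split(","),
            n_studies=int(row.n_studies),
            traits=str(row.traits).split(",")))
    return out


def stage_anchor(cfg: PipelineConfig,
                 consensus: Optional[ConsensusMap] = None,
                 metaqtls: Optional[list[MetaQTL]] = None
                 ) -> tuple[list[MetaQTL], dict[str, list]]:
    inp, out = Path(cfg.input_dir), Path(cfg.out_dir)
    consensus = consensus or _reload_consensus(cfg)
    metaqtls = metaqtls if metaqtls is not None else _reload_metaqtls(cfg)
    hits = mio.read_anchor_table(inp / "anchors.tsv")
    anchors, excluded, unanchorable = build_anchor_set(hits, consensus)
    mio.write_anchor_points(anchors, out / "anchor_points.tsv")
    (out / "anchor_report.json").write_text(json.dumps(
        {"excluded": excluded, "unanchorable_lgs": unanchorable}, indent=1))
    chrom_lengths = None
    cl_path = inp / "chrom_lengths.tsv"
    if cl_path.exists():
        cl = pd.read_csv(cl_path, sep="\t")
        chrom_lengths = dict(zip(cl["chrom"], cl["length"]))
    anchor_metaqtls(metaqtls, anchors, chrom_lengths)
    mio.write_metaqtls(metaqtls, out / "metaqtls.tsv")
    write_bed(metaqtls, out / "metaqtl_intervals.bed")
    genes = read_gff_genes(inp / "genome.gff3")
    positional: dict[str, list] = {}
    for m in metaqtls:
        if m.chrom is None:
            continue
        found = genes_in_interval(genes, m.chrom, (m.start_bp, m.end_bp))
        positional[m.name] = found
        pd.DataFrame(
            [{"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start_bp,
              "end": g.end_bp, "annotation": g.annotation} for g in found]
        ).to_csv(out / f"candidates_{m.name.replace('/', '-')}.tsv",
                 sep="\t", index=False)
    return metaqtls, positional


def stage_integrate(cfg: PipelineConfig,
                    positional: Optional[dict[str, list]] = None
                    ) -> pd.DataFrame:
    """Expression filters, intersection and GO-slim flagging."""
    inp, out = Path(cfg.input_dir), Path(cfg.out_dir)
    if positional is None:
        _, positional = stage_anchor(cfg)
    mat = read_expression(inp / "fpkm.tsv", inp / "samples.tsv")
    atlas = read_atlas_calls(inp / "atlas_calls.tsv")
    biomarkers = (inp / "biomarkers.txt").read_text().split()
    de_list = (inp / "all_genotype_de.txt").read_text().split()
    go_table = pd.read_csv(inp / "go.tsv", sep="\t")

    pos_genes = {g.gene_id for genes in positional.values() for g in genes}
    atlas_pass = filter_expressed_atlas(pos_genes, atlas, cfg.organs)
    expressed = filter_fpkm_expressed(mat, cfg.fpkm_threshold, cfg.min_reps)
    onset = {y: find_onset_interval(mat, biomarkers, y, cfg.lfc_threshold,
                                    cfg.pseudocount) for y in mat.years}
    transcriptomic = select_transcriptomic_candidates(
        mat, biomarkers, de_list, min_years=cfg.min_years,
        lfc_threshold=cfg.lfc_threshold, pseudocount=cfg.pseudocount,
        onset=onset)
    transcriptomic &= expressed | set(de_list)

    surviving = {
        name: [g for g in genes if g.gene_id in atlas_pass]
        for name, genes in positional.items()
    }
    evidence = {g: ["modulated"] for g in transcriptomic}
    for g in de_list:
        evidence.setdefault(g, []).append("all-genotype DE")
    candidates = intersect_candidates(surviving, transcriptomic, evidence)
    slim = frozenset(cfg.go_slim) if cfg.go_slim else REGULATORY_GO_SLIM
    flagged = go_slim_filter(candidates, go_table, slim)

    df = pd.DataFrame([
        {"gene_id": c.gene_id, "chrom": c.chrom, "start": c.start_bp,
         "end": c.end_bp, "annotation": c.annotation, "mQTL": c.metaqtl,
         "evidence": ";".join(c.evidence), "regulatory": int(c.regulatory)}
        for c in candidates
    ])
    df.to_csv(out / "candidates_final.tsv", sep="\t", index=False)
    n_final = len({c.gene_id for c in candidates})
    n_reg = len({c.gene_id for c in flagged})
    funnel = funnel_counts(
        len(pos_genes), len(pos_genes & atlas_pass), n_final, n_reg)
    funnel.to_csv(out / "funnel_counts.tsv", sep="\t", index=False)
    (out / "onset_intervals.json").write_text(json.dumps(
        {str(y): [int(t) for t in v] for y, v in onset.items()}, indent=1))
    logger.info("funnel: %s", funnel.to_dict("records"))
    return df


def run_stage(stage: str, cfg: PipelineConfig) -> None:
    """Run one stage (or ``all``) against the configured directories."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    if stage == "simulate":
        stage_simulate(cfg)
    elif stage == "consensus":
        stage_consensus(cfg)
    elif stage == "project":
        stage_project(cfg)
    elif stage == "colocalize":
        stage_colocalize(cfg)
    elif stage == "meta":
        stage_meta(cfg)
    elif stage == "anchor":
        stage_anchor(cfg)
    elif stage == "integrate":
        stage_integrate(cfg)
    elif stage == "all":
        if not (Path(cfg.input_dir) / "qtls.tsv").exists():
            stage_simulate(cfg)
        consensus = stage_consensus(cfg)
        projected = stage_project(cfg, consensus)
        stage_colocalize(cfg, projected)
        metaqtls = stage_meta(cfg, projected)
        _, positional = stage_anchor(cfg, consensus, metaqtls)
        stage_integrate(cfg, positional)
    else:
        raise ValueError(f"unknown stage {stage!r}; choose from "
                         f"{STAGES + ('all',)}")
    manifest = {
        "stage": stage,
        "config_digest": cfg.digest(),
        "inputs": {
            p.name: _checksum(p)
            for p in sorted(Path(cfg.input_dir).glob("*.tsv"))
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
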