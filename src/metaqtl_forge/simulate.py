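"""Synthetic input generation with known ground truth.

Every pipeline input — component genetic maps, QTL tables, the genome
annotation and anchor table, the expression time course, the organ call
table and the externally curated gene lists — can be emulated here so that
each stage is testable end-to-end without downloads.  The generator is
honest about what it does not model: map distortions are affine plus
order-preserving jitter rather than recombination events, and expression
is a log-normal baseline with a step change at the planted transition
rather than a full RNA-seq noise model.

Marker sharing: each linkage group has a marker pool; a backbone subset
(``shared_fraction`` of a map's quota) is common to all maps, the rest of
each map's quota is drawn at random.  QTL observations follow the mixture
observation model: peaks x_i ~ N(mu, sigma_i^2) with sigma_i uniform on
``sd_range`` and CI_i = 3.92 * sigma_i, expressed in a component map's
coordinates through that map's distortion.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .consensus import _piecewise_linear
from .models import GeneModel, GeneticMap, Marker, QTLRecord


@dataclass(frozen=True)
class TrueMetaQTL:
    """A planted 'true' locus from which QTL observations are sampled."""

    lg: str
    position_cm: float
    n_qtls: int
    sd_range: tuple[float, float] = (1.5, 4.0)
    r2_range: tuple[float, float] = (0.05, 0.25)
    n_studies: int = 3


def default_true_metaqtls() -> list[TrueMetaQTL]:
    """The default planted layout: one locus on LG 1, three on LG 2.

    LG 2 carries 12 QTLs around 20, 50 and 80 cM with sigma in [1.5, 4],
    the configuration used for the parameter-recovery experiment.
    """
    return [
        TrueMetaQTL(lg="1", position_cm=30.0, n_qtls=2, n_studies=2),
        TrueMetaQTL(lg="2", position_cm=20.0, n_qtls=4),
        TrueMetaQTL(lg="2", position_cm=50.0, n_qtls=4),
        TrueMetaQTL(lg="2", position_cm=80.0, n_qtls=4),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 17
    n_lgs: int = 2
    lg_length_cm: float = 100.0
    marker_pool_per_lg: int = 80
    n_maps: int = 10
    markers_per_map: int = 60
    shared_fraction: float = 0.4
    scale_range: tuple[float, float] = (0.8, 1.25)
    jitter_sd_cm: float = 0.5
    true_metaqtls: list[TrueMetaQTL] = field(default_factory=default_true_metaqtls)
    n_planted_inversions: int = 0
    n_planted_duplicates: int = 2
    n_unanchorable_qtls: int = 0
    n_other_trait_qtls: int = 0
    n_synonym_variants: int = 3
    # genome
    bp_per_cm: int = 100_000
    genes_per_lg: int = 120
    n_anchors_per_lg: int = 12
    n_multi_hit_anchors: int = 0
    n_incongruent_anchors: int = 0
    n_candidates_per_metaqtl: int = 3
    candidate_span_cm: float = 0.5
    # expression
    years: tuple[int, ...] = (2012, 2013, 2014)
    n_timepoints: int = 7
    n_replicates: int = 3
    transition_timepoint: dict[int, int] = field(
        default_factory=lambda: {2012: 3, 2013: 4, 2014: 3})
    effect_size_log2: float = 2.0
    noise_sd_log2: float = 0.2
    n_biomarkers: int = 30
    n_decoy_modulated: int = 20
    n_one_year_modulated: int = 8
    n_de_list_extra: int = 25
    n_atlas_fail: int = 6
    n_never_expressed: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in (0, 1]")
        if self.scale_range[0] <= 0:
            raise ValueError("scale range must be positive")
        for t in self.true_metaqtls:
            if not 0 <= t.position_cm <= self.lg_length_cm:
                raise ValueError(
                    f"planted locus at {t.position_cm} cM outside LG of "
                    f"length {self.lg_length_cm}")

    @property
    def lgs(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_lgs)]


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    true_marker_order: dict[str, list[str]] = field(default_factory=dict)
    true_marker_pos: dict[str, dict[str, float]] = field(default_factory=dict)
    metaqtl_positions: dict[str, list[float]] = field(default_factory=dict)
    qtl_origin: dict[str, float] = field(default_factory=dict)
    duplicate_ids: list[str] = field(default_factory=list)
    unanchorable_ids: list[str] = field(default_factory=list)
    inversion_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    synonym_variants: dict[str, str] = field(default_factory=dict)
    multi_hit_markers: list[str] = field(default_factory=list)
    incongruent_markers: list[str] = field(default_factory=list)
    candidate_genes: list[str] = field(default_factory=list)
    modulated_genes: list[str] = field(default_factory=list)
    de_list_genes: list[str] = field(default_factory=list)
    atlas_fail_genes: list[str] = field(default_factory=list)
    never_expressed_genes: list[str] = field(default_factory=list)
    regulatory_genes: list[str] = field(default_factory=list)
    transition_interval: dict[int, tuple[int, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=list)


@dataclass
class SimulatedBundle:
    """In-memory view of one complete simulated input set."""

    cfg: SimulationConfig
    true_map: GeneticMap
    maps: list[GeneticMap]
    qtls: list[QTLRecord]
    genes: list[GeneModel]
    anchors: pd.DataFrame
    go_table: pd.DataFrame
    chrom_lengths: dict[str, int]
    fpkm: pd.DataFrame
    samples: pd.DataFrame
    atlas_calls: pd.DataFrame
    biomarkers: list[str]
    all_genotype_de: list[str]
    truth: GroundTruth


# ---------------------------------------------------------------- maps


def simulate_maps(cfg: SimulationConfig, rng: np.random.Generator,
                  truth: GroundTruth) -> tuple[GeneticMap, list[GeneticMap]]:
    """Draw a true map and affinely distorted component maps."""
    true_groups: dict[str, list[Marker]] = {}
    for lg in cfg.lgs:
        pos = np.sort(rng.uniform(0, cfg.lg_length_cm, cfg.marker_pool_per_lg))
        markers = [Marker(f"M{lg}_{i:03d}", lg, float(p))
                   for i, p in enumerate(pos)]
        true_groups[lg] = markers
        truth.true_marker_order[lg] = [m.name for m in markers]
        truth.true_marker_pos[lg] = {m.name: m.pos_cm for m in markers}
    true_map = GeneticMap(map_id="true", groups=true_groups)

    n_backbone = max(2, round(cfg.shared_fraction * cfg.markers_per_map))
    backbone: dict[str, list[int]] = {
        lg: sorted(rng.choice(cfg.marker_pool_per_lg, n_backbone, replace=False))
        for lg in cfg.lgs
    }
    maps: list[GeneticMap] = []
    for j in range(cfg.n_maps):
        scale = rng.uniform(*cfg.scale_range)
        groups: dict[str, list[Marker]] = {}
        for lg in cfg.lgs:
            pool = true_groups[lg]
            extra_pool = [i for i in range(len(pool)) if i not in backbone[lg]]
            n_extra = min(len(extra_pool),
                          max(0, cfg.markers_per_map - n_backbone))
            chosen = sorted(set(backbone[lg]) | set(
                rng.choice(extra_pool, n_extra, replace=False)))
            true_pos = np.array([pool[i].pos_cm for i in chosen])
            jittered = scale * true_pos + rng.normal(0, cfg.jitter_sd_cm,
                                                     len(chosen))
            # order-preserving by construction: sorted values keep true order;
            # shift only if jitter produced a negative coordinate
            jittered = np.sort(jittered)
            jittered -= min(0.0, float(jittered.min()))
            groups[lg] = [
                Marker(pool[i].name, lg, float(p))
                for i, p in zip(chosen, jittered)
            ]
        maps.append(GeneticMap(map_id=f"map{j:02d}", study_ref=f"study{j % 5}",
                               groups=groups))

    for _ in range(cfg.n_planted_inversions):
        j = int(rng.integers(len(maps)))
        lg = cfg.lgs[int(rng.integers(len(cfg.lgs)))]
        markers = maps[j].groups[lg]
        i = int(rng.integers(len(markers) - 1))
        a, b = markers[i], markers[i + 1]
        markers[i] = Marker(b.name, lg, a.pos_cm)
        markers[i + 1] = Marker(a.name, lg, b.pos_cm)
        truth.inversion_pairs.append((maps[j].map_id, a.name, b.name))

    if cfg.n_synonym_variants:
        target = maps[0]
        flat = [(lg, i) for lg in target.groups
                for i in range(len(target.groups[lg]))]
        picks = rng.choice(len(flat), min(cfg.n_synonym_variants, len(flat)),
                           replace=False)
        for p in picks:
            lg, i = flat[int(p)]
            m = target.groups[lg][i]
            variant = m.name.lower() + "*"
            target.groups[lg][i] = Marker(variant, lg, m.pos_cm)
            truth.synonym_variants[variant] = m.name
    return true_map, maps


def _true_to_map(true_map: GeneticMap, component: GeneticMap, lg: str,
                 values: np.ndarray) -> np.ndarray:
    """Express true-map cM coordinates in a component map's frame."""
    true_pos = true_map.positions(lg)
    comp = component.markers(lg)
    xs = np.array([true_pos[m.name] for m in comp if m.name in true_pos])
    ys = np.array([m.pos_cm for m in comp if m.name in true_pos])
    order = np.argsort(xs)
    return _piecewise_linear(values, xs[order], ys[order])


# ---------------------------------------------------------------- QTLs


def simulate_qtls(cfg: SimulationConfig, true_map: GeneticMap,
                  maps: list[GeneticMap], rng: np.random.Generator,
                  truth: GroundTruth) -> list[QTLRecord]:
    """Sample QTL observations around the planted loci.

    Peaks follow the observation model in true coordinates, then both peak
    and CI are pushed through a randomly chosen component map's distortion
    so the table arrives in source-map coordinates, as published tables do.
    """
    qtls: list[QTLRecord] = []
    for k, tm in enumerate(cfg.true_metaqtls):
        truth.metaqtl_positions.setdefault(tm.lg, []).append(tm.position_cm)
        for i in range(tm.n_qtls):
            sigma = rng.uniform(*tm.sd_range)
            x = float(np.clip(rng.normal(tm.position_cm, sigma),
                              0, cfg.lg_length_cm))
            half = 1.96 * sigma
            lo, hi = x - half, x + half
            j = int(rng.integers(len(maps)))
            gmap = maps[j]
            mapped = _true_to_map(true_map, gmap, tm.lg,
                                  np.array([lo, x, hi]))
            lo_m, x_m, hi_m = (max(0.0, float(v)) for v in mapped)
            qtl_id = f"q{tm.lg}.{k}.{i}"
            qtls.append(
                QTLRecord(
                    qtl_id=qtl_id,
                    trait="ver",
                    trait_category="phenology",
                    study_ref=f"study{i % tm.n_studies}",
                    population_size=int(rng.integers(100, 260)),
                    lg=tm.lg,
                    peak_cm=x_m,
                    ci_start_cm=lo_m,
                    ci_end_cm=hi_m,
                    r2=float(np.round(rng.uniform(*tm.r2_range), 3)),
                    map_id=gmap.map_id,
                )
            )
            truth.qtl_origin[qtl_id] = tm.position_cm

    if cfg.n_other_trait_qtls:
        loci = cfg.true_metaqtls
        for i in range(cfg.n_other_trait_qtls):
            tm = loci[i % len(loci)]
            sigma = rng.uniform(*tm.sd_range)
            x = float(np.clip(rng.normal(tm.position_cm, sigma),
                              0, cfg.lg_length_cm))
            j = int(rng.integers(len(maps)))
            mapped = _true_to_map(true_map, maps[j], tm.lg,
                                  np.array([x - 1.96 * sigma, x,
                                            x + 1.96 * sigma]))
            lo_m, x_m, hi_m = (max(0.0, float(v)) for v in mapped)
            qtls.append(
                QTLRecord(
                    qtl_id=f"qflo.{i}",
                    trait="flo",
                    trait_category="phenology",
                    study_ref=f"study{3 + i % 2}",
                    population_size=150,
                    lg=tm.lg,
                    peak_cm=x_m,
                    ci_start_cm=lo_m,
                    ci_end_cm=hi_m,
                    r2=0.1,
                    map_id=maps[j].map_id,
                )
            )

    base = [q for q in qtls if q.trait == "ver"]
    for d in range(cfg.n_planted_duplicates):
        src = base[int(rng.integers(len(base)))]
        dup_id = f"{src.qtl_id}_dup{d}"
        qtls.append(
            QTLRecord(
                qtl_id=dup_id,
                trait=src.trait,
                trait_category=src.trait_category,
                study_ref=src.study_ref,
                population_size=src.population_size,
                lg=src.lg,
                peak_cm=src.peak_cm,
                ci_start_cm=src.ci_start_cm,
                ci_end_cm=src.ci_end_cm,
                r2=max(0.0, (src.r2 or 0.1) - 0.02),
                map_id=src.map_id,
            )
        )
        truth.duplicate_ids.append(dup_id)

    if cfg.n_unanchorable_qtls:
        iso = GeneticMap(
            map_id="map_iso", study_ref="study_iso",
            groups={"iso": [Marker(f"ISO_{i}", "iso", float(5 * i))
                            for i in range(6)]},
        )
        maps.append(iso)
        for i in range(cfg.n_unanchorable_qtls):
            qtl_id = f"qiso.{i}"
            peak = float(rng.uniform(5, 20))
            qtls.append(
                QTLRecord(
                    qtl_id=qtl_id, trait="ver", trait_category="phenology",
                    study_ref="study_iso", population_size=120, lg="iso",
                    peak_cm=peak, ci_start_cm=peak - 2, ci_end_cm=peak + 2,
                    r2=0.1, map_id="map_iso",
                )
            )
            truth.unanchorable_ids.append(qtl_id)
    return qtls


# ---------------------------------------------------------------- genome


def simulate_genome(cfg: SimulationConfig, true_map: GeneticMap,
                    rng: np.random.Generator, truth: GroundTruth
                    ) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame,
                               dict[str, int]]:
    """Chromosomes, gene models, anchor hits and GO annotations.

    The true cM -> bp relation is exactly linear (``bp_per_cm``), so true
    meta-QTL positions have known physical locations; candidate genes are
    planted within ``candidate_span_cm`` of each locus.
    """
    genes: list[GeneModel] = []
    chrom_lengths = {
        f"chr{lg}": int(cfg.lg_length_cm * cfg.bp_per_cm) for lg in cfg.lgs
    }
    gene_w = 2000
    planted: list[GeneModel] = []
    for k, tm in enumerate(cfg.true_metaqtls):
        chrom = f"chr{tm.lg}"
        offs = np.linspace(-cfg.candidate_span_cm, cfg.candidate_span_cm,
                           cfg.n_candidates_per_metaqtl)
        for j, off in enumerate(offs):
            center = int((tm.position_cm + off) * cfg.bp_per_cm)
            planted.append(
                GeneModel(gene_id=f"g_mq{k}_{j}", chrom=chrom,
                          start_bp=max(1, center - gene_w // 2),
                          end_bp=center + gene_w // 2,
                          annotation=f"planted candidate near locus {k}")
            )
    for lg in cfg.lgs:
        chrom = f"chr{lg}"
        length = chrom_lengths[chrom]
        centers = np.linspace(length / (2 * cfg.genes_per_lg),
                              length - length / (2 * cfg.genes_per_lg),
                              cfg.genes_per_lg)
        for i, c in enumerate(centers):
            g = GeneModel(gene_id=f"g{lg}_{i:03d}", chrom=chrom,
                          start_bp=max(1, int(c) - gene_w // 2),
                          end_bp=int(c) + gene_w // 2,
                          annotation=f"grid gene {i} on {chrom}")
            if any(p.chrom == chrom and p.start_bp <= g.end_bp
                   and g.start_bp <= p.end_bp for p in planted):
                continue
            genes.append(g)
    genes.extend(planted)
    genes.sort(key=lambda g: (g.chrom, g.start_bp))

    rows = []
    for lg in cfg.lgs:
        markers = true_map.markers(lg)
        idx = np.unique(np.linspace(0, len(markers) - 1,
                                    cfg.n_anchors_per_lg).astype(int))
        for i in idx:
            m = markers[i]
            rows.append({"marker": m.name, "lg": lg, "chrom": f"chr{lg}",
                         "bp": int(m.pos_cm * cfg.bp_per_cm) + 1, "n_hits": 1})
    anchors = pd.DataFrame(rows)

    # only interior anchors of each LG are eligible for planted defects, so
    # the terminal interpolation segments stay intact
    interior = np.array([
        i for lg, grp in anchors.groupby("lg").groups.items()
        for i in list(grp)[1:-1]
    ], dtype=int)
    picks = rng.choice(interior, size=min(len(interior),
                                          cfg.n_multi_hit_anchors +
                                          cfg.n_incongruent_anchors),
                       replace=False) if len(interior) else []
    for n, i in enumerate(picks):
        marker = anchors.loc[i, "marker"]
        if n < cfg.n_multi_hit_anchors:
            anchors.loc[i, "n_hits"] = 2
            truth.multi_hit_markers.append(marker)
        else:
            # displace far enough to conflict with many neighbours
            length = chrom_lengths[anchors.loc[i, "chrom"]]
            anchors.loc[i, "bp"] = int((anchors.loc[i, "bp"]
                                        + 0.4 * length) % length) + 1
            truth.incongruent_markers.append(marker)

    all_ids = [g.gene_id for g in genes]
    go_rows = [{"gene": g, "go": "GO:0008150"} for g in all_ids]
    reg = [g.gene_id for g in planted[::2]]
    slim = sorted(
        ["GO:0003700", "GO:0007165", "GO:0007275", "GO:0016301"])
    for i, g in enumerate(reg):
        go_rows.append({"gene": g, "go": slim[i % len(slim)]})
    truth.regulatory_genes = reg
    return genes, anchors, pd.DataFrame(go_rows), chrom_lengths


# ------------------------------------------------------------ expression


def simulate_expression(cfg: SimulationConfig, genes: list[GeneModel],
                        rng: np.random.Generator, truth: GroundTruth
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                   list[str], list[str]]:
    """FPKM time course with a planted veraison-like transition.

    Biomarkers and planted candidate genes step by ``effect_size_log2``
    log2 units at the year-specific transition time point; a planted
    never-expressed set stays below 1 FPKM everywhere; the organ call
    table silences a known subset in berry/rachis/seed.
    """
    gene_ids = [g.gene_id for g in genes]
    planted = [g for g in gene_ids if g.startswith("g_mq")]
    grid = [g for g in gene_ids if not g.startswith("g_mq")]
    # grid genes far (>=10 cM) from any planted locus, usable as decoys
    loci_bp = {
        f"chr{t.lg}": [tm.position_cm * cfg.bp_per_cm
                       for tm in cfg.true_metaqtls if tm.lg == t.lg]
        for t in cfg.true_metaqtls
    }
    by_id = {g.gene_id: g for g in genes}

    def far_from_loci(gid: str) -> bool:
        g = by_id[gid]
        return all(abs(g.start_bp - p) > 10 * cfg.bp_per_cm
                   for p in loci_bp.get(g.chrom, []))

    far = [g for g in grid if far_from_loci(g)]
    rng.shuffle(far)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = far[cursor:cursor + n]
        cursor += n
        return out

    biomarkers = take(cfg.n_biomarkers)
    decoys = take(cfg.n_decoy_modulated)
    one_year = take(cfg.n_one_year_modulated)
    de_extra = take(cfg.n_de_list_extra)
    never = take(cfg.n_never_expressed)

    # planted candidates: alternate between modulated evidence and DE-list
    # evidence; one per locus is atlas-silenced to exercise that filter
    n_per = cfg.n_candidates_per_metaqtl
    atlas_fail = [planted[k * n_per] for k in range(len(cfg.true_metaqtls))
                  if k * n_per < len(planted)][: cfg.n_atlas_fail]
    atlas_fail += [g for g in take(max(0, cfg.n_atlas_fail - len(atlas_fail)))]
    usable_planted = [g for g in planted if g not in atlas_fail]
    de_list_planted = usable_planted[1::2]
    modulated_planted = [g for g in usable_planted if g not in de_list_planted]

    modulated_3y = modulated_planted + decoys[: len(decoys) // 2]
    modulated_2y = decoys[len(decoys) // 2:]
    # atlas-silenced planted genes are still modulated: the atlas filter,
    # not the expression filter, must remove them
    modulated_3y = modulated_3y + [g for g in atlas_fail if g in planted]

    truth.candidate_genes = sorted(modulated_planted + de_list_planted)
    truth.modulated_genes = sorted(modulated_3y + modulated_2y)
    truth.de_list_genes = sorted(de_list_planted + de_extra)
    truth.atlas_fail_genes = sorted(atlas_fail)
    truth.never_expressed_genes = sorted(never)

    base = rng.normal(3.0, 1.0, len(gene_ids))
    # a floor keeps planted signal genes clear of the FPKM >= 1 filter and
    # of pseudocount attenuation of the planted fold change
    special = set(truth.modulated_genes) | set(biomarkers) | set(planted)
    for i, g in enumerate(gene_ids):
        if g in special:
            base[i] = max(base[i], 1.5)
    base_s = pd.Series(base, index=gene_ids)

    years_2y = set(cfg.years[:2])
    sample_rows = []
    cols: dict[str, np.ndarray] = {}
    for year in cfg.years:
        t_tr = cfg.transition_timepoint[year]
        truth.transition_interval[year] = (t_tr, t_tr + 1)
        for tp in range(1, cfg.n_timepoints + 1):
            days = 10 * (cfg.n_timepoints - 1 - tp)  # last point post-veraison
            for rep in range(1, cfg.n_replicates + 1):
                name = f"s{year}_t{tp}_r{rep}"
                sample_rows.append(
                    {"sample": name, "year": year, "timepoint_order": tp,
                     "days_before_veraison": days, "replicate": rep})
                step = np.zeros(len(gene_ids))
                if tp > t_tr:
                    for i, g in enumerate(gene_ids):
                        in_year = (
                            g in set(biomarkers)
                            or g in set(modulated_3y)
                            or (g in set(modulated_2y) and year in years_2y)
                            or (g in set(one_year) and year == cfg.years[0])
                        )
                        if in_year:
                            step[i] = cfg.effect_size_log2
                log2fpkm = base_s.values + step + rng.normal(
                    0, cfg.noise_sd_log2, len(gene_ids))
                vals = np.power(2.0, log2fpkm)
                never_mask = np.isin(gene_ids, never)
                vals[never_mask] = rng.uniform(0.0, 0.5, never_mask.sum())
                cols[name] = vals
    fpkm = pd.DataFrame(cols, index=gene_ids)
    samples = pd.DataFrame(sample_rows)

    atlas = pd.DataFrame(True, index=gene_ids,
                         columns=["berry", "rachis", "seed", "leaf"])
    atlas.loc[atlas_fail, ["berry", "rachis", "seed"]] = False
    return fpkm, samples, atlas, biomarkers, truth.de_list_genes


# ---------------------------------------------------------------- bundle


def simulate_all(cfg: Optional[SimulationConfig] = None) -> SimulatedBundle:
    """Run every generator stage with one seeded RNG."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    true_map, maps = simulate_maps(cfg, rng, truth)
    qtls = simulate_qtls(cfg, true_map, maps, rng, truth)
    genes, anchors, go_table, chrom_lengths = simulate_genome(
        cfg, true_map, rng, truth)
    fpkm, samples, atlas, biomarkers, de_list = simulate_expression(
        cfg, genes, rng, truth)
    return SimulatedBundle(
        cfg=cfg, true_map=true_map, maps=maps, qtls=qtls, genes=genes,
        anchors=anchors, go_table=go_table, chrom_lengths=chrom_lengths,
        fpkm=fpkm, samples=samples, atlas_calls=atlas, biomarkers=biomarkers,
        all_genotype_de=de_list, truth=truth,
    )


def write_gff(genes: list[GeneModel], chrom_lengths: dict[str, int],
              path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(chrom_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start_bp)):
            attrs = f"ID={g.gene_id};Note={g.annotation}"
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start_bp}\t{g.end_bp}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


def write_bundle(bundle: SimulatedBundle, out_dir) -> Path:
    """Serialize a bundle to the pipeline's on-disk input layout."""
    from . import io as mio

    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    for gmap in bundle.maps:
        mio.write_genetic_map(gmap, out / "maps" / f"{gmap.map_id}.tsv")
    mio.write_genetic_map(bundle.true_map, out / "true_map.tsv")
    mio.write_qtl_table(bundle.qtls, out / "qtls.tsv")
    syn = pd.DataFrame(
        [{"variant": v, "canonical": c}
         for v, c in bundle.truth.synonym_variants.items()],
        columns=["variant", "canonical"])
    syn.to_csv(out / "synonyms.tsv", sep="\t", index=False)
    bundle.anchors.to_csv(out / "anchors.tsv", sep="\t", index=False)
    write_gff(bundle.genes, bundle.chrom_lengths, out / "genome.gff3")
    bundle.go_table.to_csv(out / "go.tsv", sep="\t", index=False)
    bundle.fpkm.round(4).to_csv(out / "fpkm.tsv", sep="\t",
                                index_label="gene")
    bundle.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    bundle.atlas_calls.astype(int).to_csv(out / "atlas_calls.tsv", sep="\t",
                                          index_label="gene")
    (out / "biomarkers.txt").write_text("\n".join(bundle.biomarkers) + "\n")
    (out / "all_genotype_de.txt").write_text(
        "\n".join(bundle.all_genotype_de) + "\n")
    (out / "chrom_lengths.tsv").write_text(
        "chrom\tlength\n" + "".join(f"{c}\t{n}\n" for c, n
                                    in sorted(bundle.chrom_lengths.items())))
    (out / "ground_truth.json").write_text(bundle.truth.to_json())
    return out


# ------------------------------------------------- recovery experiment


def sample_observations(mu: list[float], n_qtls: int,
                        sd_range: tuple[float, float],
                        rng: np.random.Generator) -> list:
    """Observations straight from the mixture observation model (no maps)."""
    from .meta import QTLObservation

    obs = []
    per = n_qtls // len(mu)
    rem = n_qtls - per * len(mu)
    for k, m in enumerate(mu):
        for i in range(per + (1 if k < rem else 0)):
            sigma = float(rng.uniform(*sd_range))
            obs.append(QTLObservation(
                qtl_id=f"o{k}.{i}", x=float(rng.normal(m, sigma)),
                sigma=sigma, r2=0.1, study_ref=f"study{i % 3}"))
    return obs


def recovery_experiment(mu: tuple[float, ...] = (20.0, 50.0, 80.0),
                        n_qtls: int = 12,
                        sd_range: tuple[float, float] = (1.5, 4.0),
                        n_seeds: int = 100, k_max: int = 10,
                        restarts: int = 10,
                        seed: int = 17) -> dict[str, float]:
    """Repeatedly sample the stated layout and score model selection.

    Returns the fraction of runs selecting the true K and the median
    absolute error of the recovered means (each matched to its nearest
    true locus).
    """
    from .meta import em_fit, model_criteria, select_model

    hits = 0
    errors: list[float] = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 * s)
        obs = sample_observations(list(mu), n_qtls, sd_range, rng)
        fits = []
        for K in range(1, min(len(obs), k_max) + 1):
            fit = em_fit(obs, K, restarts=restarts, seed=seed + K)
            model_criteria(fit, obs)
            fits.append(fit)
        best = select_model(fits)
        if best.K == len(mu):
            hits += 1
        for m_hat in best.mu:
            errors.append(min(abs(m_hat - m) for m in mu))
    return {
        "k_correct_fraction": hits / n_seeds,
        "median_abs_mu_error": float(np.median(errors)),
        "n_seeds": n_seeds,
    }
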