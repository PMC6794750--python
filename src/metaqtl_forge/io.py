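"""Readers and writers for the pipeline's tab-delimited interchange formats.

One canonical dialect is used throughout: TSV with a header row, one map per
file.  Genetic maps carry (lg, marker, pos_cm); QTL tables carry the full
QTLRecord column set with empty fields for missing CI or R².  All cM values
are written with two decimals.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .models import (
    AnchorPoint,
    ConsensusMap,
    GeneticMap,
    Marker,
    MetaQTL,
    ProjectedQTL,
    QTLRecord,
    SynonymTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MAP_COLUMNS = ["lg", "marker", "pos_cm"]
QTL_COLUMNS = [
    "qtl_id",
    "trait",
    "trait_category",
    "study_ref",
    "population_size",
    "lg",
    "peak_cm",
    "ci_start_cm",
    "ci_end_cm",
    "r2",
    "map_id",
]


def read_genetic_map(path: PathLike, map_id: Optional[str] = None,
                     study_ref: str = "") -> GeneticMap:
    """Read a component genetic map from a (lg, marker, pos_cm) TSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"lg": str, "marker": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"{path}: cannot parse map file: {exc}") from exc
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    groups: dict[str, list[Marker]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = float(row.pos_cm)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}:{i}: unparseable position {row.pos_cm!r}"
            ) from exc
        try:
            marker = Marker(name=str(row.marker), lg=str(row.lg), pos_cm=pos)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{i}: {exc}") from exc
        groups.setdefault(marker.lg, []).append(marker)
    return GeneticMap(map_id=map_id or path.stem, study_ref=study_ref,
                      groups=groups)


def write_genetic_map(gmap: GeneticMap, path: PathLike) -> None:
    rows = [
        {"lg": lg, "marker": m.name, "pos_cm": round(m.pos_cm, 2)}
        for lg in gmap.groups
        for m in gmap.groups[lg]
    ]
    pd.DataFrame(rows, columns=MAP_COLUMNS).to_csv(path, sep="\t", index=False,
                                                   float_format="%.2f")


def read_synonym_table(path: PathLike) -> SynonymTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("variant", "canonical"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return SynonymTable(dict(zip(df["variant"], df["canonical"])))


def normalize_marker_names(gmap: GeneticMap, syn: SynonymTable) -> GeneticMap:
    """Replace each marker name by its canonical spelling.

    Raises if normalization collapses two distinct markers of one linkage
    group onto the same canonical name: that indicates either a bad synonym
    table or a genuinely duplicated marker.
    """
    groups: dict[str, list[Marker]] = {}
    n_replaced = 0
    for lg, markers in gmap.groups.items():
        new = []
        for m in markers:
            canon = syn.canonical(m.name)
            if canon != m.name:
                n_replaced += 1
            new.append(Marker(name=canon, lg=lg, pos_cm=m.pos_cm))
        names = [m.name for m in new]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ValidationError(
                f"map {gmap.map_id!r} LG {lg!r}: normalization collides on {dupes}"
            )
        groups[lg] = new
    if n_replaced:
        logger.info("map %s: %d marker names normalized", gmap.map_id, n_replaced)
    return GeneticMap(map_id=gmap.map_id, study_ref=gmap.study_ref, groups=groups)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_qtl_table(path: PathLike) -> list[QTLRecord]:
    """Read QTL observations; empty CI / R² fields become ``None``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"lg": str, "qtl_id": str})
    missing = [c for c in QTL_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            rec = QTLRecord(
                qtl_id=str(row["qtl_id"]),
                trait=str(row["trait"]),
                trait_category=str(row["trait_category"]),
                study_ref=str(row["study_ref"]),
                population_size=int(row["population_size"]),
                lg=str(row["lg"]),
                peak_cm=float(row["peak_cm"]),
                ci_start_cm=_opt_float(row.get("ci_start_cm")),
                ci_end_cm=_opt_float(row.get("ci_end_cm")),
                r2=_opt_float(row.get("r2")),
                map_id=(str(row["map_id"]) if "map_id" in df.columns
                        and not pd.isna(row["map_id"]) else None),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
        records.append(rec)
    n_no_ci = sum(not r.has_ci for r in records)
    if n_no_ci:
        logger.info("%s: %d/%d QTLs lack a CI (flagged for estimation)",
                    path, n_no_ci, len(records))
    return records


def write_qtl_table(records: list[QTLRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "qtl_id": r.qtl_id,
                "trait": r.trait,
                "trait_category": r.trait_category,
                "study_ref": r.study_ref,
                "population_size": r.population_size,
                "lg": r.lg,
                "peak_cm": round(r.peak_cm, 2),
                "ci_start_cm": None if r.ci_start_cm is None else round(r.ci_start_cm, 2),
                "ci_end_cm": None if r.ci_end_cm is None else round(r.ci_end_cm, 2),
                "r2": r.r2,
                "map_id": r.map_id,
            }
        )
    pd.DataFrame(rows, columns=QTL_COLUMNS).to_csv(path, sep="\t", index=False)


def write_consensus_map(cmap: ConsensusMap, path: PathLike) -> None:
    rows = [
        {
            "lg": lg,
            "marker": m.name,
            "pos_cm": round(m.pos_cm, 2),
            "n_maps": m.n_maps,
            "shared_flag": int(m.shared),
        }
        for lg in cmap.groups
        for m in cmap.groups[lg]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.2f")


def read_consensus_map(path: PathLike) -> ConsensusMap:
    from .models import ConsensusMarker

    df = pd.read_csv(path, sep="\t", dtype={"lg": str, "marker": str})
    groups: dict[str, list] = {}
    for row in df.itertuples(index=False):
        prov = [("?", float(row.pos_cm))] * int(row.n_maps)
        groups.setdefault(str(row.lg), []).append(
            ConsensusMarker(name=str(row.marker), pos_cm=float(row.pos_cm),
                            provenance=prov)
        )
    for lg in groups:
        groups[lg].sort(key=lambda m: m.pos_cm)
    return ConsensusMap(groups=groups)


def write_projected_qtls(projected: list[ProjectedQTL], path: PathLike) -> None:
    rows = []
    for p in projected:
        r = p.record
        rows.append(
            {
                "qtl_id": r.qtl_id,
                "trait": r.trait,
                "trait_category": r.trait_category,
                "study_ref": r.study_ref,
                "lg": r.lg,
                "peak_cm": None if p.peak_cm is None else round(p.peak_cm, 2),
                "ci_start_cm": None if p.ci_start_cm is None else round(p.ci_start_cm, 2),
                "ci_end_cm": None if p.ci_end_cm is None else round(p.ci_end_cm, 2),
                "r2": r.r2,
                "status": p.status,
                "reason": p.reason,
                "scale_factor": p.scale_factor,
                "extrapolated": p.extrapolated,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_metaqtls(metaqtls: list[MetaQTL], path: PathLike) -> None:
    rows = []
    for m in metaqtls:
        rows.append(
            {
                "name": m.name,
                "lg": m.lg,
                "peak_cm": round(m.peak_cm, 2),
                "mean_r2": None if m.mean_r2 is None else round(m.mean_r2, 2),
                "start_cm": round(m.ci_start_cm, 2),
                "end_cm": round(m.ci_end_cm, 2),
                "start_bp": m.start_bp,
                "end_bp": m.end_bp,
                "member_qtl_ids": ",".join(m.member_ids),
                "n_original_qtls": m.n_members,
                "n_studies": m.n_studies,
                "traits": ",".join(m.traits),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_anchor_table(path: PathLike) -> pd.DataFrame:
    """Read a marker anchor table (marker, lg, chrom, bp, n_hits)."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "lg": str, "chrom": str})
    missing = [c for c in ("marker", "lg", "chrom", "bp", "n_hits")
               if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def write_anchor_points(anchors: list[AnchorPoint], path: PathLike) -> None:
    rows = [
        {"marker": a.marker, "lg": a.lg, "pos_cm": round(a.pos_cm, 2),
         "chrom": a.chrom, "bp": a.pos_bp}
        for a in anchors
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.2f")
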