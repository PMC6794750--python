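"""Anchoring the consensus map to a genome assembly.

Markers with a unique, congruent physical position tie the genetic (cM) and
physical (bp) coordinate systems together.  Markers hitting the assembly
more than once, hitting a chromosome other than their linkage group's, or
breaking the cM/bp monotone relation are excluded; cM intervals are then
converted to bp by piecewise-linear interpolation between flanking anchors
and candidate genes are pulled from the GFF3 annotation by closed-interval
overlap.
"""

from __future__ import annotations

import logging
from itertools import combinations
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .models import AnchorPoint, ConsensusMap, GeneModel, MetaQTL

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _majority_chrom(df: pd.DataFrame) -> dict[str, str]:
    """Default LG -> chromosome assignment: majority vote of unique hits."""
    single = df[df["n_hits"] == 1]
    out: dict[str, str] = {}
    for lg, sub in single.groupby("lg"):
        out[str(lg)] = sub["chrom"].mode().iloc[0]
    return out


def _discordant_counts(cm: np.ndarray, bp: np.ndarray) -> np.ndarray:
    """Per-anchor count of marker pairs violating strict monotonicity."""
    n = len(cm)
    counts = np.zeros(n, dtype=int)
    for i, j in combinations(range(n), 2):
        if (cm[j] - cm[i]) * (bp[j] - bp[i]) <= 0:
            counts[i] += 1
            counts[j] += 1
    return counts


def build_anchor_set(hits: pd.DataFrame, consensus: ConsensusMap,
                     lg_to_chrom: Optional[dict[str, str]] = None
                     ) -> tuple[list[AnchorPoint], dict[str, str], list[str]]:
    """Filter in-silico mapping hits down to a congruent anchor set.

    ``hits`` columns: marker, lg, chrom, bp, n_hits.  Returns the retained
    anchors, an exclusion report (marker -> reason) and the list of linkage
    groups left with fewer than two anchors (un-anchorable).

    Incongruent anchors are removed greedily: at each step the anchor
    involved in the most order violations is dropped, until the retained
    set is strictly monotone in (cM, bp).
    """
    if lg_to_chrom is None:
        lg_to_chrom = _majority_chrom(hits)
    excluded: dict[str, str] = {}
    per_lg: dict[str, list[AnchorPoint]] = {}
    for row in hits.itertuples(index=False):
        marker, lg = str(row.marker), str(row.lg)
        cons_pos = consensus.positions(lg)
        if marker not in cons_pos:
            excluded[marker] = "not on consensus"
            continue
        if int(row.n_hits) != 1:
            excluded[marker] = "not unique"
            continue
        if lg_to_chrom.get(lg) is not None and str(row.chrom) != lg_to_chrom[lg]:
            excluded[marker] = "wrong chromosome"
            continue
        per_lg.setdefault(lg, []).append(
            AnchorPoint(marker=marker, lg=lg, pos_cm=cons_pos[marker],
                        chrom=str(row.chrom), pos_bp=int(row.bp))
        )

    retained: list[AnchorPoint] = []
    unanchorable: list[str] = []
    for lg in sorted(per_lg):
        anchors = sorted(per_lg[lg], key=lambda a: (a.pos_cm, a.marker))
        cm = np.array([a.pos_cm for a in anchors])
        bp = np.array([a.pos_bp for a in anchors], dtype=float)
        # orient: the physical axis may run against the genetic axis
        if len(anchors) >= 2 and len(set(cm)) > 1 and len(set(bp)) > 1:
            rho = stats.spearmanr(cm, bp).statistic
            if rho < 0:
                bp = -bp
        while len(anchors) >= 2:
            counts = _discordant_counts(cm, bp)
            if counts.max() == 0:
                break
            worst = int(np.argmax(counts))  # ties -> first (lowest cM)
            excluded[anchors[worst].marker] = "incongruent position"
            del anchors[worst]
            cm = np.delete(cm, worst)
            bp = np.delete(bp, worst)
        if len(anchors) < 2:
            unanchorable.append(lg)
            for a in anchors:
                excluded.setdefault(a.marker, "lg un-anchorable")
            continue
        retained.extend(anchors)
    if excluded:
        logger.info("anchor filtering excluded %d markers", len(excluded))
    return retained, excluded, unanchorable


def cm_to_bp(anchors: list[AnchorPoint], lg: str,
             interval_cm: tuple[float, float],
             chrom_length: Optional[int] = None) -> tuple[int, int]:
    """Convert a cM interval on one LG to a bp interval via its anchors.

    Endpoints are linearly interpolated between flanking anchors; endpoints
    outside the anchored span extrapolate the terminal anchor segment.
    Results are clamped to [1, chrom_length] and swapped if needed so that
    start <= end.
    """
    pts = sorted((a for a in anchors if a.lg == lg), key=lambda a: a.pos_cm)
    if len(pts) < 2:
        raise ValueError(f"LG {lg!r}: fewer than two anchors; cannot convert")
    cm = np.array([a.pos_cm for a in pts])
    bp = np.array([a.pos_bp for a in pts], dtype=float)
    out = []
    for x in interval_cm:
        if x <= cm[0]:
            slope = (bp[1] - bp[0]) / (cm[1] - cm[0])
            v = bp[0] + slope * (x - cm[0])
        elif x >= cm[-1]:
            slope = (bp[-1] - bp[-2]) / (cm[-1] - cm[-2])
            v = bp[-1] + slope * (x - cm[-1])
        else:
            v = float(np.interp(x, cm, bp))
        out.append(v)
    lo, hi = sorted(out)
    lo = max(1, int(round(lo)))
    hi = max(1, int(round(hi)))
    if chrom_length is not None:
        lo = min(lo, chrom_length)
        hi = min(hi, chrom_length)
    return lo, hi


def read_gff_genes(path: PathLike, feature_type: str = "gene"
                   ) -> list[GeneModel]:
    """Load gene models from a GFF3 file (1-based inclusive coordinates)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        note = ""
        for key in ("Note", "description", "product", "Name"):
            if key in feat.attributes:
                note = feat.attributes[key][0]
                break
        genes.append(
            GeneModel(gene_id=gene_id, chrom=feat.seqid, start_bp=feat.start,
                      end_bp=feat.end, strand=feat.strand or "+",
                      annotation=note)
        )
    return genes


def genes_in_interval(genes: list[GeneModel], chrom: str,
                      interval_bp: tuple[int, int]) -> list[GeneModel]:
    """Genes with any closed-interval bp overlap with the query, by start."""
    known = {g.chrom for g in genes}
    if chrom not in known:
        raise KeyError(f"unknown chromosome {chrom!r}; known: {sorted(known)}")
    start, end = min(interval_bp), max(interval_bp)
    hits = [
        g for g in genes
        if g.chrom == chrom and g.start_bp <= end and start <= g.end_bp
    ]
    return sorted(hits, key=lambda g: g.start_bp)


def anchor_metaqtls(metaqtls: list[MetaQTL], anchors: list[AnchorPoint],
                    chrom_lengths: Optional[dict[str, int]] = None
                    ) -> list[MetaQTL]:
    """Fill each meta-QTL's physical interval in place (skips un-anchorable LGs)."""
    by_lg: dict[str, list[AnchorPoint]] = {}
    for a in anchors:
        by_lg.setdefault(a.lg, []).append(a)
    for m in metaqtls:
        pts = by_lg.get(m.lg, [])
        if len(pts) < 2:
            logger.warning("meta-QTL %s: LG %s un-anchorable", m.name, m.lg)
            continue
        chrom = pts[0].chrom
        length = chrom_lengths.get(chrom) if chrom_lengths else None
        m.chrom = chrom
        m.start_bp, m.end_bp = cm_to_bp(pts, m.lg,
                                        (m.ci_start_cm, m.ci_end_cm), length)
    return metaqtls


def write_bed(metaqtls: list[MetaQTL], path: PathLike) -> None:
    """Write anchored meta-QTL intervals as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for m in metaqtls:
            if m.chrom is None:
                continue
            fh.write(f"{m.chrom}\t{m.start_bp - 1}\t{m.end_bp}\t{m.name}\n")
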