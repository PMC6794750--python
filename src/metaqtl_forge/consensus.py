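"""Consensus genetic map construction from component linkage maps.

Component maps (one per study) share subsets of transferable markers.  Each
linkage group is oriented against a reference map, groups that cannot be
connected are dropped, marker-order conflicts between map pairs are resolved
by removing the least-represented marker, and the surviving maps are merged
onto a common cM frame by monotone piecewise-linear calibration through
shared markers.  The consensus position of a marker is the arithmetic mean
of its calibrated positions over the maps that contain it.

The original consensus software's internal objective is unpublished; the
procedure here is a deterministic, testable merge that targets order-level
agreement with the component maps rather than equivalence with any
particular tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .models import ConsensusMap, ConsensusMarker, GeneticMap, Marker

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrderConflict:
    """Two markers whose relative order disagrees between a pair of maps."""

    map_a: str
    map_b: str
    lg: str
    marker_1: str
    marker_2: str
    occurrences: tuple[int, int]  # marker occurrence counts across all maps


def shared_marker_names(a: GeneticMap, b: GeneticMap, lg: str) -> list[str]:
    pos_a, pos_b = a.positions(lg), b.positions(lg)
    return [m.name for m in a.markers(lg) if m.name in pos_b]


def orient_groups(component: GeneticMap, reference: GeneticMap
                  ) -> tuple[GeneticMap, list[str]]:
    """Flip linkage groups whose marker order is reversed vs the reference.

    A group is flipped (pos -> max - pos) iff the Spearman rank correlation
    of shared-marker positions is negative.  Groups sharing fewer than two
    markers with the reference cannot be oriented and are reported.
    """
    groups: dict[str, list[Marker]] = {}
    unorientable: list[str] = []
    for lg, markers in component.groups.items():
        ref_pos = reference.positions(lg)
        shared = [m for m in markers if m.name in ref_pos]
        if len(shared) < 2:
            unorientable.append(lg)
            groups[lg] = list(markers)
            continue
        comp_vals = [m.pos_cm for m in shared]
        ref_vals = [ref_pos[m.name] for m in shared]
        if len(set(comp_vals)) < 2 or len(set(ref_vals)) < 2:
            groups[lg] = list(markers)
            continue
        rho = stats.spearmanr(comp_vals, ref_vals).statistic
        if rho < 0:
            top = max(m.pos_cm for m in markers)
            groups[lg] = [Marker(m.name, lg, top - m.pos_cm) for m in markers]
        else:
            groups[lg] = list(markers)
    return (
        GeneticMap(map_id=component.map_id, study_ref=component.study_ref,
                   groups=groups),
        unorientable,
    )


def drop_unlinked_groups(maps: list[GeneticMap]
                         ) -> tuple[list[GeneticMap], list[tuple[str, str]]]:
    """Remove linkage groups sharing <2 markers with the other maps' groups.

    Such groups cannot be oriented or calibrated.  Returns the filtered maps
    and a (map_id, lg) report of removals.
    """
    removed: list[tuple[str, str]] = []
    out: list[GeneticMap] = []
    for gmap in maps:
        kept: dict[str, list[Marker]] = {}
        for lg, markers in gmap.groups.items():
            others = {
                m.name
                for other in maps
                if other.map_id != gmap.map_id
                for m in other.markers(lg)
            }
            n_shared = sum(m.name in others for m in markers)
            if n_shared >= 2:
                kept[lg] = markers
            else:
                removed.append((gmap.map_id, lg))
        out.append(GeneticMap(map_id=gmap.map_id, study_ref=gmap.study_ref,
                              groups=kept))
    if removed:
        logger.info("dropped %d unlinked linkage groups: %s", len(removed), removed)
    return out, removed


def _occurrence_counts(maps: Iterable[GeneticMap], lg: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for gmap in maps:
        for m in gmap.markers(lg):
            counts[m.name] = counts.get(m.name, 0) + 1
    return counts


def detect_order_conflicts(maps: list[GeneticMap], lg: str) -> list[OrderConflict]:
    """Enumerate marker pairs whose relative order differs between two maps.

    Maps must already be oriented.  Pairs at identical positions in one map
    (ties) never conflict.
    """
    counts = _occurrence_counts(maps, lg)
    conflicts: list[OrderConflict] = []
    for a, b in combinations(maps, 2):
        pos_a, pos_b = a.positions(lg), b.positions(lg)
        common = sorted(set(pos_a) & set(pos_b))
        for m1, m2 in combinations(common, 2):
            da = pos_a[m1] - pos_a[m2]
            db = pos_b[m1] - pos_b[m2]
            if da * db < 0:
                m_lo, m_hi = sorted((m1, m2))
                conflicts.append(
                    OrderConflict(a.map_id, b.map_id, lg, m_lo, m_hi,
                                  (counts[m_lo], counts[m_hi]))
                )
    return conflicts


def resolve_inversions(maps: list[GeneticMap], lg: str
                       ) -> tuple[list[GeneticMap], list[str]]:
    """Iteratively drop the least-represented conflicting marker until the
    group is conflict-free.

    At each round the marker involved in at least one conflict with the
    lowest occurrence count across all maps is removed from every map
    (ties broken by name for determinism).  Terminates because each round
    removes one marker.
    """
    maps = [GeneticMap(g.map_id, g.study_ref, dict(g.groups)) for g in maps]
    removed: list[str] = []
    while True:
        conflicts = detect_order_conflicts(maps, lg)
        if not conflicts:
            break
        counts = _occurrence_counts(maps, lg)
        involved = {c.marker_1 for c in conflicts} | {c.marker_2 for c in conflicts}
        victim = min(involved, key=lambda name: (counts[name], name))
        removed.append(victim)
        for gmap in maps:
            if lg in gmap.groups:
                gmap.groups[lg] = [m for m in gmap.groups[lg] if m.name != victim]
    if removed:
        logger.info("LG %s: removed %d conflicting markers: %s", lg,
                    len(removed), removed)
    return maps, removed


def _piecewise_linear(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with terminal-segment linear extrapolation."""
    x = np.asarray(x, dtype=float)
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        lo = x < xp[0]
        hi = x > xp[-1]
        slope_lo = (fp[1] - fp[0]) / (xp[1] - xp[0])
        slope_hi = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(lo, fp[0] + slope_lo * (x - xp[0]), y)
        y = np.where(hi, fp[-1] + slope_hi * (x - xp[-1]), y)
    return y


def _monotone_shared_points(source: dict[str, float],
                            target: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Shared markers as strictly increasing (source, target) breakpoints."""
    names = sorted(set(source) & set(target), key=lambda n: (source[n], n))
    xs: list[float] = []
    ys: list[float] = []
    for n in names:
        if xs and (source[n] <= xs[-1] or target[n] <= ys[-1]):
            continue
        xs.append(source[n])
        ys.append(target[n])
    return np.array(xs), np.array(ys)


def build_consensus_group(maps: list[GeneticMap], lg: str) -> list[ConsensusMarker]:
    """Merge one linkage group across conflict-free component maps.

    The map with the most markers on the group is the initial frame; the
    remaining maps are merged in decreasing order of markers shared with the
    current consensus, calibrating each via monotone piecewise-linear
    interpolation through shared markers (terminal-slope extrapolation
    outside the shared span).  Consensus positions are refreshed after each
    merge as the mean of calibrated positions, then shifted so the first
    marker sits at 0 cM.
    """
    present = [g for g in maps if g.n_markers(lg) > 0]
    if not present:
        return []
    frame = max(present, key=lambda g: (g.n_markers(lg), g.map_id))
    # frame ties resolved to lexicographically smallest id among the largest
    top_n = frame.n_markers(lg)
    frame = min((g for g in present if g.n_markers(lg) == top_n),
                key=lambda g: g.map_id)

    calibrated: dict[str, dict[str, float]] = {
        frame.map_id: dict(frame.positions(lg))
    }

    def consensus_positions() -> dict[str, float]:
        acc: dict[str, list[float]] = {}
        for posmap in calibrated.values():
            for name, p in posmap.items():
                acc.setdefault(name, []).append(p)
        return {name: float(np.mean(v)) for name, v in acc.items()}

    pending = [g for g in present if g.map_id != frame.map_id]
    while pending:
        cons = consensus_positions()
        pending.sort(
            key=lambda g: (-sum(m.name in cons for m in g.markers(lg)), g.map_id)
        )
        nxt = pending.pop(0)
        source = nxt.positions(lg)
        xs, ys = _monotone_shared_points(source, cons)
        if len(xs) < 2:
            raise ValueError(
                f"LG {lg}: map {nxt.map_id!r} shares <2 usable markers with the "
                f"consensus frame (disconnected marker graph)"
            )
        names = list(source)
        vals = _piecewise_linear(np.array([source[n] for n in names]), xs, ys)
        calibrated[nxt.map_id] = dict(zip(names, (float(v) for v in vals)))

    cons = consensus_positions()
    provenance: dict[str, list[tuple[str, float]]] = {name: [] for name in cons}
    for gmap in present:
        src = gmap.positions(lg)
        for name in src:
            provenance[name].append((gmap.map_id, src[name]))
    offset = min(cons.values())
    markers = [
        ConsensusMarker(name=name, pos_cm=cons[name] - offset,
                        provenance=sorted(provenance[name]))
        for name in cons
    ]
    markers.sort(key=lambda m: (m.pos_cm, -m.n_maps, m.name))
    return markers


def build_consensus(maps: list[GeneticMap],
                    lgs: Optional[list[str]] = None) -> ConsensusMap:
    """Build the full consensus map, one linkage group at a time."""
    if lgs is None:
        lgs = sorted({lg for g in maps for lg in g.lgs},
                     key=lambda s: (len(s), s))
    groups = {}
    for lg in lgs:
        group = build_consensus_group(maps, lg)
        if group:
            groups[lg] = group
    return ConsensusMap(groups=groups)


def map_order_correlation(component: GeneticMap, consensus: ConsensusMap
                          ) -> dict[str, Optional[tuple[float, int]]]:
    """Spearman rank correlation of marker order, per LG and overall.

    Returns ``{lg: (rho, n_shared) | None}`` plus an ``"overall"`` entry
    (shared-marker-count weighted mean of defined per-LG values).  Groups
    with fewer than three shared markers are reported as undefined.
    """
    out: dict[str, Optional[tuple[float, int]]] = {}
    weighted: list[tuple[float, int]] = []
    for lg in component.lgs:
        cons_pos = consensus.positions(lg)
        shared = [m for m in component.markers(lg) if m.name in cons_pos]
        if len(shared) < 3:
            out[lg] = None
            continue
        rho = stats.spearmanr(
            [m.pos_cm for m in shared], [cons_pos[m.name] for m in shared]
        ).statistic
        out[lg] = (float(rho), len(shared))
        weighted.append((float(rho), len(shared)))
    if weighted:
        total = sum(n for _, n in weighted)
        out["overall"] = (
            sum(r * n for r, n in weighted) / total,
            total,
        )
    else:
        out["overall"] = None
    return out
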