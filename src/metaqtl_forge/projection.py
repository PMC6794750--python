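"""Homothetic projection of QTLs from component maps onto the consensus.

A QTL is moved between maps by locating the closest pair of markers shared
by the source and consensus maps that brackets its peak, and applying the
linear scaling f(x) = b_L + s * (x - a_L) with s = (b_R - b_L)/(a_R - a_L),
where a/b are source/consensus flank positions.  Projections that would
shrink the coordinate frame by more than a factor of four (s < 0.25 by
default) are rejected, as are QTLs on groups without at least two shared
anchoring markers.

QTLs published without a confidence interval get the standard population
size based fallback CI95 = 530 / (N * R²) cM before projection; if R² is
also missing the peak alone is projected and the record is flagged so the
meta-analysis can exclude it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .models import ConsensusMap, GeneticMap, ProjectedQTL, QTLRecord

logger = logging.getLogger(__name__)

#: Minimum allowed contraction factor for a projection (rejection threshold).
MIN_SCALE = 0.25


def estimate_ci(qtl: QTLRecord, width_constant: float = 530.0
                ) -> Optional[QTLRecord]:
    """Fill a missing CI from population size and R².

    Uses the empirical relation CI95 = k / (N * R²) cM with k = 530 for a
    biparental population, centred on the reported peak.  Returns ``None``
    when R² is missing, since the relation is then inapplicable.
    """
    if qtl.has_ci:
        return qtl
    if qtl.r2 is None or qtl.r2 == 0:
        return None
    width = width_constant / (qtl.population_size * qtl.r2)
    return QTLRecord(
        qtl_id=qtl.qtl_id,
        trait=qtl.trait,
        trait_category=qtl.trait_category,
        study_ref=qtl.study_ref,
        population_size=qtl.population_size,
        lg=qtl.lg,
        peak_cm=qtl.peak_cm,
        ci_start_cm=max(0.0, qtl.peak_cm - width / 2),
        ci_end_cm=qtl.peak_cm + width / 2,
        r2=qtl.r2,
        map_id=qtl.map_id,
    )


@dataclass
class FlankPair:
    """Shared markers bracketing (or nearest to) a QTL peak on its source map."""

    left: str
    right: str
    a_left: float
    a_right: float
    b_left: float
    b_right: float
    extrapolated: bool = False


def find_flanking_shared_markers(qtl: QTLRecord, source: GeneticMap,
                                 consensus: ConsensusMap) -> Optional[FlankPair]:
    """Locate the closest shared marker pair bracketing the QTL peak.

    Among shared markers with distinct source positions, the bracketing pair
    minimizing a_R - a_L is chosen.  If the peak lies outside the shared
    span, the two nearest shared markers on the near side form an
    extrapolation pair.  Returns ``None`` when fewer than two usable shared
    markers exist on the linkage group.
    """
    src = source.positions(qtl.lg)
    cons = consensus.positions(qtl.lg)
    shared = sorted((src[n], n) for n in src if n in cons)
    # collapse source-position ties: keep first name at each position
    distinct: list[tuple[float, str]] = []
    for pos, name in shared:
        if not distinct or pos > distinct[-1][0]:
            distinct.append((pos, name))
    if len(distinct) < 2:
        return None
    x = qtl.peak_cm
    best: Optional[tuple[float, int]] = None
    for i in range(len(distinct) - 1):
        a_l, a_r = distinct[i][0], distinct[i + 1][0]
        if a_l <= x <= a_r:
            width = a_r - a_l
            if best is None or width < best[0]:
                best = (width, i)
    if best is not None:
        i = best[1]
        (a_l, left), (a_r, right) = distinct[i], distinct[i + 1]
        extrapolated = False
    elif x < distinct[0][0]:
        (a_l, left), (a_r, right) = distinct[0], distinct[1]
        extrapolated = True
    else:
        (a_l, left), (a_r, right) = distinct[-2], distinct[-1]
        extrapolated = True
    return FlankPair(left=left, right=right, a_left=a_l, a_right=a_r,
                     b_left=cons[left], b_right=cons[right],
                     extrapolated=extrapolated)


def project_qtl(qtl: QTLRecord, flanks: FlankPair,
                min_scale: float = MIN_SCALE,
                max_scale: Optional[float] = None) -> ProjectedQTL:
    """Apply the homothetic scaling rule to one QTL given its flank pair."""
    span = flanks.a_right - flanks.a_left
    if span <= 0:
        return ProjectedQTL(record=qtl, status="rejected",
                            reason="degenerate flanks")
    s = (flanks.b_right - flanks.b_left) / span
    if s <= 0:
        return ProjectedQTL(record=qtl, status="rejected",
                            reason="degenerate flanks",
                            scale_factor=s,
                            flank_markers=(flanks.left, flanks.right))
    if s < min_scale or (max_scale is not None and s > max_scale):
        return ProjectedQTL(record=qtl, status="rejected", reason="scale",
                            scale_factor=s,
                            flank_markers=(flanks.left, flanks.right))

    def f(x: float) -> float:
        return flanks.b_left + s * (x - flanks.a_left)

    return ProjectedQTL(
        record=qtl,
        status="projected",
        peak_cm=f(qtl.peak_cm),
        ci_start_cm=None if qtl.ci_start_cm is None else f(qtl.ci_start_cm),
        ci_end_cm=None if qtl.ci_end_cm is None else f(qtl.ci_end_cm),
        scale_factor=s,
        flank_markers=(flanks.left, flanks.right),
        extrapolated=flanks.extrapolated,
    )


@dataclass
class ProjectionReport:
    """Bookkeeping for a batch projection run."""

    n_total: int = 0
    n_projected: int = 0
    rejections: dict[str, int] = field(default_factory=dict)
    per_trait: dict[str, tuple[int, int]] = field(default_factory=dict)
    per_category: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def projected_fraction(self) -> float:
        return self.n_projected / self.n_total if self.n_total else 0.0


def project_all(qtls: list[QTLRecord], maps: dict[str, GeneticMap],
                consensus: ConsensusMap, min_scale: float = MIN_SCALE,
                max_scale: Optional[float] = None,
                ci_width_constant: float = 530.0
                ) -> tuple[list[ProjectedQTL], ProjectionReport]:
    """Project every QTL, producing exactly one projected-or-rejected record each."""
    out: list[ProjectedQTL] = []
    report = ProjectionReport(n_total=len(qtls))
    for qtl in qtls:
        if qtl.map_id is None or qtl.map_id not in maps:
            raise KeyError(
                f"QTL {qtl.qtl_id!r} references unknown map {qtl.map_id!r}"
            )
        source = maps[qtl.map_id]
        work = qtl
        if not qtl.has_ci:
            est = estimate_ci(qtl, ci_width_constant)
            if est is None:
                logger.warning(
                    "QTL %s: no CI and no R²; projecting peak only "
                    "(excluded from meta-analysis)", qtl.qtl_id)
            else:
                work = est
        flanks = find_flanking_shared_markers(work, source, consensus)
        if flanks is None:
            proj = ProjectedQTL(record=work, status="rejected",
                                reason="no anchoring markers")
        else:
            proj = project_qtl(work, flanks, min_scale=min_scale,
                               max_scale=max_scale)
        out.append(proj)
        ok = int(proj.projected)
        report.n_projected += ok
        if not ok:
            report.rejections[proj.reason] = report.rejections.get(proj.reason, 0) + 1
        for key, table in ((qtl.trait, report.per_trait),
                           (qtl.trait_category, report.per_category)):
            done, tot = table.get(key, (0, 0))
            table[key] = (done + ok, tot + 1)
    logger.info("projected %d/%d QTLs (%.0f%%); rejections: %s",
                report.n_projected, report.n_total,
                100 * report.projected_fraction, report.rejections)
    return out, report
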