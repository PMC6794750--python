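"""Redundancy pruning, co-location clustering and co-localization testing.

QTLs repeatedly reported by one study over an overlapping region would
inflate a meta-analysis; such same-study overlaps are pruned down to the
highest-R² representative.  Co-located QTLs (within one trait or across
traits) are grouped by single-linkage clustering of their confidence
intervals, with shared endpoints counting as overlap.  Whether two traits
co-localize more than chance is tested on a binned consensus map with a
Yates-corrected chi-square, or by a circular-shift permutation null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .models import ProjectedQTL

# closed-interval overlap: touching endpoints count


def intervals_overlap(a_start: float, a_end: float,
                      b_start: float, b_end: float) -> bool:
    return a_start <= b_end and b_start <= a_end


def _qtl_overlaps(a: ProjectedQTL, b: ProjectedQTL) -> bool:
    if a.ci_start_cm is None or b.ci_start_cm is None:
        return False
    return intervals_overlap(a.ci_start_cm, a.ci_end_cm,
                             b.ci_start_cm, b.ci_end_cm)


def _single_linkage(qtls: list[ProjectedQTL]) -> list[list[ProjectedQTL]]:
    """Cluster intervals by transitive CI overlap (sorted sweep)."""
    with_ci = [q for q in qtls if q.ci_start_cm is not None]
    with_ci.sort(key=lambda q: (q.ci_start_cm, q.ci_end_cm, q.qtl_id))
    clusters: list[list[ProjectedQTL]] = []
    reach = -math.inf
    for q in with_ci:
        if clusters and q.ci_start_cm <= reach:
            clusters[-1].append(q)
            reach = max(reach, q.ci_end_cm)
        else:
            clusters.append([q])
            reach = q.ci_end_cm
    return clusters


def prune_redundant(qtls: list[ProjectedQTL]) -> list[ProjectedQTL]:
    """Collapse same-study overlapping QTLs to the highest-R² member.

    Ties on R² prefer the longer CI, then the first QTL id in input order.
    QTLs without a CI cannot be assessed for overlap and pass through.
    """
    order = {q.qtl_id: i for i, q in enumerate(qtls)}
    kept: list[ProjectedQTL] = [q for q in qtls if q.ci_start_cm is None]
    groups: dict[tuple[str, str], list[ProjectedQTL]] = {}
    for q in qtls:
        if q.ci_start_cm is None:
            continue
        groups.setdefault((q.record.study_ref, q.record.lg), []).append(q)
    for members in groups.values():
        for cluster in _single_linkage(members):
            best = max(
                cluster,
                key=lambda q: (
                    -1.0 if q.record.r2 is None else q.record.r2,
                    q.ci_end_cm - q.ci_start_cm,
                    -order[q.qtl_id],
                ),
            )
            kept.append(best)
    kept.sort(key=lambda q: order[q.qtl_id])
    return kept


@dataclass
class OverlapCluster:
    """A maximal set of QTLs connected through CI overlaps on one LG."""

    cluster_id: str
    lg: str
    traits: list[str]
    member_ids: list[str]
    n_populations: int
    span_start_cm: float
    span_end_cm: float

    @property
    def confirmed(self) -> bool:
        """True when independent populations support the region."""
        return self.n_populations >= 2


def find_colocated(qtls: list[ProjectedQTL],
                   scope: str = "within-trait") -> list[OverlapCluster]:
    """Single-linkage CI-overlap clusters per LG.

    ``scope="within-trait"`` clusters each trait separately;
    ``scope="cross-trait"`` pools all traits on a linkage group.
    """
    if scope not in ("within-trait", "cross-trait"):
        raise ValueError(f"unknown scope {scope!r}")
    usable = [q for q in qtls if q.projected and q.ci_start_cm is not None]
    keys: dict[tuple, list[ProjectedQTL]] = {}
    for q in usable:
        key = (q.record.lg,) if scope == "cross-trait" else (q.record.lg, q.record.trait)
        keys.setdefault(key, []).append(q)
    clusters: list[OverlapCluster] = []
    for key in sorted(keys):
        lg = key[0]
        for members in _single_linkage(keys[key]):
            traits = sorted({q.record.trait for q in members})
            clusters.append(
                OverlapCluster(
                    cluster_id=f"{'+'.join(traits)}_{lg}.{sum(c.lg == lg for c in clusters) + 1}",
                    lg=lg,
                    traits=traits,
                    member_ids=[q.qtl_id for q in members],
                    n_populations=len({q.record.study_ref for q in members}),
                    span_start_cm=min(q.ci_start_cm for q in members),
                    span_end_cm=max(q.ci_end_cm for q in members),
                )
            )
    return clusters


def _bin_coverage(qtls: list[ProjectedQTL], lg: str, n_bins: int,
                  bin_cm: float) -> np.ndarray:
    """Boolean per-bin coverage of one trait's CIs on one LG."""
    covered = np.zeros(n_bins, dtype=bool)
    for q in qtls:
        if q.record.lg != lg or q.ci_start_cm is None:
            continue
        lo = max(0, int(math.floor(q.ci_start_cm / bin_cm)))
        hi = min(n_bins - 1, int(math.floor(q.ci_end_cm / bin_cm)))
        if hi >= lo:
            covered[lo:hi + 1] = True
    return covered


def _coverage_vectors(qtls_a: list[ProjectedQTL], qtls_b: list[ProjectedQTL],
                      lg_lengths: dict[str, float], bin_cm: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    cov_a, cov_b = [], []
    for lg, length in sorted(lg_lengths.items()):
        n_bins = max(1, int(math.ceil(length / bin_cm)))
        cov_a.append(_bin_coverage(qtls_a, lg, n_bins, bin_cm))
        cov_b.append(_bin_coverage(qtls_b, lg, n_bins, bin_cm))
    return np.concatenate(cov_a), np.concatenate(cov_b)


def chi2_colocalization_test(qtls_a: list[ProjectedQTL],
                             qtls_b: list[ProjectedQTL],
                             lg_lengths: dict[str, float],
                             bin_cm: float = 5.0,
                             method: str = "chi2",
                             n_perm: int = 999,
                             seed: int = 0) -> tuple[float, float]:
    """Test whether two traits' QTLs co-occupy map bins more than chance.

    The consensus map is partitioned into ``bin_cm`` bins; each bin is
    scored covered/uncovered by each trait's CIs, giving a 2x2 table
    (both, a only, b only, neither).  ``method="chi2"`` applies a
    Yates-corrected chi-square with 1 df; ``method="permutation"``
    circularly shifts trait-b intervals per LG and reports the empirical
    p-value of the observed jointly-covered bin count.
    """
    if not qtls_a or not qtls_b:
        raise ValueError("both QTL lists must be non-empty")
    a, b = _coverage_vectors(qtls_a, qtls_b, lg_lengths, bin_cm)
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    table = np.array([[n11, n10], [n01, n00]])
    if np.count_nonzero(table) < 2 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        raise ValueError(f"degenerate contingency table {table.tolist()}")
    if method == "chi2":
        res = stats.chi2_contingency(table, correction=True)
        return float(res.statistic), float(res.pvalue)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        shifted = _circular_shift(qtls_b, lg_lengths, rng)
        _, b_perm = _coverage_vectors(qtls_a, shifted, lg_lengths, bin_cm)
        if int(np.sum(a & b_perm)) >= n11:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return float(n11), p


def _circular_shift(qtls: list[ProjectedQTL], lg_lengths: dict[str, float],
                    rng: np.random.Generator) -> list[ProjectedQTL]:
    """Shift each LG's intervals by one random offset, wrapping around."""
    offsets = {lg: rng.uniform(0, length) for lg, length in lg_lengths.items()}
    out: list[ProjectedQTL] = []
    for q in qtls:
        if q.ci_start_cm is None or q.record.lg not in offsets:
            out.append(q)
            continue
        length = lg_lengths[q.record.lg]
        off = offsets[q.record.lg]
        s = (q.ci_start_cm + off) % length
        e = s + (q.ci_end_cm - q.ci_start_cm)
        pieces = [(s, min(e, length))]
        if e > length:
            pieces.append((0.0, e - length))
        for ps, pe in pieces:
            out.append(
                ProjectedQTL(record=q.record, status=q.status,
                             peak_cm=ps, ci_start_cm=ps, ci_end_cm=pe)
            )
    return out
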