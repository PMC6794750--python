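"""Transcriptomic candidate selection and intersection with meta-QTL genes.

The berry ripening onset (veraison) is preceded by a large transcriptomic
rearrangement.  Given a multi-year FPKM time course, the year-specific
onset interval is located as the adjacent pre-veraison time-point pair
across which the most "biomarker" genes change expression; genes modulated
across that interval in at least two years, together with an externally
supplied list of genes differentially expressed across veraison in many
genotypes, form the transcriptomic candidate set.  Intersecting it with
the positional candidates under meta-QTLs, after discarding genes never
expressed in berry, rachis or seed, yields the final prioritized list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .models import CandidateGene, MetaQTL

logger = logging.getLogger(__name__)

#: GO slim accessions flagging regulation of gene expression, signalling
#: or development.
REGULATORY_GO_SLIM = frozenset({
    "GO:0000166", "GO:0003676", "GO:0003677", "GO:0003682", "GO:0003700",
    "GO:0005102", "GO:0005634", "GO:0007154", "GO:0007165", "GO:0007275",
    "GO:0009653", "GO:0009719", "GO:0009791", "GO:0009908", "GO:0016301",
    "GO:0030154", "GO:0038023", "GO:0040007",
})

#: Organs whose expression atlas calls qualify a gene as berry-relevant.
DEFAULT_ORGANS = ("berry", "rachis", "seed")


@dataclass
class ExpressionMatrix:
    """FPKM values (genes x samples) with per-sample time-course metadata.

    ``samples`` columns: sample, year, timepoint_order, days_before_veraison,
    replicate.  Time points are ordered within a year by ``timepoint_order``;
    ``days_before_veraison >= 0`` marks pre-veraison collections.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.samples["sample"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"samples absent from FPKM matrix: {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be nonnegative")

    @property
    def years(self) -> list[int]:
        return sorted(self.samples["year"].unique())

    def timepoints(self, year: int, pre_veraison: bool = False) -> list[int]:
        sub = self.samples[self.samples["year"] == year]
        if pre_veraison:
            sub = sub[sub["days_before_veraison"] >= 0]
        return sorted(sub["timepoint_order"].unique())

    def replicate_values(self, year: int, timepoint: int) -> pd.DataFrame:
        cols = self.samples.loc[
            (self.samples["year"] == year)
            & (self.samples["timepoint_order"] == timepoint),
            "sample",
        ]
        return self.values[list(cols)]

    def mean_fpkm(self, year: int, timepoint: int) -> pd.Series:
        return self.replicate_values(year, timepoint).mean(axis=1)


def read_expression(fpkm_path, samples_path) -> ExpressionMatrix:
    values = pd.read_csv(fpkm_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    return ExpressionMatrix(values=values, samples=samples)


def read_atlas_calls(path) -> pd.DataFrame:
    """Organ-level expressed-call table: gene index x organ boolean columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)


def filter_expressed_atlas(genes: Iterable[str], calls: pd.DataFrame,
                           organs: Iterable[str] = DEFAULT_ORGANS) -> set[str]:
    """Genes with an expressed call in at least one of the given organs.

    Genes missing from the call table are treated as never expressed (with
    a warning), mirroring how absent probes are handled in organ atlases.
    """
    organs = list(organs)
    if not organs:
        raise ValueError("organ set must be non-empty")
    missing_cols = [o for o in organs if o not in calls.columns]
    if missing_cols:
        raise ValueError(f"organs absent from call table: {missing_cols}")
    genes = list(genes)
    unknown = [g for g in genes if g not in calls.index]
    if unknown:
        logger.warning("%d genes missing from atlas calls; treated as "
                       "not expressed", len(unknown))
    known = [g for g in genes if g in calls.index]
    mask = calls.loc[known, organs].any(axis=1)
    return set(mask.index[mask])


def filter_fpkm_expressed(mat: ExpressionMatrix, threshold: float = 1.0,
                          min_reps: int = 2) -> set[str]:
    """Genes expressed somewhere in the time course.

    A gene is retained iff some (year, time point) has at least ``min_reps``
    replicates with FPKM >= ``threshold``; otherwise it is considered never
    expressed.
    """
    retained = pd.Series(False, index=mat.values.index)
    for year in mat.years:
        for tp in mat.timepoints(year):
            reps = mat.replicate_values(year, tp)
            retained |= (reps >= threshold).sum(axis=1) >= min_reps
    return set(retained.index[retained])


def de_across_interval(mat: ExpressionMatrix, gene: str,
                       interval: tuple[int, int], year: int,
                       lfc_threshold: float = 1.0,
                       pseudocount: float = 1.0) -> bool:
    """Is the gene's mean FPKM shifted by >= ``lfc_threshold`` log2 units
    across the adjacent time-point pair?"""
    t0, t1 = interval
    m0 = float(mat.mean_fpkm(year, t0).loc[gene])
    m1 = float(mat.mean_fpkm(year, t1).loc[gene])
    lfc = math.log2((m1 + pseudocount) / (m0 + pseudocount))
    return abs(lfc) >= lfc_threshold


def _de_counts(mat: ExpressionMatrix, genes: list[str], year: int,
               lfc_threshold: float, pseudocount: float
               ) -> dict[tuple[int, int], int]:
    """Per adjacent pre-veraison pair: how many of ``genes`` are modulated."""
    tps = mat.timepoints(year, pre_veraison=True)
    counts: dict[tuple[int, int], int] = {}
    present = [g for g in genes if g in mat.values.index]
    for t0, t1 in zip(tps, tps[1:]):
        m0 = mat.mean_fpkm(year, t0).loc[present] + pseudocount
        m1 = mat.mean_fpkm(year, t1).loc[present] + pseudocount
        lfc = np.log2(m1 / m0)
        counts[(t0, t1)] = int((lfc.abs() >= lfc_threshold).sum())
    return counts


def find_onset_interval(mat: ExpressionMatrix, biomarkers: list[str],
                        year: int, lfc_threshold: float = 1.0,
                        pseudocount: float = 1.0) -> tuple[int, int]:
    """The adjacent pre-veraison pair where most biomarkers switch.

    Ties resolve to the earliest pair, since the aim is the first molecular
    event of the transition.
    """
    if not biomarkers:
        raise ValueError("biomarker list must be non-empty")
    counts = _de_counts(mat, biomarkers, year, lfc_threshold, pseudocount)
    if not counts:
        raise ValueError(f"year {year}: fewer than two pre-veraison time points")
    return max(sorted(counts), key=lambda pair: counts[pair])
    # note: max() keeps the first maximal element of the sorted pairs


def select_transcriptomic_candidates(mat: ExpressionMatrix,
                                     biomarkers: list[str],
                                     all_genotype_de: Iterable[str],
                                     min_years: int = 2,
                                     lfc_threshold: float = 1.0,
                                     pseudocount: float = 1.0,
                                     onset: Optional[dict[int, tuple[int, int]]] = None
                                     ) -> set[str]:
    """Genes modulated across the onset interval in >= ``min_years`` years,
    unioned with the externally defined all-genotype DE list."""
    if onset is None:
        onset = {y: find_onset_interval(mat, biomarkers, y, lfc_threshold,
                                        pseudocount)
                 for y in mat.years}
    n_years = pd.Series(0, index=mat.values.index)
    for year, (t0, t1) in onset.items():
        m0 = mat.mean_fpkm(year, t0) + pseudocount
        m1 = mat.mean_fpkm(year, t1) + pseudocount
        lfc = np.log2(m1 / m0)
        n_years += (lfc.abs() >= lfc_threshold).astype(int)
    modulated = set(n_years.index[n_years >= min_years])
    return modulated | set(all_genotype_de)


def intersect_candidates(positional: dict[str, list],
                         transcriptomic: set[str],
                         evidence: Optional[dict[str, list[str]]] = None
                         ) -> list[CandidateGene]:
    """Intersect per-meta-QTL positional gene lists with the transcriptomic set.

    ``positional`` maps meta-QTL name -> GeneModel list.  Returns one
    CandidateGene per (meta-QTL, gene) pair surviving the intersection.
    """
    if not positional or not transcriptomic:
        raise ValueError("both candidate sources must be non-empty")
    out: list[CandidateGene] = []
    for mq_name in sorted(positional):
        for gene in positional[mq_name]:
            if gene.gene_id in transcriptomic:
                out.append(
                    CandidateGene(
                        gene_id=gene.gene_id,
                        metaqtl=mq_name,
                        chrom=gene.chrom,
                        start_bp=gene.start_bp,
                        end_bp=gene.end_bp,
                        annotation=gene.annotation,
                        evidence=(evidence or {}).get(gene.gene_id,
                                                      ["transcriptomic"]),
                    )
                )
    return out


def go_slim_filter(candidates: list[CandidateGene],
                   go_table: pd.DataFrame,
                   slim_set: frozenset[str] = REGULATORY_GO_SLIM
                   ) -> list[CandidateGene]:
    """Flag candidates annotated with a regulatory/signalling/development
    GO slim accession; returns the flagged subset.

    ``go_table`` columns: gene, go.  Malformed accessions are ignored with
    a warning.
    """
    valid = go_table["go"].str.match(r"^GO:\d{7}$", na=False)
    if (~valid).any():
        logger.warning("%d malformed GO accessions ignored", int((~valid).sum()))
    table = go_table[valid]
    by_gene = table.groupby("gene")["go"].apply(set).to_dict()
    flagged = []
    for c in candidates:
        if by_gene.get(c.gene_id, set()) & slim_set:
            c.regulatory = True
            flagged.append(c)
    return flagged


def funnel_counts(n_positional: int, n_expressed: int, n_final: int,
                  n_regulatory: int) -> pd.DataFrame:
    """The candidate-reduction funnel along the positional branch.

    Counts are monotone non-increasing: genes under meta-QTLs, of those
    the ones expressed in berry/rachis/seed, of those the transcriptomic
    candidates, of those the regulatory-annotated ones.
    """
    return pd.DataFrame(
        {
            "stage": [
                "positional (under meta-QTLs)",
                "expressed in berry/rachis/seed",
                "positional ∩ transcriptomic",
                "regulatory (GO slim)",
            ],
            "n_genes": [n_positional, n_expressed, n_final, n_regulatory],
        }
    )
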