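"""Core domain types for the meta-QTL pipeline.

The analysis manipulates four coordinate systems: component genetic maps
(cM, one per study), the consensus map (cM), the physical genome (bp) and
gene-expression space (FPKM per gene x sample).  The types below carry the
identifiers needed to move records between those systems without losing
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: The eight trait categories used to group published QTLs.
TRAIT_CATEGORIES = (
    "phenology",
    "pathogen_resistance",
    "berry_metabolites",
    "berry_morphology",
    "abiotic_stress",
    "cluster_traits",
    "seed_traits",
    "vegetative_traits",
)


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


@dataclass(frozen=True)
class Marker:
    """A genetic marker placed on one linkage group of one map."""

    name: str
    lg: str
    pos_cm: float

    def __post_init__(self) -> None:
        if self.pos_cm < 0:
            raise ValidationError(
                f"marker {self.name!r}: negative position {self.pos_cm}"
            )


@dataclass
class GeneticMap:
    """An ordered set of markers per linkage group, from a single study.

    Markers within a group are kept sorted by position; ties preserve
    insertion order.  Marker names must be unique within a group.
    """

    map_id: str
    study_ref: str = ""
    groups: dict[str, list[Marker]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lg, markers in self.groups.items():
            self.groups[lg] = sorted(markers, key=lambda m: m.pos_cm)
            names = [m.name for m in self.groups[lg]]
            dupes = {n for n in names if names.count(n) > 1}
            if dupes:
                raise ValidationError(
                    f"map {self.map_id!r} LG {lg!r}: duplicate markers {sorted(dupes)}"
                )

    @property
    def lgs(self) -> list[str]:
        return list(self.groups)

    def markers(self, lg: str) -> list[Marker]:
        return self.groups.get(lg, [])

    def positions(self, lg: str) -> dict[str, float]:
        """Marker name -> cM position for one linkage group."""
        return {m.name: m.pos_cm for m in self.groups.get(lg, [])}

    def n_markers(self, lg: Optional[str] = None) -> int:
        if lg is not None:
            return len(self.groups.get(lg, []))
        return sum(len(v) for v in self.groups.values())


@dataclass
class SynonymTable:
    """Functional mapping from variant marker spellings to canonical names."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for variant, canonical in self.mapping.items():
            target = self.mapping.get(canonical, canonical)
            if target != canonical:
                raise ValidationError(
                    f"canonical name {canonical!r} is itself mapped to {target!r}; "
                    "canonical names must be fixed points"
                )

    def canonical(self, name: str) -> str:
        return self.mapping.get(name, name)


@dataclass
class QTLRecord:
    """One published QTL observation in the coordinates of its source map.

    ``ci_start_cm``/``ci_end_cm`` may be ``None`` when the study did not
    report a confidence interval; such records are flagged for downstream
    CI estimation from population size and R².
    """

    qtl_id: str
    trait: str
    trait_category: str
    study_ref: str
    population_size: int
    lg: str
    peak_cm: float
    ci_start_cm: Optional[float] = None
    ci_end_cm: Optional[float] = None
    r2: Optional[float] = None
    map_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.trait_category not in TRAIT_CATEGORIES:
            raise ValidationError(
                f"QTL {self.qtl_id!r}: unknown trait category "
                f"{self.trait_category!r}; allowed: {', '.join(TRAIT_CATEGORIES)}"
            )
        if self.population_size <= 0:
            raise ValidationError(
                f"QTL {self.qtl_id!r}: population size must be positive"
            )
        if (self.ci_start_cm is None) != (self.ci_end_cm is None):
            raise ValidationError(
                f"QTL {self.qtl_id!r}: confidence interval must have both ends"
            )
        if self.has_ci and not (
            self.ci_start_cm <= self.peak_cm <= self.ci_end_cm
        ):
            raise ValidationError(
                f"QTL {self.qtl_id!r}: peak {self.peak_cm} outside CI "
                f"[{self.ci_start_cm}, {self.ci_end_cm}]"
            )
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(f"QTL {self.qtl_id!r}: R² must lie in [0, 1]")

    @property
    def has_ci(self) -> bool:
        return self.ci_start_cm is not None

    @property
    def ci_length(self) -> Optional[float]:
        if not self.has_ci:
            return None
        return self.ci_end_cm - self.ci_start_cm


@dataclass
class ConsensusMarker:
    """A marker on the consensus map with per-component provenance."""

    name: str
    pos_cm: float
    provenance: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_maps(self) -> int:
        return len(self.provenance)

    @property
    def shared(self) -> bool:
        return self.n_maps >= 2


@dataclass
class ConsensusMap:
    """The merged map: per-LG ordered consensus markers."""

    groups: dict[str, list[ConsensusMarker]] = field(default_factory=dict)

    @property
    def lgs(self) -> list[str]:
        return list(self.groups)

    def markers(self, lg: str) -> list[ConsensusMarker]:
        return self.groups.get(lg, [])

    def positions(self, lg: str) -> dict[str, float]:
        return {m.name: m.pos_cm for m in self.groups.get(lg, [])}

    def summary(self) -> list[dict]:
        """Per-LG marker counts and lengths (consensus-map feature table)."""
        rows = []
        for lg, markers in self.groups.items():
            n_shared = sum(m.shared for m in markers)
            maps = {mid for m in markers for mid, _ in m.provenance}
            length = markers[-1].pos_cm - markers[0].pos_cm if markers else 0.0
            rows.append(
                {
                    "lg": lg,
                    "n_markers": len(markers),
                    "n_unique": len(markers) - n_shared,
                    "n_shared": n_shared,
                    "length_cm": round(length, 2),
                    "n_maps": len(maps),
                }
            )
        return rows


@dataclass
class ProjectedQTL:
    """A QTL re-expressed in consensus coordinates, or a rejection record."""

    record: QTLRecord
    status: str  # "projected" | "rejected"
    reason: Optional[str] = None
    peak_cm: Optional[float] = None
    ci_start_cm: Optional[float] = None
    ci_end_cm: Optional[float] = None
    scale_factor: Optional[float] = None
    flank_markers: Optional[tuple[str, str]] = None
    extrapolated: bool = False

    @property
    def projected(self) -> bool:
        return self.status == "projected"

    @property
    def qtl_id(self) -> str:
        return self.record.qtl_id

    @property
    def ci_length(self) -> Optional[float]:
        if self.ci_start_cm is None or self.ci_end_cm is None:
            return None
        return self.ci_end_cm - self.ci_start_cm


@dataclass
class MetaQTL:
    """A consensus locus summarizing one fitted mixture component."""

    name: str
    lg: str
    peak_cm: float
    ci_start_cm: float
    ci_end_cm: float
    mean_r2: Optional[float]
    member_ids: list[str]
    n_studies: int
    traits: list[str]
    start_bp: Optional[int] = None
    end_bp: Optional[int] = None
    chrom: Optional[str] = None

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def ci_length(self) -> float:
        return self.ci_end_cm - self.ci_start_cm


@dataclass(frozen=True)
class AnchorPoint:
    """A marker with both consensus (cM) and genome (bp) coordinates."""

    marker: str
    lg: str
    pos_cm: float
    chrom: str
    pos_bp: int


@dataclass(frozen=True)
class GeneModel:
    """A gene feature from the annotation, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "+"
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start_bp} > end {self.end_bp}"
            )


@dataclass
class CandidateGene:
    """A final candidate: positional + transcriptomic evidence."""

    gene_id: str
    metaqtl: str
    chrom: Optional[str] = None
    start_bp: Optional[int] = None
    end_bp: Optional[int] = None
    annotation: str = ""
    evidence: list[str] = field(default_factory=list)
    regulatory: bool = False
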