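"""Domain types for the prophage-host interaction pipeline.

The objects here mirror the entities of the study design: bacterial strains
with capsule locus types (CLT), prophages with PHASTER-style completeness
classes, their proteomes, homology hits between prophage proteins, defense
systems (restriction-modification and CRISPR arrays), the all-against-all
infection matrix, and capsule-loss trajectories from evolution experiments.

All are lightweight dataclasses with invariant checks in ``__post_init__``;
file I/O lives in :mod:`prophagenet.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .seq import DNA_ALPHABET, IUPAC_BASES, PROTEIN_ALPHABET


class Completeness(str, enum.Enum):
    """Prophage completeness class (detection-confidence tiers)."""

    INTACT = "intact"
    QUESTIONABLE = "questionable"
    INCOMPLETE = "incomplete"


class BacteriocinStatus(str, enum.Enum):
    NONE = "none"
    PARTIAL = "partial"
    FULL_OPERON = "full_operon"


class RMType(str, enum.Enum):
    I = "I"
    II = "II"
    IIG = "IIG"
    III = "III"
    IV = "IV"


class RMRole(str, enum.Enum):
    MTASE = "MTase"
    REASE = "REase"
    OTHER = "other"


class Treatment(str, enum.Enum):
    """Evolution-experiment environment: rich medium, with citrate (inhibits
    phage adsorption), with mitomycin C (induces prophages), or both."""

    LB = "LB"
    LB_CITRATE = "LB_citrate"
    MMC = "MMC"
    MMC_CITRATE = "MMC_citrate"


@dataclass
class Strain:
    strain_id: str
    species: str = "Klebsiella sp."
    clt: str = "unknown"
    lps_type: str = "unknown"
    genome_length: int | None = None
    chromosome_gc: float | None = None
    prophage_ids: list[str] = field(default_factory=list)
    bacteriocin_status: BacteriocinStatus = BacteriocinStatus.NONE

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise ValueError("strain_id must be non-empty")
        if not self.clt:
            raise ValueError(f"strain {self.strain_id}: clt must be non-empty")
        if self.chromosome_gc is not None and not 0.0 <= self.chromosome_gc <= 1.0:
            raise ValueError(f"strain {self.strain_id}: chromosome_gc out of [0,1]")
        self.bacteriocin_status = BacteriocinStatus(self.bacteriocin_status)


@dataclass
class Prophage:
    prophage_id: str
    host_strain_id: str
    start: int
    end: int
    completeness: Completeness = Completeness.INTACT
    sequence: str | None = None
    protein_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.completeness = Completeness(self.completeness)
        if self.start > self.end:
            raise ValueError(f"prophage {self.prophage_id}: start > end")
        if self.start < 1:
            raise ValueError(f"prophage {self.prophage_id}: coordinates are 1-based")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"prophage {self.prophage_id}: non-DNA characters {sorted(bad)}"
                )
            if len(self.sequence) != self.end - self.start + 1:
                raise ValueError(
                    f"prophage {self.prophage_id}: sequence length "
                    f"{len(self.sequence)} != end - start + 1 = {self.end - self.start + 1}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinRecord:
    protein_id: str
    parent_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: non-protein characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProphageProteome:
    """The protein set of one prophage; its size is the denominator candidate
    of the wGRR score."""

    prophage_id: str
    proteins: list[ProteinRecord]

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"proteome {self.prophage_id}: at least one protein required")
        ids = [p.protein_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValueError(f"proteome {self.prophage_id}: duplicate protein ids")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]


@dataclass
class HomologyHit:
    """One row of a BLAST-like tabular search between prophage proteins."""

    query_id: str
    subject_id: str
    pct_identity: float
    query_coverage: float
    subject_coverage: float
    evalue: float
    bitscore: float
    alignment_length: int | None = None

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError(f"self-hit {self.query_id} must be removed at read time")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: pct_identity out of [0,100]")
        for name, cov in (("query_coverage", self.query_coverage),
                          ("subject_coverage", self.subject_coverage)):
            if not 0.0 <= cov <= 1.0:
                raise ValueError(f"hit {self.query_id}->{self.subject_id}: {name} out of [0,1]")
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative evalue")
        if self.bitscore < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative bitscore")


@dataclass
class BBHPair:
    """A reciprocal-best-hit homolog pair between two prophages.

    ``identity`` is a percent in [0, 100] (the id(A_i, B_i) term of the wGRR
    sum is this value divided by 100).
    """

    protein_a: str
    protein_b: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"BBH {self.protein_a}~{self.protein_b}: identity out of [0,100]")


@dataclass
class InfectionMatrix:
    """Producer x target grid of replicate clearing counts.

    ``counts`` is a DataFrame indexed by producer strain id with target strain
    ids as columns; each cell holds the number of replicates (of
    ``n_replicates``) in which the producer's lysate cleared the target lawn.
    """

    counts: pd.DataFrame
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        arr = self.counts.to_numpy()
        if arr.size and ((arr < 0) | (arr > self.n_replicates)).any():
            raise ValueError(f"counts must lie in [0, {self.n_replicates}]")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate producer or target ids")

    @property
    def producers(self) -> list[str]:
        return list(self.counts.index)

    @property
    def targets(self) -> list[str]:
        return list(self.counts.columns)

    def count(self, producer: str, target: str) -> int:
        return int(self.counts.at[producer, target])


@dataclass
class RMSystem:
    """A restriction-modification system: typed components (MTase/REase) and,
    when known, the recognition motif as a degenerate IUPAC string."""

    system_id: str
    strain_id: str
    rm_type: RMType
    components: list[tuple[RMRole, str]] = field(default_factory=list)
    recognition_motif: str | None = None

    def __post_init__(self) -> None:
        self.rm_type = RMType(self.rm_type)
        self.components = [(RMRole(r), s.upper()) for r, s in self.components]
        if self.recognition_motif is not None:
            self.recognition_motif = self.recognition_motif.upper()
            bad = set(self.recognition_motif) - set(IUPAC_BASES)
            if bad:
                raise ValueError(
                    f"R-M system {self.system_id}: non-IUPAC motif characters {sorted(bad)}"
                )


@dataclass
class CRISPRArray:
    array_id: str
    strain_id: str
    spacers: list[str]

    def __post_init__(self) -> None:
        self.spacers = [s.upper() for s in self.spacers]
        for s in self.spacers:
            if not s:
                raise ValueError(f"array {self.array_id}: empty spacer")
            bad = set(s) - DNA_ALPHABET
            if bad:
                raise ValueError(f"array {self.array_id}: non-DNA spacer characters {sorted(bad)}")

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)


@dataclass
class Trajectory:
    """Daily capsulated-clone fractions for one evolving population."""

    population_id: str
    strain_id: str
    treatment: Treatment
    values: dict[int, float]

    def __post_init__(self) -> None:
        self.treatment = Treatment(self.treatment)
        for day, frac in self.values.items():
            if day < 0:
                raise ValueError(f"population {self.population_id}: negative day {day}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"population {self.population_id}: fraction {frac} at day {day} out of [0,1]"
                )

    @property
    def days(self) -> list[int]:
        return sorted(self.values)
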