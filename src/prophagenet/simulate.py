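"""Seeded generators for synthetic study panels.

Every analysis stage can be exercised without external data: proteome pairs
with planted homologs of controlled identity (wGRR), genomes with planted
recognition motifs and protospacers (defense inference), 35-strain
infection matrices with configurable same-CLT vs cross-CLT infection
probabilities and three replicates (modularity statistics), and
capsule-fraction trajectories under treatment-dependent selection (AUC
analysis).

Defaults emulate the study conditions: 35 strains whose capsule-serotype
multiplicities give 105 ordered same-CLT pairs (including self) and 1120
cross-CLT pairs out of 1225; per-replicate infection probabilities 0.33
(same CLT) vs 0.036 (cross CLT); ten days of evolution at ~7 generations
per day with six populations per strain x environment.

A single root seed drives an independent substream per component, so adding
one generator never perturbs another's output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .defense import find_motif_sites
from .seq import IUPAC_BASES, reverse_complement
from .types import (
    CRISPRArray,
    HomologyHit,
    InfectionMatrix,
    Prophage,
    ProphageProteome,
    ProteinRecord,
    RMRole,
    RMSystem,
    RMType,
    Strain,
    Trajectory,
    Treatment,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"

# CLT group sizes for the default 35-strain panel: sum(n_i) = 35 and
# sum(n_i^2) = 105 ordered same-CLT pairs including self, leaving 1120
# cross-CLT pairs — the arithmetic of the study's 1225-combination panel.
DEFAULT_CLT_SIZES = (7, 5, 3, 2) + (1,) * 18

# Selection coefficients per environment for the capsule-loss model:
# phage predation (MMC > LB via induced vs spontaneous induction) selects
# non-capsulated escape mutants; citrate inhibits adsorption and nearly
# removes that selection.
DEFAULT_SELECTION = {
    Treatment.MMC: 0.30,
    Treatment.LB: 0.10,
    Treatment.MMC_CITRATE: 0.05,
    Treatment.LB_CITRATE: 0.02,
}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Independent, reproducible substream for a named component."""
    key = zlib.crc32(component.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), key]))


# ---------------------------------------------------------------------------
# Proteomes with planted homologs

def generate_proteome_pair(n_a: int, n_b: int, n_hom: int,
                           identity_target: float,
                           length_range: tuple[int, int] = (80, 300),
                           seed: int = 0,
                           id_a: str = "phageA", id_b: str = "phageB",
                           ) -> tuple[ProphageProteome, ProphageProteome, list[dict]]:
    """Two proteomes sharing ``n_hom`` planted homolog pairs.

    Background proteins are i.i.d. uniform over the 20 residues. Each
    planted homolog of B is a copy of a protein of A with exactly
    round((1 - identity_target) * L) positions substituted to a different
    residue, so the realized identity is (L - k)/L. The returned truth table
    lists the pairs with their realized identities (fractions).
    """
    if not 0.0 < identity_target <= 1.0:
        raise ValueError("identity_target must lie in (0, 1]")
    if n_hom > min(n_a, n_b):
        raise ValueError("n_hom exceeds the smaller proteome size")
    rng = component_rng(seed, "proteomes")
    lo, hi = length_range

    def random_protein(length: int) -> str:
        return "".join(rng.choice(list(AMINO_ACIDS), size=length))

    prot_a = [ProteinRecord(f"{id_a}_{i + 1:04d}", id_a,
                            random_protein(int(rng.integers(lo, hi + 1))))
              for i in range(n_a)]

    prot_b: list[ProteinRecord] = []
    truth: list[dict] = []
    for i in range(n_hom):
        template = prot_a[i].sequence
        length = len(template)
        k = round((1.0 - identity_target) * length)
        seq = list(template)
        positions = rng.choice(length, size=k, replace=False)
        for pos in positions:
            alternatives = [aa for aa in AMINO_ACIDS if aa != seq[pos]]
            seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
        rec = ProteinRecord(f"{id_b}_{i + 1:04d}", id_b, "".join(seq))
        prot_b.append(rec)
        truth.append({"protein_a": prot_a[i].protein_id,
                      "protein_b": rec.protein_id,
                      "identity": (length - k) / length})
    for i in range(n_hom, n_b):
        prot_b.append(ProteinRecord(f"{id_b}_{i + 1:04d}", id_b,
                                    random_protein(int(rng.integers(lo, hi + 1)))))

    return (ProphageProteome(id_a, prot_a), ProphageProteome(id_b, prot_b), truth)


def exact_hits_from_truth(proteomes: Mapping[str, ProphageProteome],
                          truth: Sequence[Mapping]) -> list[HomologyHit]:
    """Lossless hit table for planted homolog pairs: one hit per pair per
    direction with pident = realized identity, full coverage, e-value 1e-50,
    and bitscore proportional to identity x length. No background hits."""
    lengths = {p.protein_id: p.length
               for proteome in proteomes.values() for p in proteome.proteins}
    hits: list[HomologyHit] = []
    for row in truth:
        pa, pb = row["protein_a"], row["protein_b"]
        identity = float(row["identity"])
        length = min(lengths[pa], lengths[pb])
        for q, s in ((pa, pb), (pb, pa)):
            hits.append(HomologyHit(
                query_id=q, subject_id=s, pct_identity=identity * 100.0,
                query_coverage=1.0, subject_coverage=1.0,
                evalue=1e-50, bitscore=2.0 * identity * length,
                alignment_length=length))
    return hits


# ---------------------------------------------------------------------------
# Infection panels

@dataclass
class PanelConfig:
    """Configuration of a synthetic all-against-all infection panel."""

    n_strains: int = 35
    clt_assignment: dict[str, str] | None = None
    p_same: float = 0.33
    p_diff: float = 0.036
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (("p_same", self.p_same), ("p_diff", self.p_diff)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} out of [0,1]")
        if self.clt_assignment is None:
            self.clt_assignment = default_clt_assignment(self.n_strains)
        if len(self.clt_assignment) != self.n_strains:
            raise ValueError("clt_assignment size does not match n_strains")


def default_clt_assignment(n_strains: int = 35) -> dict[str, str]:
    """Strain -> CLT labels with the study-like multiplicity spectrum.

    For 35 strains, group sizes (7, 5, 3, 2, 1 x 18) give exactly 105
    ordered same-CLT pairs (self included). Other panel sizes reuse the
    size list truncated/extended with singletons.
    """
    sizes = list(DEFAULT_CLT_SIZES)
    while sum(sizes) < n_strains:
        sizes.append(1)
    assignment: dict[str, str] = {}
    strain_idx = 0
    for group_idx, size in enumerate(sizes):
        for _ in range(size):
            if strain_idx >= n_strains:
                return assignment
            assignment[f"S{strain_idx + 1:02d}"] = f"KL{group_idx + 1:02d}"
            strain_idx += 1
    return assignment


def default_lps_assignment(strain_ids: Sequence[str], n_types: int = 5,
                           seed: int = 0) -> dict[str, str]:
    """O-locus labels assigned independently of the CLT (round-robin over a
    seeded strain shuffle), for the LPS null analysis."""
    rng = component_rng(seed, "lps")
    order = list(strain_ids)
    rng.shuffle(order)
    return {sid: f"O{i % n_types + 1}" for i, sid in enumerate(order)}


def generate_infection_panel(config: PanelConfig,
                             ) -> tuple[InfectionMatrix, list[Strain]]:
    """Infection matrix with per-replicate Bernoulli clearing: probability
    p_same when producer and target share a CLT, p_diff otherwise,
    independent across replicates."""
    rng = component_rng(config.seed, "infection_panel")
    strain_ids = sorted(config.clt_assignment)
    lps = default_lps_assignment(strain_ids, seed=config.seed)
    n = len(strain_ids)
    counts = np.zeros((n, n), dtype=int)
    for i, a in enumerate(strain_ids):
        for j, b in enumerate(strain_ids):
            p = config.p_same if config.clt_assignment[a] == config.clt_assignment[b] \
                else config.p_diff
            counts[i, j] = rng.binomial(config.n_replicates, p)
    matrix = InfectionMatrix(
        counts=pd.DataFrame(counts, index=strain_ids, columns=strain_ids),
        n_replicates=config.n_replicates)
    strains = [Strain(strain_id=sid, clt=config.clt_assignment[sid],
                      lps_type=lps[sid]) for sid in strain_ids]
    return matrix, strains


# ---------------------------------------------------------------------------
# Defense scenarios

@dataclass
class DefenseScenario:
    strains: list[Strain]
    prophages_by_strain: dict[str, list[Prophage]]
    rm_systems: list[RMSystem]
    crispr_arrays: list[CRISPRArray]
    truth: dict


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def _concrete_motif(rng: np.random.Generator, motif: str) -> str:
    return "".join(b if b in BASES else
                   sorted(IUPAC_BASES[b])[int(rng.integers(len(IUPAC_BASES[b])))]
                   for b in motif)


def _random_protein(rng: np.random.Generator, length: int = 200) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_defense_scenario(n_strains: int = 4,
                              motif_set: Sequence[str] = ("GAATTC", "GCCGGC"),
                              spacer_plants: int = 2,
                              mismatch_counts: Sequence[int] = (0,),
                              seed: int = 0,
                              genome_length: int = 4000,
                              gc: float = 0.5,
                              spacer_length: int = 32) -> DefenseScenario:
    """Genomes with planted recognition motifs and protospacers, plus the
    R-M and CRISPR annotations that should (or should not) target them.

    Each motif belongs to one strain as a Type II system (MTase + REase with
    random protein sequences) and is planted once, on a random strand, into
    every other strain's prophage. Protospacers are copied from a source
    strain's prophage into another strain's CRISPR array with the requested
    number of substitutions; arrays are padded with random spacers to the
    three-spacer minimum. The truth dict records every planted feature and,
    for motifs, all post-planting occurrences (chance background hits
    included, via a scan of the final sequences).
    """
    if any(len(m) > genome_length for m in motif_set):
        raise ValueError("motif longer than genome")
    rng = component_rng(seed, "defense")
    strain_ids = [f"S{i + 1:02d}" for i in range(n_strains)]
    strains = [Strain(strain_id=sid, clt=f"KL{i + 1:02d}")
               for i, sid in enumerate(strain_ids)]

    genomes = {sid: list(_random_genome(rng, genome_length, gc))
               for sid in strain_ids}
    truth: dict = {"planted_motifs": [], "planted_protospacers": [],
                   "motif_sites": []}

    rm_systems: list[RMSystem] = []
    for m_idx, motif in enumerate(motif_set):
        owner = strain_ids[m_idx % n_strains]
        rm_systems.append(RMSystem(
            system_id=f"RM{m_idx + 1:02d}", strain_id=owner, rm_type=RMType.II,
            components=[(RMRole.MTASE, _random_protein(rng)),
                        (RMRole.REASE, _random_protein(rng))],
            recognition_motif=motif))
        for sid in strain_ids:
            if sid == owner:
                continue
            concrete = _concrete_motif(rng, motif)
            strand = "+" if rng.random() < 0.5 else "-"
            planted = concrete if strand == "+" else reverse_complement(concrete)
            pos = int(rng.integers(0, genome_length - len(planted)))
            genomes[sid][pos:pos + len(planted)] = list(planted)
            truth["planted_motifs"].append({
                "motif": motif, "strain_id": sid, "prophage_id": f"P_{sid}",
                "position": pos + 1, "strand": strand})

    prophages_by_strain = {
        sid: [Prophage(prophage_id=f"P_{sid}", host_strain_id=sid,
                       start=1, end=genome_length,
                       sequence="".join(genomes[sid]))]
        for sid in strain_ids}

    # CRISPR arrays: planted protospacer copies plus random padding spacers.
    arrays: dict[str, CRISPRArray] = {}

    def array_of(sid: str) -> CRISPRArray:
        if sid not in arrays:
            arrays[sid] = CRISPRArray(array_id=f"CR_{sid}", strain_id=sid,
                                      spacers=[])
        return arrays[sid]

    for k in range(spacer_plants):
        source = strain_ids[k % n_strains]
        target = strain_ids[(k + 1) % n_strains]
        n_mm = mismatch_counts[k % len(mismatch_counts)]
        pos = int(rng.integers(0, genome_length - spacer_length))
        proto = prophages_by_strain[source][0].sequence[pos:pos + spacer_length]
        spacer = list(proto)
        mm_positions = rng.choice(spacer_length, size=n_mm, replace=False)
        for p in mm_positions:
            alternatives = [b for b in BASES if b != spacer[p]]
            spacer[p] = alternatives[int(rng.integers(3))]
        array_of(target).spacers.append("".join(spacer))
        truth["planted_protospacers"].append({
            "spacer_strain": target, "source_strain": source,
            "prophage_id": f"P_{source}", "position": pos + 1,
            "n_mismatches": int(n_mm), "spacer": "".join(spacer)})

    for sid in strain_ids:
        arr = array_of(sid)
        while arr.n_spacers < 3:
            arr.spacers.append(_random_genome(rng, spacer_length, 0.5))

    # Post-scan: every motif occurrence actually present (planting + chance).
    for motif in motif_set:
        for sid in strain_ids:
            prophage = prophages_by_strain[sid][0]
            for site in find_motif_sites(motif, prophage.sequence,
                                         sequence_id=prophage.prophage_id):
                truth["motif_sites"].append({
                    "motif": motif, "prophage_id": prophage.prophage_id,
                    "position": site.position, "strand": site.strand})

    return DefenseScenario(strains=strains,
                           prophages_by_strain=prophages_by_strain,
                           rm_systems=rm_systems,
                           crispr_arrays=list(arrays.values()), truth=truth)


# ---------------------------------------------------------------------------
# Capsule-loss trajectories

@dataclass
class EvolutionConfig:
    """Selection-against-capsule model with unidirectional loss mutation.

    Per generation the capsulated frequency f follows
    f' = f(1-mu) / (f(1-mu) + (1 - f(1-mu)) (1+s)): capsule-loss mutants
    arise at rate mu and enjoy selective advantage s (phage escape). Daily
    observations are binomial samples of ``sampling_n`` clones.
    """

    s: float = 0.1
    mu: float = 1e-3
    generations_per_day: int = 7
    days: int = 10
    n_populations: int = 6
    sampling_n: int = 100
    seed: int = 0
    strain_id: str = "S01"
    treatment: Treatment = Treatment.LB

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mutation rate out of [0,1]")


def _next_frequency(f: float, mu: float, s: float) -> float:
    capsulated = f * (1.0 - mu)
    return capsulated / (capsulated + (1.0 - capsulated) * (1.0 + s))


def generate_trajectories(config: EvolutionConfig) -> list[Trajectory]:
    """Deterministic selection/mutation recursion with binomial sampling
    noise at each daily observation."""
    rng = component_rng(config.seed,
                        f"evolution:{config.strain_id}:{config.treatment.value}")
    out: list[Trajectory] = []
    for pop in range(config.n_populations):
        f = 1.0
        values: dict[int, float] = {}
        values[0] = rng.binomial(config.sampling_n, f) / config.sampling_n
        for day in range(1, config.days + 1):
            for _ in range(config.generations_per_day):
                f = _next_frequency(f, config.mu, config.s)
            values[day] = rng.binomial(config.sampling_n, f) / config.sampling_n
        out.append(Trajectory(
            population_id=f"{config.strain_id}_{config.treatment.value}_pop{pop + 1}",
            strain_id=config.strain_id, treatment=config.treatment,
            values=values))
    return out


def generate_evolution_experiment(strain_ids: Sequence[str] = ("S01",),
                                  selection: Mapping[Treatment, float] | None = None,
                                  mu: float = 1e-3, seed: int = 0,
                                  **kwargs) -> list[Trajectory]:
    """Trajectories for every strain x environment with the default
    treatment-dependent selection coefficients."""
    selection = dict(DEFAULT_SELECTION if selection is None else selection)
    out: list[Trajectory] = []
    for strain in strain_ids:
        for treatment, s in selection.items():
            config = EvolutionConfig(s=s, mu=mu, seed=seed, strain_id=strain,
                                     treatment=treatment, **kwargs)
            out.extend(generate_trajectories(config))
    return out


# ---------------------------------------------------------------------------
# File emission (the dialects the other modules consume)

def write_panel(outdir: str | Path, matrix: InfectionMatrix,
                strains: Sequence[Strain], config: PanelConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_infection_matrix(matrix, outdir / "infection_matrix.csv")
    pio.write_strain_table(strains, outdir / "strains.tsv")
    truth = {"p_same": config.p_same, "p_diff": config.p_diff,
             "n_replicates": config.n_replicates, "seed": config.seed,
             "clt_assignment": config.clt_assignment}
    (outdir / "infection_truth.json").write_text(json.dumps(truth, indent=2))


def write_defense_scenario(outdir: str | Path, scenario: DefenseScenario) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = [(p.prophage_id, p.sequence)
               for plist in scenario.prophages_by_strain.values() for p in plist]
    pio.write_fasta(records, outdir / "prophages.fasta")
    rows = [{"prophage_id": p.prophage_id, "strain_id": p.host_strain_id,
             "start": p.start, "end": p.end,
             "completeness": p.completeness.value}
            for plist in scenario.prophages_by_strain.values() for p in plist]
    pd.DataFrame(rows).to_csv(outdir / "prophages.tsv", sep="\t", index=False)
    pio.write_rm_table(scenario.rm_systems, outdir / "rm_systems.tsv")
    protein_records = []
    for s in scenario.rm_systems:
        for i, (role, seq) in enumerate(s.components):
            protein_records.append((f"{s.system_id}_{role.value}_{i}", seq))
    pio.write_fasta(protein_records, outdir / "rm_proteins.fasta")
    pio.write_crispr_table(scenario.crispr_arrays, outdir / "crispr_arrays.tsv")
    (outdir / "defense_truth.json").write_text(json.dumps(scenario.truth, indent=2))


def write_proteome_pair(outdir: str | Path, proteome_a: ProphageProteome,
                        proteome_b: ProphageProteome, truth: list[dict]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for proteome in (proteome_a, proteome_b):
        records = [(p.protein_id, p.sequence) for p in proteome.proteins]
        pio.write_fasta(records, outdir / f"{proteome.prophage_id}.faa")
    hits = exact_hits_from_truth(
        {proteome_a.prophage_id: proteome_a, proteome_b.prophage_id: proteome_b},
        truth)
    pio.write_hits_table(hits, outdir / "hits.tsv")
    (outdir / "homolog_truth.json").write_text(json.dumps(truth, indent=2))


def write_trajectory_set(outdir: str | Path,
                         trajectories: Sequence[Trajectory]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_trajectories(trajectories, outdir / "trajectories.csv")
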