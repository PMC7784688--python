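"""Superinfection-immunity and defense-system analyses.

Three inference procedures that probe why the infection network might be
sparse:

* **Repressor similarity** — phage repressors confer immunity to similar
  incoming phages; similarity between candidate repressors is the number of
  matched positions in a match-only global alignment (equivalently the
  longest-common-subsequence length) divided by the length of the smaller
  sequence.
* **CRISPR targeting** — spacers of a target strain are matched against the
  prophages of a lysate-producing strain (ungapped, both strands, identity
  and spacer coverage at least 90%).
* **R-M targeting** — a prophage is putatively targeted when its genome
  carries the recognition site of a restriction-modification system present
  in the target strain and absent (no sufficiently similar same-type,
  same-role protein) from the producer strain; motif scanning is
  IUPAC-aware and searches the complementary strand for non-palindromic
  motifs. Some systems need two sites to cleave, hence the optional
  two-site mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from numpy.lib.stride_tricks import sliding_window_view

from .seq import is_palindrome, iupac_regex, reverse_complement
from .types import (
    CRISPRArray,
    Completeness,
    InfectionMatrix,
    Prophage,
    RMRole,
    RMSystem,
    RMType,
)

logger = logging.getLogger(__name__)

REPRESSOR_KEYWORDS = ("immunity", "superinfection", "repressor", "exclusion")

# Per-type identity thresholds above which two R-M proteins are considered
# able to target similar recognition sites.
RM_IDENTITY_THRESHOLDS: dict[tuple[RMType, RMRole], float] = {
    (RMType.II, RMRole.REASE): 0.50,
    (RMType.IV, RMRole.REASE): 0.50,
    (RMType.IIG, RMRole.REASE): 0.55,
    (RMType.IIG, RMRole.MTASE): 0.55,
    (RMType.II, RMRole.MTASE): 0.60,
    (RMType.I, RMRole.MTASE): 0.80,
    (RMType.I, RMRole.REASE): 0.80,
    (RMType.III, RMRole.MTASE): 0.80,
    (RMType.III, RMRole.REASE): 0.80,
}


# ---------------------------------------------------------------------------
# Repressor similarity

_lcs_aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                     mismatch_score=0, gap_score=0)


def repressor_similarity(seq_a: str, seq_b: str) -> float:
    """Matched positions of a zero-cost global alignment divided by the
    length of the smaller sequence.

    With zero mismatch and gap costs the maximal number of matched positions
    equals the longest-common-subsequence length, so the statistic is
    LCS(a, b) / min(|a|, |b|), in [0, 1].
    """
    a, b = seq_a.upper(), seq_b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    lcs = _lcs_aligner.score(a, b)
    return lcs / min(len(a), len(b))


def select_repressor_candidates(profile_hits: pd.DataFrame) -> pd.DataFrame:
    """Filter profile-search hits down to credible repressor candidates.

    Keeps rows with viral quotient VQ > 0.8, best-domain e-value <= 1e-4,
    profile coverage >= 0.6, and a description containing at least one of
    the immunity keywords (immunity, superinfection, repressor, exclusion).
    """
    required = {"vq", "best_domain_evalue", "coverage", "description"}
    missing = required - set(profile_hits.columns)
    if missing:
        raise ValueError(f"profile hits missing columns {sorted(missing)}")
    desc = profile_hits["description"].astype(str).str.lower()
    keyword_ok = desc.apply(lambda d: any(k in d for k in REPRESSOR_KEYWORDS))
    mask = (
        (profile_hits["vq"] > 0.8)
        & (profile_hits["best_domain_evalue"] <= 1e-4)
        & (profile_hits["coverage"] >= 0.6)
        & keyword_ok
    )
    return profile_hits[mask].copy()


# ---------------------------------------------------------------------------
# CRISPR spacer matching

@dataclass
class SpacerMatch:
    """An ungapped spacer-protospacer match on a prophage sequence."""

    spacer_id: str
    prophage_id: str
    position: int  # 1-based start on the forward strand
    strand: str  # "+" or "-"
    matched_length: int
    n_mismatches: int

    @property
    def identity(self) -> float:
        return (self.matched_length - self.n_mismatches) / self.matched_length


def filter_crispr_arrays(arrays: Iterable[CRISPRArray]) -> list[CRISPRArray]:
    """Retain arrays with at least three spacers (shorter arrays are likely
    annotation noise)."""
    return [a for a in arrays if a.n_spacers >= 3]


def match_spacer(spacer: str, prophage_seq: str,
                 min_identity: float = 0.9, min_coverage: float = 0.9,
                 spacer_id: str = "spacer", prophage_id: str = "prophage",
                 ) -> list[SpacerMatch]:
    """Ungapped scan of a spacer against both strands of a prophage.

    Window lengths run from ceil(min_coverage * L) to L (contiguous
    truncation of the spacer from either end); a window is reported when its
    identity is at least ``min_identity``. Overlapping reports on the same
    strand collapse to the best one (fewest mismatches, then longest, then
    leftmost).
    """
    spacer = spacer.upper()
    seq = prophage_seq.upper()
    L = len(spacer)
    if L < 10:
        raise ValueError("spacer shorter than 10 nt")
    min_len = math.ceil(min_coverage * L)
    if len(seq) < min_len:
        return []

    seq_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    raw: list[SpacerMatch] = []
    for strand in "+-":
        query = spacer if strand == "+" else reverse_complement(spacer)
        for sub_len in range(min_len, L + 1):
            if sub_len > len(seq):
                break
            windows = sliding_window_view(seq_arr, sub_len)
            # identity >= min_identity  <=>  matches >= min_identity * sub_len
            min_matches = min_identity * sub_len - 1e-9
            for offset in range(L - sub_len + 1):
                sub = np.frombuffer(query[offset:offset + sub_len].encode("ascii"),
                                    dtype=np.uint8)
                mismatches = (windows != sub).sum(axis=1)
                hit_idx = np.nonzero(sub_len - mismatches >= min_matches)[0]
                for i in hit_idx:
                    raw.append(SpacerMatch(
                        spacer_id=spacer_id, prophage_id=prophage_id,
                        position=int(i) + 1, strand=strand,
                        matched_length=sub_len,
                        n_mismatches=int(mismatches[i]),
                    ))
    return _collapse_overlaps(raw)


def _collapse_overlaps(matches: list[SpacerMatch]) -> list[SpacerMatch]:
    """Per strand, merge overlapping reports keeping the best (fewest
    mismatches, then longest, then leftmost)."""
    out: list[SpacerMatch] = []
    for strand in "+-":
        strand_matches = sorted(
            (m for m in matches if m.strand == strand),
            key=lambda m: (m.position, -m.matched_length))
        clusters: list[list[SpacerMatch]] = []
        cluster_end = -1
        for m in strand_matches:
            start, end = m.position, m.position + m.matched_length - 1
            if clusters and start <= cluster_end:
                clusters[-1].append(m)
                cluster_end = max(cluster_end, end)
            else:
                clusters.append([m])
                cluster_end = end
        for cluster in clusters:
            out.append(min(cluster, key=lambda m: (m.n_mismatches,
                                                   -m.matched_length,
                                                   m.position)))
    return sorted(out, key=lambda m: (m.position, m.strand))


# ---------------------------------------------------------------------------
# R-M protein equivalence and motif scanning

_protein_aligner = Align.PairwiseAligner(
    mode="global",
    substitution_matrix=substitution_matrices.load("BLOSUM62"),
    open_gap_score=-11.0, extend_gap_score=-1.0,
)


def global_protein_identity(seq_a: str, seq_b: str) -> float:
    """Identity of the best global alignment: identical columns divided by
    aligned columns, terminal gap columns excluded."""
    a, b = seq_a.upper(), seq_b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    alignment = _protein_aligner.align(a, b)[0]
    ga, gb = alignment[0], alignment[1]
    start, end = 0, len(ga)
    while start < end and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    # trim only the runs of terminal gaps, not internal gap columns
    lead = 0
    while lead < len(ga) and (ga[lead] == "-" or gb[lead] == "-"):
        lead += 1
    trail = len(ga)
    while trail > lead and (ga[trail - 1] == "-" or gb[trail - 1] == "-"):
        trail -= 1
    columns = trail - lead
    if columns <= 0:
        return 0.0
    identical = sum(1 for x, y in zip(ga[lead:trail], gb[lead:trail]) if x == y and x != "-")
    return identical / columns


def rm_protein_equivalent(seq_a: str, seq_b: str, role: RMRole | str,
                          rm_type: RMType | str) -> bool:
    """Whether two R-M proteins of the same role/type plausibly target the
    same recognition sites, using the per-type identity thresholds
    (REase II/IV: 50%, IIG: 55%, MTase II: 60%, type I/III: 80%)."""
    role = RMRole(role)
    rm_type = RMType(rm_type)
    try:
        threshold = RM_IDENTITY_THRESHOLDS[(rm_type, role)]
    except KeyError:
        raise ValueError(f"no identity threshold for ({rm_type.value}, {role.value})") from None
    identity = global_protein_identity(seq_a, seq_b)
    return identity >= threshold and identity > 0.5


@dataclass
class MotifSite:
    """One occurrence of a recognition motif on a sequence (1-based forward
    coordinates; strand "-" means the reverse complement of the motif was
    found on the forward strand)."""

    motif: str
    sequence_id: str
    position: int
    strand: str


def find_motif_sites(motif: str, sequence: str,
                     sequence_id: str = "seq") -> list[MotifSite]:
    """All IUPAC-compatible windows of a motif in a DNA sequence.

    The forward strand is always scanned; the complementary strand is
    scanned only when the motif is not its own reverse complement, so
    palindromic motifs (which occur identically on both strands) are not
    double-counted.
    """
    motif = motif.upper()
    if len(motif) < 4:
        raise ValueError("motif shorter than 4 nt")
    seq = sequence.upper()
    forward = iupac_regex(motif)
    # manual search loop so that overlapping occurrences are all reported
    sites = _overlapping_finditer(forward, seq, motif, sequence_id, "+")
    if not is_palindrome(motif):
        rc_pat = iupac_regex(reverse_complement(motif))
        sites += _overlapping_finditer(rc_pat, seq, motif, sequence_id, "-")
    return sorted(sites, key=lambda s: (s.position, s.strand))


def _overlapping_finditer(pattern, seq: str, motif: str, sequence_id: str,
                          strand: str) -> list[MotifSite]:
    sites = []
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            break
        sites.append(MotifSite(motif=motif, sequence_id=sequence_id,
                               position=m.start() + 1, strand=strand))
        pos = m.start() + 1
    return sites


# ---------------------------------------------------------------------------
# Targeting inference

@dataclass
class TargetingCall:
    """Producer strain A's prophage as seen by target strain B's defenses."""

    producer_strain: str
    target_strain: str
    prophage_id: str
    targeted: bool
    mechanism: str  # "rm" or "crispr"
    evidence: int

    def __post_init__(self) -> None:
        if self.targeted and self.evidence < 1:
            raise ValueError("targeted call requires evidence >= 1")


def _system_absent_from(system: RMSystem, strain_systems: Sequence[RMSystem]) -> bool:
    """True when no same-type, same-role protein in ``strain_systems`` is
    equivalent to any component of ``system``."""
    for role, seq in system.components:
        if (system.rm_type, role) not in RM_IDENTITY_THRESHOLDS:
            continue
        for other in strain_systems:
            if other.rm_type != system.rm_type:
                continue
            for o_role, o_seq in other.components:
                if o_role != role:
                    continue
                if rm_protein_equivalent(seq, o_seq, role, system.rm_type):
                    return False
    return True


def rm_targeting(rm_systems: Iterable[RMSystem],
                 prophages_by_strain: Mapping[str, Sequence[Prophage]],
                 strain_ids: Sequence[str] | None = None,
                 two_site_mode: bool = False,
                 intact_only: bool = True) -> list[TargetingCall]:
    """R-M targeting calls for all ordered strain pairs (A producer, B target).

    A prophage of A is putatively targeted when B carries an R-M system with
    a known recognition motif, A has no equivalent same-type/same-role
    system, and the motif occurs at least once (twice in two-site mode) in
    the prophage sequence. One call is emitted per (A, B, prophage).
    """
    systems = list(rm_systems)
    if strain_ids is None:
        strain_ids = sorted({s.strain_id for s in systems} | set(prophages_by_strain))
    by_strain: dict[str, list[RMSystem]] = {sid: [] for sid in strain_ids}
    for s in systems:
        by_strain.setdefault(s.strain_id, []).append(s)

    required_sites = 2 if two_site_mode else 1
    calls: list[TargetingCall] = []
    for a in strain_ids:
        prophages = [p for p in prophages_by_strain.get(a, [])
                     if p.sequence is not None
                     and (not intact_only or p.completeness == Completeness.INTACT)]
        if not prophages:
            continue
        for b in strain_ids:
            if a == b:
                continue
            candidates = []
            for system in by_strain.get(b, []):
                if system.recognition_motif is None:
                    logger.warning("R-M system %s of strain %s has no recognition "
                                   "motif; skipped", system.system_id, b)
                    continue
                if _system_absent_from(system, by_strain.get(a, [])):
                    candidates.append(system)
            for prophage in prophages:
                best_sites = 0
                for system in candidates:
                    n_sites = len(find_motif_sites(system.recognition_motif,
                                                   prophage.sequence,
                                                   sequence_id=prophage.prophage_id))
                    best_sites = max(best_sites, n_sites)
                calls.append(TargetingCall(
                    producer_strain=a, target_strain=b,
                    prophage_id=prophage.prophage_id,
                    targeted=best_sites >= required_sites,
                    mechanism="rm", evidence=best_sites,
                ))
    return calls


def crispr_targeting(arrays: Iterable[CRISPRArray],
                     prophages_by_strain: Mapping[str, Sequence[Prophage]],
                     strain_ids: Sequence[str] | None = None,
                     min_identity: float = 0.9, min_coverage: float = 0.9,
                     intact_only: bool = True) -> list[TargetingCall]:
    """CRISPR targeting calls: prophages of producer A matched by spacers of
    target B (arrays are expected to be pre-filtered to >= 3 spacers)."""
    arrays = list(arrays)
    if strain_ids is None:
        strain_ids = sorted({a.strain_id for a in arrays} | set(prophages_by_strain))
    spacers_by_strain: dict[str, list[tuple[str, str]]] = {sid: [] for sid in strain_ids}
    for arr in arrays:
        for i, spacer in enumerate(arr.spacers):
            spacers_by_strain.setdefault(arr.strain_id, []).append(
                (f"{arr.array_id}:{i + 1}", spacer))

    calls: list[TargetingCall] = []
    for a in strain_ids:
        prophages = [p for p in prophages_by_strain.get(a, [])
                     if p.sequence is not None
                     and (not intact_only or p.completeness == Completeness.INTACT)]
        if not prophages:
            continue
        for b in strain_ids:
            if a == b:
                continue
            for prophage in prophages:
                n_matches = 0
                for spacer_id, spacer in spacers_by_strain.get(b, []):
                    n_matches += len(match_spacer(
                        spacer, prophage.sequence, min_identity, min_coverage,
                        spacer_id=spacer_id, prophage_id=prophage.prophage_id))
                calls.append(TargetingCall(
                    producer_strain=a, target_strain=b,
                    prophage_id=prophage.prophage_id,
                    targeted=n_matches >= 1,
                    mechanism="crispr", evidence=n_matches,
                ))
    return calls


def pair_level_targeting(calls: Iterable[TargetingCall]) -> dict[tuple[str, str], bool]:
    """Collapse per-prophage calls to an (A, B) pair-level flag: the pair is
    targeted when any prophage of A is targeted by B's defenses."""
    pairs: dict[tuple[str, str], bool] = {}
    for c in calls:
        key = (c.producer_strain, c.target_strain)
        pairs[key] = pairs.get(key, False) or c.targeted
    return pairs


def defense_association(matrix: InfectionMatrix,
                        calls: Iterable[TargetingCall]):
    """Cross-tabulate pair-level targeting against infection outcome.

    Rows: targeted true/false; columns: infected (>= 1 replicate) / not,
    over ordered non-self pairs with a prophage-bearing producer (i.e. the
    pairs for which calls exist). Returns a ContingencyResult.
    """
    from .netstats import fisher_exact_2x2  # local import avoids cycle at import time

    pairs = pair_level_targeting(calls)
    producers = set(matrix.producers)
    targets = set(matrix.targets)
    table = np.zeros((2, 2), dtype=int)
    n_used = 0
    for (a, b), targeted in pairs.items():
        if a == b or a not in producers or b not in targets:
            continue
        infected = matrix.count(a, b) >= 1
        table[0 if targeted else 1][0 if infected else 1] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no targeting calls overlap the infection matrix panel")
    return fisher_exact_2x2(table)


def targeting_table(calls: Iterable[TargetingCall]) -> pd.DataFrame:
    rows = [{"producer": c.producer_strain, "target": c.target_strain,
             "prophage_id": c.prophage_id, "mechanism": c.mechanism,
             "targeted": c.targeted, "evidence": c.evidence} for c in calls]
    return pd.DataFrame(rows, columns=["producer", "target", "prophage_id",
                                       "mechanism", "targeted", "evidence"])
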