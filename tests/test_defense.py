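"""Defense and immunity analyses: repressor similarity, spacer matching,
motif scanning, R-M equivalence, and targeting inference."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prophagenet import defense as d
from prophagenet import simulate as sim
from prophagenet.seq import matches_iupac, reverse_complement
from prophagenet.types import (
    CRISPRArray,
    InfectionMatrix,
    Prophage,
    RMRole,
    RMSystem,
    RMType,
)


# ---------------------------------------------------------------------------
# Repressor similarity (matched positions / min length == LCS / min length)

def brute_force_lcs(a: str, b: str) -> int:
    """Longest common subsequence by exhaustive subsequence enumeration."""
    if len(a) > len(b):
        a, b = b, a
    best = 0
    for r in range(len(a), 0, -1):
        for combo in itertools.combinations(a, r):
            it = iter(b)
            if all(c in it for c in combo):
                return r
    return best


@pytest.mark.parametrize("a, b, expected", [
    ("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY", 1.0),
    ("ACDEF", "AXCXDXEXF", 1.0),  # shorter is a subsequence of longer
    ("AAAA", "CCCC", 0.0),
])
def test_repressor_similarity_examples(a, b, expected):
    assert d.repressor_similarity(a, b) == pytest.approx(expected)


def test_repressor_similarity_empty_errors():
    with pytest.raises(ValueError, match="empty"):
        d.repressor_similarity("", "ACD")


@given(st.text(alphabet="ACDE", min_size=1, max_size=8),
       st.text(alphabet="ACDE", min_size=1, max_size=8))
def test_repressor_similarity_equals_brute_force_lcs(a, b):
    expected = brute_force_lcs(a, b) / min(len(a), len(b))
    assert d.repressor_similarity(a, b) == pytest.approx(expected)
    # symmetry and bounds
    assert d.repressor_similarity(b, a) == pytest.approx(expected)
    assert 0.0 <= expected <= 1.0


# ---------------------------------------------------------------------------
# Repressor candidate selection

def test_select_repressor_candidates_filters():
    df = pd.DataFrame([
        {"vq": 0.9, "best_domain_evalue": 1e-6, "coverage": 0.7,
         "description": "phage repressor"},                       # kept
        {"vq": 0.8, "best_domain_evalue": 1e-6, "coverage": 0.7,
         "description": "repressor"},                              # vq not > 0.8
        {"vq": 0.9, "best_domain_evalue": 1e-6, "coverage": 0.59,
         "description": "superinfection exclusion"},               # low coverage
        {"vq": 0.9, "best_domain_evalue": 1e-6, "coverage": 0.7,
         "description": "tail fiber"},                             # no keyword
        {"vq": 0.9, "best_domain_evalue": 2e-4, "coverage": 0.7,
         "description": "immunity protein"},                       # e-value
    ])
    kept = d.select_repressor_candidates(df)
    assert list(kept.index) == [0]


# ---------------------------------------------------------------------------
# CRISPR arrays and spacer matching

def test_filter_crispr_arrays_three_spacer_minimum():
    arrays = [CRISPRArray("a2", "S1", ["ACGT" * 8] * 2),
              CRISPRArray("a3", "S1", ["ACGT" * 8] * 3)]
    assert [a.array_id for a in d.filter_crispr_arrays(arrays)] == ["a3"]
    assert d.filter_crispr_arrays([]) == []


def _plant(spacer, mismatches, rng, flank=60, interior=False):
    """Random sequence with the (mutated) spacer planted once.

    With ``interior=True`` the substitutions avoid the outer 3 positions, so
    no >= 90%-coverage truncation of the spacer can shed a mismatch.
    """
    L = len(spacer)
    seq = list("".join(rng.choice(list("ACGT"), size=2 * flank + L)))
    mutated = list(spacer)
    candidates = np.arange(3, L - 3) if interior else np.arange(L)
    for pos in rng.choice(candidates, size=mismatches, replace=False):
        mutated[pos] = rng.choice([b for b in "ACGT" if b != mutated[pos]])
    seq[flank:flank + L] = mutated
    return "".join(seq), flank + 1


def test_match_spacer_exact_plant():
    rng = np.random.default_rng(0)
    spacer = "".join(rng.choice(list("ACGT"), size=32))
    seq, pos = _plant(spacer, 0, rng)
    matches = [m for m in d.match_spacer(spacer, seq) if m.position == pos]
    assert matches and matches[0].n_mismatches == 0
    assert matches[0].matched_length == 32 and matches[0].identity == 1.0


def test_match_spacer_four_interior_mismatches_rejected():
    # every >=29-nt truncation keeps all 4 mismatches: best is 28/32 < 0.9
    rng = np.random.default_rng(1)
    spacer = "".join(rng.choice(list("ACGT"), size=32))
    seq, pos = _plant(spacer, 4, rng, interior=True)
    assert not [m for m in d.match_spacer(spacer, seq) if abs(m.position - pos) < 16]


def test_match_spacer_inclusive_identity_boundary():
    # 3 interior mismatches in 30 nt: only the full-length window reaches
    # 27/30 = 0.9 exactly (inclusive threshold)
    rng = np.random.default_rng(2)
    spacer = "".join(rng.choice(list("ACGT"), size=30))
    seq, pos = _plant(spacer, 3, rng, interior=True)
    matches = [m for m in d.match_spacer(spacer, seq) if m.position == pos]
    assert matches and matches[0].identity == pytest.approx(0.9)
    assert matches[0].matched_length == 30


def test_match_spacer_reverse_strand():
    rng = np.random.default_rng(3)
    spacer = "".join(rng.choice(list("ACGT"), size=32))
    seq, pos = _plant(reverse_complement(spacer), 0, rng)
    matches = [m for m in d.match_spacer(spacer, seq) if m.position == pos]
    assert matches and matches[0].strand == "-"


def test_match_spacer_short_sequence_empty():
    assert d.match_spacer("ACGTACGTACGTACGTACGT", "ACGTA") == []


def test_match_spacer_short_spacer_errors():
    with pytest.raises(ValueError, match="10"):
        d.match_spacer("ACGTACGTA", "A" * 100)


def brute_force_spacer_windows(spacer, seq, min_identity=0.9, min_coverage=0.9):
    """All (position, strand, length, mismatches) windows passing thresholds."""
    L = len(spacer)
    out = set()
    for strand, query in (("+", spacer), ("-", reverse_complement(spacer))):
        for sub_len in range(math.ceil(min_coverage * L), L + 1):
            for off in range(L - sub_len + 1):
                sub = query[off:off + sub_len]
                for start in range(len(seq) - sub_len + 1):
                    window = seq[start:start + sub_len]
                    mm = sum(1 for x, y in zip(sub, window) if x != y)
                    if (sub_len - mm) >= min_identity * sub_len - 1e-9:
                        out.add((start + 1, strand, sub_len, mm))
    return out


def test_match_spacer_equals_brute_force_windows():
    rng = np.random.default_rng(42)
    for case in range(25):
        L = int(rng.integers(20, 36))
        spacer = "".join(rng.choice(list("ACGT"), size=L))
        n_mm = int(rng.integers(0, 4))
        seq, _pos = _plant(spacer if case % 2 == 0 else reverse_complement(spacer),
                           n_mm, rng, flank=40)
        oracle = brute_force_spacer_windows(spacer, seq)
        reported = d.match_spacer(spacer, seq)
        # every reported match is a genuine brute-force window
        for m in reported:
            assert (m.position, m.strand, m.matched_length, m.n_mismatches) in oracle
            assert m.identity >= 0.9 - 1e-9
            assert m.matched_length >= math.ceil(0.9 * L)
        # every brute-force window overlaps some reported match on its strand
        for pos, strand, sub_len, _mm in oracle:
            assert any(m.strand == strand
                       and m.position <= pos + sub_len - 1
                       and pos <= m.position + m.matched_length - 1
                       for m in reported)


def test_planted_protospacer_recall_full_length():
    # 100% recall at <= floor(0.1 L) mismatches on full-length windows
    rng = np.random.default_rng(7)
    for _ in range(20):
        L = int(rng.integers(25, 41))
        spacer = "".join(rng.choice(list("ACGT"), size=L))
        seq, pos = _plant(spacer, int(rng.integers(0, L // 10 + 1)), rng)
        assert any(m.position <= pos + L - 1
                   and pos <= m.position + m.matched_length - 1
                   for m in d.match_spacer(spacer, seq))


# ---------------------------------------------------------------------------
# R-M protein equivalence

def test_rm_equivalent_identical_type_ii_reases():
    seq = "MKLVINSDGSLLLDAKQWERTYIPASDFGHKLMNQV"
    assert d.rm_protein_equivalent(seq, seq, RMRole.REASE, RMType.II)


def test_rm_equivalent_type_i_mtase_needs_80_percent():
    rng = np.random.default_rng(5)
    a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
    b = list(a)
    for pos in rng.choice(100, size=30, replace=False):  # ~70% identity
        b[pos] = rng.choice([x for x in "ACDEFGHIKLMNPQRSTVWY" if x != b[pos]])
    b = "".join(b)
    assert not d.rm_protein_equivalent(a, b, RMRole.MTASE, RMType.I)
    assert d.rm_protein_equivalent(a, b, RMRole.REASE, RMType.II)  # needs only 50%


def test_rm_equivalent_threshold_boundary_type_ii_rease():
    rng = np.random.default_rng(6)
    a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
    b = list(a)
    for pos in rng.choice(100, size=48, replace=False):  # 52% identity
        b[pos] = rng.choice([x for x in "ACDEFGHIKLMNPQRSTVWY" if x != b[pos]])
    b = "".join(b)
    identity = d.global_protein_identity(a, b)
    assert identity >= 0.5  # alignment can only match more, never fewer
    assert d.rm_protein_equivalent(a, b, RMRole.REASE, RMType.II)


def test_rm_equivalent_unknown_combination_errors():
    with pytest.raises(ValueError, match="threshold"):
        d.rm_protein_equivalent("MKL", "MKL", RMRole.MTASE, RMType.IV)
    with pytest.raises(ValueError, match="threshold"):
        d.rm_protein_equivalent("MKL", "MKL", RMRole.OTHER, RMType.II)


def test_global_identity_substitution_only_case():
    # without indels the alignment is the trivial one: identity = matches / L
    a = "MKWVINSDGSLLLDAKQWER"
    b = "MKWVINSDGSLLLDAKQAAA"
    assert d.global_protein_identity(a, b) == pytest.approx(17 / 20)


# ---------------------------------------------------------------------------
# Motif scanning

def test_find_motif_sites_palindrome_reported_once():
    sites = d.find_motif_sites("GAATTC", "AAGAATTCAA")
    assert len(sites) == 1
    assert (sites[0].position, sites[0].strand) == (3, "+")


def test_find_motif_sites_non_palindrome_both_strands():
    motif = "GACGC"
    seq = "TT" + motif + "TTTT" + reverse_complement(motif) + "TT"
    sites = d.find_motif_sites(motif, seq)
    assert {(s.position, s.strand) for s in sites} == {(3, "+"), (12, "-")}


def test_find_motif_sites_iupac_expansion():
    sites = d.find_motif_sites("GANTC", "AAGACTCAA")
    assert [(s.position, s.strand) for s in sites] == [(3, "+")]


def test_find_motif_sites_rejects_bad_motif():
    with pytest.raises(ValueError, match="non-IUPAC"):
        d.find_motif_sites("GAJT", "ACGT")


def brute_force_motif_sites(motif, seq):
    from prophagenet.seq import is_palindrome
    out = set()
    k = len(motif)
    for i in range(len(seq) - k + 1):
        if matches_iupac(motif, seq[i:i + k]):
            out.add((i + 1, "+"))
    if not is_palindrome(motif):
        rc = reverse_complement(motif)
        for i in range(len(seq) - k + 1):
            if matches_iupac(rc, seq[i:i + k]):
                out.add((i + 1, "-"))
    return out


def test_find_motif_sites_equals_brute_force():
    rng = np.random.default_rng(11)
    motifs = ["GAATTC", "GANTC", "GACGC", "CCWGG", "RGATCY", "ACNNGT"]
    for case in range(40):
        motif = motifs[case % len(motifs)]
        seq = "".join(rng.choice(list("ACGT"), size=300))
        # plant a concrete instance forward and one reverse
        inst = (motif.replace("N", "A").replace("W", "A")
                .replace("R", "A").replace("Y", "C"))
        seq = seq[:50] + inst + seq[50:250] + reverse_complement(inst) + seq[250:]
        got = {(s.position, s.strand) for s in d.find_motif_sites(motif, seq)}
        assert got == brute_force_motif_sites(motif, seq)


def test_palindromic_motif_sites_map_under_reverse_complement():
    rng = np.random.default_rng(13)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    seq = seq[:100] + "GAATTC" + seq[100:]
    fwd = d.find_motif_sites("GAATTC", seq)
    rev = d.find_motif_sites("GAATTC", reverse_complement(seq))
    mapped = sorted(len(seq) - (s.position + 6 - 1) + 1 for s in rev)
    assert sorted(s.position for s in fwd) == mapped


# ---------------------------------------------------------------------------
# Targeting inference

def _ecori_system(strain_id, seed=0):
    rng = np.random.default_rng(seed)
    return RMSystem(
        system_id=f"RM_{strain_id}", strain_id=strain_id, rm_type=RMType.II,
        components=[(RMRole.MTASE,
                     "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))),
                    (RMRole.REASE,
                     "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80)))],
        recognition_motif="GAATTC")


def _prophage_with(strain_id, insert, seed=0, length=2000):
    rng = np.random.default_rng(seed)
    # background free of GAATTC so the site count is exactly the insert's
    seq = "".join(rng.choice(list("ACG"), size=length))
    seq = seq[:500] + insert + seq[500:]
    return Prophage(prophage_id=f"P_{strain_id}", host_strain_id=strain_id,
                    start=1, end=len(seq), sequence=seq)


def test_rm_targeting_one_site_vs_two_site_mode():
    systems = [_ecori_system("B")]
    prophages = {"A": [_prophage_with("A", "GAATTC")]}
    one = d.rm_targeting(systems, prophages, ["A", "B"], two_site_mode=False)
    two = d.rm_targeting(systems, prophages, ["A", "B"], two_site_mode=True)
    call_one = next(c for c in one if c.target_strain == "B")
    call_two = next(c for c in two if c.target_strain == "B")
    assert call_one.targeted and call_one.evidence == 1
    assert not call_two.targeted


def test_rm_targeting_equivalent_system_in_producer_excluded():
    shared = _ecori_system("B", seed=1)
    same_in_a = RMSystem(system_id="RM_A", strain_id="A", rm_type=RMType.II,
                         components=list(shared.components),
                         recognition_motif="GAATTC")
    prophages = {"A": [_prophage_with("A", "GAATTC")]}
    calls = d.rm_targeting([shared, same_in_a], prophages, ["A", "B"])
    call = next(c for c in calls if c.target_strain == "B")
    assert not call.targeted


def test_rm_targeting_producer_without_prophages_emits_no_calls():
    calls = d.rm_targeting([_ecori_system("B")], {}, ["A", "B"])
    assert calls == []


def test_rm_two_site_positives_subset_of_one_site(defense_scenario):
    one = d.rm_targeting(defense_scenario.rm_systems,
                         defense_scenario.prophages_by_strain,
                         two_site_mode=False)
    two = d.rm_targeting(defense_scenario.rm_systems,
                         defense_scenario.prophages_by_strain,
                         two_site_mode=True)
    pos_one = {(c.producer_strain, c.target_strain, c.prophage_id)
               for c in one if c.targeted}
    pos_two = {(c.producer_strain, c.target_strain, c.prophage_id)
               for c in two if c.targeted}
    assert pos_two <= pos_one


def test_crispr_targeting_verbatim_spacer():
    rng = np.random.default_rng(21)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    prophage = Prophage("P_A", "A", 1, 1000, sequence=seq)
    spacer = seq[100:132]
    arrays = [CRISPRArray("arr", "B", [spacer, "A" * 32, "C" * 32])]
    calls = d.crispr_targeting(arrays, {"A": [prophage]}, ["A", "B"])
    call = next(c for c in calls if c.target_strain == "B")
    assert call.targeted and call.evidence >= 1


def test_crispr_targeting_no_spacers_all_false():
    rng = np.random.default_rng(22)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    prophage = Prophage("P_A", "A", 1, 500, sequence=seq)
    calls = d.crispr_targeting([], {"A": [prophage]}, ["A", "B"])
    assert calls and not any(c.targeted for c in calls)


def test_crispr_targeting_85_percent_identity_rejected():
    rng = np.random.default_rng(23)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    spacer = list(seq[100:140])  # 40 nt; 6 mismatches -> 85%
    for pos in rng.choice(40, size=6, replace=False):
        spacer[pos] = rng.choice([b for b in "ACGT" if b != spacer[pos]])
    prophage = Prophage("P_A", "A", 1, 1000, sequence=seq)
    arrays = [CRISPRArray("arr", "B", ["".join(spacer), "G" * 32, "T" * 32])]
    calls = d.crispr_targeting(arrays, {"A": [prophage]}, ["A", "B"])
    call = next(c for c in calls if c.target_strain == "B")
    assert not call.targeted


# ---------------------------------------------------------------------------
# Association with the infection matrix

def _matrix(ids, counts):
    return InfectionMatrix(counts=pd.DataFrame(counts, index=ids, columns=ids),
                           n_replicates=3)


def test_defense_association_degenerate_margin():
    from prophagenet.defense import TargetingCall
    ids = ["A", "B"]
    matrix = _matrix(ids, [[0, 0], [0, 0]])
    calls = [TargetingCall("A", "B", "P_A", True, "rm", 1),
             TargetingCall("B", "A", "P_B", True, "rm", 1)]
    res = d.defense_association(matrix, calls)
    assert res.p_two_sided == 1.0
    assert math.isnan(res.odds_ratio)


def test_defense_association_independence_simulation():
    # targeting drawn independently of infection -> OR concentrates near 1
    rng = np.random.default_rng(31)
    from prophagenet.defense import TargetingCall
    ids = [f"S{i}" for i in range(12)]
    log_ors = []
    for _ in range(300):
        counts = rng.binomial(3, 0.3, size=(12, 12))
        matrix = _matrix(ids, counts)
        calls = []
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                targeted = bool(rng.random() < 0.4)
                calls.append(TargetingCall(a, b, f"P_{a}", targeted, "rm",
                                           1 if targeted else 0))
        res = d.defense_association(matrix, calls)
        if np.isfinite(res.odds_ratio) and res.odds_ratio > 0:
            log_ors.append(np.log(res.odds_ratio))
    geo_mean = float(np.exp(np.mean(log_ors)))
    assert 0.8 <= geo_mean <= 1.25


def test_defense_association_disjoint_panels_errors():
    from prophagenet.defense import TargetingCall
    matrix = _matrix(["X", "Y"], [[0, 1], [1, 0]])
    calls = [TargetingCall("A", "B", "P_A", True, "rm", 1)]
    with pytest.raises(ValueError, match="overlap"):
        d.defense_association(matrix, calls)
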