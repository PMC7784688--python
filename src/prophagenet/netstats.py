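"""Statistics on the all-against-all infection matrix.

The infection experiment crosses induced lysates of every strain (producers)
with lawns of every strain (targets) in three replicates. This module
quantifies: per-strain infection scores, replicate reproducibility, whether
infections concentrate within capsule serotype (CLT) modules or LPS
serotypes, whether prophage similarity (superinfection immunity) or defense
targeting explains the outcomes, and the GC deficit of prophages relative
to their host chromosomes.

The exact 2x2 test follows the point-probability two-sided convention: the
p-value sums the hypergeometric probabilities of all tables with the same
margins whose point probability does not exceed that of the observed table
(a 1e-7 relative tolerance guards ties). Computation is exact big-integer
arithmetic, so the enumeration itself never loses precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import InfectionMatrix, Prophage, Strain
from .seq import gc_content
from .wgrr import WgrrMatrix


@dataclass
class ContingencyResult:
    """A 2x2 table with its odds ratio and exact two-sided p-value.

    Odds ratio is (a*d)/(b*c); +inf when b*c == 0 with a*d > 0, NaN when
    both products are zero (degenerate table).
    """

    table: np.ndarray
    odds_ratio: float
    p_two_sided: float
    test_name: str = "fisher_exact"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p-value out of [0,1]")


def fisher_exact_2x2(table) -> ContingencyResult:
    """Exact two-sided Fisher test on a 2x2 contingency table.

    Enumerate all tables with the observed margins; the two-sided p-value is
    the total probability of tables at most as probable as the observed one.
    All arithmetic is exact (integer binomials), with a 1e-7 relative
    tolerance when comparing point probabilities.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("table cells must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise ValueError("negative cell in contingency table")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("all-zero contingency table")

    ad, bc = a * d, b * c
    if bc == 0:
        odds_ratio = math.inf if ad > 0 else math.nan
    else:
        odds_ratio = ad / bc

    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = {k: math.comb(r1, k) * math.comb(r2, c1 - k)
                  for k in range(lo, hi + 1)}
    observed = numerators[a]
    # include tables with P <= P_obs * (1 + 1e-7); integer-exact comparison
    kept = sum(num for num in numerators.values()
               if num * 10_000_000 <= observed * 10_000_001)
    p = float(Fraction(kept, math.comb(n, c1)))
    return ContingencyResult(table=arr, odds_ratio=odds_ratio,
                             p_two_sided=min(p, 1.0))


# ---------------------------------------------------------------------------
# Infection-matrix summaries

def infection_score(matrix: InfectionMatrix, producer: str) -> float:
    """Mean frequency (over all targets, self included) at which a
    producer's lysate cleared a target lawn, pooling replicates."""
    if producer not in matrix.counts.index:
        raise ValueError(f"unknown producer {producer!r}")
    row = matrix.counts.loc[producer]
    return float(row.sum()) / (matrix.n_replicates * len(row))


def infected_pairs(matrix: InfectionMatrix, min_replicates: int = 1) -> pd.DataFrame:
    """Boolean producer x target grid; a pair is infected when at least
    ``min_replicates`` replicates showed clearing."""
    if not 1 <= min_replicates <= matrix.n_replicates:
        raise ValueError("min_replicates out of range")
    return matrix.counts >= min_replicates


@dataclass
class ReproducibilityResult:
    """Fraction of infected pairs positive in every replicate; None when no
    pair was infected. Stratified values are populated when CLT labels are
    supplied."""

    overall: float | None
    n_infected: int
    same_clt: float | None = None
    cross_clt: float | None = None


def replicate_reproducibility(matrix: InfectionMatrix,
                              clt_by_strain: Mapping[str, str] | None = None,
                              ) -> ReproducibilityResult:
    if matrix.n_replicates < 2:
        raise ValueError("reproducibility needs n_replicates >= 2")
    counts = matrix.counts
    infected = counts >= 1
    n_infected = int(infected.to_numpy().sum())
    if n_infected == 0:
        return ReproducibilityResult(overall=None, n_infected=0)
    full = counts == matrix.n_replicates
    overall = int(full.to_numpy().sum()) / n_infected

    same = cross = None
    if clt_by_strain is not None:
        same_n = same_full = cross_n = cross_full = 0
        for p in counts.index:
            for t in counts.columns:
                if not infected.at[p, t]:
                    continue
                is_same = clt_by_strain[p] == clt_by_strain[t]
                if is_same:
                    same_n += 1
                    same_full += int(full.at[p, t])
                else:
                    cross_n += 1
                    cross_full += int(full.at[p, t])
        same = same_full / same_n if same_n else None
        cross = cross_full / cross_n if cross_n else None
    return ReproducibilityResult(overall=overall, n_infected=n_infected,
                                 same_clt=same, cross_clt=cross)


# ---------------------------------------------------------------------------
# Serotype modularity

def _label_contingency(matrix: InfectionMatrix, label_by_strain: Mapping[str, str],
                       include_self: bool, label_kind: str) -> np.ndarray:
    for sid in list(matrix.producers) + list(matrix.targets):
        if sid not in label_by_strain:
            raise ValueError(f"strain {sid!r} lacks a {label_kind} label")
    table = np.zeros((2, 2), dtype=int)
    infected = matrix.counts >= 1
    for p in matrix.producers:
        for t in matrix.targets:
            if not include_self and p == t:
                continue
            same = label_by_strain[p] == label_by_strain[t]
            inf = bool(infected.at[p, t])
            table[0 if same else 1][0 if inf else 1] += 1
    return table


def clt_contingency(matrix: InfectionMatrix, clt_by_strain: Mapping[str, str],
                    include_self: bool = True) -> np.ndarray:
    """2x2 table (rows: same-CLT / cross-CLT ordered pairs; columns:
    infected / not infected)."""
    return _label_contingency(matrix, clt_by_strain, include_self, "CLT")


def clt_association(matrix: InfectionMatrix, clt_by_strain: Mapping[str, str],
                    include_self: bool = True) -> ContingencyResult:
    """Fisher's exact test of capsule-serotype modularity."""
    return fisher_exact_2x2(clt_contingency(matrix, clt_by_strain, include_self))


def lps_contingency(matrix: InfectionMatrix, lps_by_strain: Mapping[str, str],
                    include_self: bool = True) -> ContingencyResult:
    """Same construction as the CLT analysis, with LPS (O-locus) labels."""
    table = _label_contingency(matrix, lps_by_strain, include_self, "LPS")
    return fisher_exact_2x2(table)


# ---------------------------------------------------------------------------
# Superinfection-immunity proxies

def prophage_similarity_association(matrix: InfectionMatrix,
                                    wgrr: WgrrMatrix,
                                    prophages_by_strain: Mapping[str, Sequence],
                                    threshold: float = 0.5) -> ContingencyResult:
    """Association between infection outcome and the target already carrying
    a prophage similar (wGRR strictly above ``threshold``) to one of the
    producer's prophages."""
    def ids_of(strain: str) -> list[str]:
        out = []
        for p in prophages_by_strain.get(strain, []):
            out.append(p.prophage_id if isinstance(p, Prophage) else str(p))
        return out

    table = np.zeros((2, 2), dtype=int)
    infected = matrix.counts >= 1
    for a in matrix.producers:
        for b in matrix.targets:
            if a == b:
                continue
            exposed = False
            for pa in ids_of(a):
                for pb in ids_of(b):
                    if pa in wgrr.values.index and pb in wgrr.values.index \
                            and wgrr.get(pa, pb) > threshold:
                        exposed = True
                        break
                if exposed:
                    break
            table[0 if exposed else 1][0 if bool(infected.at[a, b]) else 1] += 1
    return fisher_exact_2x2(table)


def repressor_pair_fraction(wgrr: WgrrMatrix,
                            repressor_similarities: Mapping[tuple[str, str], float],
                            wgrr_max: float = 0.5, rep_min: float = 0.8) -> float:
    """Fraction of prophage pairs that are dissimilar overall (wGRR below
    ``wgrr_max``) yet have similar repressors (similarity above ``rep_min``)
    — the pairs where superinfection immunity could act without overall
    genome similarity."""
    sims = {frozenset(k): v for k, v in repressor_similarities.items()}
    ids = list(wgrr.values.index)
    total = qualifying = 0
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            total += 1
            rep = sims.get(frozenset((a, b)))
            if rep is not None and wgrr.get(a, b) < wgrr_max and rep > rep_min:
                qualifying += 1
    return qualifying / total if total else 0.0


# ---------------------------------------------------------------------------
# Rank correlation and GC comparison

@dataclass
class SpearmanResult:
    rho: float | None
    p_value: float | None
    n_permutations: int = 0


def spearman_rho(x: Sequence[float], y: Sequence[float],
                 n_permutations: int = 9999, seed: int = 0) -> SpearmanResult:
    """Spearman correlation (mid-rank Pearson) with a seeded two-sided
    permutation p-value; constant input yields a flagged null result."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=None, p_value=None)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ry)
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return SpearmanResult(rho=rho, p_value=p, n_permutations=n_permutations)


@dataclass
class GcComparisonResult:
    median_difference_points: float  # prophage minus host chromosome, in % points
    p_value: float
    n_pairs: int


def gc_comparison(prophages: Iterable[Prophage],
                  strains: Iterable[Strain] | Mapping[str, Strain],
                  ) -> GcComparisonResult:
    """Paired comparison of prophage GC content against the host chromosome.

    Differences (prophage - host, in percentage points) are tested with the
    two-sided Wilcoxon signed-rank test: exact null for n <= 25 without
    zero differences, normal approximation with continuity correction
    otherwise.
    """
    if not isinstance(strains, Mapping):
        strains = {s.strain_id: s for s in strains}
    diffs = []
    for p in prophages:
        if p.sequence is None:
            continue
        host = strains.get(p.host_strain_id)
        if host is None or host.chromosome_gc is None:
            continue
        diffs.append((gc_content(p.sequence) - host.chromosome_gc) * 100.0)
    if len(diffs) < 5:
        raise ValueError("insufficient pairs (need >= 5 prophage/host GC pairs)")
    diffs = np.asarray(diffs)
    median = float(np.median(diffs))
    if np.all(diffs == 0):
        return GcComparisonResult(median_difference_points=0.0, p_value=1.0,
                                  n_pairs=len(diffs))
    method = "exact" if (len(diffs) <= 25 and not np.any(diffs == 0)) else "approx"
    res = stats.wilcoxon(diffs, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return GcComparisonResult(median_difference_points=median,
                              p_value=float(res.pvalue), n_pairs=len(diffs))
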