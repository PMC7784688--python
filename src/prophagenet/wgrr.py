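"""Weighted gene repertoire relatedness (wGRR) between prophages.

For two prophages A and B with #A and #B proteins and p reciprocal-best-hit
(BBH) homolog pairs::

    wGRR(A, B) = sum_i id(A_i, B_i) / min(#A, #B)

where id(A_i, B_i) is the identity fraction of pair i. The score is 0 with
no homologs and 1 when every protein of the smaller prophage has a
100%-identical reciprocal best hit in the other. Hits are pre-filtered
(e-value < 1e-4, identity >= 35%, coverage >= 50% on both proteins) before
BBH computation, mirroring standard comparative-genomics practice.

A similarity network connects prophage pairs whose wGRR strictly exceeds a
threshold (default 0.5).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .types import BBHPair, HomologyHit, ProphageProteome

#: Hit-filter defaults.
MAX_EVALUE = 1e-4
MIN_IDENTITY_PCT = 35.0
MIN_COVERAGE = 0.5


@dataclass
class WgrrResult:
    """wGRR score for one prophage pair; symmetric in (a, b)."""

    prophage_a: str
    prophage_b: str
    n_bbh_pairs: int
    wgrr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.wgrr <= 1.0:
            raise ValueError(f"wgrr {self.wgrr} out of [0,1]")
        if (self.wgrr == 0.0) != (self.n_bbh_pairs == 0) and self.wgrr == 0.0:
            raise ValueError("wgrr 0 requires zero BBH pairs")


def filter_hits(hits: Iterable[HomologyHit],
                max_evalue: float = MAX_EVALUE,
                min_identity_pct: float = MIN_IDENTITY_PCT,
                min_coverage: float = MIN_COVERAGE,
                coverage_mode: str = "both") -> list[HomologyHit]:
    """Keep hits with e-value strictly below ``max_evalue``, identity at
    least ``min_identity_pct``, and coverage at least ``min_coverage``.

    ``coverage_mode`` is "both" (query and subject, the stricter standard BBH
    reading) or "query" (query-side only).
    """
    if coverage_mode not in ("both", "query"):
        raise ValueError("coverage_mode must be 'both' or 'query'")
    out = []
    for h in hits:
        if h.evalue >= max_evalue or h.pct_identity < min_identity_pct:
            continue
        if h.query_coverage < min_coverage:
            continue
        if coverage_mode == "both" and h.subject_coverage < min_coverage:
            continue
        out.append(h)
    return out


def _protein_index(proteomes: Mapping[str, ProphageProteome]) -> dict[str, str]:
    index: dict[str, str] = {}
    for pid, proteome in proteomes.items():
        for prot in proteome.proteins:
            if prot.protein_id in index:
                raise ValueError(f"protein {prot.protein_id} assigned to multiple prophages")
            index[prot.protein_id] = pid
    return index


def _hit_rank(h: HomologyHit) -> tuple:
    # Higher bitscore, then lower e-value, then higher identity, then
    # lexicographically smaller subject id.
    return (-h.bitscore, h.evalue, -h.pct_identity, h.subject_id)


def best_hits(filtered: Iterable[HomologyHit],
              proteomes: Mapping[str, ProphageProteome],
              ) -> dict[tuple[str, str], HomologyHit]:
    """Best hit of each protein into each *other* prophage.

    Returns a map (query protein id, subject prophage id) -> HomologyHit.
    Ties on bitscore break by lower e-value, then higher identity, then
    lexicographically smaller subject id. Hits within one prophage are
    ignored.
    """
    index = _protein_index(proteomes)
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in filtered:
        if h.query_id not in index:
            raise ValueError(f"protein {h.query_id} not in any proteome")
        if h.subject_id not in index:
            raise ValueError(f"protein {h.subject_id} not in any proteome")
        q_phage, s_phage = index[h.query_id], index[h.subject_id]
        if q_phage == s_phage:
            continue
        key = (h.query_id, s_phage)
        if key not in best or _hit_rank(h) < _hit_rank(best[key]):
            best[key] = h
    return best


def bidirectional_best_hits(best: Mapping[tuple[str, str], HomologyHit],
                            proteomes: Mapping[str, ProphageProteome],
                            prophage_a: str, prophage_b: str) -> list[BBHPair]:
    """Reciprocal best hits between two prophages.

    A pair (x in A, y in B) is kept iff x's best hit into B is y and y's
    best hit into A is x. The pair identity is the arithmetic mean of the
    two directional identities (they can differ when alignments differ).
    """
    pairs: list[BBHPair] = []
    for prot in proteomes[prophage_a].proteins:
        fwd = best.get((prot.protein_id, prophage_b))
        if fwd is None:
            continue
        rev = best.get((fwd.subject_id, prophage_a))
        if rev is not None and rev.subject_id == prot.protein_id:
            pairs.append(BBHPair(
                protein_a=prot.protein_id, protein_b=fwd.subject_id,
                identity=(fwd.pct_identity + rev.pct_identity) / 2.0,
            ))
    return pairs


def wgrr(pairs: list[BBHPair], n_a: int, n_b: int,
         prophage_a: str = "A", prophage_b: str = "B") -> WgrrResult:
    """Compute the wGRR score from BBH pairs and the two proteome sizes.

    Identities are percents and are converted to fractions inside the sum,
    so e.g. 3 pairs at 100% over min(#A,#B)=100 gives 0.03.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("proteome sizes must be >= 1")
    m = min(n_a, n_b)
    if len(pairs) > m:
        raise ValueError(
            f"{len(pairs)} BBH pairs exceed min proteome size {m} "
            "(violates one-pair-per-protein)")
    score = sum(p.identity / 100.0 for p in pairs) / m
    return WgrrResult(prophage_a=prophage_a, prophage_b=prophage_b,
                      n_bbh_pairs=len(pairs), wgrr=score)


@dataclass
class WgrrMatrix:
    """All-against-all wGRR results: a symmetric value grid (diagonal 1.0 by
    convention) plus the per-pair results keyed by sorted id pair."""

    values: pd.DataFrame
    results: dict[tuple[str, str], WgrrResult]

    def get(self, a: str, b: str) -> float:
        return float(self.values.at[a, b])

    def to_long(self) -> pd.DataFrame:
        rows = [{"prophage_a": r.prophage_a, "prophage_b": r.prophage_b,
                 "n_bbh": r.n_bbh_pairs, "wgrr": r.wgrr}
                for r in self.results.values()]
        return pd.DataFrame(rows, columns=["prophage_a", "prophage_b", "n_bbh", "wgrr"])


def wgrr_matrix(proteomes: Mapping[str, ProphageProteome],
                hits: Iterable[HomologyHit],
                max_evalue: float = MAX_EVALUE,
                min_identity_pct: float = MIN_IDENTITY_PCT,
                min_coverage: float = MIN_COVERAGE,
                coverage_mode: str = "both") -> WgrrMatrix:
    """Filter hits, compute BBHs, and assemble the symmetric wGRR grid."""
    ids = sorted(proteomes)
    filtered = filter_hits(hits, max_evalue, min_identity_pct, min_coverage,
                           coverage_mode)
    best = best_hits(filtered, proteomes)
    values = pd.DataFrame(0.0, index=ids, columns=ids)
    results: dict[tuple[str, str], WgrrResult] = {}
    for a in ids:
        values.at[a, a] = 1.0
    for a, b in itertools.combinations(ids, 2):
        pairs = bidirectional_best_hits(best, proteomes, a, b)
        res = wgrr(pairs, proteomes[a].n_proteins, proteomes[b].n_proteins,
                   prophage_a=a, prophage_b=b)
        results[(a, b)] = res
        values.at[a, b] = res.wgrr
        values.at[b, a] = res.wgrr
    return WgrrMatrix(values=values, results=results)


def similarity_network(matrix: WgrrMatrix, threshold: float = 0.5) -> nx.Graph:
    """Undirected network with an edge for every pair with wGRR strictly
    above ``threshold`` ("higher than 50%" for the default)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0,1]")
    g = nx.Graph()
    g.add_nodes_from(matrix.values.index)
    for (a, b), res in matrix.results.items():
        if res.wgrr > threshold:
            g.add_edge(a, b, wgrr=res.wgrr, n_bbh=res.n_bbh_pairs)
    return g


def network_edge_list(graph: nx.Graph) -> pd.DataFrame:
    rows = [{"prophage_a": a, "prophage_b": b, "wgrr": d["wgrr"]}
            for a, b, d in sorted(graph.edges(data=True))]
    return pd.DataFrame(rows, columns=["prophage_a", "prophage_b", "wgrr"])
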