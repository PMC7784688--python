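"""Capsule-loss trajectory analysis.

Evolution experiments track the fraction of capsulated clones in serially
passaged populations under four environments (LB, LB + citrate, MMC,
MMC + citrate). Most capsule loss happens early, so populations are
summarized by the area under the capsulated-fraction curve over the first
five days (trapezoidal rule on daily samples); smaller AUC means faster
loss. Treatments are compared per strain with the exact Mann-Whitney U
test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import Trajectory, Treatment

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 5


@dataclass
class AucResult:
    population_id: str
    treatment: Treatment
    auc: float
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= self.window + 1e-12:
            raise ValueError(f"AUC {self.auc} out of [0, {self.window}]")


def capsule_auc(traj: Trajectory, window: int = DEFAULT_WINDOW) -> AucResult:
    """Trapezoidal integral of the capsulated fraction over days [0, window].

    A missing day 0 defaults to a fully capsulated founder population (1.0);
    missing interior days are linearly interpolated (logged). Fewer than two
    observed points inside the window is an error.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    in_window = {d: f for d, f in traj.values.items() if 0 <= d <= window}
    if 0 not in in_window:
        in_window[0] = 1.0
        logger.info("population %s: day 0 missing, assuming fully capsulated founders",
                    traj.population_id)
    if len([d for d in in_window if d in traj.values]) < 2:
        raise ValueError(
            f"population {traj.population_id}: fewer than 2 points in window")
    days = sorted(in_window)
    if days[-1] < window:
        raise ValueError(
            f"population {traj.population_id}: trajectory ends at day {days[-1]}, "
            f"before the window end {window}")
    missing = [d for d in range(window + 1) if d not in in_window]
    if missing:
        logger.warning("population %s: interpolating missing days %s",
                       traj.population_id, missing)
    grid = np.arange(window + 1)
    values = np.interp(grid, days, [in_window[d] for d in days])
    auc = float(np.trapezoid(values, grid))
    return AucResult(population_id=traj.population_id, treatment=traj.treatment,
                     auc=auc, window=window)


@dataclass
class TreatmentComparison:
    u_statistic: float
    p_two_sided: float
    n_a: int
    n_b: int
    method: str


def compare_treatments(aucs_a: Sequence[float], aucs_b: Sequence[float],
                       ) -> TreatmentComparison:
    """Two-sided Mann-Whitney U between two groups of per-population AUCs:
    exact distribution for combined n <= 20, normal approximation with tie
    correction otherwise."""
    if len(aucs_a) < 3 or len(aucs_b) < 3:
        raise ValueError("each group needs at least 3 populations")
    method = "exact" if len(aucs_a) + len(aucs_b) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(aucs_a, aucs_b, alternative="two-sided",
                             method=method)
    return TreatmentComparison(u_statistic=float(res.statistic),
                               p_two_sided=float(res.pvalue),
                               n_a=len(aucs_a), n_b=len(aucs_b), method=method)


def loss_rate_summary(trajectories: Iterable[Trajectory],
                      window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Mean +/- SD of per-population AUC for every strain x treatment group."""
    rows = []
    for t in trajectories:
        res = capsule_auc(t, window)
        rows.append({"strain_id": t.strain_id, "treatment": t.treatment.value,
                     "population_id": t.population_id, "auc": res.auc})
    if not rows:
        return pd.DataFrame(columns=["strain_id", "treatment", "n_populations",
                                     "mean_auc", "sd_auc"])
    df = pd.DataFrame(rows)
    grouped = df.groupby(["strain_id", "treatment"], sort=True)["auc"]
    out = grouped.agg(n_populations="count", mean_auc="mean",
                      sd_auc=lambda s: float(np.std(s, ddof=1)) if len(s) > 1 else 0.0)
    return out.reset_index()


def pairwise_treatment_tests(trajectories: Iterable[Trajectory],
                             window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """All pairwise treatment comparisons within each strain (only groups
    with >= 3 populations are compared)."""
    aucs: dict[tuple[str, str], list[float]] = {}
    for t in trajectories:
        res = capsule_auc(t, window)
        aucs.setdefault((t.strain_id, t.treatment.value), []).append(res.auc)
    rows = []
    strains = sorted({k[0] for k in aucs})
    for strain in strains:
        groups = {treat: v for (s, treat), v in aucs.items() if s == strain}
        for ta, tb in itertools.combinations(sorted(groups), 2):
            if len(groups[ta]) < 3 or len(groups[tb]) < 3:
                continue
            cmp = compare_treatments(groups[ta], groups[tb])
            rows.append({"strain_id": strain, "treatment_a": ta, "treatment_b": tb,
                         "mean_auc_a": float(np.mean(groups[ta])),
                         "mean_auc_b": float(np.mean(groups[tb])),
                         "u_statistic": cmp.u_statistic,
                         "p_two_sided": cmp.p_two_sided, "method": cmp.method})
    return pd.DataFrame(rows, columns=["strain_id", "treatment_a", "treatment_b",
                                       "mean_auc_a", "mean_auc_b", "u_statistic",
                                       "p_two_sided", "method"])
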