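"""Chromosome-wide activity map: positional structure and Y-paralogue tests.

The activity map orders per-locus escape estimates along the X chromosome.
If inactivation spread from an inactivation center, escape frequency would
show polarity (a trend along the chromosome) or clustering (neighbors more
alike than distant loci). Both are tested with rank-based permutation nulls,
shuffling estimates across map positions. A third permutation test asks
whether escape frequency differs between loci grouped by the expression
status of their Y-chromosome paralogue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .escape import EscapeEstimate
from .locus_model import LocusMeta, YParalogue

__all__ = [
    "ActivityMap",
    "PositionTestResult",
    "AssociationResult",
    "build_map",
    "polarity_test",
    "y_paralogue_association",
]

MIN_LOCI_FOR_POSITION_TEST = 5


@dataclass(frozen=True)
class PositionTestResult:
    statistic_name: str
    statistic_value: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class AssociationResult:
    """Rank-based permutation test of escape frequency across Y-status groups."""

    statistic_value: float
    p_value: float
    n_permutations: int
    seed: int
    group_means: dict[str, float]
    group_sizes: dict[str, int]


@dataclass(frozen=True)
class ActivityMap:
    """Escape estimates ordered along the chromosome."""

    entries: tuple[tuple[LocusMeta, EscapeEstimate], ...]

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.x_position for m, _ in self.entries], dtype=float)

    def values(self, corrected: bool = False) -> np.ndarray:
        return np.array(
            [e.e_corrected if corrected else e.e_raw for _, e in self.entries]
        )


def build_map(
    metas: Sequence[LocusMeta], estimates: Sequence[EscapeEstimate]
) -> ActivityMap:
    """Join metadata with estimates and order by chromosome position.

    Loci lacking a position, or lacking either side of the join, are dropped
    with a warning. Duplicate positions are tie-broken by locus_id.
    """
    meta_by_id = {m.locus_id: m for m in metas}
    pairs: list[tuple[LocusMeta, EscapeEstimate]] = []
    for est in estimates:
        meta = meta_by_id.get(est.locus_id)
        if meta is None:
            warnings.warn(f"no metadata for locus {est.locus_id}; dropped", stacklevel=2)
            continue
        if meta.x_position is None:
            warnings.warn(f"locus {est.locus_id} has no position; dropped", stacklevel=2)
            continue
        pairs.append((meta, est))
    positions = [m.x_position for m, _ in pairs]
    if len(set(positions)) < len(positions):
        warnings.warn("duplicate map positions; tie-broken by locus_id", stacklevel=2)
    pairs.sort(key=lambda p: (p[0].x_position, p[0].locus_id))
    return ActivityMap(entries=tuple(pairs))


def _rank_z(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x)
    return (r - r.mean()) / r.std()


def polarity_test(
    amap: ActivityMap,
    n_permutations: int = 9999,
    seed: int = 0,
    corrected: bool = False,
) -> dict[str, PositionTestResult]:
    """Permutation tests for positional structure of escape frequency.

    Two statistics, each referred to the null that escape estimates are
    exchangeable across map positions (estimates permuted, positions fixed):

    - ``trend``: Spearman rank correlation of escape frequency with position
      (polarity from one chromosome end); two-sided.
    - ``adjacency``: mean absolute difference of escape frequency between
      map-adjacent loci (clustering; small values mean neighbors are alike);
      one-sided, small = extreme.

    Permutation p-values use the add-one rule (1 + #extreme) / (1 + n_perm),
    so they are never exactly zero.
    """
    k = len(amap.entries)
    if k < MIN_LOCI_FOR_POSITION_TEST:
        raise ValueError(
            f"polarity test needs >= {MIN_LOCI_FOR_POSITION_TEST} mapped loci, got {k}"
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")
    rng = np.random.default_rng(seed)
    values = amap.values(corrected=corrected)

    pos_z = _rank_z(amap.positions)
    val_ranks = stats.rankdata(values)
    val_z = (val_ranks - val_ranks.mean()) / val_ranks.std()
    rho_obs = float(val_z @ pos_z) / k
    adj_obs = float(np.abs(np.diff(values)).mean())

    perm = np.tile(values, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    perm_ranks = stats.rankdata(perm, axis=1)
    perm_z = (perm_ranks - perm_ranks.mean(axis=1, keepdims=True)) / perm_ranks.std(
        axis=1, keepdims=True
    )
    rho_perm = (perm_z @ pos_z) / k
    adj_perm = np.abs(np.diff(perm, axis=1)).mean(axis=1)

    p_trend = (1 + int(np.sum(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))) / (
        1 + n_permutations
    )
    p_adj = (1 + int(np.sum(adj_perm <= adj_obs + 1e-12))) / (1 + n_permutations)
    return {
        "trend": PositionTestResult(
            statistic_name="spearman_rho_vs_position",
            statistic_value=rho_obs,
            p_value=p_trend,
            n_permutations=n_permutations,
            seed=seed,
        ),
        "adjacency": PositionTestResult(
            statistic_name="mean_abs_adjacent_difference",
            statistic_value=adj_obs,
            p_value=p_adj,
            n_permutations=n_permutations,
            seed=seed,
        ),
    }


def y_paralogue_association(
    amap: ActivityMap,
    n_permutations: int = 9999,
    seed: int = 0,
    corrected: bool = False,
) -> AssociationResult:
    """Test association of escape frequency with Y-paralogue status.

    Statistic: between-group sum of squared deviations of group mean ranks
    from the overall mean rank, weighted by group size (the Kruskal-Wallis
    numerator); null distribution from permuting group labels. Groups with no
    members are collapsed away with a notice.
    """
    labels = np.array([m.y_paralogue.value for m, _ in amap.entries])
    values = amap.values(corrected=corrected)
    groups = [g.value for g in YParalogue if (labels == g.value).any()]
    if len(groups) < 2:
        raise ValueError("Y-paralogue association needs >= 2 non-empty groups")
    if len(groups) < len(YParalogue):
        warnings.warn(
            f"collapsed to available Y-status groups: {groups}", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(values)
    grand = ranks.mean()
    masks = [labels == g for g in groups]

    def stat(r: np.ndarray) -> float:
        return float(
            sum(m.sum() * (r[m].mean() - grand) ** 2 for m in masks)
        )

    obs = stat(ranks)
    perm_stats = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_stats[i] = stat(rng.permutation(ranks))
    p = (1 + int(np.sum(perm_stats >= obs - 1e-12))) / (1 + n_permutations)
    return AssociationResult(
        statistic_value=obs,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        group_means={
            g: float(values[m].mean()) for g, m in zip(groups, masks)
        },
        group_sizes={g: int(m.sum()) for g, m in zip(groups, masks)},
    )
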