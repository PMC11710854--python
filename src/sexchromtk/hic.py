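"""Hi-C-based assignment of unplaced scaffolds to chromosomes or PAR status.

Under the standard Hi-C assumption that intra-chromosomal contacts are
stronger than inter-chromosomal ones, a scaffold belongs to a chromosome
when its bin-level interaction strengths with that chromosome are
stochastically greater than with every competitor (one-sided Wilcoxon
rank-sum per competitor, all tests significant).  The pair variant pools
the scaffold's interactions with two chromosomes flanking a candidate PAR
and applies the same all-competitor rule.  Being rank-based, decisions are
invariant under global rescaling of strengths, so raw (unbalanced)
matrices are accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import InteractionSet

__all__ = [
    "AssignmentResult",
    "interaction_profile",
    "wilcoxon_one_sided",
    "assign_single",
    "assign_pair",
]


@dataclass(frozen=True)
class AssignmentResult:
    scaffold: str
    mode: str  # single_target | pair_target
    targets: tuple[str, ...]
    p_values: dict[str, float]
    decision: str  # assigned | unassigned
    alpha: float


def interaction_profile(
    interactions: InteractionSet,
    scaffold: str,
    chrom: str,
    dense: bool = False,
    chrom_sizes: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Strengths of all (scaffold bin, chromosome bin) pairs.

    Sparse by default: only observed record pairs contribute.  With
    ``dense=True`` every bin pair is represented, absent ones as 0
    (requires ``chrom_sizes`` for both sequences).
    """
    df = interactions.records
    if scaffold not in set(df["chrom_a"]) | set(df["chrom_b"]):
        raise ValueError(f"scaffold {scaffold!r} absent from interaction records")
    fwd = df[(df["chrom_a"] == scaffold) & (df["chrom_b"] == chrom)]
    rev = df[(df["chrom_b"] == scaffold) & (df["chrom_a"] == chrom)]
    strengths = np.concatenate([fwd["strength"].to_numpy(), rev["strength"].to_numpy()])
    if not dense:
        return strengths
    if chrom_sizes is None:
        raise ValueError("dense profiles need chrom_sizes")
    res = interactions.resolution
    n_pairs = -(-chrom_sizes[scaffold] // res) * -(-chrom_sizes[chrom] // res)
    if len(strengths) > n_pairs:
        raise ValueError("more records than bin pairs; resolution mismatch?")
    return np.concatenate([strengths, np.zeros(n_pairs - len(strengths))])


def wilcoxon_one_sided(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> float:
    """One-sided Wilcoxon rank-sum p-value for H1: x stochastically greater.

    With ``method="auto"``: exact enumeration when the pooled sample is
    small (n+m <= 16) and tie-free, otherwise the normal approximation
    with tie and continuity corrections.  Either path can be forced.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        small = len(pooled) <= 16 and len(np.unique(pooled)) == len(pooled)
        method = "exact" if small else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue)


def _assign(
    interactions: InteractionSet,
    scaffold: str,
    targets: tuple[str, ...],
    competitors: Sequence[str],
    alpha: float,
    mode: str,
    pooled: bool,
) -> AssignmentResult:
    for t in targets:
        if t in competitors:
            raise ValueError(f"target {t!r} also listed as competitor")
    if alpha >= 1.0:
        warnings.warn("alpha >= 1 assigns everything; result is degenerate")
    target_profile = np.concatenate(
        [interaction_profile(interactions, scaffold, t) for t in targets]
    )
    p_values: dict[str, float] = {}
    for comp in competitors:
        comp_profile = interaction_profile(interactions, scaffold, comp)
        if len(target_profile) == 0 or len(comp_profile) == 0:
            p_values[comp] = 1.0
            continue
        if pooled:
            p_values[comp] = wilcoxon_one_sided(target_profile, comp_profile)
        else:
            # per-target AND rule: every member of the pair must beat the competitor
            p_values[comp] = max(
                wilcoxon_one_sided(
                    interaction_profile(interactions, scaffold, t), comp_profile
                )
                for t in targets
            )
    decision = "assigned" if p_values and all(p < alpha for p in p_values.values()) else "unassigned"
    if not competitors:
        decision = "unassigned"
    return AssignmentResult(scaffold, mode, targets, p_values, decision, alpha)


def assign_single(
    interactions: InteractionSet,
    scaffold: str,
    candidate: str,
    competitors: Sequence[str],
    alpha: float = 0.05,
) -> AssignmentResult:
    """Assign a scaffold to one chromosome if its interactions with it are
    significantly higher than with every competitor chromosome."""
    return _assign(interactions, scaffold, (candidate,), competitors, alpha,
                   "single_target", pooled=True)


def assign_pair(
    interactions: InteractionSet,
    scaffold: str,
    pair: tuple[str, str],
    competitors: Sequence[str],
    alpha: float = 0.05,
    pooled: bool = True,
) -> AssignmentResult:
    """PAR test: the scaffold's pooled interactions with both members of
    ``pair`` must significantly exceed those with every competitor.

    ``pooled=False`` switches to a per-chromosome AND rule (each member of
    the pair must separately beat each competitor).
    """
    return _assign(interactions, scaffold, tuple(pair), competitors, alpha,
                   "pair_target", pooled=pooled)
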