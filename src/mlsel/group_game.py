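"""Deterministic group-reproduction game with tunable assortment.

The interaction rule inside a group: each cooperator gives birth to one
cooperator offspring and helps every *other* group member to sire one
additional offspring, then dies; each cheater gives birth to two cheater
offspring and helps nobody, then dies.  For a group with ``c``
cooperators and ``d`` cheaters the offspring counts are closed-form::

    c' = c + c*(c - 1)       = c**2
    d' = 2*d + c*d           = d*(2 + c)

Cooperator frequency always falls *within* a mixed group (cheaters get
the help without paying), yet the community-wide frequency can rise when
groups vary enough in initial cooperator frequency — the Price
covariance term outweighs the within-group decline.  Group formation
schemes control that variance; a group-culling operator removes groups
below a cooperator-frequency threshold (selective abortion of
cheater-dominated substructures: partner choice at the community level,
partner fidelity feedback at the group level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .price import GroupRecord, PriceDecomposition, price_decompose

__all__ = [
    "GroupComposition",
    "AssortmentScheme",
    "reproduce_group",
    "form_groups",
    "cull_groups",
    "run_generations",
    "GenerationsResult",
    "CULL_ANNOTATION",
]

# Dual reading of the culling operator at two entity levels.
CULL_ANNOTATION = {
    "community↔groups": "PC",
    "group↔members": "PFF",
}


@dataclass(frozen=True)
class GroupComposition:
    """Cooperator/cheater counts of one interaction group."""

    cooperators: int
    cheaters: int

    def __post_init__(self) -> None:
        if self.cooperators < 0 or self.cheaters < 0:
            raise ValueError("counts must be non-negative")

    @property
    def size(self) -> int:
        return self.cooperators + self.cheaters

    @property
    def cooperator_freq(self) -> Fraction:
        if self.size == 0:
            raise ValueError("empty group has no cooperator frequency")
        return Fraction(self.cooperators, self.size)


@dataclass(frozen=True)
class AssortmentScheme:
    """How a pooled population is partitioned into interaction groups.

    scheme
        ``"random"`` — shuffle individuals and chunk into groups of
        ``group_size`` (multivariate hypergeometric composition);
        ``"fixed-counts"`` — explicit per-group cooperator counts, each
        group filled to ``group_size`` with cheaters;
        ``"perfect-segregation"`` — cooperators and cheaters in separate
        groups (maximal across-group variance).
    """

    scheme: str = "random"
    group_size: int = 6
    cooperator_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("random", "fixed-counts", "perfect-segregation"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.scheme == "fixed-counts" and not self.cooperator_counts:
            raise ValueError("fixed-counts scheme requires cooperator_counts")


def reproduce_group(g: GroupComposition) -> GroupComposition:
    """One bout of interaction and reproduction; parents die.

    (c, d) -> (c**2, d*(2+c)).  Raises on an empty group.
    """
    if g.size == 0:
        raise ValueError("cannot reproduce an empty group")
    c, d = g.cooperators, g.cheaters
    return GroupComposition(c * c, d * (2 + c))


def form_groups(
    total_cooperators: int,
    total_cheaters: int,
    scheme: AssortmentScheme,
    rng: np.random.Generator | None = None,
) -> list[GroupComposition]:
    """Partition a pooled population into interaction groups.

    Conserves individuals exactly.  A remainder that does not fill a
    complete group forms a final smaller group.  The random scheme needs
    an ``rng``.
    """
    if total_cooperators < 0 or total_cheaters < 0:
        raise ValueError("totals must be non-negative")
    n = total_cooperators + total_cheaters
    if n == 0:
        return []
    if scheme.group_size > n:
        raise ValueError(f"group_size {scheme.group_size} exceeds population size {n}")

    if scheme.scheme == "fixed-counts":
        counts = scheme.cooperator_counts
        if sum(counts) != total_cooperators:
            raise ValueError(
                f"fixed counts {counts} sum to {sum(counts)}, not {total_cooperators}"
            )
        if any(k > scheme.group_size or k < 0 for k in counts):
            raise ValueError("each fixed count must lie in [0, group_size]")
        need_cheaters = len(counts) * scheme.group_size - total_cooperators
        if need_cheaters != total_cheaters:
            raise ValueError(
                f"fixed-counts groups need {need_cheaters} cheaters, have {total_cheaters}"
            )
        return [GroupComposition(k, scheme.group_size - k) for k in counts]

    if scheme.scheme == "perfect-segregation":
        groups: list[GroupComposition] = []
        for count, is_coop in ((total_cooperators, True), (total_cheaters, False)):
            while count > 0:
                take = min(scheme.group_size, count)
                groups.append(
                    GroupComposition(take, 0) if is_coop else GroupComposition(0, take)
                )
                count -= take
        return groups

    # random: shuffle and chunk
    if rng is None:
        raise ValueError("random scheme requires an rng (seeded for reproducibility)")
    members = np.zeros(n, dtype=np.int64)
    members[:total_cooperators] = 1
    rng.shuffle(members)
    groups = []
    for start in range(0, n, scheme.group_size):
        chunk = members[start : start + scheme.group_size]
        c = int(chunk.sum())
        groups.append(GroupComposition(c, len(chunk) - c))
    return groups


def cull_groups(
    groups: Sequence[GroupComposition], min_cooperator_freq: float
) -> list[GroupComposition]:
    """Remove groups whose initial cooperator frequency is strictly below
    the threshold (all their members die); survivors are unchanged.

    Selective abortion of cheater-dominated substructures.  The operator
    reads as partner choice at the whole-community level and as partner
    fidelity feedback at the group level (``CULL_ANNOTATION``).
    """
    if not 0 <= min_cooperator_freq <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return [
        g for g in groups if g.size > 0 and g.cooperator_freq >= Fraction(min_cooperator_freq)
    ]


@dataclass
class GenerationsResult:
    """Per-generation trajectory of a multi-generation community run."""

    history: pd.DataFrame
    decompositions: list[PriceDecomposition]
    extinct: bool = False
    final_cooperators: int = 0
    final_cheaters: int = 0


def run_generations(
    initial_cooperators: int,
    initial_cheaters: int,
    scheme: AssortmentScheme,
    n_generations: int,
    culling_threshold: float | None = None,
    seed: int | None = None,
    max_population: int | None = None,
) -> GenerationsResult:
    """Iterate the community life cycle: form groups -> (cull) ->
    reproduce -> pool offspring.

    Emits the community cooperator frequency and the Price decomposition
    (uniform weighting) for every generation.  Extinction is reported via
    the ``extinct`` flag, not raised.  ``max_population`` caps the pooled
    population by hypergeometric downsampling (the deterministic rule
    grows the community geometrically).
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)
    nc, nd = initial_cooperators, initial_cheaters

    rows = []
    decomps: list[PriceDecomposition] = []
    extinct = False
    for gen in range(1, n_generations + 1):
        if nc + nd == 0:
            extinct = True
            break
        groups = form_groups(nc, nd, scheme, rng=rng)
        if culling_threshold is not None:
            groups = cull_groups(groups, culling_threshold)
        if not groups:
            nc = nd = 0
            extinct = True
            break
        records = []
        for g in groups:
            off = reproduce_group(g)
            records.append(
                GroupRecord(g.size, g.cooperators, off.size, off.cooperators)
            )
        nc = sum(r.final_cooperators for r in records)
        nd = sum(r.final_size - r.final_cooperators for r in records)
        if nc + nd == 0:
            extinct = True
            dec = None
        else:
            dec = price_decompose(records)
            decomps.append(dec)
        if max_population is not None and nc + nd > max_population:
            nc = int(rng.hypergeometric(nc, nd, max_population))
            nd = max_population - nc
        rows.append(
            {
                "generation": gen,
                "n_cooperators": nc,
                "n_cheaters": nd,
                "community_freq": nc / (nc + nd) if nc + nd else float("nan"),
                "delta_p": float(dec.delta_p) if dec else float("nan"),
                "cov_term": float(dec.covariance_term) if dec else float("nan"),
                "ave_term": float(dec.expectation_term) if dec else float("nan"),
                "var_p": float(dec.variance_p) if dec else float("nan"),
            }
        )
        if extinct:
            break

    return GenerationsResult(
        history=pd.DataFrame(rows),
        decompositions=decomps,
        extinct=extinct or nc + nd == 0,
        final_cooperators=nc,
        final_cheaters=nd,
    )
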