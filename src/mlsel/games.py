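"""Proportional tit-for-tat (pTFT) in an iterated within-group
public-goods game.

A pTFT player cooperates in the first round and thereafter cooperates
with probability equal to the fraction of its *partners* (excluding
itself) that cooperated in the previous round.  pTFT does not
discriminate between individual partners — there is no partner choice —
so it can only be maintained by partner fidelity feedback, which needs
both of: repeated interactions within lasting groups, and large
variation in pTFT frequency across groups.  The factorial experiment in
the test suite checks that pTFT beats unconditional cheating in mean
payoff only when both requirements hold.

Payoffs are a linear public good: each cooperative act costs ``c`` to
the actor and delivers ``b/(n-1)`` to each of the ``n-1`` partners.
The rule itself specifies no payoffs; the defaults b=3, c=1 are an
arbitrary but conventional choice with b > c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PTFT",
    "ALWAYS_CHEAT",
    "ALWAYS_COOPERATE",
    "StrategyProfile",
    "ptft_probability",
    "iterated_group_game",
    "mean_payoff_by_strategy",
]

PTFT = "pTFT"
ALWAYS_CHEAT = "always-cheat"
ALWAYS_COOPERATE = "always-cooperate"
_STRATEGIES = (PTFT, ALWAYS_CHEAT, ALWAYS_COOPERATE)


def ptft_probability(prev_fraction_cooperative_partners: float, round_index: int) -> float:
    """Probability that a pTFT player cooperates this round.

    Round 1 (``round_index == 1``): always cooperates.  Later rounds:
    exactly the previous round's fraction of cooperating partners
    (self excluded).
    """
    if round_index < 1:
        raise ValueError("round_index is 1-based")
    if not 0 <= prev_fraction_cooperative_partners <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if round_index == 1:
        return 1.0
    return float(prev_fraction_cooperative_partners)


@dataclass(frozen=True)
class StrategyProfile:
    """Group assignment and game parameters.

    ``groups`` is a tuple of groups, each a tuple of strategy names.
    ``benefit`` and ``cost`` are per cooperative act, with benefit split
    evenly among the actor's partners.
    """

    groups: tuple[tuple[str, ...], ...]
    rounds: int = 10
    benefit: float = 3.0
    cost: float = 1.0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not self.benefit > 0 or not self.cost > 0:
            raise ValueError("benefit and cost must be positive")
        if self.benefit <= self.cost:
            raise ValueError("a public good needs benefit > cost")
        for g in self.groups:
            if len(g) < 2:
                raise ValueError("groups need at least 2 members (no partners otherwise)")
            for strat in g:
                if strat not in _STRATEGIES:
                    raise ValueError(f"unknown strategy {strat!r}")


def iterated_group_game(
    profile: StrategyProfile, seed: int | None = None
) -> pd.DataFrame:
    """Play the iterated public-goods game once in every group.

    Returns a tidy DataFrame with one row per individual: columns
    ``group``, ``strategy``, ``payoff`` (total over all rounds).
    Stochastic only through the pTFT cooperation draws; deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    b, c = profile.benefit, profile.cost
    rows = []
    for gi, group in enumerate(profile.groups):
        n = len(group)
        strategies = np.array(group)
        is_ptft = strategies == PTFT
        payoff = np.zeros(n)
        p_coop = np.where(strategies == ALWAYS_CHEAT, 0.0, 1.0)  # round 1
        for rnd in range(1, profile.rounds + 1):
            acted = rng.random(n) < p_coop
            n_coop = acted.sum()
            # each act: cost c to actor, b/(n-1) to every partner
            payoff -= c * acted
            payoff += (b / (n - 1)) * (n_coop - acted)
            # update pTFT probabilities from partners' actions
            partner_frac = (n_coop - acted) / (n - 1)
            p_coop = np.where(
                is_ptft,
                partner_frac,
                np.where(strategies == ALWAYS_CHEAT, 0.0, 1.0),
            )
        for i in range(n):
            rows.append({"group": gi, "strategy": group[i], "payoff": payoff[i]})
    return pd.DataFrame(rows)


def mean_payoff_by_strategy(
    profile: StrategyProfile, replicates: int = 1, seed: int | None = None
) -> pd.Series:
    """Population mean total payoff per strategy, averaged over replicates."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(replicates)
    frames = [
        iterated_group_game(profile, seed=np.random.default_rng(s).integers(2**31))
        for s in seeds
    ]
    all_rows = pd.concat(frames, ignore_index=True)
    return all_rows.groupby("strategy")["payoff"].mean()
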