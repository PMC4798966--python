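"""Toxin–antitoxin anti-competition cooperation.

Cooperators carry a toxin–antitoxin pair: they grow slightly slower than
cheaters, but when the population hits a density threshold a fraction of
them lyses ("suicide"), releasing a stable toxin.  The remaining
cooperators are immune (antitoxin); cheaters are sensitive and die.
Killing is the shared benefit: it frees resources for every survivor.

Well-mixed dynamics: an episode fires whenever the total population
reaches the density threshold ``K``.  A fraction ``s`` of cooperators
dies, and each suicide kills up to ``k`` cheaters.  Cheaters decline in
*frequency* across an episode only when the cooperator frequency exceeds
``1/(1+k)`` (with no growth cost): cooperator immunity acts as partner
choice, but on its own it needs cooperators to be common.

On a spatial lattice the toxin acts locally: a suicide kills only
cheaters within ``kill_radius``.  Repeated local interactions (partner
fidelity feedback) concentrate both the cost and the benefit around
cooperator clusters, so even initially rare — but clustered —
cooperators can invade, reproducing the classic colicin-plate contrast
between liquid culture and agar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ToxinState",
    "suicide_episode",
    "critical_cooperator_frequency",
    "well_mixed_trajectory",
    "make_lattice",
    "lattice_trajectory",
    "LatticeResult",
    "TOXIN_ANNOTATION",
]

EMPTY, COOP, CHEAT = 0, 1, 2

TOXIN_ANNOTATION = {
    "cooperator-immunity (antitoxin)": ("individual↔individual", "PC"),
    "local toxin action on lattice": ("neighborhood↔individual", "PFF"),
}


@dataclass(frozen=True)
class ToxinState:
    """Cooperator/cheater abundances plus the episode parameters.

    ``suicide_fraction`` s: fraction of cooperators lysing per episode.
    ``kill_coefficient`` k: cheaters killed per suicidal cooperator.
    ``density_threshold`` K: total population size that triggers an episode.
    ``growth_cost``: relative growth-rate deficit of cooperators
    (cheater rate 1, cooperator rate 1 - growth_cost).
    """

    cooperators: float
    cheaters: float
    suicide_fraction: float = 0.1
    kill_coefficient: float = 2.0
    density_threshold: float = 250.0
    growth_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.cooperators < 0 or self.cheaters < 0:
            raise ValueError("abundances must be non-negative")
        if not 0 <= self.suicide_fraction <= 1:
            raise ValueError("suicide_fraction must lie in [0, 1]")
        if self.kill_coefficient < 0:
            raise ValueError("kill_coefficient must be >= 0")
        if self.density_threshold < 1:
            raise ValueError("density_threshold must be >= 1")
        if self.growth_cost < 0:
            raise ValueError("growth_cost must be >= 0")

    @property
    def total(self) -> float:
        return self.cooperators + self.cheaters

    @property
    def cooperator_freq(self) -> float:
        if self.total == 0:
            raise ValueError("empty population has no cooperator frequency")
        return self.cooperators / self.total


def suicide_episode(state: ToxinState) -> ToxinState:
    """One deterministic suicide episode.

    suicides = round(s*C) (round half-even), new C = C - suicides;
    kills = min(k*suicides, D), new D = D - kills.  Deaths are exactly
    suicides + kills; kills are capped at the cheaters present.
    """
    if state.total < 1:
        raise ValueError("episode requires at least one individual")
    suicides = round(state.suicide_fraction * state.cooperators)
    kills = min(state.kill_coefficient * suicides, state.cheaters)
    return replace(
        state,
        cooperators=state.cooperators - suicides,
        cheaters=state.cheaters - kills,
    )


def _grow_to_threshold(state: ToxinState) -> ToxinState:
    """Deterministic exponential growth until C + D reaches K.

    Cheaters grow at rate 1, cooperators at rate 1 - growth_cost.
    """
    C, D, K = state.cooperators, state.cheaters, state.density_threshold
    if C + D >= K:
        return state
    r = 1.0 - state.growth_cost

    def deficit(t: float) -> float:
        return C * np.exp(r * t) + D * np.exp(t) - K

    hi = 1.0
    while deficit(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise ValueError("population cannot reach the density threshold")
    t = brentq(deficit, 0.0, hi)
    return replace(state, cooperators=C * np.exp(r * t), cheaters=D * np.exp(t))


def critical_cooperator_frequency(
    s: float,
    k: float,
    growth_cost: float = 0.0,
    density_threshold: float = 250.0,
) -> float:
    """Initial cooperator frequency above which cheater frequency declines.

    With no growth cost this is the closed form ``1/(1+k)``: across one
    episode cheaters lose the fraction ``k*s*C/D`` and cooperators lose
    ``s``, so cheaters fare worse iff ``C/(C+D) > 1/(1+k)``.  With a
    growth cost the threshold of one full growth-plus-episode cycle is
    located numerically by bisection (continuous dynamics, no rounding).
    Raises for ``k <= 0``: cooperators then never gain and no threshold
    exists.
    """
    if s <= 0:
        raise ValueError("suicide_fraction must be positive")
    if k <= 0:
        raise ValueError("no threshold exists for kill_coefficient <= 0")
    if growth_cost == 0:
        return 1.0 / (1.0 + k)

    K = density_threshold

    def freq_gain(f: float) -> float:
        C, D = f * K, (1 - f) * K
        suicides = s * C
        kills = min(k * suicides, D)
        C, D = C - suicides, D - kills
        st = _grow_to_threshold(
            ToxinState(C, D, s, k, K, growth_cost)
        )
        return st.cooperator_freq - f

    grid = np.linspace(1e-6, 1 - 1e-6, 1000)
    vals = np.array([freq_gain(f) for f in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        return 1.0 if vals.max() <= 0 else 0.0
    i = sign_change[0]
    return brentq(freq_gain, grid[i], grid[i + 1])


def well_mixed_trajectory(state: ToxinState, n_episodes: int) -> pd.DataFrame:
    """Alternate deterministic growth-to-threshold with suicide episodes.

    Records (episode, phase, cooperators, cheaters, cooperator_freq) for
    each pre-episode and post-episode state.  If the starting population
    already exceeds the threshold the first episode fires immediately.
    Stops early on total extinction (reported via the final row).
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    rows = []
    st = state
    for ep in range(1, n_episodes + 1):
        if st.total == 0:
            break
        if st.total < st.density_threshold:
            st = _grow_to_threshold(st)
        rows.append(
            {
                "episode": ep,
                "phase": "pre",
                "cooperators": st.cooperators,
                "cheaters": st.cheaters,
                "cooperator_freq": st.cooperator_freq,
            }
        )
        st = suicide_episode(st)
        rows.append(
            {
                "episode": ep,
                "phase": "post",
                "cooperators": st.cooperators,
                "cheaters": st.cheaters,
                "cooperator_freq": st.cooperator_freq if st.total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Spatial lattice variant


def _roll_sum(mask: np.ndarray, radius: int, exclude_center: bool = True) -> np.ndarray:
    """Count of True cells in the (2r+1)^2 Chebyshev box, torus boundary."""
    out = np.zeros(mask.shape, dtype=np.int64)
    m = mask.astype(np.int64)
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            if exclude_center and dx == 0 and dy == 0:
                continue
            out += np.roll(np.roll(m, dx, axis=0), dy, axis=1)
    return out


def make_lattice(
    shape: tuple[int, int],
    cooperator_freq: float,
    occupancy: float,
    placement: str = "clustered",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Build an initial grid: 0 empty, 1 cooperator, 2 cheater.

    ``clustered`` places all cooperators in one centered square block
    (a founding microcolony); ``mixed`` scatters them uniformly among
    the occupied sites.
    """
    if rng is None:
        rng = np.random.default_rng()
    if placement not in ("clustered", "mixed"):
        raise ValueError(f"unknown placement {placement!r}")
    h, w = shape
    n_sites = h * w
    n_occupied = int(round(occupancy * n_sites))
    n_coop = int(round(cooperator_freq * n_occupied))
    n_cheat = n_occupied - n_coop
    grid = np.zeros(shape, dtype=np.int8)

    if placement == "clustered" and n_coop > 0:
        side = int(np.ceil(np.sqrt(n_coop)))
        r0, c0 = (h - side) // 2, (w - side) // 2
        block = [(r0 + i, c0 + j) for i in range(side) for j in range(side)]
        for r, c in block[:n_coop]:
            grid[r % h, c % w] = COOP
        free = np.flatnonzero(grid.ravel() == EMPTY)
        idx = rng.choice(free, size=n_cheat, replace=False)
        grid.ravel()[idx] = CHEAT
    else:
        idx = rng.choice(n_sites, size=n_occupied, replace=False)
        flat = grid.ravel()
        flat[idx[:n_coop]] = COOP
        flat[idx[n_coop:]] = CHEAT
    return grid


@dataclass
class LatticeResult:
    """Frequency time series and final grid of a lattice run."""

    frequencies: pd.DataFrame
    final_grid: np.ndarray
    grids: list[np.ndarray] | None = None


def lattice_trajectory(
    grid: np.ndarray,
    s: float = 0.1,
    k: float | None = None,
    kill_radius: int = 2,
    n_steps: int = 150,
    seed: int | None = None,
    growth_cost: float = 0.05,
    density_threshold: float = 0.5,
    colonization_rate: float = 0.3,
    record_grids: bool = False,
) -> LatticeResult:
    """Stochastic lattice dynamics with local reproduction and local killing.

    Per step, synchronously: every empty site is colonized with
    probability ``colonization_rate`` times the growth-rate-weighted
    fraction of occupied Moore neighbors (cooperator rate 1 - growth_cost,
    cheater rate 1); the colonizer's type is drawn proportionally to
    those weights.  Then each cooperator whose Chebyshev ``kill_radius``
    neighborhood is at least ``density_threshold`` occupied commits
    suicide with probability ``s``, killing up to ``k`` cheaters within
    the radius (``k=None``: the toxin kills every cheater in the
    radius).  Suicides resolve sequentially in seeded random order.
    Torus boundary throughout; deterministic given the seed.
    """
    if kill_radius < 1:
        raise ValueError("kill_radius must be >= 1")
    rng = np.random.default_rng(seed)
    grid = grid.astype(np.int8).copy()
    h, w = grid.shape
    box = (2 * kill_radius + 1) ** 2 - 1

    rows = []
    grids = [grid.copy()] if record_grids else None

    def record(step: int) -> None:
        C = int((grid == COOP).sum())
        D = int((grid == CHEAT).sum())
        rows.append(
            {
                "step": step,
                "cooperators": C,
                "cheaters": D,
                "cooperator_freq": C / (C + D) if C + D else float("nan"),
            }
        )

    record(0)
    for step in range(1, n_steps + 1):
        # synchronous reproduction into empty neighboring sites
        coop_n = _roll_sum(grid == COOP, 1)
        cheat_n = _roll_sum(grid == CHEAT, 1)
        wc = (1.0 - growth_cost) * coop_n
        wtot = wc + cheat_n
        empty = grid == EMPTY
        p_fill = np.minimum(colonization_rate * wtot / 8.0, 1.0)
        fill = empty & (rng.random((h, w)) < p_fill) & (wtot > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_coop = np.where(wtot > 0, wc / np.maximum(wtot, 1e-300), 0.0)
        becomes_coop = rng.random((h, w)) < p_coop
        grid[fill & becomes_coop] = COOP
        grid[fill & ~becomes_coop] = CHEAT

        # density-triggered local suicide episodes
        occ = _roll_sum(grid != EMPTY, kill_radius)
        dense = (grid == COOP) & (occ >= density_threshold * box)
        fire = dense & (rng.random((h, w)) < s)
        coords = np.argwhere(fire)
        if len(coords):
            coords = coords[rng.permutation(len(coords))]
        for r, c in coords:
            rr = np.arange(r - kill_radius, r + kill_radius + 1) % h
            cc = np.arange(c - kill_radius, c + kill_radius + 1) % w
            window = grid[np.ix_(rr, cc)]
            cheat_pos = np.argwhere(window == CHEAT)
            if k is not None and len(cheat_pos) > int(k):
                pick = rng.choice(len(cheat_pos), size=int(k), replace=False)
                cheat_pos = cheat_pos[pick]
            for i, j in cheat_pos:
                grid[rr[i], cc[j]] = EMPTY
            grid[r, c] = EMPTY  # the suicidal cooperator lyses

        record(step)
        if record_grids:
            grids.append(grid.copy())

    return LatticeResult(
        frequencies=pd.DataFrame(rows), final_grid=grid, grids=grids
    )
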