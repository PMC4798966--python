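"""Nested-entity simulator for mtDNA -> mitochondrion -> cell -> organism.

Cooperation between multicellular eukaryotes and their mitochondria is a
multi-level affair.  A *dysfunctional* mtDNA replicates at least as well
as a functional one within the same heteroplasmic pool (per-copy
replication bonus ``delta``) but contributes less to the host — a
classic cheater.  Several counter-mechanisms act at different entity
levels, each classifiable as partner choice (PC) or partner fidelity
feedback (PFF) between the entities it couples:

====================  ======================  ====
mechanism             entity levels           class
====================  ======================  ====
replication advantage mitochondrion <-> mtDNA PFF (the feedback's target)
mito fitness          mitochondrion <-> mtDNA PFF
selective import      cell <-> mitochondria   PC
asymmetric segregation cell <-> mitochondria  PC
mitophagy             cell <-> mitochondria   PC
apoptosis / arrest    cell <-> mtDNA          PFF
organism fecundity    organism <-> mtDNA      PFF
germline bottleneck   organism <-> mtDNA      PFF variance source
====================  ======================  ====

The germline bottleneck (a founder sample of ``N_b`` mtDNAs per oocyte)
does not itself select, but inflates the between-offspring variance in
heteroplasmy ``h`` (Var(h_founder) ~ h(1-h)/N_b), which is exactly what
the downstream PFF filters (apoptosis, organism-level selection) need to
act on — the Price covariance term again.

Heteroplasmy is binary (functional vs dysfunctional copies) and there is
no mutation by default, so h = 0 and h = 1 are absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .price import GroupRecord, PriceDecomposition, price_decompose

__all__ = [
    "MtPool",
    "MitoState",
    "CellState",
    "Organism",
    "MechanismConfig",
    "MECHANISM_ANNOTATIONS",
    "replicate_mtdna",
    "divide_mitochondria",
    "mitophagy",
    "asymmetric_inheritance",
    "apoptosis_filter",
    "selective_import",
    "germline_transmission",
    "make_population",
    "run_multilevel",
    "MultilevelResult",
    "constant",
    "linear_fecundity",
    "logistic_apoptosis",
    "step_apoptosis",
]

MECHANISM_ANNOTATIONS: dict[str, tuple[str, str]] = {
    "replication_advantage": ("mitochondrion↔mtDNA", "PFF"),
    "mito_fitness": ("mitochondrion↔mtDNA", "PFF"),
    "import_selectivity": ("cell↔mitochondria", "PC"),
    "segregation_bias": ("cell↔mitochondria", "PC"),
    "mitophagy_selectivity": ("cell↔mitochondria", "PC"),
    "apoptosis_rule": ("cell↔mtDNA", "PFF"),
    "organism_fecundity": ("organism↔mtDNA", "PFF"),
    "bottleneck_size": ("organism↔mtDNA", "PFF variance source"),
}


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MtPool:
    """A pool of mtDNA copies: functional vs dysfunctional counts."""

    functional: int
    dysfunctional: int

    def __post_init__(self) -> None:
        if self.functional < 0 or self.dysfunctional < 0:
            raise ValueError("mtDNA counts must be non-negative")

    @property
    def total(self) -> int:
        return self.functional + self.dysfunctional

    @property
    def heteroplasmy(self) -> float:
        """Dysfunctional fraction h; undefined (raises) for an empty pool."""
        if self.total == 0:
            raise ValueError("heteroplasmy undefined for an empty pool")
        return self.dysfunctional / self.total


@dataclass(frozen=True)
class MitoState:
    """One mitochondrion, characterized by its internal mtDNA pool."""

    pool: MtPool

    @property
    def functional_fraction(self) -> float:
        return 1.0 - self.pool.heteroplasmy


class CellState:
    """A cell's mitochondria, stored as an (n_mito, 2) count array.

    Column 0: functional copies, column 1: dysfunctional copies.  The
    array form keeps the per-generation operators vectorized; the
    ``mitochondria`` property exposes the object view.
    """

    __slots__ = ("counts", "alive")

    def __init__(self, counts: np.ndarray, alive: bool = True):
        counts = np.asarray(counts, dtype=np.int64).reshape(-1, 2)
        if (counts < 0).any():
            raise ValueError("mtDNA counts must be non-negative")
        self.counts = counts
        self.alive = alive

    @classmethod
    def from_mitochondria(cls, mitos: Sequence[MitoState]) -> "CellState":
        return cls(
            np.array(
                [[m.pool.functional, m.pool.dysfunctional] for m in mitos],
                dtype=np.int64,
            ).reshape(-1, 2)
        )

    @property
    def mitochondria(self) -> list[MitoState]:
        return [MitoState(MtPool(int(f), int(d))) for f, d in self.counts]

    @property
    def n_mitochondria(self) -> int:
        return len(self.counts)

    @property
    def pool(self) -> MtPool:
        f, d = self.counts.sum(axis=0) if len(self.counts) else (0, 0)
        return MtPool(int(f), int(d))

    @property
    def heteroplasmy(self) -> float:
        return self.pool.heteroplasmy

    def copy(self) -> "CellState":
        return CellState(self.counts.copy(), self.alive)


@dataclass
class Organism:
    """An organism reduced to its germline: a set of germ cells."""

    cells: list[CellState]

    @property
    def pool(self) -> MtPool:
        f = sum(c.pool.functional for c in self.cells)
        d = sum(c.pool.dysfunctional for c in self.cells)
        return MtPool(f, d)

    @property
    def heteroplasmy(self) -> float:
        return self.pool.heteroplasmy


def constant(value: float) -> Callable[[np.ndarray], np.ndarray]:
    """A rate/probability map that ignores its argument."""

    def f(x):
        return np.full_like(np.asarray(x, dtype=float), value)

    f.__name__ = f"constant({value})"
    return f


def linear_fecundity(max_offspring: float) -> Callable[[float], float]:
    """Expected offspring count declining linearly in heteroplasmy."""

    def f(h: float) -> float:
        return max_offspring * (1.0 - h)

    f.__name__ = f"linear_fecundity({max_offspring})"
    return f


def logistic_apoptosis(h50: float = 0.5, slope: float = 10.0) -> Callable:
    """Death probability rising sigmoidally with cell heteroplasmy."""

    def f(h):
        return 1.0 / (1.0 + np.exp(-slope * (np.asarray(h, dtype=float) - h50)))

    f.__name__ = f"logistic_apoptosis(h50={h50}, slope={slope})"
    return f


def step_apoptosis(threshold: float) -> Callable:
    """Die iff cell heteroplasmy exceeds the threshold."""

    def f(h):
        return (np.asarray(h, dtype=float) > threshold).astype(float)

    f.__name__ = f"step_apoptosis({threshold})"
    return f


@dataclass
class MechanismConfig:
    """Toggleable PC/PFF operators with rates and scale parameters.

    Every rate of 0 (or a constant map) switches its mechanism off; the
    annotation of each mechanism — entity level and PC/PFF class — is
    fixed in :data:`MECHANISM_ANNOTATIONS` and written into every run
    manifest.  Carrying capacities are arbitrary scale choices (kept
    small so multi-seed experiments run in minutes).
    """

    replication_advantage: float = 0.0  # delta: per-copy bonus of dysfunctional mtDNA
    mito_fitness: Callable = field(default_factory=lambda: constant(1.0))
    import_selectivity: float = 0.0
    segregation_bias: float = 0.0
    mitophagy_selectivity: float = 0.0
    mitophagy_rate: float = 0.0
    apoptosis_rule: Callable = field(default_factory=lambda: constant(0.0))
    bottleneck_size: int = 8
    organism_fecundity: Callable = field(default_factory=lambda: constant(2.0))
    mtdna_per_mito: int = 8
    mitos_per_cell: int = 16
    cells_per_organism: int = 4
    max_organisms: int = 20
    bottleneck_sampling: str = "hypergeometric"

    def __post_init__(self) -> None:
        if self.replication_advantage < 0:
            raise ValueError("replication_advantage must be >= 0")
        for name in ("import_selectivity", "segregation_bias", "mitophagy_selectivity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.mitophagy_rate < 1:
            raise ValueError("mitophagy_rate must lie in [0, 1)")
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1")
        for name in ("mtdna_per_mito", "mitos_per_cell", "cells_per_organism", "max_organisms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bottleneck_sampling not in ("hypergeometric", "binomial"):
            raise ValueError("bottleneck_sampling must be hypergeometric or binomial")

    @property
    def annotations(self) -> dict[str, tuple[str, str]]:
        return dict(MECHANISM_ANNOTATIONS)


# --------------------------------------------------------------------------
# operators


def _replicate_counts(
    counts: np.ndarray, delta: float, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Weighted-urn replication, vectorized over mitochondria.

    Copies are added one at a time; at each step a pool adds a
    dysfunctional copy with probability d*(1+delta) / (d*(1+delta) + f).
    Pools already at or above ``target`` (and empty pools, which cannot
    template replication) are left untouched.
    """
    counts = counts.copy()
    totals = counts.sum(axis=1)
    while True:
        active = (totals < target) & (totals > 0)
        if not active.any():
            break
        f = counts[active, 0].astype(float)
        d = counts[active, 1].astype(float)
        wd = d * (1.0 + delta)
        p_dys = wd / (wd + f)
        draw = rng.random(active.sum()) < p_dys
        counts[active, 1] += draw
        counts[active, 0] += ~draw
        totals[active] += 1
    return counts


def replicate_mtdna(
    pool: MtPool, delta: float, target_copy_number: int, rng: np.random.Generator
) -> MtPool:
    """Replicate a pool up to ``target_copy_number`` by a weighted urn.

    Per-copy weight 1 for functional, 1 + delta for dysfunctional
    templates.  With delta = 0 the expected heteroplasmy is unchanged
    (neutral drift only); with delta > 0 it increases in expectation.
    """
    if pool.total == 0:
        raise ValueError("cannot replicate an empty pool")
    if target_copy_number < pool.total:
        raise ValueError("target copy number below current total")
    counts = _replicate_counts(
        np.array([[pool.functional, pool.dysfunctional]]), delta, target_copy_number, rng
    )
    return MtPool(int(counts[0, 0]), int(counts[0, 1]))


def divide_mitochondria(
    cell: CellState,
    mito_fitness: Callable,
    rng: np.random.Generator,
    capacity: int | None = None,
) -> CellState:
    """Mitochondrial division with fitness tied to functional content.

    Each mitochondrion divides with probability
    ``mito_fitness(functional_fraction)``; its mtDNAs partition
    binomially between the two daughters.  Daughters left with zero
    copies are dropped.  If a ``capacity`` is given the population is
    capped by uniform random removal.
    """
    counts = cell.counts
    if len(counts) == 0:
        return cell.copy()
    totals = counts.sum(axis=1)
    ffrac = np.where(totals > 0, counts[:, 0] / np.maximum(totals, 1), 0.0)
    p = np.clip(np.asarray(mito_fitness(ffrac), dtype=float), 0.0, 1.0)
    divides = rng.random(len(counts)) < p

    keep = counts[~divides]
    parents = counts[divides]
    if len(parents):
        f1 = rng.binomial(parents[:, 0], 0.5)
        d1 = rng.binomial(parents[:, 1], 0.5)
        daughters = np.concatenate(
            [
                np.stack([f1, d1], axis=1),
                np.stack([parents[:, 0] - f1, parents[:, 1] - d1], axis=1),
            ]
        )
        new = np.concatenate([keep, daughters])
    else:
        new = keep
    new = new[new.sum(axis=1) > 0]
    if capacity is not None and len(new) > capacity:
        idx = rng.choice(len(new), size=capacity, replace=False)
        new = new[idx]
    return CellState(new, cell.alive)


def mitophagy(
    cell: CellState,
    selectivity: float,
    rate: float,
    rng: np.random.Generator,
    weight: float = 1.0,
) -> CellState:
    """Selective mitochondrial turnover.

    Baseline destruction probability ``rate`` per mitochondrion; the
    destruction *odds* are multiplied by
    ``1 + selectivity * (1 - functional_fraction) * weight``, so fully
    dysfunctional mitochondria are targeted hardest.  ``selectivity = 0``
    is unbiased turnover and leaves expected heteroplasmy unchanged.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    counts = cell.counts
    if len(counts) == 0 or rate == 0:
        return cell.copy()
    totals = counts.sum(axis=1)
    ffrac = counts[:, 0] / np.maximum(totals, 1)
    odds = (rate / (1.0 - rate)) * (1.0 + selectivity * (1.0 - ffrac) * weight)
    p_destroy = odds / (1.0 + odds)
    survive = rng.random(len(counts)) >= p_destroy
    return CellState(counts[survive], cell.alive)


def asymmetric_inheritance(
    cell: CellState, bias: float, rng: np.random.Generator
) -> tuple[CellState, CellState]:
    """Partition mitochondria between two daughter cells with a quality bias.

    A mitochondrion counts as functional when its functional fraction is
    at least 1/2.  Functional mitochondria go to the favored daughter
    with probability ``0.5 + bias/2``, dysfunctional ones with
    ``0.5 - bias/2``; ``bias = 0`` is a symmetric binomial split and
    ``bias = 1`` deterministically sorts by quality.  mtDNA copies are
    conserved exactly (they travel with their mitochondrion).
    """
    if not 0 <= bias <= 1:
        raise ValueError("bias must lie in [0, 1]")
    counts = cell.counts
    totals = counts.sum(axis=1)
    functional = counts[:, 0] * 2 >= totals
    p_favored = np.where(functional, 0.5 + bias / 2.0, 0.5 - bias / 2.0)
    to_favored = rng.random(len(counts)) < p_favored
    return CellState(counts[to_favored]), CellState(counts[~to_favored])


def apoptosis_filter(
    cells: Sequence[CellState],
    apoptosis_rule: Callable,
    rng: np.random.Generator,
) -> list[CellState]:
    """Programmed cell death driven by cellular dysfunctional load.

    Each cell dies with probability ``apoptosis_rule(h_cell)``.  Cells
    without any mtDNA are not viable and are always removed.  For a
    non-decreasing rule the survivors' mean h cannot exceed the
    pre-filter mean in expectation.
    """
    survivors = []
    for cell in cells:
        if cell.pool.total == 0:
            continue
        p = float(np.asarray(apoptosis_rule(cell.heteroplasmy)))
        if rng.random() >= p:
            survivors.append(cell)
    return survivors


def selective_import(
    pool: MtPool, n: int, selectivity: float, rng: np.random.Generator
) -> MtPool:
    """Draw ``n`` copies without replacement, favoring functional ones.

    Per-draw weights: functional 1, dysfunctional ``1 - selectivity``.
    ``selectivity = 0`` is a plain hypergeometric draw; ``selectivity = 1``
    imports dysfunctional copies only once the functional ones are
    exhausted.
    """
    if n > pool.total:
        raise ValueError("cannot draw more copies than the pool holds")
    if not 0 <= selectivity <= 1:
        raise ValueError("selectivity must lie in [0, 1]")
    if selectivity == 0:
        d = int(rng.hypergeometric(pool.dysfunctional, pool.functional, n))
        return MtPool(n - d, d)
    f, d = pool.functional, pool.dysfunctional
    got_f = got_d = 0
    w_d = 1.0 - selectivity
    for _ in range(n):
        wf, wd = f, d * w_d
        if wf + wd == 0:  # only dysfunctional left under selectivity 1
            take_d = min(n - got_f - got_d, d)
            got_d += take_d
            break
        if rng.random() < wf / (wf + wd):
            f -= 1
            got_f += 1
        else:
            d -= 1
            got_d += 1
    return MtPool(got_f, got_d)


def germline_transmission(
    mother_pool: MtPool,
    bottleneck_size: int,
    n_offspring: int,
    rng: np.random.Generator,
    sampling: str = "hypergeometric",
    import_selectivity: float = 0.0,
    amplify_to: int | None = None,
    delta: float = 0.0,
) -> list[MtPool]:
    """Found offspring mtDNA pools through the germline bottleneck.

    Each offspring's founder pool is a draw of ``bottleneck_size``
    copies from the mother's pool — hypergeometric (without replacement,
    default) or binomial (large-pool approximation).  Across offspring
    the founder heteroplasmy variance is the hypergeometric variance,
    approximately ``h(1-h)/N_b`` for a large maternal pool.  With
    ``amplify_to`` set, each founder pool is then replicated up to the
    adult copy number by the urn scheme (neutral when ``delta`` is 0).
    """
    if bottleneck_size > mother_pool.total:
        raise ValueError("bottleneck size exceeds the maternal pool")
    if sampling not in ("hypergeometric", "binomial"):
        raise ValueError("sampling must be hypergeometric or binomial")
    if n_offspring < 0:
        raise ValueError("n_offspring must be >= 0")

    if import_selectivity > 0:
        founders = [
            selective_import(mother_pool, bottleneck_size, import_selectivity, rng)
            for _ in range(n_offspring)
        ]
    elif sampling == "hypergeometric":
        d = rng.hypergeometric(
            mother_pool.dysfunctional, mother_pool.functional, bottleneck_size, size=n_offspring
        )
        founders = [MtPool(bottleneck_size - int(x), int(x)) for x in d]
    else:
        h = mother_pool.heteroplasmy
        d = rng.binomial(bottleneck_size, h, size=n_offspring)
        founders = [MtPool(bottleneck_size - int(x), int(x)) for x in d]

    if amplify_to is None:
        return founders
    if amplify_to < bottleneck_size:
        raise ValueError("amplify_to below bottleneck size")
    counts = np.array([[p.functional, p.dysfunctional] for p in founders], dtype=np.int64)
    counts = counts.reshape(-1, 2)
    if len(counts):
        counts = _replicate_counts(counts, delta, amplify_to, rng)
    return [MtPool(int(f), int(d)) for f, d in counts]


# --------------------------------------------------------------------------
# whole-lifecycle simulator


def make_population(
    config: MechanismConfig,
    n_organisms: int,
    initial_h: float,
    rng: np.random.Generator,
) -> list[Organism]:
    """Build a founding population at a given mean heteroplasmy.

    Every mtDNA copy is independently dysfunctional with probability
    ``initial_h`` (binomial within each mitochondrion).
    """
    pop = []
    for _ in range(n_organisms):
        cells = []
        for _ in range(config.cells_per_organism):
            d = rng.binomial(config.mtdna_per_mito, initial_h, size=config.mitos_per_cell)
            counts = np.stack([config.mtdna_per_mito - d, d], axis=1)
            cells.append(CellState(counts))
        pop.append(Organism(cells=cells))
    return pop


def _restock(cell: CellState, config: MechanismConfig, rng: np.random.Generator) -> CellState:
    """Replicate mtDNAs to the per-mito target, then let mitochondria divide
    up to the per-cell capacity."""
    counts = _replicate_counts(
        cell.counts, config.replication_advantage, config.mtdna_per_mito, rng
    )
    cell = CellState(counts, cell.alive)
    return divide_mitochondria(cell, config.mito_fitness, rng, capacity=config.mitos_per_cell)


def _develop_offspring(
    founder: MtPool, config: MechanismConfig, rng: np.random.Generator
) -> Organism | None:
    """Grow an organism's germline from a founder mtDNA pool.

    Zygote assembly, mitochondrial amplification with the replication
    advantage, germline cell expansion with asymmetric segregation,
    mitophagy, then the apoptosis filter.  Returns None if no germ cell
    survives.
    """
    if founder.total == 0:
        return None
    # partition founder copies into starting mitochondria
    n_mito0 = max(1, round(founder.total / config.mtdna_per_mito))
    assign_f = rng.multinomial(founder.functional, np.full(n_mito0, 1.0 / n_mito0))
    assign_d = rng.multinomial(founder.dysfunctional, np.full(n_mito0, 1.0 / n_mito0))
    counts = np.stack([assign_f, assign_d], axis=1)
    cell = CellState(counts[counts.sum(axis=1) > 0])

    # amplify organelle content in the zygote
    for _ in range(32):
        if cell.n_mitochondria >= config.mitos_per_cell:
            break
        cell = _restock(cell, config, rng)
    if cell.pool.total == 0:
        return None

    # germline expansion with asymmetric segregation
    cells = [cell]
    guard = 0
    while len(cells) < config.cells_per_organism and guard < 32:
        guard += 1
        nxt: list[CellState] = []
        for c in cells:
            c = _restock(c, config, rng)
            d1, d2 = asymmetric_inheritance(c, config.segregation_bias, rng)
            nxt.extend(cc for cc in (d1, d2) if cc.pool.total > 0)
        if not nxt:
            return None
        cells = nxt
    if len(cells) > config.cells_per_organism:
        idx = rng.choice(len(cells), size=config.cells_per_organism, replace=False)
        cells = [cells[i] for i in idx]

    # somatic quality control in the germline
    if config.mitophagy_rate > 0:
        cells = [
            mitophagy(c, config.mitophagy_selectivity, config.mitophagy_rate, rng)
            for c in cells
        ]
        cells = [c for c in cells if c.pool.total > 0]
    cells = apoptosis_filter(cells, config.apoptosis_rule, rng)
    if not cells:
        return None
    return Organism(cells=cells)


@dataclass
class MultilevelResult:
    """Per-generation summaries of a full multi-level run."""

    history: pd.DataFrame
    decompositions: list[PriceDecomposition]
    final_population: list[Organism]
    annotations: dict[str, tuple[str, str]]
    extinct: bool = False


def run_multilevel(
    config: MechanismConfig,
    n_generations: int,
    seed: int | None = None,
    initial_population: list[Organism] | None = None,
    initial_h: float = 0.3,
    n_organisms: int | None = None,
) -> MultilevelResult:
    """Iterate the full organismal life cycle.

    Per generation, for every organism: fecundity (Poisson with mean
    ``organism_fecundity(h)``) -> per-offspring germline bottleneck
    (optionally with selective import) -> offspring germline development
    (replication advantage, mitochondrial division, asymmetric
    segregation, mitophagy, apoptosis).  The offspring pool is capped at
    ``max_organisms`` by uniform subsampling.  Emits per generation the
    population mean h, the between-oocyte (founder) variance in h, the
    organism count, and the Price decomposition treating each parent
    organism as a group of mtDNAs (pi = mtDNAs transmitted, P =
    functional-mtDNA frequency).
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)
    if initial_population is None:
        initial_population = make_population(
            config, n_organisms or config.max_organisms, initial_h, rng
        )
    pop = initial_population

    rows = []
    decomps: list[PriceDecomposition] = []
    extinct = False
    for gen in range(1, n_generations + 1):
        offspring: list[Organism] = []
        founder_h: list[float] = []
        records: list[GroupRecord] = []
        for org in pop:
            pool = org.pool
            if pool.total == 0:
                continue
            fec = float(np.asarray(config.organism_fecundity(org.heteroplasmy)))
            n_off = int(rng.poisson(max(fec, 0.0)))
            transmitted_f = transmitted_d = 0
            for _ in range(n_off):
                cell = org.cells[rng.integers(len(org.cells))]
                cpool = cell.pool
                nb = min(config.bottleneck_size, cpool.total)
                founder = germline_transmission(
                    cpool,
                    nb,
                    1,
                    rng,
                    sampling=config.bottleneck_sampling,
                    import_selectivity=config.import_selectivity,
                )[0]
                founder_h.append(founder.heteroplasmy)
                transmitted_f += founder.functional
                transmitted_d += founder.dysfunctional
                child = _develop_offspring(founder, config, rng)
                if child is not None:
                    offspring.append(child)
            records.append(
                GroupRecord(
                    initial_size=pool.total,
                    initial_cooperators=pool.functional,
                    final_size=transmitted_f + transmitted_d,
                    final_cooperators=transmitted_f,
                )
            )

        if len(offspring) > config.max_organisms:
            idx = rng.choice(len(offspring), size=config.max_organisms, replace=False)
            offspring = [offspring[i] for i in idx]
        pop = offspring

        dec = None
        if records and sum(r.final_size for r in records) > 0:
            dec = price_decompose(records)
            decomps.append(dec)

        if pop:
            totals = np.array([o.pool.total for o in pop])
            dys = np.array([o.pool.dysfunctional for o in pop])
            mean_h = dys.sum() / totals.sum()
        else:
            mean_h = float("nan")
            extinct = True
        rows.append(
            {
                "generation": gen,
                "n_organisms": len(pop),
                "mean_h": mean_h,
                "between_oocyte_var_h": float(np.var(founder_h)) if founder_h else float("nan"),
                "price_cov": float(dec.covariance_term) if dec else float("nan"),
                "price_ave": float(dec.expectation_term) if dec else float("nan"),
                "price_residual": float(dec.residual()) if dec else float("nan"),
            }
        )
        if extinct:
            break

    return MultilevelResult(
        history=pd.DataFrame(rows),
        decompositions=decomps,
        final_population=pop,
        annotations=config.annotations,
        extinct=extinct,
    )
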