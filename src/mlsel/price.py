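"""Price-equation accounting for grouped cooperator/cheater populations.

A community is partitioned into interaction groups.  Group *i* starts with
``n_i`` members of which ``c_i`` are cooperators (initial cooperator
frequency ``P_i = c_i / n_i``), and after one bout of interaction and
reproduction has final size ``pi_i`` with final cooperator frequency
``P'_i``.  The Price identity partitions the change in community-wide
cooperator frequency into a between-group covariance term and a
within-group change term::

    pibar * dPbar = Cov(pi, P) + Ave(pi * dP)

where ``pibar`` is the mean final group size, ``dPbar = Pbar' - Pbar`` the
community-level frequency change, and ``dP = P' - P`` the within-group
change.  Cooperation can spread globally (``dPbar > 0``) even though
cooperator frequency falls inside every group, provided the covariance
between group productivity and initial cooperator frequency is large
enough — the covariance grows with the across-group variance ``Var(P)``
through ``Cov(pi, P) = beta * Var(P)``.

Two weighting conventions are exposed; both make the identity exact:

``uniform`` (default)
    Each group counts 1/G.  ``pi`` is the absolute final group size,
    ``Pbar`` the unweighted mean of group initial frequencies, and
    ``Pbar'`` the pooled final frequency (total cooperators over total
    individuals).  This is the convention of the two-group worked example
    with 0.5 weights per group.

``initial_size``
    Groups are weighted by their initial sizes; ``pi`` is replaced by the
    per-capita growth factor ``pi_i / n_i`` and both ``Pbar`` and
    ``Pbar'`` are pooled community frequencies.

All quantities can be computed in exact rational arithmetic
(``exact=True``) — the identity then has a residual of literally zero —
or in floating point for large simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GroupRecord",
    "PriceDecomposition",
    "price_decompose",
    "price_identity_residual",
    "read_group_table",
    "write_decomposition",
]


@dataclass(frozen=True)
class GroupRecord:
    """One interaction group's census before and after reproduction.

    The unit of Price accounting: ``initial_size`` members of which
    ``initial_cooperators`` cooperate, growing (or shrinking) to
    ``final_size`` members with ``final_cooperators`` cooperators.
    """

    initial_size: int
    initial_cooperators: int
    final_size: int
    final_cooperators: int

    def __post_init__(self) -> None:
        if self.initial_size <= 0:
            raise ValueError("initial_size must be positive (initial frequency undefined otherwise)")
        if not 0 <= self.initial_cooperators <= self.initial_size:
            raise ValueError(
                f"initial_cooperators={self.initial_cooperators} outside [0, {self.initial_size}]"
            )
        if self.final_size < 0:
            raise ValueError("final_size must be non-negative")
        if not 0 <= self.final_cooperators <= max(self.final_size, 0):
            raise ValueError(
                f"final_cooperators={self.final_cooperators} outside [0, {self.final_size}]"
            )

    @property
    def initial_freq(self) -> Fraction:
        """Initial cooperator frequency P."""
        return Fraction(self.initial_cooperators, self.initial_size)

    @property
    def final_freq(self) -> Fraction | None:
        """Final cooperator frequency P'; ``None`` for an extinct group."""
        if self.final_size == 0:
            return None
        return Fraction(self.final_cooperators, self.final_size)


@dataclass
class PriceDecomposition:
    """Terms of the Price identity for one set of groups.

    ``mean_final_size * delta_p == covariance_term + expectation_term``
    holds exactly in rational mode and to ~1e-9 relative in float mode.
    ``beta`` is the regression slope ``Cov(pi, P) / Var(P)``; it is
    ``None`` when all groups share the same initial frequency.
    """

    mean_final_size: float | Fraction
    community_initial_freq: float | Fraction
    community_final_freq: float | Fraction
    delta_p: float | Fraction
    covariance_term: float | Fraction
    expectation_term: float | Fraction
    variance_p: float | Fraction
    beta: float | Fraction | None
    weighting: str = "uniform"
    n_groups: int = 0

    def residual(self) -> float | Fraction:
        """Signed residual pibar*dPbar - Cov - Ave (zero when exact)."""
        return (
            self.mean_final_size * self.delta_p
            - self.covariance_term
            - self.expectation_term
        )

    def to_dict(self, float_values: bool = True) -> dict:
        d = asdict(self)
        if float_values:
            for k, v in d.items():
                if isinstance(v, Fraction):
                    d[k] = float(v)
        return d


def _check_groups(groups: Sequence[GroupRecord]) -> None:
    if len(groups) == 0:
        raise ValueError("at least one group is required")
    if sum(g.final_size for g in groups) == 0:
        raise ValueError("all groups went extinct: final community frequency undefined")


def price_decompose(
    groups: Sequence[GroupRecord],
    weighting: str = "uniform",
    exact: bool = False,
    center: Fraction | float | None = None,
) -> PriceDecomposition:
    """Decompose the community-level cooperator-frequency change.

    Parameters
    ----------
    groups
        Group censuses.  Extinct final groups (final_size 0) contribute
        ``pi = 0``; their within-group change term is defined as 0.
    weighting
        ``"uniform"`` (1/G per group, absolute final sizes) or
        ``"initial_size"`` (initial-size weights, per-capita growth).
    exact
        Use :class:`fractions.Fraction` throughout; the identity residual
        is then exactly zero.
    center
        Constant at which P is centered inside the covariance term.
        Immaterial for the result because pi is centered at its mean
        (exposed so the invariance can be asserted); defaults to Pbar.
    """
    _check_groups(groups)
    if weighting not in ("uniform", "initial_size"):
        raise ValueError(f"unknown weighting {weighting!r}")

    G = len(groups)
    one = Fraction(1) if exact else 1.0

    P = [g.initial_freq if exact else float(g.initial_freq) for g in groups]
    # Within-group change; 0 for extinct groups (their pi*dP term vanishes).
    dP = []
    for g, p in zip(groups, P):
        if g.final_size == 0:
            dP.append(0 * one)
        else:
            f = g.final_freq
            dP.append((f if exact else float(f)) - p)

    total_final = sum(g.final_size for g in groups)
    total_final_coop = sum(g.final_cooperators for g in groups)
    pooled_final = Fraction(total_final_coop, total_final)
    if not exact:
        pooled_final = float(pooled_final)

    if weighting == "uniform":
        w = [one / G] * G
        pi = [g.final_size * one for g in groups]
        p_bar = sum(wi * pi_ for wi, pi_ in zip(w, P))
    else:
        total_initial = sum(g.initial_size for g in groups)
        w = [
            (Fraction(g.initial_size, total_initial) if exact else g.initial_size / total_initial)
            for g in groups
        ]
        pi = [
            (Fraction(g.final_size, g.initial_size) if exact else g.final_size / g.initial_size)
            for g in groups
        ]
        pooled_initial = Fraction(
            sum(g.initial_cooperators for g in groups), total_initial
        )
        p_bar = pooled_initial if exact else float(pooled_initial)

    pi_bar = sum(wi * x for wi, x in zip(w, pi))
    a = p_bar if center is None else (Fraction(center) if exact else float(center))

    cov = sum(wi * (x - pi_bar) * (p - a) for wi, x, p in zip(w, pi, P))
    ave = sum(wi * x * d for wi, x, d in zip(w, pi, dP))
    var_p = sum(wi * (p - p_bar) ** 2 for wi, p in zip(w, P))

    p_bar_final = pooled_final
    delta_p = p_bar_final - p_bar
    beta = cov / var_p if var_p > 0 else None

    return PriceDecomposition(
        mean_final_size=pi_bar,
        community_initial_freq=p_bar,
        community_final_freq=p_bar_final,
        delta_p=delta_p,
        covariance_term=cov,
        expectation_term=ave,
        variance_p=var_p,
        beta=beta,
        weighting=weighting,
        n_groups=G,
    )


def price_identity_residual(
    groups: Sequence[GroupRecord],
    weighting: str = "uniform",
    exact: bool = False,
) -> float | Fraction:
    """Signed residual pibar*dPbar - Cov(pi,P) - Ave(pi*dP).

    Diagnostic surface for the identity: exactly 0 in rational mode, and
    within ~1e-9 of 0 in floating point, for any valid group list.
    """
    return price_decompose(groups, weighting=weighting, exact=exact).residual()


_TABLE_COLUMNS = ["initial_size", "initial_cooperators", "final_size", "final_cooperators"]


def read_group_table(path) -> list[GroupRecord]:
    """Read group records from a delimited text file (CSV/TSV, header required)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"group table {path} lacks required columns: {missing}")
    return [
        GroupRecord(*(int(row[c]) for c in _TABLE_COLUMNS))
        for _, row in df.iterrows()
    ]


def _printed(x: float) -> str:
    """Round half-even to the precision used in printed worked examples.

    Three significant figures for magnitudes >= 0.1, two below (so 8/3
    prints as 2.67 and 1/24 as 0.042).
    """
    if x == 0:
        return "0"
    sig = 3 if abs(x) >= 0.1 else 2
    s = f"{x:.{sig}g}"  # Python's g-format rounds half-even
    return s


def write_decomposition(dec: PriceDecomposition, path, format: str = "json") -> None:
    """Write a decomposition as JSON or a one-row CSV.

    Both carry full-precision values plus printed-precision companions
    matching the rounding of the worked examples.
    """
    d = dec.to_dict()
    printed = {
        f"{k}_printed": _printed(v)
        for k, v in d.items()
        if isinstance(v, float)
    }
    if format == "json":
        with open(path, "w") as fh:
            json.dump({**d, **printed}, fh, indent=2)
    elif format == "csv":
        pd.DataFrame([{**d, **printed}]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
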