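"""Domain types for scaffold configurations, mass peaks and candidate compounds.

The solver works on a *scaffold* — the core of a natural product left after
all terminal sidechains are removed — with ``n`` substitutable positions.
At position ``s`` there are ``k_s`` candidate sidechains, the ``j``-th having
mass ``W[s, j]`` (Da) and attachment probability ``P[s, j]``.  A compound is
one sidechain choice per position; its mass is the sum of the chosen
sidechain masses and its probability the product of the chosen attachment
probabilities.  A *mass peak* is a molecular-weight window
``[w_min, w_max]`` resolved to ``D`` decimal digits; all masses are mapped
to integers by multiplying with ``10**D`` so that compounds can be indexed
by total mass in a dynamic-programming table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CsccpError",
    "InvalidWindowError",
    "SelectionError",
    "ScaffoldConfiguration",
    "MassPeak",
    "IntegerizedProblem",
    "CandidateCompound",
    "validate_scaffold",
    "integerize",
    "evaluate_compound",
]


class CsccpError(Exception):
    """Base class for solver errors."""


class InvalidWindowError(CsccpError):
    """Mass window with w_max < w_min."""


class SelectionError(CsccpError):
    """A sidechain selection indexes outside the valid range at a position."""


@dataclass
class ScaffoldConfiguration:
    """One configuration of a scaffold: ``(n, K, W, P)`` plus bookkeeping.

    ``W`` and ``P`` are ``n x h`` arrays with ``h = max(K)``; columns
    ``j >= K[s]`` are zero-padded (both mass and probability), which keeps a
    rectangular layout while position ``s`` only offers ``K[s]`` sidechains.

    Parameters
    ----------
    scaffold_id : str
        Identifier of the parent scaffold; several configurations may share it.
    config_index : int
        Index of this configuration within its scaffold.
    K : sequence of int
        Per-position sidechain counts ``k_s`` (length ``n``).
    W : array-like, shape (n, h)
        Sidechain masses in Da.
    P : array-like, shape (n, h)
        Sidechain attachment probabilities in ``[0, 1]``.  They are *not*
        required to sum to 1 within a position and are never renormalised.
    sidechain_labels : optional
        Per-position identifier lists, for reporting only.
    """

    scaffold_id: str
    config_index: int
    K: np.ndarray
    W: np.ndarray
    P: np.ndarray
    sidechain_labels: list[list[str]] | None = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=np.int64)
        self.W = np.asarray(self.W, dtype=np.float64)
        self.P = np.asarray(self.P, dtype=np.float64)

    @property
    def n(self) -> int:
        """Number of substitutable positions."""
        return int(self.K.shape[0])

    @property
    def h(self) -> int:
        """Maximum sidechain count over positions, ``max(K)``."""
        return int(self.K.max()) if self.K.size else 0

    def labels_for(self, selection: Sequence[int]) -> list[str]:
        """Human-readable sidechain identifiers for a selection."""
        if self.sidechain_labels is not None:
            return [self.sidechain_labels[s][j] for s, j in enumerate(selection)]
        return [f"s{s}j{j}" for s, j in enumerate(selection)]


def validate_scaffold(cfg: ScaffoldConfiguration) -> list[str]:
    """Check all configuration invariants; return violation descriptions.

    Returns an empty list iff the configuration is valid.  Violations are
    reported (never raised) so that a batch run can log and skip bad files.
    """
    violations: list[str] = []
    K, W, P = cfg.K, cfg.W, cfg.P
    n = cfg.n
    if n == 0:
        violations.append("configuration has no positions (n = 0)")
        return violations
    if np.any(K < 1):
        bad = np.flatnonzero(K < 1)
        for s in bad:
            violations.append(f"position {s}: sidechain count k_s = {K[s]} < 1")
    if W.shape != P.shape or W.shape[0] != n:
        violations.append(
            f"shape mismatch: W {W.shape}, P {P.shape}, expected ({n}, h)"
        )
        return violations
    h = W.shape[1]
    if K.max() != h:
        violations.append(
            f"h = {h} columns but max(K) = {int(K.max())}; W/P must have h = max(K)"
        )
    for s in range(n):
        for j in range(h):
            w, p = W[s, j], P[s, j]
            if j >= K[s]:
                # padding rule: beyond k_s both mass and probability are zero
                if p != 0.0 or w != 0.0:
                    violations.append(
                        f"position {s}, index {j}: padding rule violated "
                        f"(j >= k_s = {int(K[s])} requires w = p = 0, "
                        f"got w = {w}, p = {p})"
                    )
            else:
                if w < 0.0 or not math.isfinite(w):
                    violations.append(
                        f"position {s}, index {j}: weight {w} negative or non-finite"
                    )
                if not (0.0 <= p <= 1.0):
                    violations.append(
                        f"position {s}, index {j}: probability {p} outside [0,1]"
                    )
    return violations


@dataclass(frozen=True)
class MassPeak:
    """A molecular-weight window ``[w_min, w_max]`` in Da at ``D`` decimals."""

    w_min: float
    w_max: float
    D: int = 5

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")


@dataclass
class IntegerizedProblem:
    """Integer form of a (peak, configuration) pair: masses scaled by 10**D.

    ``warnings`` records any weight whose scaled value was not already an
    integer to within 1e-6 — on conforming inputs (masses carrying at most
    ``D`` decimals) rounding is exact and this list is empty.
    """

    w_prime_min: int
    w_prime_max: int
    W_prime: np.ndarray
    D: int
    warnings: list[str] = field(default_factory=list)


def _round_half_away(x: float) -> int:
    # round-to-nearest, ties away from zero; x >= 0 throughout this package
    return int(math.floor(x + 0.5))


def integerize(peak: MassPeak, cfg: ScaffoldConfiguration) -> IntegerizedProblem:
    """Scale the peak window and the weight matrix by ``10**D`` to integers.

    Raises
    ------
    InvalidWindowError
        If ``peak.w_max < peak.w_min``.
    """
    if peak.w_max < peak.w_min:
        raise InvalidWindowError(
            f"w_max = {peak.w_max} < w_min = {peak.w_min}"
        )
    scale = 10 ** peak.D
    warnings: list[str] = []
    W_prime = np.zeros(cfg.W.shape, dtype=np.int64)
    for s in range(cfg.W.shape[0]):
        for j in range(cfg.W.shape[1]):
            scaled = cfg.W[s, j] * scale
            r = _round_half_away(scaled)
            if abs(scaled - r) > 1e-6:
                warnings.append(
                    f"position {s}, sidechain {j}: weight {cfg.W[s, j]} has more "
                    f"than D = {peak.D} decimals (residual {abs(scaled - r):.3g})"
                )
            W_prime[s, j] = r
    return IntegerizedProblem(
        w_prime_min=_round_half_away(peak.w_min * scale),
        w_prime_max=_round_half_away(peak.w_max * scale),
        W_prime=W_prime,
        D=peak.D,
        warnings=warnings,
    )


@dataclass(frozen=True)
class CandidateCompound:
    """One solved compound: a sidechain index per position, ranked."""

    selection: tuple[int, ...]
    total_mass_int: int  # units of 10**-D Da
    probability: float
    rank: int

    def mass_da(self, D: int) -> float:
        return self.total_mass_int / 10**D


def evaluate_compound(
    cfg: ScaffoldConfiguration,
    selection: Sequence[int],
    problem: IntegerizedProblem | None = None,
) -> tuple[int, float]:
    """Integer total sidechain mass and probability of an explicit selection.

    The mass is the sum of integerized sidechain weights and the probability
    the product of attachment probabilities, folded left-to-right in position
    order (bit-identical to the DP recurrence, which multiplies one factor
    per position onto a running product).

    If ``problem`` is omitted, ``W`` is assumed integer-valued (D = 0).
    """
    sel = list(selection)
    if len(sel) != cfg.n:
        raise SelectionError(f"selection length {len(sel)} != n = {cfg.n}")
    for s, j in enumerate(sel):
        if not (0 <= j < cfg.K[s]):
            raise SelectionError(
                f"position {s}: index {j} outside [0, {int(cfg.K[s])})"
            )
    if problem is None:
        W_int = np.rint(cfg.W).astype(np.int64)
    else:
        W_int = problem.W_prime
    total = int(sum(int(W_int[s, j]) for s, j in enumerate(sel)))
    prob = 1.0
    for s, j in enumerate(sel):
        prob = prob * float(cfg.P[s, j])
    return total, prob
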