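"""Two-phase top-R dynamic program for the CSCCP, plus a brute-force oracle.

Phase one sweeps the ``n`` scaffold positions.  For position ``s`` it fills
a layer of cells indexed by integer total mass ``w`` in ``[0, w'_max]`` and
rank ``r`` in ``[0, R)``: cell ``(w, r)`` holds the r-th highest probability
of any partial compound over positions ``0..s`` whose integerized sidechain
masses sum to ``w``.  A cell is updated from the previous layer by trying
every sidechain ``k`` at ``s`` against every predecessor rank at mass
``w - W'[s, k]`` (the knapsack recurrence), ranking the ``k_s * R``
candidate products and keeping the best R.  Only two probability layers are
live at a time (rolling C-/C+ buffers); traceback — which ``(k, r_prev)``
produced each cell — is kept either as one raw layer per position or
bit-packed into two 32-bit words carried along with each cell (see
:mod:`csccp.compression`).

Phase two collects all final-layer cells with mass inside the peak window,
ranks them, and backtracks each to an explicit sidechain selection.

Probabilities with exact float ties are ordered deterministically:
probability descending, then sidechain index ``k`` ascending, then
predecessor rank ``r_prev`` ascending (final ranking additionally by mass
``w`` then rank ``r`` ascending).  Distinct ``(k, r_prev)`` entries at a
cell index distinct partial compounds by construction — two entries with
the same ``k`` extend different predecessor compounds, and entries with
different ``k`` differ at position ``s`` itself — so no deduplication is
needed.

Two update engines are provided: a plain sequential loop (the reference
semantics) and a vectorized engine that updates all masses of a layer
simultaneously, mirroring a one-thread-per-mass parallelisation.  They are
required — and tested — to produce bit-identical tables.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .compression import (
    PackedTraceback,
    TracebackRecord,
    bits_for_rank,
    check_compression_feasible,
    field_offsets,
    pack,
    unpack,
)
from .model import (
    CandidateCompound,
    CsccpError,
    IntegerizedProblem,
    MassPeak,
    ScaffoldConfiguration,
    evaluate_compound,
    integerize,
    validate_scaffold,
)
from .resources import DeviceProfile, FeasibilityVerdict, classify_integerized

__all__ = [
    "FeasibilityError",
    "TracebackCorruptionError",
    "StateTable",
    "state_update",
    "dp_forward",
    "finalize_top_r",
    "backtrack",
    "solve_csccp",
    "brute_force_solve",
]

logger = logging.getLogger(__name__)

Engine = Literal["vectorized", "sequential"]
TracebackMode = Literal["raw", "packed"]


class FeasibilityError(CsccpError):
    """Instance refused because it violates the modelled device limits."""

    def __init__(self, verdict: FeasibilityVerdict):
        self.verdict = verdict
        super().__init__(
            f"instance classified {verdict.category!r} for the modelled device "
            f"(detail: {verdict.detail}); pass force=True to solve anyway"
        )


class TracebackCorruptionError(CsccpError):
    """Internal consistency failure while walking the traceback."""


@dataclass
class StateTable:
    """Forward-pass output: final probability layer plus traceback storage.

    ``C_plus`` is the final layer (shape ``(w'_max + 1, R)``); a cell with
    probability 0 is invalid/unreachable.  In raw mode ``layers[s]`` holds
    the per-position traceback as two int arrays ``(k, r_prev)`` with -1
    marking invalid cells; in packed mode ``k_words``/``r_words`` carry the
    whole path for every final cell.  ``stats`` records instrumentation
    (state-update count, table sizes, valid final cells).
    """

    C_plus: np.ndarray
    R: int
    mode: TracebackMode
    layers: list[tuple[np.ndarray, np.ndarray]] | None = None
    k_words: np.ndarray | None = None
    r_words: np.ndarray | None = None
    stats: dict = field(default_factory=dict)


def state_update(
    cfg: ScaffoldConfiguration,
    problem: IntegerizedProblem,
    C_minus: np.ndarray,
    s: int,
    w: int,
    R: int,
) -> tuple[list[float], list[TracebackRecord | None]]:
    """Rank the candidate extensions of one cell ``(s, w)``.

    Builds the candidate set over ``k in [0, k_s)`` and predecessor rank
    ``r in [0, R)`` with probability ``P[s, k] * C_minus[w - W'[s, k], r]``
    (candidates with negative predecessor mass or zero probability are
    dropped), sorts by probability descending with ties broken by ``k`` then
    ``r_prev`` ascending, and returns the top R probabilities and traceback
    records.  Unfilled ranks come back as probability 0 with record ``None``.
    """
    entries: list[tuple[float, int, int]] = []
    k_s = int(cfg.K[s])
    for k in range(k_s):
        wp = w - int(problem.W_prime[s, k])
        if wp < 0:
            continue
        p = float(cfg.P[s, k])
        for r in range(R):
            prob = p * float(C_minus[wp, r])
            if prob > 0.0:
                entries.append((prob, k, r))
    # stable sort on descending probability; generation order is (k, r_prev)
    # ascending, so ties already sit in the required order
    entries.sort(key=lambda e: -e[0])
    probs: list[float] = [0.0] * R
    records: list[TracebackRecord | None] = [None] * R
    for rank, (prob, k, r_prev) in enumerate(entries[:R]):
        probs[rank] = prob
        records[rank] = TracebackRecord(k=k, r_prev=r_prev)
    return probs, records


def _base_layer(w_prime_max: int, R: int) -> np.ndarray:
    # virtual layer s = -1: the empty selection, mass 0, probability 1, rank 0
    C = np.zeros((w_prime_max + 1, R), dtype=np.float64)
    C[0, 0] = 1.0
    return C


def dp_forward(
    cfg: ScaffoldConfiguration,
    problem: IntegerizedProblem,
    R: int,
    *,
    engine: Engine = "vectorized",
    traceback: TracebackMode = "raw",
    device: DeviceProfile | None = None,
    force: bool = False,
) -> StateTable:
    """Run phase one over all positions; return the final layer + traceback.

    If ``device`` is given, the instance is first classified against its
    limits and refused with :class:`FeasibilityError` unless ``force`` is
    set (the limits are a device artifact; on CPU the refusal is advisory).
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    if device is not None and not force:
        verdict = classify_integerized(cfg.K, R, problem.w_prime_max, device)
        if not verdict.feasible:
            raise FeasibilityError(verdict)
    if traceback == "packed":
        eq1, eq2 = check_compression_feasible(cfg.K, R)
        if not (eq1 and eq2):
            raise FeasibilityError(
                classify_integerized(cfg.K, R, problem.w_prime_max)
            )
    if engine == "sequential":
        table = _forward_sequential(cfg, problem, R, traceback)
    else:
        table = _forward_vectorized(cfg, problem, R, traceback)
    n_valid = int(np.count_nonzero(table.C_plus > 0.0))
    table.stats["valid_final_cells"] = n_valid
    table.stats["w_prime_max"] = problem.w_prime_max
    logger.info(
        "forward pass: n=%d h=%d R=%d D=%d w'_max=%d cells=%d valid_final=%d",
        cfg.n, cfg.h, R, problem.D, problem.w_prime_max,
        table.stats["cells"], n_valid,
    )
    return table


def _forward_sequential(
    cfg: ScaffoldConfiguration,
    problem: IntegerizedProblem,
    R: int,
    traceback: TracebackMode,
) -> StateTable:
    n = cfg.n
    Wp1 = problem.w_prime_max + 1
    k_off, r_off, _ = field_offsets(cfg.K, R) if traceback == "packed" else ([], [], 0)
    C_minus = _base_layer(problem.w_prime_max, R)
    layers: list[tuple[np.ndarray, np.ndarray]] = []
    pk_minus = np.zeros((Wp1, R), dtype=np.uint32)
    pr_minus = np.zeros((Wp1, R), dtype=np.uint32)
    updates = 0
    for s in range(n):
        C_plus = np.zeros_like(C_minus)
        k_arr = np.full((Wp1, R), -1, dtype=np.int32)
        r_arr = np.full((Wp1, R), -1, dtype=np.int32)
        pk_plus = np.zeros((Wp1, R), dtype=np.uint32)
        pr_plus = np.zeros((Wp1, R), dtype=np.uint32)
        for w in range(Wp1):
            probs, records = state_update(cfg, problem, C_minus, s, w, R)
            updates += 1
            for r, (prob, rec) in enumerate(zip(probs, records)):
                if rec is None:
                    continue
                C_plus[w, r] = prob
                k_arr[w, r] = rec.k
                r_arr[w, r] = rec.r_prev
                if traceback == "packed":
                    wp = w - int(problem.W_prime[s, rec.k])
                    pk_plus[w, r] = pk_minus[wp, rec.r_prev] | np.uint32(
                        rec.k << k_off[s]
                    )
                    pr_plus[w, r] = pr_minus[wp, rec.r_prev] | np.uint32(
                        rec.r_prev << r_off[s]
                    )
        if traceback == "raw":
            layers.append((k_arr, r_arr))
        else:
            pk_minus, pr_minus = pk_plus, pr_plus
        C_minus = C_plus
    stats = {"state_updates": updates, "cells": n * Wp1 * R}
    if traceback == "raw":
        return StateTable(C_plus=C_minus, R=R, mode="raw", layers=layers, stats=stats)
    return StateTable(
        C_plus=C_minus, R=R, mode="packed", k_words=pk_minus, r_words=pr_minus,
        stats=stats,
    )


def _forward_vectorized(
    cfg: ScaffoldConfiguration,
    problem: IntegerizedProblem,
    R: int,
    traceback: TracebackMode,
) -> StateTable:
    """All-masses-at-once update; bit-identical to the sequential engine.

    Candidate ``j = k * R + r_prev`` for each mass row; a stable argsort on
    descending probability therefore breaks exact ties by ``k`` then
    ``r_prev`` ascending, exactly as the sequential sort does.
    """
    n = cfg.n
    Wp1 = problem.w_prime_max + 1
    k_off, r_off, _ = field_offsets(cfg.K, R) if traceback == "packed" else ([], [], 0)
    C_minus = _base_layer(problem.w_prime_max, R)
    layers: list[tuple[np.ndarray, np.ndarray]] = []
    pk_minus = np.zeros((Wp1, R), dtype=np.uint32)
    pr_minus = np.zeros((Wp1, R), dtype=np.uint32)
    w_col = np.arange(Wp1, dtype=np.int64)[:, None]
    updates = 0
    for s in range(n):
        k_s = int(cfg.K[s])
        cand = np.zeros((Wp1, k_s * R), dtype=np.float64)
        for k in range(k_s):
            wk = int(problem.W_prime[s, k])
            p = float(cfg.P[s, k])
            if wk >= Wp1:
                continue
            if wk == 0:
                cand[:, k * R : (k + 1) * R] = p * C_minus
            else:
                cand[wk:, k * R : (k + 1) * R] = p * C_minus[:-wk]
        order = np.argsort(-cand, axis=1, kind="stable")[:, :R]
        probs = np.take_along_axis(cand, order, axis=1)
        valid = probs > 0.0
        k_sel = (order // R).astype(np.int32)
        r_sel = (order % R).astype(np.int32)
        updates += Wp1
        if traceback == "raw":
            layers.append(
                (np.where(valid, k_sel, -1), np.where(valid, r_sel, -1))
            )
        else:
            k_safe = np.where(valid, k_sel, 0)
            r_safe = np.where(valid, r_sel, 0)
            pred_w = np.where(valid, w_col - problem.W_prime[s][k_safe], 0)
            shifts_k = np.uint32(k_off[s])
            shifts_r = np.uint32(r_off[s])
            pk_plus = np.where(
                valid,
                pk_minus[pred_w, r_safe] | (k_safe.astype(np.uint32) << shifts_k),
                np.uint32(0),
            ).astype(np.uint32)
            pr_plus = np.where(
                valid,
                pr_minus[pred_w, r_safe] | (r_safe.astype(np.uint32) << shifts_r),
                np.uint32(0),
            ).astype(np.uint32)
            pk_minus, pr_minus = pk_plus, pr_plus
        C_minus = np.where(valid, probs, 0.0)
    stats = {"state_updates": updates, "cells": n * Wp1 * R}
    if traceback == "raw":
        return StateTable(C_plus=C_minus, R=R, mode="raw", layers=layers, stats=stats)
    return StateTable(
        C_plus=C_minus, R=R, mode="packed", k_words=pk_minus, r_words=pr_minus,
        stats=stats,
    )


def finalize_top_r(
    table: StateTable, problem: IntegerizedProblem, R: int
) -> list[tuple[int, int, float]]:
    """Phase two ranking: top R final cells with mass inside the window.

    Returns at most R ``(w, r, prob)`` triples sorted by probability
    descending, then mass ``w`` ascending, then rank ``r`` ascending.
    Empty when no reachable compound lies in ``[w'_min, w'_max]``.
    """
    lo = max(problem.w_prime_min, 0)
    hi = min(problem.w_prime_max, table.C_plus.shape[0] - 1)
    if lo > hi:
        return []
    window = table.C_plus[lo : hi + 1]
    w_idx, r_idx = np.nonzero(window > 0.0)
    if w_idx.size == 0:
        return []
    probs = window[w_idx, r_idx]
    order = np.lexsort((r_idx, w_idx, -probs))[:R]
    return [
        (int(w_idx[i]) + lo, int(r_idx[i]), float(probs[i])) for i in order
    ]


def backtrack(
    table: StateTable, problem: IntegerizedProblem, cfg: ScaffoldConfiguration,
    w: int, r: int,
) -> tuple[int, ...]:
    """Recover the sidechain selection behind final cell ``(w, r)``.

    Raw mode walks positions ``n-1 .. 0``, reading ``(k, r_prev)`` at each
    layer and stepping the mass down by the chosen sidechain weight; packed
    mode decodes the cell's two words directly.  The walk must terminate at
    mass 0 or the traceback is corrupt.
    """
    n = cfg.n
    if table.mode == "packed":
        assert table.k_words is not None and table.r_words is not None
        packed = PackedTraceback(
            k_word=int(table.k_words[w, r]), r_word=int(table.r_words[w, r])
        )
        records = unpack(packed, cfg.K, table.R)
        selection = tuple(rec.k for rec in records)
        residual = w - int(sum(int(problem.W_prime[s, k]) for s, k in enumerate(selection)))
        if residual != 0:
            raise TracebackCorruptionError(
                f"packed traceback at (w={w}, r={r}) sums to {w - residual}, not {w}"
            )
        return selection
    assert table.layers is not None
    selection = [0] * n
    for s in range(n - 1, -1, -1):
        k_arr, r_arr = table.layers[s]
        k = int(k_arr[w, r])
        r_prev = int(r_arr[w, r])
        if k < 0:
            raise TracebackCorruptionError(
                f"invalid cell reached at position {s} (w={w}, r={r})"
            )
        selection[s] = k
        w -= int(problem.W_prime[s, k])
        if w < 0:
            raise TracebackCorruptionError(
                f"mass underflow at position {s} (k={k})"
            )
        r = r_prev
    if w != 0:
        raise TracebackCorruptionError(f"nonzero terminal mass {w}")
    return tuple(selection)


def solve_csccp(
    cfg: ScaffoldConfiguration,
    peak: MassPeak,
    R: int,
    *,
    engine: Engine = "vectorized",
    traceback: TracebackMode = "raw",
    device: DeviceProfile | None = None,
    force: bool = False,
) -> list[CandidateCompound]:
    """Top-R most probable compounds with total sidechain mass in the window.

    Composition of integerize -> forward DP -> window ranking -> backtrack.
    Every returned compound has probability > 0 and integer mass inside
    ``[w'_min, w'_max]``; ranks run 0 (best) upward.  Fewer than R compounds
    are returned when fewer exist.
    """
    violations = validate_scaffold(cfg)
    if violations:
        raise CsccpError(
            "invalid scaffold configuration: " + "; ".join(violations)
        )
    problem = integerize(peak, cfg)
    table = dp_forward(
        cfg, problem, R, engine=engine, traceback=traceback,
        device=device, force=force,
    )
    ranked = finalize_top_r(table, problem, R)
    out: list[CandidateCompound] = []
    for rank, (w, r, prob) in enumerate(ranked):
        selection = backtrack(table, problem, cfg, w, r)
        mass_chk, prob_chk = evaluate_compound(cfg, selection, problem)
        if mass_chk != w or not math.isclose(prob_chk, prob, rel_tol=1e-12, abs_tol=0.0):
            raise TracebackCorruptionError(
                f"cell (w={w}, r={r}, prob={prob}) backtracked to {selection} "
                f"which re-evaluates to (mass={mass_chk}, prob={prob_chk})"
            )
        out.append(
            CandidateCompound(
                selection=selection, total_mass_int=w, probability=prob, rank=rank
            )
        )
    return out


def brute_force_solve(
    cfg: ScaffoldConfiguration,
    peak: MassPeak,
    R: int,
    *,
    cap: int = 10**6,
) -> list[CandidateCompound]:
    """Exhaustive oracle: enumerate every selection, filter, sort, truncate.

    Enumerates the full product space of per-position sidechain choices
    (refused above ``cap`` selections), keeps those with integer mass inside
    the window, sorts by probability descending with ties broken by the
    lexicographically smallest selection, and returns the top R.  Intended
    as the independent reference the DP is verified against.
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    violations = validate_scaffold(cfg)
    if violations:
        raise CsccpError(
            "invalid scaffold configuration: " + "; ".join(violations)
        )
    space = 1
    for k in cfg.K:
        space *= int(k)
    if space > cap:
        raise CsccpError(f"search space {space} exceeds cap {cap}")
    problem = integerize(peak, cfg)
    hits: list[tuple[float, tuple[int, ...], int]] = []
    for selection in itertools.product(*(range(int(k)) for k in cfg.K)):
        mass = int(sum(int(problem.W_prime[s, j]) for s, j in enumerate(selection)))
        if not (problem.w_prime_min <= mass <= problem.w_prime_max):
            continue
        prob = 1.0
        for s, j in enumerate(selection):
            prob = prob * float(cfg.P[s, j])
        if prob > 0.0:
            hits.append((prob, selection, mass))
    hits.sort(key=lambda t: (-t[0], t[1]))
    return [
        CandidateCompound(
            selection=sel, total_mass_int=mass, probability=prob, rank=rank
        )
        for rank, (prob, sel, mass) in enumerate(hits[:R])
    ]
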