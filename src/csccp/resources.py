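"""Device resource accounting and problem-feasibility classification.

The DP table is indexed by integer mass up to ``w'_max = w_max * 10**D``,
so memory grows tenfold per mass decimal digit.  On an accelerator this is
the binding constraint: the rolling probability buffers and the packed
traceback each cost ``8 * w'_max * R`` bytes of global memory (16 bytes per
(w, r) cell in total), per-block sort buffers of ``8 * h * R`` bytes per
thread bound the threads per block through shared memory, and the
traceback packing must fit two 32-bit words.  This module reproduces that
accounting for a reference device (11 440 MiB global / 48 KiB shared
memory) and classifies instances as feasible or not, so the solver can
refuse — or a survey can tabulate — configurations a device could not run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .compression import check_compression_feasible
from .model import ScaffoldConfiguration

__all__ = [
    "DeviceProfile",
    "DEFAULT_DEVICE",
    "FeasibilityVerdict",
    "FEASIBLE",
    "INSUFFICIENT_GLOBAL_MEMORY",
    "COMPRESSION_IMPOSSIBLE",
    "BOTH_PROBLEMS",
    "state_memory_bytes",
    "c_matrix_saving_fraction",
    "max_target_weight",
    "max_threads_per_block",
    "classify_feasibility",
    "classify_integerized",
    "feasibility_report",
]

# Bytes per (w, r) cell for one float buffer plus its mirror (C- and C+),
# and likewise for the two packed traceback words: 8 bytes each.
_BYTES_PER_CELL_C = 8
_BYTES_PER_CELL_L = 8
_BYTES_PER_BUFFER_ENTRY = 8  # per-thread shared-memory sort buffer entry


@dataclass(frozen=True)
class DeviceProfile:
    """Resource limits of the accelerator being modelled.

    Defaults describe the reference card: 11 440 MiB of global memory,
    49 152 bytes of shared memory per block, at most 1024 threads per block.
    """

    global_memory_bytes: int = 11_440 * 2**20
    shared_memory_bytes: int = 49_152
    max_threads_hw: int = 1024

    def __post_init__(self) -> None:
        if min(self.global_memory_bytes, self.shared_memory_bytes, self.max_threads_hw) <= 0:
            raise ValueError("device limits must be positive")


DEFAULT_DEVICE = DeviceProfile()

FEASIBLE = "feasible"
INSUFFICIENT_GLOBAL_MEMORY = "insufficient_global_memory"
COMPRESSION_IMPOSSIBLE = "compression_impossible"
BOTH_PROBLEMS = "both_problems"

CATEGORIES = (FEASIBLE, INSUFFICIENT_GLOBAL_MEMORY, COMPRESSION_IMPOSSIBLE, BOTH_PROBLEMS)


@dataclass(frozen=True)
class FeasibilityVerdict:
    """Why an instance can or cannot run on the modelled device."""

    category: str
    detail: dict = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        return self.category == FEASIBLE


def state_memory_bytes(R: int, D: int, w_max: float) -> int:
    """Global memory for DP state: ``16 * R * w_max * 10**D`` bytes.

    8 bytes per (w, r) cell for the rolling probability buffers plus 8 for
    the packed traceback words.
    """
    w_prime_max = int(round(w_max * 10**D))
    return (_BYTES_PER_CELL_C + _BYTES_PER_CELL_L) * R * w_prime_max


def c_matrix_saving_fraction(n: int) -> float:
    """Percent of cost-matrix memory saved by rolling two layers: 100(1-2/n)."""
    if n < 2:
        raise ValueError(f"rolling buffers need n >= 2, got {n}")
    return 100.0 * (1.0 - 2.0 / n)


def max_target_weight(R: int, D: int, device: DeviceProfile = DEFAULT_DEVICE) -> int:
    """Largest w_max (Da) whose DP state fits the device's global memory."""
    if R < 1 or D < 0:
        raise ValueError("need R >= 1 and D >= 0")
    return device.global_memory_bytes // ((_BYTES_PER_CELL_C + _BYTES_PER_CELL_L) * R * 10**D)


def max_threads_per_block(R: int, h: int, device: DeviceProfile = DEFAULT_DEVICE) -> int:
    """Largest power-of-two thread count whose sort buffers fit shared memory.

    Each thread ranks up to ``h * R`` candidate extensions in a shared-memory
    buffer at 8 bytes per entry, so T threads need ``T * h * R * 8`` bytes.
    The result is capped at the hardware thread limit.
    """
    if R < 1 or h < 1:
        raise ValueError("need R >= 1 and h >= 1")
    bound = device.shared_memory_bytes // (h * R * _BYTES_PER_BUFFER_ENTRY)
    if bound < 1:
        raise ValueError(
            f"one thread's buffer ({h * R * _BYTES_PER_BUFFER_ENTRY} B) exceeds "
            f"shared memory ({device.shared_memory_bytes} B)"
        )
    t = 1
    while t * 2 <= min(bound, device.max_threads_hw):
        t *= 2
    return t


def classify_integerized(
    K: Sequence[int],
    R: int,
    w_prime_max: int,
    device: DeviceProfile = DEFAULT_DEVICE,
) -> FeasibilityVerdict:
    """Feasibility verdict from already-integerized quantities."""
    mem = (_BYTES_PER_CELL_C + _BYTES_PER_CELL_L) * R * w_prime_max
    mem_bad = mem > device.global_memory_bytes
    eq1_ok, eq2_ok = check_compression_feasible(K, R)
    comp_bad = not (eq1_ok and eq2_ok)
    if mem_bad and comp_bad:
        category = BOTH_PROBLEMS
    elif mem_bad:
        category = INSUFFICIENT_GLOBAL_MEMORY
    elif comp_bad:
        category = COMPRESSION_IMPOSSIBLE
    else:
        category = FEASIBLE
    return FeasibilityVerdict(
        category=category,
        detail={
            "state_memory_bytes": mem,
            "global_memory_bytes": device.global_memory_bytes,
            "eq1_ok": eq1_ok,
            "eq2_ok": eq2_ok,
        },
    )


def classify_feasibility(
    cfg: ScaffoldConfiguration,
    R: int,
    D: int,
    w_max: float,
    device: DeviceProfile = DEFAULT_DEVICE,
) -> FeasibilityVerdict:
    """Classify a (configuration, R, D, w_max) instance for the device."""
    return classify_integerized(cfg.K, R, int(round(w_max * 10**D)), device)


def feasibility_report(
    configurations: Iterable[ScaffoldConfiguration],
    R: int,
    w_max: float,
    D_values: Sequence[int],
    device: DeviceProfile = DEFAULT_DEVICE,
) -> pd.DataFrame:
    """Tabulate feasibility over a configuration set for each D.

    Returns one row per D with the percentage of feasible configurations
    (2 d.p.) and the count in each verdict category.
    """
    cfgs = list(configurations)
    if not cfgs:
        raise ValueError("configuration set is empty")
    rows = []
    for D in D_values:
        counts = {c: 0 for c in CATEGORIES}
        for cfg in cfgs:
            verdict = classify_feasibility(cfg, R, D, w_max, device)
            counts[verdict.category] += 1
        total = len(cfgs)
        rows.append(
            {
                "D": D,
                "total": total,
                "feasible_pct": round(100.0 * counts[FEASIBLE] / total, 2),
                **counts,
            }
        )
    return pd.DataFrame(rows).set_index("D")
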