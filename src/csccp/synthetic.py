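"""Deterministic generator of scaffold configurations and mass peaks.

Emulates the structural statistics of a natural-product scaffold database —
a handful of substitutable positions, around four candidate sidechains per
position, sidechain masses of tens of Da quantized to a fixed number of
decimals, and per-position attachment probabilities — so every solver path
can be exercised without any external dataset.  Weights are drawn uniformly
and rounded to exactly ``digits`` decimals, which makes integerization
exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MassPeak, ScaffoldConfiguration, evaluate_compound, integerize

__all__ = ["GeneratorSpec", "generate_scaffold", "generate_peak_for", "generate_instance"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic scaffold distribution.

    Defaults mirror typical scaffold statistics: 2-6 substitutable
    positions, 2-4 sidechains per position (a database-wide mean of about
    4 possible sidechains), sidechain masses 1-150 Da at 2 decimals, and
    attachment probabilities normalised within each position (attachment
    frequencies).  ``uniform01`` mode instead draws raw probabilities in
    [0, 1] to exercise the weaker contract the solver actually requires.
    """

    n_range: tuple[int, int] = (2, 6)
    k_range: tuple[int, int] = (2, 4)
    weight_range: tuple[float, float] = (1.0, 150.0)
    digits: int = 2
    prob_mode: str = "normalized-per-position"  # or "uniform01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_range[0] > self.n_range[1] or self.n_range[0] < 1:
            raise ValueError(f"bad n_range {self.n_range}")
        if self.k_range[0] > self.k_range[1] or self.k_range[0] < 1:
            raise ValueError(f"bad k_range {self.k_range}")
        if self.weight_range[0] > self.weight_range[1] or self.weight_range[0] < 0:
            raise ValueError(f"bad weight_range {self.weight_range}")
        if self.digits < 0:
            raise ValueError("digits must be >= 0")
        if self.prob_mode not in ("normalized-per-position", "uniform01"):
            raise ValueError(f"unknown prob_mode {self.prob_mode!r}")


def generate_scaffold(spec: GeneratorSpec) -> ScaffoldConfiguration:
    """Draw one valid scaffold configuration; same spec => same output."""
    rng = np.random.default_rng(spec.seed)
    n = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
    K = rng.integers(spec.k_range[0], spec.k_range[1] + 1, size=n)
    h = int(K.max())
    W = np.zeros((n, h))
    P = np.zeros((n, h))
    labels: list[list[str]] = []
    for s in range(n):
        k_s = int(K[s])
        w = rng.uniform(spec.weight_range[0], spec.weight_range[1], size=k_s)
        W[s, :k_s] = np.round(w, spec.digits)
        p = rng.uniform(0.0, 1.0, size=k_s)
        if spec.prob_mode == "normalized-per-position":
            p = p / p.sum()
        P[s, :k_s] = p
        labels.append([f"SC{s}_{j}" for j in range(k_s)])
    return ScaffoldConfiguration(
        scaffold_id=f"SYN{spec.seed}",
        config_index=0,
        K=K,
        W=W,
        P=P,
        sidechain_labels=labels,
    )


def generate_peak_for(
    cfg: ScaffoldConfiguration,
    spec: GeneratorSpec,
    rng: np.random.Generator,
    max_half_width: float = 0.5,
) -> MassPeak:
    """A mass window guaranteed to contain at least one compound of ``cfg``.

    Picks a random selection, centres the window on its total sidechain
    mass, and widens it by a random half-width in ``[0, max_half_width]`` Da
    (0 gives a degenerate window containing exactly that mass).
    """
    selection = tuple(int(rng.integers(0, int(k))) for k in cfg.K)
    # exact mass on the 10**-digits grid, via the integerized weights
    probe = integerize(MassPeak(0.0, 1.0, spec.digits), cfg)
    mass_int, _ = evaluate_compound(cfg, selection, probe)
    mass = mass_int / 10**spec.digits
    hw = float(rng.uniform(0.0, max_half_width)) if max_half_width > 0 else 0.0
    hw = round(hw, spec.digits)
    return MassPeak(w_min=max(mass - hw, 0.0), w_max=mass + hw, D=spec.digits)


def generate_instance(
    seed: int, spec: GeneratorSpec | None = None
) -> tuple[ScaffoldConfiguration, MassPeak]:
    """Convenience: a (configuration, peak) pair from a single seed."""
    base = spec if spec is not None else GeneratorSpec()
    spec_s = GeneratorSpec(
        n_range=base.n_range,
        k_range=base.k_range,
        weight_range=base.weight_range,
        digits=base.digits,
        prob_mode=base.prob_mode,
        seed=seed,
    )
    cfg = generate_scaffold(spec_s)
    rng = np.random.default_rng(seed + 10_000_019)
    peak = generate_peak_for(cfg, spec_s, rng)
    return cfg, peak
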