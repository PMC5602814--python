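# Methods

## Problem

A natural-product *scaffold* is the core structure left after removing all
terminal sidechains. A *configuration* of a scaffold fixes `n`
substitutable positions; position `s` offers `k_s` candidate sidechains,
the `j`-th with mass `W[s,j]` (Da) and attachment probability `P[s,j]`
estimated from a reference database. Choosing one sidechain per position
yields a compound `x` with mass `g(x) = sum_s W[s, x_s]` and probability
`f(x) = prod_s P[s, x_s]`. Given an LC–MS-derived molecular-weight window
`[w_min, w_max]` at `D` decimal digits, the chemical substituent core
combinatorial problem (CSCCP) asks for the `R` compounds of highest `f(x)`
with `g(x)` inside the window. The search space is a full product space
(`prod_s k_s` compounds), so exhaustive enumeration is exponential in `n`;
the solver here is pseudo-polynomial instead, `O(n · w'_max · R · h)` after
integerizing masses.

## Dynamic program

All masses are multiplied by `10^D` and rounded to the nearest integer
(ties away from zero). Inputs are assumed to carry at most `D` decimals, in
which case the rounding is exact; any weight with a larger residual than
1e-6 of a grid unit is surfaced as a warning rather than silently
truncated. The DP table cell `(s, w, r)` holds the `r`-th highest
probability of a partial compound over positions `0..s` with integer mass
exactly `w`. The base state is a virtual layer before position 0 holding
probability 1 at mass 0, rank 0 (the empty selection); the recurrence
ranks, for each `(s, w)`, all products `P[s,k] · c_{s-1, w - W'[s,k], r}`
over sidechains `k` and predecessor ranks `r`, keeping the best `R`.
Keeping `R` ranks per state is sound because extending a predecessor by a
fixed factor preserves its internal order — the top-`R` at `(s, w)` can
only extend top-`R` predecessors. Distinct `(k, r_prev)` candidates at one
state denote distinct partial compounds (different `k` differ at position
`s`; equal `k` with different `r_prev` extend different predecessor
compounds), so no deduplication is needed.

Phase two scans the final layer over `w ∈ [w'_min, w'_max]`, ranks the
valid cells, and backtracks each through the stored `(k, r_prev)` tuples to
an explicit selection. Every returned selection is re-evaluated from the
input matrices; a mismatch with its cell raises an internal-consistency
error rather than returning silently wrong output.

### Determinism and ties

Floating-point probability ties are broken deterministically: probability
descending, then sidechain index `k` ascending, then predecessor rank
ascending; the final ranking additionally by mass then rank ascending.
Note this orders tied compounds by their selection read from the *last*
position backwards, whereas the brute-force oracle orders tied compounds by
lexicographically smallest selection — for continuous probability inputs
exact float ties essentially never arise (the DP and the oracle compute
bit-identical products, both folding the same factors one position at a
time), so the two orders coincide in practice; tie-heavy constructed cases
are compared by probability multiset in the tests.

### Probability arithmetic

Probabilities are multiplied in double precision in the linear domain, as a
direct product per position. This mirrors the recurrence exactly and keeps
DP and oracle bit-identical, but underflows for very deep scaffolds
(roughly `n ≫ 30` with small per-position probabilities); a log-domain
variant is deliberately not used because it would break the exact
equivalence checks. Probabilities are *not* required to sum to 1 within a
position and are never renormalised by the solver.

### Update engines

Two interchangeable engines implement the layer update:

* `sequential` — the reference four-nested-loop form `(s, w, r, k)` with an
  explicit candidate sort per state;
* `vectorized` (default) — updates all masses of a layer at once with
  numpy, emulating a one-thread-per-mass parallelisation. Candidates are
  laid out as `j = k·R + r_prev` and ranked with a stable argsort on
  descending probability, which reproduces the tie rule exactly.

The two are required to produce bit-identical tables (tested), so the
parallel-style path is a pure performance choice, never a numerical one.

## Memory scheme

Only two probability layers are live at any time (rolling previous/current
buffers), reducing cost-matrix memory by `100·(1 − 2/n)` %. Traceback is
stored either *raw* — one `(k, r_prev)` layer per position, `8·n·w'_max·R`
bytes in the device accounting — or *packed*: the whole path of a cell is
carried along in two 32-bit words (`8·w'_max·R` bytes, saving
`100·(1 − 1/n)` %), with per-position field widths `floor(log2(k_s)) + 1`
and a uniform rank width `floor(log2(R)) + 1` (layout in `packing.md`).
Packing exists only when both words fit 32 bits; raw storage is the default
on CPU, and both modes must return identical results (tested). Instances
larger than memory are refused, not streamed.

## Device resource model

The feasibility model reproduces the accounting of a reference accelerator
(11 440 MiB global memory, 49 152 B shared memory per block, ≤1024 threads
per block). Two printed figures for the global memory differ by 1 MiB
across sources; 11 440 MiB is used because it is the value consistent with
the derived weight bounds. DP state costs `16·R·w_max·10^D` bytes (8 per
cell for the probability buffers, 8 for the packed traceback), giving a
maximum target weight `floor(global_mem / (16·R·10^D))` — 2499 Da at
`R=3, D=5` and 749 Da at `R=10, D=5`; the totals at `w_max = 500` are
2.24 GiB and 7.45 GiB (GiB, i.e. 2^30 bytes, which is what reproduces
those printed values). Threads per block is the largest power of two `T`
with `T·h·R·8 ≤ shared_mem`, modelling an 8-byte per candidate sort-buffer
entry per thread; this closed form is a reconstruction validated by
agreement with all five reference `(R, h)` rows (512, 256, 128, 64, 32). An
instance is classified `feasible`, `insufficient_global_memory`,
`compression_impossible`, or `both_problems`; on CPU the classification is
advisory and `force=True` overrides it.

## Synthetic data

The generator emulates the structural statistics of a natural-product
scaffold database: `n ∈ [2, 6]` positions, `k_s ∈ [2, 4]` sidechains per
position (database-wide mean of about 4 possible sidechains per scaffold),
sidechain masses drawn uniformly on `[1, 150]` Da and rounded to exactly
`digits` decimals (default 2) so integerization is lossless by
construction, and attachment probabilities normalised within each position
(attachment frequencies; a `uniform01` mode exercises the weaker
`p ∈ [0,1]` contract the solver actually requires). Peaks are built by
picking a random compound of the configuration and widening its exact mass
by a random half-width of up to 0.5 Da, so every generated instance has at
least one in-window solution. What the generator does **not** emulate:
real sidechain chemistry and mass clustering (real sidechains share common
fragments, so integer masses collide far more often than uniform draws),
empirical probability distributions (database frequencies are heavy-tailed,
not uniform), or adduct/charge effects in window construction. Passing
tests therefore demonstrate combinatorial and numerical correctness of the
solver, not predictive accuracy on real spectra — the latter is entirely a
property of the probability data supplied.

## Verification problem sizes

The oracle-equivalence suite runs 200 generated instances with
`n ≤ 6`, `k_s ≤ 5`, masses at 2 decimals and windows under 100 Da, with
`R` cycling through 1, 3, 8 — sizes chosen so the brute-force oracle
(full enumeration, ≤ 5^6 selections) stays instantaneous while the DP
tables still reach ~10^4 mass bins. The compression round-trip property is
checked on 1000 random record sequences, raw-vs-packed solver identity on
a further 30 instances, and the ×10-per-digit growth of the forward sweep
is asserted by counting state updates at `D = 0..3` rather than timing
anything (wall-clock comparisons are hardware statements, out of scope).

## Defaults

| parameter | default | meaning |
|---|---|---|
| `R` | 3 | candidates per configuration; 3 suffices to recover verified structures in reference mixtures |
| `D` | 5 | mass decimals; table size and runtime grow ×10 per digit, and 5 matches high-resolution LC–MS practice |
| `w_max` | 500 Da | cap on total sidechain mass; windows above it are skipped |
| traceback | raw | packed mode by flag, or when emulating device limits |
| brute-force cap | 10^6 | oracle refuses larger product spaces |

## Known limitations

* Linear-domain products underflow for very deep scaffolds (`n ≫ 30`).
* Raw m/z handling (adducts, charge states) is out of scope — inputs are
  neutral-mass windows.
* The device model covers global/shared memory and thread bounds only;
  constant memory, registers and occupancy are treated as negligible.
* No chemical-validity checking of sidechain attachments; a zero-mass
  sidechain (e.g. an explicit hydrogen) is legal input with no special
  handling.
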