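# csccp

Top-R candidate enumeration for mass-spectrometry structure elucidation of
natural-product mixtures: given a molecular scaffold with per-position
substituent (sidechain) masses and attachment probabilities, and a
molecular-weight window from an LC–MS peak, find the R most probable
substituted compounds whose total sidechain mass lies in the window.

This is the *chemical substituent core combinatorial problem* (CSCCP). For
a scaffold configuration with `n` substitutable positions, `k_s` candidate
sidechains at position `s` with masses `W[s,j]` and probabilities
`P[s,j]`, a compound `x` (one sidechain per position) has

```
g(x) = Σ_s W[s, x_s]        (total sidechain mass, Da)
f(x) = Π_s P[s, x_s]        (probability)
```

and the task is the top-R of `f(x)` subject to `g(x) ∈ [w_min, w_max]`.
The package solves it with a pseudo-polynomial dynamic program over
integerized masses (`× 10^D` for `D` decimal digits): DP cell `(s, w, r)`
holds the r-th best probability of a partial compound over positions
`0..s` with integer mass `w`, updated by ranking all sidechain ×
predecessor-rank extensions. It includes:

* rolling two-layer probability buffers and an optional bit-packed
  traceback (a full compound path in two 32-bit words, `docs/packing.md`);
* a device resource model (global/shared memory, threads per block) that
  classifies instances as feasible or not for a reference accelerator;
* an exhaustive brute-force oracle and a deterministic synthetic-data
  generator, so correctness is fully testable offline;
* a `csccp` CLI with `solve`, `batch`, `feasibility`, `simulate`
  subcommands.

Intended users: cheminformatics / natural-product researchers ranking
candidate structures for LC–MS peaks against a scaffold–sidechain
probability database, and anyone needing a verified top-K knapsack-style
enumerator over integerized masses.

## Worked example

Generate four small synthetic scaffolds with matching peaks, then solve
all of them at 2 mass decimals, keeping 3 candidates per configuration:

```sh
csccp simulate --out-dir demo --count 4 --seed 11 --n-max 4 --w-max 90
csccp batch --scaffolds demo --peaks demo/peaks.csv --out demo/res.tsv --digits 2 --rank 3
cat demo/res.tsv
```

```
scaffold_id  config_index  peak_id  rank  probability             total_sidechain_mass  sidechain_ids
SYN11        0             PK0      0     0.13058027815673798     59.90                 SC0_1;SC1_3
SYN12        0             PK1      0     0.00011244919221137436  119.00                SC0_1;SC1_0;SC2_1
SYN13        0             PK2      0     0.012073314553098949    239.60                SC0_3;SC1_3;SC2_1;SC3_1
SYN13        0             PK2      1     0.006062317656185529    239.24                SC0_3;SC1_0;SC2_1;SC3_1
SYN13        0             PK2      2     0.0003138524595424163   239.20                SC0_3;SC1_1;SC2_3;SC3_1
SYN14        0             PK3      0     0.12750953186604067     144.97                SC0_1;SC1_0
```

Each row is one candidate compound: for peak `PK2` (window
239.17–239.87 Da) scaffold `SYN13` admits three compounds, the best being
sidechains `SC0_3;SC1_3;SC2_1;SC3_1` with total sidechain mass 239.60 Da
and probability 0.0121; within a peak, rows are the merged ranking by
probability. The same result comes from the library:

```python
from csccp import read_scaffold_json, read_peaks_csv, solve_csccp

(cfg,) = read_scaffold_json("demo/SYN13.json")
[(peak_id, peak)] = [p for p in read_peaks_csv("demo/peaks.csv", digits=2) if p[0] == "PK2"]
for c in solve_csccp(cfg, peak, R=3):
    print(c.rank, c.selection, c.mass_da(2), c.probability)
```

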