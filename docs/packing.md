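# Packed traceback layout

This is the binary contract implemented by `csccp.compression` and used by
the solver's packed traceback mode. It is part of the package ABI: words
packed under one `(K, R)` layout decode only under the same layout.

## Words

Each DP cell `(w, r)` of the final layer carries its entire compound path
in two 32-bit unsigned words:

* **k-word** — the sidechain index chosen at each position;
* **r-word** — the predecessor rank used at each position.

## Field widths

* Position `s`'s field in the k-word is `floor(log2(k_s)) + 1` bits wide,
  where `k_s` is the sidechain count at that position. This is the width
  the device-resource model charges; note it spends one extra bit when
  `k_s` is an exact power of two (`k_s = 4` gets 3 bits although indices
  0–3 need only 2). The layout keeps the formula as-is so that the
  feasibility inequalities and byte accounting stay consistent.
* Every field in the r-word is uniformly `floor(log2(R)) + 1` bits wide.

## Bit order

Position 0 occupies the **least-significant** bits of each word; position
`s`'s field starts at the sum of the widths of positions `0 .. s-1`
(k-word) or at `s * (floor(log2(R)) + 1)` (r-word). Unused high bits are
zero.

## Applicability

The layout exists only when both words fit:

```
sum_s floor(log2(k_s)) + 1   <= 32      (k-word)
n * (floor(log2(R)) + 1)     <= 32      (r-word)
```

`check_compression_feasible(K, R)` evaluates both flags; `pack` refuses
layouts that violate either, and refuses any record whose value exceeds
its field.

## Example

`K = [2, 2]`, `R = 1`: both k-fields are 2 bits wide. Records
`[(k=0, r_prev=0), (k=1, r_prev=0)]` pack to `k_word = 0b0100 = 4`
(position 1's `k = 1` at bit offset 2), `r_word = 0`.
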