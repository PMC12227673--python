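# dpcrmux

Combinatorial fluorescence encoding, simulation and Poisson deconvolution for
multiplexed digital PCR (dPCR).

## The problem

A dPCR instrument reads a handful of color channels (typically 4–6), which
ordinarily caps a reaction at one target per channel. Universal signal
encoding breaks that cap: each target's primer carries a synthetic tag with
one or two universal probe-binding sites, and each channel offers two probe
classes at a 2:1 concentration ratio — a low-intensity "1i" probe (level 1)
and a high-intensity "2i" probe (level 2). A tag's *signature* is therefore a
ternary string over the channels, e.g. `1100` or `0202`, and a four-channel
instrument with up to two probe sites per tag encodes

```
capacity(C, L, s) = Σ_{k=1..s} C(C, k) · L^k        capacity(4, 2, 2) = 32
```

distinct targets. With sites on every channel this telescopes to `3^C − 1`
(80 on four channels, 728 on six).

The price of encoding is ambiguity: when two targets co-occupy a partition
their probe consumption combines, so an observed partition *label* (digits
0–3 per channel; 3 = both probe classes fired) can have several explanations
— label `1100` may be the `1100` tag alone or tags `1000` + `0100` together.
`dpcrmux` implements the hierarchical Poisson deconvolution that resolves
this: for a tag with signature L, processed in ascending probe-site order,

```
E_L  = P₀ · Σ_{S ⊆ contained tags, ∪S = L} Π_{t∈S} (e^{λ̂_t} − 1)   expected co-presence counts
P′_L = max(P_L − E_L, 0)                                           corrected count
P*_L = P′_L · Π_{t ∈ contained} e^{−λ̂_t}                           partitions holding L alone
λ̂_L  = ln(1 + P*_L / P₀),     copies = N · λ̂_L
```

where P₀ is the null-partition count and N the total partitions. Applied to
exact expected counts the scheme recovers the generating λ identically; the
test suite asserts this to 1e−10 relative error.

The package covers the full stack a panel designer or analyst needs:

- **`codebook`** — signatures, capacity combinatorics, signature unions,
  and decomposition of ambiguous labels into candidate tag sets;
- **`simulate`** — Poisson partition loading and fluorescence rendering
  with Gaussian cluster scatter, baseline offsets, spectral crosstalk,
  "rain", and incomplete-hydrolysis artifacts;
- **`signal`** — baseline subtraction (3rd percentile), crosstalk
  compensation, 1i-anchored calibration, threshold classification, presence
  calls, Euclidean-distance QC;
- **`deconvolve`** — the hierarchical estimator plus an exact
  label-distribution oracle;
- **`metrics`** — partition/target accuracy, sensitivity, specificity,
  variant allele fractions (VAF), rank-sum comparison to background;
- **`studies`** — Monte Carlo design studies: encoded-vs-classic CV
  scaling, co-presence multiplexing limits, crosstalk sensitivity.

## Worked example

Simulate a four-target well (reference tag `1100` at 500 copies, variants at
200/120/80) among 26,000 partitions with mild crosstalk and a baseline
offset, then decode it:

```python
import numpy as np
from dpcrmux import *
from dpcrmux.pipeline import decode_well

cb = enumerate_codebook(4, 2, 2)                      # the 32-tag codebook
truth = TruthSpec(cb, {"1100": 500.0, "1000": 200.0,
                       "0100": 120.0, "0022": 80.0},
                  partitions=26_000, seed=7)
run = simulate_run(truth, NoiseModel(baseline_offset=0.2),
                   CrosstalkMatrix.adjacent_bleed(4, 0.05))
out = decode_well(run.amplitudes, cb, CrosstalkMatrix.adjacent_bleed(4, 0.05))
df = out.result.to_frame()
print(df[df.copies > 5].to_string(index=False))
```

```
 tag signature  count  expected  corrected_final   lambda     copies
0022      0022     71  0.000000        71.000000 0.002823  73.395274
0100      0100    107  0.000000       107.000000 0.004251 110.530769
1000      1000    175  0.000000       175.000000 0.006944 180.531207
1100      1100    529  0.745541       522.373791 0.020585 535.212915
```

Column `count` is the raw number of partitions whose label matches the
signature exactly; for `1100` about 0.75 of those are *expected* from chance
co-localization of `1000` + `0100` (the `expected` column) and are removed
before the Poisson inversion, giving copy estimates within sampling error of
the simulated truth (500/200/120/80). All four tags are called present at
the ≥5-partition threshold, and `vaf(out.result, "1100")` reports per-variant
fractions relative to the reference tag (mean 0.022 across the 31-tag
panel, i.e. the three real variants averaged over the panel).

The same pipeline is scriptable from the shell:

```sh
dpcrmux codebook enumerate --channels 4 --out cb.json
dpcrmux simulate --config sim.yaml --out run/
dpcrmux decode quantify --codebook cb.json --partitions run/partitions.csv --out decoded/
dpcrmux study copresence --targets 728 --out copresence.json
```

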