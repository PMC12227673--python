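# Methods

## Encoding model

A tag signature assigns each color channel one of three states — no probe
site (0), a low-concentration "1i" probe site (1), or a high-concentration
"2i" probe site (2) — with at most `max_sites` nonzero digits. The 2:1 probe
concentration ratio makes intensities additive, so a partition's observed
per-channel level is 0, 1, 2 or 3, where 3 means both probe classes of the
channel were consumed. Level 3 can only arise from co-presence of distinct
tags; internally a label digit is a bitmask over the probe classes, which
makes the union of co-occupying signatures a per-channel bitwise OR and the
"tag contained in label" relation a bitmask inclusion. Probe consumption
saturates: several tags sharing one probe class do not raise the intensity
further. This saturation is the load-bearing semantic choice behind both the
simulator and the deconvolution.

The code-space size is `capacity(C, L, s) = Σ_{k=1..s} C(C,k)·L^k`
(`3^C − 1` when `s = C`). No canonical target-to-signature assignment is
assumed; `enumerate_codebook` produces the full code space in lexicographic
order as a reproducible reference, and user codebooks (JSON or two-column
CSV) may assign any bijection.

## Partition statistics and deconvolution

All estimators assume molecules are distributed over the `N` partitions
randomly, uniformly and independently, so per-partition molecule counts of a
target with `copies` expected molecules are iid Poisson(λ), λ = copies/N,
and tag *presence* events are independent Bernoulli(1 − e^{−λ}) across tags
and partitions. Under that assumption the probability of an exact label L
satisfies `P_L / P_0 = Σ_{S: ∪S = L} Π_{t∈S} (e^{λ_t} − 1)`, summing over
subsets of the tags contained in L. The hierarchical estimator inverts this
one probe-site order at a time:

1. single-site tags: `λ̂ = ln(1 + P_L/P_0)` (with a one-tag codebook this is
   exactly the textbook `−ln(1 − P_pos/N)`);
2. for a higher-order tag, expected counts `E_L` are formed from the
   already-estimated contained tags via the subset sum above with the
   plug-in ratios `e^{λ̂_t} − 1`, subtracted (`P′_L`, clamped at zero —
   sampling noise can push it negative, and λ must be non-negative),
   and deflated by `e^{−λ̂_t}` per contained tag to isolate partitions
   holding the tag alone (`P*_L`), whence `λ̂ = ln(1 + P*_L/P_0)`.

For the two-single-tag case this reduces to the familiar
`E_1100 = P_0·(P_1000/P_0)·(P_0100/P_0)`. Distinct tags of equal site count
are never contained in one another, so processing within an order is
order-independent (ties broken lexicographically). On exact expected counts
the recursion telescopes and recovers the generating λ to machine precision;
the acceptance tests assert ≤1e−10 relative error over the full 32-tag
codebook and 100 random geometries.

Labels matching no signature — in particular any label containing a
level-3 digit — are excluded from estimation and reported with their counts.
They do carry co-presence information; a joint maximum-likelihood fit over
the whole label distribution would use them and be statistically more
efficient, but the hierarchical moment scheme is what is implemented, and
the exclusion is deliberate. `label_probabilities` provides the exact label
distribution via a dynamic program over the 4^C label lattice (polynomial in
the tag count, so it also serves the 728-tag studies); it doubles as the
independent oracle for the estimator tests. Saturated wells (P₀ = 0) raise
an explicit error rather than returning infinities. Confidence intervals are
not computed.

## Signal processing

- **Baseline**: per channel, the 3rd percentile (linear interpolation
  between order statistics — the percentile definition is fixed here since
  instruments differ) is subtracted; negative values are retained.
  Multi-well inputs are processed per well before any pooling.
- **Crosstalk**: observed vectors are multiplied by the inverse of a
  measured crosstalk matrix (diagonal 1, non-negative bleed coefficients);
  mixing followed by compensation is the identity to ≤1e−9.
- **Calibration**: each channel is divided by its 1i cluster center so the
  low-intensity reference sits at 1.0; centers are supplied explicitly or
  estimated as the median of a provisional level-1 gate.
- **Classification**: fixed per-channel cuts (defaults 0.5/1.5/2.5 on the
  calibrated scale, the midpoints between level means) assign each channel a
  level 0–3; the tool never auto-tunes thresholds — reproducibility over
  cleverness. Classification is monotone in each channel by construction.
- **Presence calls**: a tag is present when ≥ `min_partitions` partitions
  match its signature exactly (1 for maximum sensitivity, 5 for specificity).
- **QC**: per-partition Euclidean distance to the assigned signature's ideal
  vector, after zeroing channels where the signature has no site.

## Simulator

`load_partitions` samples per-partition tag presence directly from the
Bernoulli occupancy law — exact, by Poisson thinning, and fast.
`render_signal` maps occupancy unions to level intensities (defaults
0/1/2/3; the level-3 mean defaults to the additive 1+2, configurable since
real instruments may compress it) and applies, in order: incomplete
hydrolysis (with probability `incomplete_hydrolysis_prob` a 2i contribution
is scaled by `incomplete_hydrolysis_factor`, default 0.75 — a [0,0,1,2] tag
rendering at [0,0,1,1.5]); rain (with probability `rain_fraction` a positive
channel is redrawn uniformly between its level mean and the next lower one);
Gaussian cluster scatter (default sd 0.05, chosen so default simulations are
cleanly classifiable — no instrument noise magnitudes are published to fit
against); crosstalk mixing; and a baseline offset. What the simulator does
*not* emulate: amplification kinetics, primer interactions, sequence-context
specificity failures, inter-well optical drift beyond a constant offset, or
instrument-specific partition volumes. Passing tests therefore demonstrate
the correctness of the statistical machinery under the stated model, not
instrument-level performance.

## Design studies

- **Co-presence limit** (closed form): with m targets at p = 1 − e^{−λ}
  each, the fraction of occupied partitions holding ≥2 distinct targets is
  `[1 − q^m − m p q^{m−1}] / [1 − q^m]`, q = 1 − p. The 5% threshold is the
  conservative point where quantification begins to degrade; for 728 targets
  in 26,000 partitions it is reached at 4 copies/target, for 32 targets near
  90–100.
- **CV study**: a classic 1-channel-per-target 4-plex against the encoded
  32-plex, same expected copies per target, Poisson loading, perfect
  classification assumed (the study isolates sampling statistics, so the
  encoded arm feeds true label counts straight into the deconvolution). The
  encoded arm samples label counts from Multinomial(N, exact label
  probabilities) — identical in distribution to per-partition simulation and
  ~10× faster; an explicit occupancy sampler is kept and tested for
  agreement. At low concentration the encoded design's CV of total copies is
  ~√8 lower (32 vs 4 effectively independent targets); oversaturation
  reverses the advantage at a crossover near 1,200 copies/target
  (log-log interpolated between grid points). Desk default: 1,000 runs on a
  coarse grid {1,3,10,30,100,300,1000,2000,5000}; the acceptance script uses
  10,000 runs on a finer grid.
- **Crosstalk study**: 728-plex, 6 channels, uncorrected bleed.
  Parameterization: each channel leaks fraction α of its true signal into
  its next spectral neighbor — the dominant red-shifted bleed-through mode.
  A full all-pairs bleed matrix was rejected: with it, even α = 0.2 pushes
  ≥0.5 intensity units into empty channels for common two-site tags,
  misclassifying a large tag fraction, whereas physical instruments at
  moderate crosstalk do not behave that way; under the neighbor model the
  digit outcomes are provably identical for α ∈ {0, 0.2} and for
  α ∈ {0.8, 1.0} at the default thresholds, with a sharp transition as
  2α crosses the first threshold (α ≥ 0.25 for 2i sources, α ≥ 0.5 for 1i).
  Accuracy is defined as the fraction of occupied partitions that hold
  exactly one tag *and* classify to that tag's signature — co-present
  partitions count as incorrect, so the α = 0 curve equals one minus the
  co-presence fraction. Cluster scatter is excluded to isolate the crosstalk
  effect. Both definitions are declared in the study's output metadata.

## Numerical and interface choices

- Labels and signatures serialize as digit strings, channel 1 leftmost;
  CSV output quotes them to survive spreadsheet round trips.
- Subset enumeration in `decompositions` is exponential and capped at 20
  contained tags (configurable) with an explicit error.
- All randomness flows from a single integer seed per run; identical seeds
  give byte-identical simulation outputs. CLI runs emit a manifest with a
  config hash and file digests (the manifest timestamp is informational).
- Problem sizes used in the shipped studies and tests (26,000 partitions,
  200-replicate recovery, 1,000–10,000 Monte Carlo runs) were chosen to keep
  Monte Carlo error well below the effects being measured while remaining
  desk-scale.

## Known limitations

- Level-3 and other non-signature labels are discarded by the estimator
  (information-losing but faithful to the hierarchical scheme).
- Replicate wells are estimated per well; pooled and averaged summaries are
  both reported downstream, since the better convention is context-dependent.
- No automatic clustering/gating of partition clouds is provided or planned;
  fixed thresholds are the contract.
- Instrument-specific results (per-platform classification accuracies,
  regression slopes against dilution series) require real instrument data
  and are out of scope for the simulator-backed test suite.
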