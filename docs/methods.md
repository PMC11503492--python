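# Methods

## Screen model

One droplet is the unit record: a timestamp, a fluorescence value (RFU),
and the identities of any beads it contains. The simulator and the
analytics share one statistical model of the assay:

* **Bead occupancy.** Bead count per droplet is Poisson(λ). The default
  λ = 0.06 corresponds to ~90,000 beads in ~1.5 × 10⁶ droplets, a loading
  sparse enough that ~97% of occupied droplets hold a single bead. Library
  beads are drawn without replacement from a finite pool of
  `beads_per_structure` copies per structure (default 18, i.e. ~20×
  library representation); positive-control beads are spiked in i.i.d. at
  `control_bead_fraction`.
* **Fluorescence.** Uninhibited droplets draw from Normal(μ₋, σ₋). A
  droplet containing beads with inhibition fractions *i* has mean
  μ₋ · (1 − max *i*) with unchanged σ: inhibitors act on a shared reporter
  and the strongest occupant dominates (a conservative combination rule
  for the rare multi-bead droplet). Values are not clipped at zero —
  detector offset is arbitrary in RFU and downstream code tolerates
  slightly negative draws.
* **Defaults** μ₋ = 100, σ₋ = 5 RFU are a calibration chosen so that a
  full-inhibition positive control gives Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋| = 0.70,
  matching the quality regime of a good droplet IVTT assay; they are not
  measured values.

## Sorting

Windows are tumbling 30 s blocks (matching the transient-histogram
binning). Per window the negative population is summarized by
**median / 1.4826 × MAD** rather than mean/SD: the estimator must not be
dragged by the very tail it is trying to isolate, and median/MAD tolerate
the few-percent hit contamination seen in a productive screen. The
threshold is μ̂ − kσ̂ with k = 5 by default; a droplet is sorted iff its
fluorescence is **strictly below** the threshold ("k σ below the mean"
describes droplets beyond the bound, and the strict rule makes the
boundary case deterministic). Windows with fewer than `min_events`
(default 100) droplets inherit the previous window's estimates; an
under-populated first window is an error. The threshold is computed from
all droplets in the window, not occupied ones only, because occupancy is
unknown at sort time. At k = 5 the Gaussian-null false-sort fraction is
Φ(−5) ≈ 2.9 × 10⁻⁷ — unverifiable directly at test scale, so the suite
verifies the calibration at k ∈ {2, 3} against Φ(−k) on 10⁵ null droplets.

Histogram binning is visualization only and has no effect on sort
decisions (asserted by a test).

## Codon scheme

The DNA tag architecture is a generic stand-in (the real headpiece /
ligation design of such libraries is instrument- and vendor-specific):
amplicons read `const5 + codon1 + spacer + codon2 + const3`. Codons are
fixed-length (default 8 nt) with minimum pairwise within-cycle Hamming
distance d_min (default 3), placed by seeded greedy rejection sampling with
an explicit capacity error rather than an unbounded loop. d_min = 3 allows
single-substitution correction (Hamming balls of radius 1 are disjoint);
396 codons fit trivially in the 65,536-sequence space at length 8.
Positive-control beads carry a reserved codon at distance ≥ d_min from all
cycle-1 codons — in a real screen control beads are identified by their
activity, so this labelling is a simulation convention that lets
deconvolution separate them cleanly.

Decoding resolves each codon slot independently: exact dictionary match;
else a *unique* codon within `max_mismatch` (default 1) → corrected; two or
more candidates → ambiguous; none → fail. Bead calling is a plurality vote
over non-fail reads with a support-fraction floor (default 0.5, denominator
includes ambiguous reads) and no-call on an exact tie.

## k class and the false discovery matrix

k is the number of distinct beads in a screen's hit collection called as
the same structure, summed across screens for the heat map. The null
matrix draws `n_samples` (default 3) samples of `sample_size` (default
1,500) beads **uniformly over structures with replacement** and reports,
per threshold k, the mean fraction of observed structures with count ≥ k.
Uniform-with-replacement is an adequate null because the physical pool
(~18–19 beads/structure) is deep relative to a 1,500-bead draw; the
without-replacement correction would be second-order. FDR(1) = 1 by
construction and the matrix is nonincreasing in k. For a library of N
structures the per-structure count is ≈ Poisson(λ = sample_size/N), giving
the closed-form check FDR(k) ≈ P(X ≥ k)/P(X ≥ 1); at N = 5,348 and 1,500
beads this is ≈ 1.2% at k = 3, and the Monte Carlo estimate agrees within
sampling error. A threshold where no replicate produced any qualifying
structure is reported as 0 with a `degenerate` flag rather than 0/0.

## Enrichment

Building-block overrepresentation uses the **distinct-structure** hit set
(default k ≥ 3) rather than bead-weighted counts — replicate beads of one
structure are evidence about that structure, not independently about its
building blocks. For a block in K of the N library members and a hit set
of n distinct structures containing it x times, p is the one-sided
hypergeometric tail P(X ≥ x | N, K, n). Bonferroni across all blocks
tested keeps the adjustment simple and conservative.

## Similarity profile

3D shape/color overlap scoring is out of scope; `similarity_profile` is a
clearly labelled 2D stand-in (Morgan radius-2/2048-bit Tanimoto via RDKit)
over the disconnected union of a member's fragment SMILES, suitable only
for coarse ranking. The fingerprint function is injectable, which the
tests use for exact set-arithmetic oracles.

## What the simulator does and does not emulate

It reproduces the *statistical* structure the analytics rely on: Poisson
occupancy, a stationary Gaussian negative population, mean suppression by
actives, control cadence, and i.i.d. substitution sequencing errors.
It does not model droplet coalescence or size dispersion, photocleavage
kinetics, IVTT drift over the screen (the dynamic threshold exists for
such drift, but the generator keeps μ₋ stationary), PCR amplification
bias, chimeric reads, or indels. Passing the recovery tests therefore
demonstrates the pipeline's correctness under the stated model, not
robustness to every instrument artifact.

## Problem sizes and numerical choices

Test simulations use 10⁵–10⁶ droplets and libraries of 12 (exact
oracles), 420 (end-to-end recovery), and 5,348 (full-scale statistics)
members — sizes at which every closed-form comparison is resolvable within
3 SE in seconds. Stochastic assertions fix their seeds and compare within
3 binomial standard errors. Vote ties in bead calling and exact-
threshold droplets are resolved deterministically (no-call / not-a-hit).
The pipeline derives per-stage seeds from the global seed by SHA-256 of
`"{seed}:{stage}"` (mod 2³¹), so any stage is re-runnable in isolation
with unchanged output.

## Known limitations

* The false discovery matrix assumes uniform library representation on
  beads; strong synthesis skew would need a weighted null.
* Bonferroni is conservative when blocks are correlated through shared
  members (they are, mildly).
* The decoder treats the two codon slots independently; it does not
  exploit joint (starter, acid) validity to rescue ambiguous reads.
* Z′ from screen data uses mean/SD of the unoccupied vs control-occupied
  droplet populations; with very few control droplets the estimate is
  noisy and is reported as-is.
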