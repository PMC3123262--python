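# Methods

## Signal model

A hybridization is a vector of per-probe log2 ratios over an ordered probe
map. The generative model used throughout (simulation, and implicitly the
calling model) is

    r_i = b + w · (g_i − ḡ) + Σ_j Δ_j · 1[probe i inside CNV j] + ε_i

where `b` is a global dye-bias offset, `g_i` the local GC fraction in a
window around probe *i*, `ḡ` the genome-average GC fraction, `w` the
genomic-wave coefficient (log2 units per unit GC fraction), `Δ_j` the log2
shift of planted CNV *j*, and `ε_i ~ N(0, σ²)` iid probe noise. Assumptions:
noise independent across probes, CNV effects additive and constant across a
CNV, and the wave linear in local GC (the simplest monotone form of the
GC association; nothing stronger is claimed by the data this emulates).

## Calling

Tracks are segmented per chromosome by **exact penalized least-squares
change-point detection**: the partition minimizing

    Σ_segments SSE(segment) + β · (number of segments)

found by PELT-style pruned dynamic programming (the pruning inequality is
valid because SSE is sub-additive under splitting). Greedy binary
segmentation was evaluated first and rejected: an interior CNV inside a
long flat block can be invisible to any *single* split (observed at desk
scale: a 29-probe, −0.67 loss whose best single-split gain fell just below
the penalty), while the exact optimum isolates it. Ties in the DP are
broken toward the leftmost candidate, which prefers longer (fewer)
segments; the penalty strictly favours fewer segments otherwise.

Default penalty: BIC-style `β = 2 σ̂² log n`, with σ̂ the robust noise
estimate `median|Δr| / (√2 · 0.6745)` from first differences (insensitive
to CNVs, which affect few differences). Noise-free tracks give σ̂ = 0; the
penalty is floored at 1e-12 so that only strictly error-reducing splits
are made, which yields exact recovery of noise-free planted events.

Events: segments with `|mean| ≥ Δ` are fused with adjacent qualifying
segments of the same sign (no fusion across chromosome breaks or masked
probes); a fused run with ≥ k observed probes becomes an event spanning
the start of its first probe to the end of its last probe — no extension
into flanking gaps, so event length is conservative. Masked (NaN) probes
split runs. Nominal resolution is `(k − 1) ×` mean spacing: `(0.5, 5)` at
1.2 kb spacing → 4.8 kb.

## Calibration on self-self controls

Self-self hybridizations contain no true events, so the sweep counts
false-positive events per criterion cell, summed over tracks; the grid
must be (and is asserted) non-increasing along both axes. Selection takes
the least-stringent cell (smallest shift, then smallest probe count)
whose total is within the false-positive budget (default 0), falling back
to the arg-min cell. Since self tracks have no true events, a
false-discovery *rate* is undefined on them; an FDR proxy
(mean self events / mean comparative events) is provided when comparative
tracks are supplied.

The sweep's default segmentation penalty is matched to the laxest grid
cell, `β = 0.5 · k_min · Δ_min²` (half the SSE gain of that cell's
marginal event): a variance-based penalty at realistic noise suppresses
every sub-threshold segment and returns an all-zero grid, making the
criterion comparison vacuous.

**Known quantitative limitation.** With iid Gaussian noise at σ = 0.2 the
zero-false-positive frontier sits at shift ≈ 0.4 (the calibration driver
and acceptance script compute the grid; cells from (0.4, 6) upward are
empty at desk scale), so budget-0 selection returns (0.4, 5)–(0.4, 7)
rather than the published (0.5, 5). The per-probe rates of the
neighbouring cells (0.4, 7) and (0.5, 4) are within roughly an order of
magnitude of (0.5, 5)'s — their squared-error gains `k·Δ²` are 1.12, 1.00
and 1.25 — so no problem size makes (0.5, 5) the *robust* least-stringent
zero-FP cell under Gaussian noise. The published pair is strictly
conservative for Gaussian noise; its selection on real arrays reflects
heavier-tailed structure (genomic waves) that inflates lax-cell counts.

## Shared-event triage

An event is *shared* when it overlaps (≥1 bp by default; a max-gap
parameter exists) an event from a different hybridization, regardless of
gain/loss direction — the published large-event table flags
opposite-signed recurrences at the same locus as shared, so a same-type
requirement could not reproduce it; direction agreement is reported
separately (`same_type`). Unique loci are the union-merge of all events
pooled across hybridizations; the >10 kb size class uses a strict
inequality ("larger than 10 kb"; the smallest packaged event is 10,090 bp).

## GC analysis

`gc_fraction` is (G+C)/(A+C+G+T), case-insensitive, with N excluded from
numerator and denominator (all-N regions are signalled, not silently 0).
Windowed profiles tile the sequence (step = window, default 5 bp,
browser-style), scoring the trailing partial window over its actual
length. Per-probe local GC uses a 500 bp window centred on the probe
midpoint — neighbourhood GC, not probe-sequence GC, drives the wave
artifact. The genome average is always computed from the supplied
sequence, never hard-coded; 0.417 (the bovine genome average) is only the
default simulation target.

Wave correction (off by default — the pipeline this mirrors flagged
GC-driven calls post hoc rather than correcting them) fits log2 ratio on
local GC by local-linear regression with tricube weights, fixed bandwidth
= 20% of the observed GC range, and one bisquare reweighting pass to damp
probes inside real CNVs; the fit is subtracted. Local-*linear* (not
constant) fitting removes an exactly linear wave without boundary bias.
A constant GC vector makes the regression unidentifiable: warn and no-op.
Leave-one-out residual diagnostics are attached on request.

## Remapping

UCSC chain records are parsed with their block-sum invariants enforced
(malformed lines reported by number). An interval maps through the
highest-scoring chain whose span touches it, iff ≥ `min_match` (default
0.95, the conventional liftOver setting) of its bases lie in aligned
blocks of that single chain; the image spans the extreme target positions
of the intersected blocks, with minus-strand target coordinates flipped to
forward convention. Distinct failure reasons: `unmapped` (no chain),
`deleted` (inside a chain but in gaps), `split` (no single chain
suffices but several align parts). Multi-chain stitching is deliberately
out of scope; a split is a failure, as in batch liftOver.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical* structure the pipeline needs:
Gaussian probe noise (default σ = 0.2, placing the published criterion
near — in fact beyond — the self-track false-positive boundary), a smooth
GC landscape around a 0.417 target with flat-top GC-rich islands
(default 2 per Mb, ~8 kb wide, +0.15 GC — the feature class on which
recurrent artifact calls concentrated, sized to be callable at 1.2 kb
probe spacing), a linear GC wave, a global dye bias, planted CNVs snapped
to probe boundaries, and self tracks with no true events. The GC
propensity field is re-centred so the realized genome GC hits the target.

Default desk scale is 5 chromosomes × 2 Mb with ~8,300 probes at ~1.2 kb
jittered spacing (the real design's spacing at ~1/250 of its probe
count); larger scales are a parameter, not a code change. Not emulated:
two-channel raw intensities and their normalization, spatial on-chip
effects, autocorrelated (non-wave) noise, repeat/segmental-duplication
structure, and real inter-assembly chains. Consequently, passing tests
show the pipeline's operations are correct and calibrated *under the
stated model*; they do not show that real-array noise is Gaussian — the
calibration limitation above is exactly where that distinction bites.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; published tables are
  ingested as printed (their Length column equals End − Start, consistent
  with half-open spans), thousands separators stripped on parse.
- "Nearby genomic regions" is operationalized as ≥1 bp overlap
  (max_gap = 0): it reproduces the printed shared flags exactly, so no
  looser definition is needed.
- Event "Log R" is the probe-weighted mean of the fused run, matching the
  treatment of the published column as a segment mean.
- Criterion thresholds use ≥ comparisons; the event/criterion classes
  validate `Δ > 0`, `k ≥ 2`, sign/kind agreement at construction.
- Per-track seeds and normalization steps are recorded in track notes and
  echoed into every CLI run's config snapshot.

## Known limitations

- The calibration clause discussed above: under the Gaussian noise model
  the published criterion is not recoverable as the least-stringent
  zero-FP cell; the pipeline reports what the model actually yields.
- The empirical "45% of all events shared" statistic from the original
  study requires the full unpublished event list; only the >10 kb subset
  is packaged, and cohort-level sharing on synthetic data stands in for
  the rest.
- Segmentation is exact for the penalized SSE objective but is not, and
  does not claim to be, bit-compatible with vendor segmentation software.
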