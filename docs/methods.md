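# Methods

This note documents the models and procedures ttkit implements, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Transcription units

A transcription unit (TU) is the per-gene genomic span [min start, max end)
over the gene's transcript isoforms. The span convention — rather than an
interval union preserving intronic gaps — is used because every downstream
per-TU statistic (RPK over TU length, TSS→pA metagene scaling,
transcribed-base sums) treats the TU as one contiguous region; nascent-RNA
coverage, unlike mRNA-seq, populates introns, so the span is also the
biologically appropriate region for TT-seq signal. Coordinates are 0-based
half-open internally (BED convention); GTF input is converted on read.
Biotype labels (histone, snRNA, intronless) come from annotation attributes,
overridable by curated gene-id lists, since public annotations differ in how
they tag these classes. Gene-length classes default to cuts at 9, 21.1 and
41.3 kb — the strata in which the elongation defect's length dependence is
typically displayed — with half-open bins and the boundary going right.

## Spike-in normalization model

Counts on the two strands of a spike-in (or TU) mix through reverse
transcription: with true sense/antisense quantities (s, a) and antisense
bias c, the observed values are S = s + c·a and A = a + c·s. The correction
s = (S − c·A)/(1 − c²) inverts this exactly for c < 1. Estimators, per
sample j:

| parameter | estimator | spike-ins used |
|---|---|---|
| antisense bias c_j | median of A/S | all with S > 0 |
| depth scale σ_j | median of k/l (reads per base) | labeled |
| cross-contamination ε_j | median of k/l, divided by σ_j | unlabeled |

k is the sense-assigned count and l the spike-in length. Medians make all
three robust to a single aberrant spike-in. σ is optionally rescaled to
geometric mean 1 across samples, since only relative depths matter
downstream. ε is estimated but not applied by default: it is typically below
a few percent and the correction (an optional, experimental flag) would
couple samples through the unlabeled background. Negative antisense-corrected
values are floored at zero — counts are physical — and the floored fraction
is logged because a large one indicates an overestimated c.

Depth normalization is t_ij = s_ij/σ_j. Residual library variation between
replicates is then balanced by median-of-ratios size factors
(factor_j = medianᵢ k_ij / geomeanⱼ′ k_ij′, rows with any zero excluded)
computed on a reference TU set. Crucially, size factors are applied only
WITHIN replicate groups of one condition: balancing across conditions would
re-center a genuine global transcription shift onto unaffected genes, which
is precisely the artifact spike-in normalization exists to avoid.

The reference set is chosen among expressed TUs (RPK ≥ 100 over summed
replicates; RPK ≥ 20 is the preset for plotting-oriented sets) longer than
50 kb — long TUs are where an elongation defect is most visible, so TUs that
remain flat there are the safest anchors. A TU is kept when its |log2 fold
change| between condition means is within 0.25 at every time point, with an
optional normal-approximation test on log counts (off by default). This is a
deliberate tolerance-band criterion rather than a significance test: the
contract is a stable, unaffected anchor set, and "not significantly DE" at
low replication would admit noisy TUs that a band excludes. A pseudocount of
0.5 guards the log against zero cells.

RPK-to-coverage conversion: coverage ≈ RPK × fragment length / 1000 /
replicates; with 200 bp fragments and two summed replicates, RPK 100 ≈
coverage 10 and RPK 20 ≈ coverage 2 per sample.

## Elongation-velocity simulator

The simulator produces expected TT-seq coverage for one gene under a
schedule: treatment (a velocity change) at time 0, harvest at `elapsed`
minutes, 4sU labeling during the final `t_lab` minutes. Model components:

* **Initiation** — Poisson process at `initiation_rate` events/min (default
  2/min, a typical productive initiation rate at active mammalian genes).
  Events are drawn from `lab_start − L/v_min` to `lab_end`, which covers
  every polymerase whose labeled interval can overlap the gene — this is the
  burn-in that guarantees pre-treatment steady state. A variance-free mode
  places events on a regular grid with spacing 1/rate, making the analytic
  oracles exact (with rate × t_lab integral, a half-open time window contains
  exactly rate × t_lab grid events regardless of phase).
* **Elongation** — all polymerases share a piecewise-constant v(t) in
  absolute time (defaults: 2000 bp/min control, halving to 1000 bp/min at
  onset; the paper-scale magnitude for mammalian pol II). Positions are exact
  integrals of v, so propagation is analytic per polymerase — equivalent to
  per-nucleotide stepping for piecewise-constant v, and fast. Velocity is
  time-dependent only; position-dependent acceleration from the TSS is an
  extension hook, not implemented.
* **Labeling** — a polymerase's labeled interval is its position at labeling
  start (0 if it initiated later) to its position at labeling end, clipped
  at the pA site, past which it no longer contributes.
* **Fragmentation and library biases** — the labeled interval is cut into
  exponential fragments (mean 200 nt, matching the average library fragment
  size), the last truncated at the interval end. Only the labeled interval
  is fragmented (unlabeled nascent flanks are not carried): the capture
  weight presumes fragments drawn from labeled RNA, and confining fragments
  keeps the closed-form oracles exact. Each fragment contributes
  capture × size weight to every base it covers, with fractional coverage at
  non-integer ends so that total coverage equals Σ weight × length exactly.
  Capture weight l_f = 1 − (1 − 0.01)^(0.28·len) (labeling probability 0.01
  per uracil, uracil density 0.28 per nt, used as a real-valued exponent).
  Size selection is logistic around 80 nt with steepness 0.25/nt (≈10–90%
  transition over ~18 nt — a typical gel/bead size-selection spread; the
  midpoint is the modelled protocol's cutoff, the steepness a package
  choice).

Closed forms used as oracles: at steady state with weights off, interior
coverage is initiation_rate × t_lab for any velocity (each covered base is
passed by exactly the polymerases crossing it during labeling, whose count
is rate × t_lab). Immediately after a slowdown, distal coverage is
rate × t_lab × v_new/v_old (the pre-onset polymerase density is rate/v_old
per base and a window of v_new·t_lab of them label each base). At longer
elapsed times the profile has a recovered 5′ plateau (x < v_new·(elapsed −
t_lab)), a linear ramp, and a depressed distal plateau from x = v_new·elapsed
— so coverage recovers from the TSS outward at the new velocity, and genes
shorter than v_new·elapsed recover fully while long genes do not.

Metagene accumulation simulates a log-spaced gene-length grid (default 18
lengths over 0.1–2000 kbp) under both velocity profiles, rescales each gene
body to a common bin count and averages.

## Metagene profiles

Profiles anchor each TU at TSS and pA: unscaled flank bins (default 10 bp)
outside the anchors and a body resampled to a fixed bin count by
area-preserving (length-weighted) averaging via the linear interpolant of
the cumulative sum — exact for per-base signal, so a constant gene stays
exactly constant, the profile is linear in the track, and signal mass is
conserved (nearest-neighbour sampling satisfies none of these). Minus-strand
genes are reflected so profiles read TSS→pA. The profile is the arithmetic
mean over genes (required for the gene-resampling bootstrap; pooled-read
binning would weight genes by expression instead). Replicates are summed
before profiling, then condition-level size factors applied.

Uncertainty bands are nonparametric bootstrap percentile intervals over
genes (default 1000 resamples, 95%, seed-controlled). Percentile intervals
slightly undercover at small gene counts (~93% observed at n = 30); the
calibration check in the acceptance suite allows ±5 points around nominal.

Transcribed-base ratios (treated/control summed signal over the TU span, on
antisense-corrected depth-normalized tracks) are reported per TU with a
length-class label; TUs with zero control signal are dropped with a warning.
Ratio profiles divide bin-wise with a small positive floor (default 1e−6) on
the denominator; flagged by construction, bins with an empty denominator
surface as very large finite values rather than NaNs.

## mNET-seq 3′ ends and track renormalization

From each properly-paired alignment, one count is placed at the 3′-most
aligned base of mate 2 (highest coordinate on +, lowest on −) — the RNA 3′
end in the polymerase active site — on the transcript strand taken as the
opposite of mate 1's alignment strand (dUTP-style directionality; a flag
covers the other convention). Improper and cross-chromosome pairs are
skipped and counted; the track total equals the accepted pair count.

Renormalization to a reference set: per reference window the
control/treated signal ratio over the gene body (TSS+500 → pA by default;
full TU spans for histone genes, which are too short for the offset), and
the factor is the geometric mean of these ratios (robust to a few extreme
genes, and antisymmetric: factor(a,b)·factor(b,a) = 1); the arithmetic mean
is available. Applying the factor to the treated track is exactly
invertible and equalizes average reference-set signal. RPKM scaling
(1e9/(mapped reads × bin width)) is provided for comparability with
conventional pipelines.

## Synthetic data: what it does and does not emulate

The generators plant known truth at realistic scales: log-uniform gene
lengths (0.1–2000 kbp), 1–3 nested isoforms per gene, biotype fractions
with short histone (0.4–1 kb) and snRNA (0.1–0.3 kb) genes; 12 spike-ins
(two-thirds labeled, equimolar — spike-in mixes are added at controlled
amounts) with Poisson counts around the mixing-model expectations at a mean
depth of 10⁴; count matrices over 2 conditions × 2 time points × 2
replicates with Poisson noise, log-normal expression around RPK 50, and a
planted non-DE subset at fold change 1 (DE TUs at log2 FC −1); coverage
tracks from the simulator, with histone TUs keeping the control velocity in
the treated condition — planting the inhibition-insensitive histone
transcription used for CTD-phospho renormalization.

Deliberately absent: overdispersion beyond Poisson (keeps recovery
tolerances analytic; an overdispersion knob is a documented extension),
sequence content and alignment artifacts, RNA degradation/turnover,
pausing/termination kinetics, and position-dependent velocity. Passing
tests therefore demonstrate correctness of the estimators and profile
machinery under the stated model, not robustness to biological
overdispersion or mapping noise.

Every generator is deterministic given its seed and writes its planted
parameters to a GroundTruth sidecar (JSON); estimator tests read truth from
the sidecar, never from hard-coded numbers.

## Numerical conventions and test scales

* Medians use the even-length midpoint convention throughout.
* Fragment coverage accumulates fractionally at non-integer interval ends;
  conservation (Σ coverage = Σ weight × length) holds to ~1e−10 relative.
* Unit and acceptance tests run the simulator at gene lengths up to 120 kb
  and the end-to-end closure at 40 genes; the generators' defaults (200
  genes, lengths to 2 Mb) are the intended analysis scale and run in a few
  minutes.
* Seeds: all randomness flows through numpy Generators seeded explicitly;
  per-gene and per-condition streams are derived through SeedSequence-style
  spawning with fixed condition indices, so adding genes does not perturb
  earlier ones.

## Known limitations

* The non-DE criterion is a fold-change band, not a dispersion-modelled
  test; with very low counts it can admit noisy TUs (mitigated by the
  expression and length filters).
* Band propagation through ratio profiles (ratio of bounds) is indicative,
  not a formal interval.
* The simulator's fragmentation of only the labeled interval slightly
  understates capture of fragments straddling the label boundary; ratio-level
  conclusions are insensitive to this choice.
* BED12 input uses only the transcript span (no exon structure), consistent
  with the span-based TU definition.
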