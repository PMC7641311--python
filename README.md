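# ttkit

Spike-in normalization, elongation-velocity simulation and metagene
profiling for nascent-RNA sequencing (TT-seq and mNET-seq).

When transcription is perturbed globally — for example by rapid chemical
inhibition of a transcriptional kinase such as CDK12 — ordinary library-size
normalization silently erases the effect, because every sample is rescaled to
the same total signal. ttkit implements the normalization and modelling
machinery needed to measure such global changes honestly, for computational
biologists working with 4sU-labeling data (TT-seq) or native elongating
transcript data (mNET-seq):

* **Spike-in normalization.** From RNA spike-ins of known identity (labeled
  and unlabeled) it estimates, per sample *j*: the sequencing-depth scale
  σⱼ = medianᵢ(kᵢⱼ/lᵢ) over labeled spike-ins; the antisense bias ratio
  cⱼ = medianᵢ(kᵢⱼᵃⁿᵗⁱˢᵉⁿˢᵉ/kᵢⱼˢᵉⁿˢᵉ) introduced by reverse transcription;
  and the cross-contamination rate εⱼ = medianᵢ(kᵢⱼ/lᵢ)/σⱼ over unlabeled
  spike-ins. Observed counts follow the mixing model S = s + c·a,
  A = a + c·s, inverted exactly by s = (S − c·A)/(1 − c²). Corrected counts
  are expressed as RPK (reads per kilobase of transcription unit),
  depth-normalized as tᵢⱼ = sᵢⱼ/σⱼ, and balanced with DESeq-style
  median-of-ratios size factors computed on a non-differentially-expressed
  reference set of long, expressed transcription units.
* **Kinetic simulation.** A polymerase-resolution model of TT-seq coverage:
  Poisson initiation, piecewise-constant elongation velocity v(t) shared by
  all polymerases (position τ\* = ∫₀^t\* v(t)dt, computed exactly), a 4sU
  labeling window, exponential fragmentation, a uracil-content capture bias
  l_f = 1 − (1 − p_lab)^{#u_f} with #u_f = 0.28·len, and a sigmoidal size
  selection around 80 nt. Gene-wise profiles accumulate into metagenes.
  Closed-form oracles (steady-state coverage = initiation rate × labeling
  time; post-slowdown plateaus scaling as v_new/v_old; a 5′ recovery front at
  v_new × elapsed time) make the simulator fully testable.
* **Metagene profiling and renormalization.** Anchored (TSS/pA), scaled,
  binned average profiles with bootstrap confidence bands; per-gene
  transcribed-base ratios stratified by gene length; single-nucleotide 3′-end
  extraction from paired mNET-seq alignments; and reference-gene-set
  renormalization factors (geometric mean of control/treated fold changes)
  for comparing tracks across a global perturbation.
* **Synthetic data.** Generators for every input — annotation, spike-in
  tables, count matrices, coverage tracks — with planted ground truth, so the
  whole pipeline is testable end to end without downloads.

## Worked example

```python
from ttkit.synthetic import gen_spikeins
from ttkit.spikein import estimate_params, rpk_to_coverage
from ttkit.simulate import SimulationConfig, VelocityProfile, simulate_gene

spikes, truth = gen_spikeins(12, sigma={"dmso": 1.0, "nm": 2.0},
                             c=0.08, epsilon=0.02, depth=1e4, seed=1)
params = estimate_params(spikes, rescale_sigma=False)
for j in ("dmso", "nm"):
    print(f"{j:6s}  {params.sigma[j]:.3f}  {params.c[j]:.4f}  {params.epsilon[j]:.4f}")
print("RPK 100 ->", rpk_to_coverage(100), "x coverage per sample")

cfg = SimulationConfig(elapsed=30.0, t_lab=10.0, initiation_rate=2.0)
prof = simulate_gene(60_000, VelocityProfile.slowdown(2000.0, 1000.0), cfg,
                     variance_free=True, apply_weights=False)
print(f"5' plateau {prof.values[5_000]:.1f}  distal plateau {prof.values[45_000]:.1f}")
```

prints

```
dmso    10.523  0.0815  0.0206
nm      21.175  0.0796  0.0208
RPK 100 -> 10.0 x coverage per sample
5' plateau 20.0  distal plateau 10.0
```

The estimated depth scales recover the planted two-fold ratio (10.5 vs 21.2),
the antisense bias the planted 0.08 and the cross-contamination the planted
0.02, from twelve Poisson-sampled spike-ins. An RPK of 100 corresponds to a
coverage of about 10 per sample (200 bp fragments, two summed replicates).
In the simulation, 30 minutes after velocity halves, coverage near the TSS
has recovered to the control level (initiation rate × labeling time = 20)
while the distal gene body sits at half that — the recovery front that
distinguishes an elongation defect from an initiation defect, spreading from
the 5′ end at the new velocity.

The same operations are exposed on the command line as `ttk annotation`,
`ttk normalize`, `ttk simulate`, `ttk metagene`, `ttk net3p`, `ttk renorm`
and `ttk synth` (see `ttk --help`).

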