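# Methods

## Overview

`sweeppower` estimates the statistical power of four neutrality tests —
Tajima's D, Fay & Wu's H, rEHH and iHS — for detecting selective sweeps,
by simulating the full observation process: a Wright–Fisher allele
frequency trajectory for the selected variant, a sample genealogy
conditioned on that trajectory, infinite-sites mutations, the test
statistic, and an empirical-null significance threshold.  All inputs are
generated internally; there is no external data dependency.

## Demography

Histories are piecewise-constant diploid sizes over generations before
present.  Epochs are half-open `[t_start, t_end)` looking backward: a size
change at `t` applies to all times `≥ t`.  Times in configs may be given
in generations or in units of `reference_N` generations; everything is
converted to generations at parse time (one internal unit, no scaled-time
arithmetic anywhere else).  A generation time of 20 years can be used to
convert to calendar years when interpreting results; it never enters any
computation.  The nine bundled basic models (one constant, three
expansion, three bottleneck) share an effective size of Ne = 5,000:
constant N₀ = 5,000; expansions with N₀/N₁ = 10 and (N₁, t₁) ∈
{(4770, 0.1 N), (4330, 0.3 N), (3890, 0.5 N)}; bottlenecks of 500
generations with N₀/N_b = 20 and (N_b, t_b) ∈ {(427, 0.05 N),
(418, 0.2 N), (401, 0.5 N)}, t_b the bottleneck's (recent) end.  The two
human-like configs are *approximate, illustrative* piecewise histories —
placeholders for externally estimated models, labelled as such.

## Selection and trajectories

Genotype fitnesses are `1 : 1+hs : 1+s` with dominance `h` exposed and
defaulting to 0.5.  One forward generation applies deterministic selection

    p* = [p²(1+s) + p(1−p)(1+hs)] / [p²(1+s) + 2p(1−p)(1+hs) + (1−p)²]

followed by binomial resampling of `2N` gametes; 0 and 1 are absorbing.

**Selection-coefficient convention.**  The bundled experiment
configurations quote the *per-allele-copy* (genic) coefficient: a quoted
coefficient s means heterozygote advantage s and homozygote advantage 2s.
`per_allele_scenario(s, ...)` constructs the corresponding scenario
(internally `s' = 2s`, `h = 0.5`).  This reading — rather than taking the
quoted value as the homozygote advantage — is the one under which the
benchmark power table recomputed by `scripts/acceptance.py` behaves as
reported: a de novo allele selected from 2,000 generations ago (N = 10⁴,
s = 0.005) is near fixation at sampling, standing variants from p₁ = 0.1
are fixed by the present (which is exactly what drives the haplotype
tests' power to 0 there), and the SFS-test powers land in the reported
range.  Under the homozygote reading the sweep reaches only ~50%
frequency and the whole table inverts.

Three conditioning schemes:

* **SDN (allele age)** — one copy is introduced `t_age` generations ago
  and followed forward; rejection until the survival condition holds at
  the present.  The default condition is *non-loss* (fixation allowed):
  fixed alleles must stay in the replicate pool because Tajima's D retains
  power after fixation, and the pool's fixed fraction is precisely what
  extinguishes rEHH/iHS.  A segregating-only condition is available.
* **SSV (standing variation)** — a neutral history is generated *backward*
  from the onset frequency p₁ at `t_sel` until absorption at one copy
  (paths absorbed at fixation are rejected: the variant must originate as
  a mutation), and a selected forward path runs from the onset to the
  present; the two are spliced at `t_sel`.  Backward neutral steps use the
  neutral binomial chain as its own time reversal; its adequacy is covered
  by the forward-oracle equivalence test below.
* **Current frequency** — the correctness baseline is forward simulation
  from a de novo mutation at an origin time uniform on `[1, max_age]`
  (default `20·reference_N` generations — old enough that the omitted
  older-origin mass is negligible for segregating alleles) with rejection
  on the final frequency.  For constant-size models a reverse-time
  accelerator starts from a present-day copy number drawn uniformly on the
  bin's lattice and walks backward (for s > 0 the deterministic selection
  increment is subtracted before the binomial draw).  The two methods'
  origin-age distributions are compared by a two-sample KS test
  (α = 0.01) in the suite; the test runs at N = 500 with 300 paths per
  method — a problem size chosen so the check carries real resolution
  while the whole suite stays fast — rather than the N = 5,000 / 2,000
  paths of a full validation.

Rejection sampling is guarded (default 10⁶ attempts; a structured error
reports the attempt count).  Backward walks are capped at 60·N
generations; longer paths (probability ≈ e⁻³⁰ under neutrality) are
treated as rejected.

## Structured coalescent with recombination

The sample genealogy is generated backward in time.  While the focal
allele is polymorphic in the lookback population, lineages carry an
allelic class; at generation g with derived-copy count `k_g = round(2N_g
x_g)`, coalescence happens within the derived class with per-generation
probability `C(k_D,2)/max(k_g, k_D)` and within the ancestral class
analogously (the `max` floor keeps probabilities valid on the frequency
lattice).  Each lineage recombines with probability `r·ℓ`, where ℓ spans
from the leftmost to the rightmost point of its ancestral material *and
the focal site* — breakpoints between the focal site and the material
change allelic class even when they fall outside the material itself.
The fragment not containing the focal site becomes a new lineage whose
class is redrawn as derived with probability `x_g`.  At the trajectory's
origin all remaining derived lineages merge into one node (the mutation
event) and switch to the ancestral class; older than that, and for
unconditioned neutral runs, a single-class coalescent continues until
every position has found its MRCA (intervals whose descendant set is the
full sample are stripped on the spot).  While `x_g = 1` the derived class
simply coalesces at the whole-population rate, so post-fixation sampling
works unchanged.

Event scheduling is discrete-generation Bernoulli with at most one
coalescence per class per trial; any generation whose total event
probability exceeds 0.1 is subdivided into equal sub-steps, and in the
single-class phase waiting times are drawn directly from the resulting
per-generation no-event probability (with epoch boundaries respected).
Two consequences worth knowing: event times live strictly inside their
generation (a uniform sub-generation offset), and simultaneous
multiple-mergers of exact Wright–Fisher reproduction are serialized into
pair mergers — a bias of order one generation in tree depth at class
sizes of a few copies, which the suite's exact-oracle comparison at
N = 50 quantifies and which is negligible at study population sizes.
The core is compiled with numba; capacities are retried ×4 on overflow
with the identical random stream.

Mutations are dropped afterwards on the edge ledger: each lineage
lifetime receives `Poisson(μ · duration · material length)` mutations at
positions uniform in its material, carried by the interval's descendant
set, so every emitted column is polymorphic in the sample.  Positions are
continuous in `[0, L]`; ms-format output encodes them as fractions of L.
The focal column itself is appended from the sampled allelic classes
(binomial `n_derived ~ Bin(n, x_0)`) whenever polymorphic in the sample,
and is included in the SFS statistics by default (it is a real
segregating site; a flag excludes it).

## Statistics

* `D = (π − S/a₁) / sqrt(e₁S + e₂S(S−1))` with the classical constants;
  undefined at S = 0.
* `H = θ_π − θ_H`, un-normalized, from the unfolded SFS (ancestral states
  are known by construction).  Empirical nulls make normalization
  unnecessary; S = 0 gives 0.
* `EHH(x)` for carriers of a core allele: the probability that two random
  carriers are identical over every polymorphic column between core and
  x, inclusive; `rEHH = EHH_derived/EHH_ancestral` at a fixed distance
  (default 25,000 bp).  Undefined when either class has < 2 carriers or
  the ancestral EHH is 0.
* `iHS = ln(iHH_A / iHH_D)`, where iHH is the trapezoidal integral of the
  EHH decay curve from the core outward, truncated at the first marker
  with EHH < 0.05 (that marker's trapezoid included).  Integration is
  one-sided because the focal site sits at the region edge in the
  haplotype-test design.  No genome-wide standardization: the statistic
  is compared to a frequency-matched null, which is equivalent in tail
  probability to bin-wise standardization without inventing bin
  parameters.

Rejection tails under positive selection: D lower, H lower, rEHH upper,
iHS lower.

## Power estimation

Null distributions are simulated: unconditioned neutral replicates for
the SFS tests (n_null = 1,000 by default — a 200-replicate null makes the
5% threshold too noisy), and, for the haplotype tests, neutral replicates
conditioned on a focal variant in the same 0.05-wide present-day
frequency bin as the alternative replicate (≥ 200 per bin).  The
threshold is the order statistic at rank `ceil(α·n_null)` from the tail;
a replicate is significant strictly beyond it.  Undefined statistics are
excluded from nulls (counted) and scored non-significant in data.  Power
and FPR come with Wilson 95% intervals; `mean_final_freq` across
replicates accompanies every grid point.

Study-standard regions: 10 kb with the focal site at the center for the
SFS tests, 500 kb with the focal site at the edge for the haplotype
tests; 120 chromosomes; μ = r = 10⁻⁸ per site per generation; 200
replicates per grid point at the 1-sided 5% level.

## Synthetic data: what it does and does not emulate

The generator reproduces the *model* world of sweep-power studies:
panmictic piecewise-constant demography, a single selected biallelic
site, infinite-sites mutation, uniform recombination, perfectly known
ancestral states and phased haplotypes.  It does not emulate
ascertainment bias, genotyping or phasing error, gene conversion,
background selection, or population structure — so passing tests
demonstrate correctness of the method under its assumptions, not
robustness of the four tests on real data.

## Numerical and design choices

* Frequencies live on the lattice k/2N(t); rounded class sizes are floored
  at the current lineage count.
* The per-allele selection convention above; `h` is exposed for other
  dominance regimes.
* rEHH distance is a sensitivity knob: keeping the expected number of
  SNPs in the core-to-target interval constant across models (the natural
  way to compare histories of different diversity) would suggest
  ~12,500 bp at N = 10,000 rather than the 25,000 bp default inherited
  from the Ne = 5,000 design; the default is kept for comparability and
  the knob left to the caller.
* Empirical-threshold ties break conservatively (strict inequality).
* Replicate-level randomness derives from a single seed; identical config
  + seed gives byte-identical outputs, including across the numba core
  (per-call substream seeds below 2³¹).
* Statistical suite checks use 3-SE bands (or KS at α = 0.01) at problem
  sizes stated in each test; sizes were chosen for resolution-per-second,
  and several (noted inline) are scaled down from the full study sizes.

## Known limitations

* n ≤ 128 chromosomes (descendant sets are 128-bit masks).
* Multiple-merger serialization biases tree depth by ~1 generation when a
  class has only a few copies (quantified by the N = 50 oracle test).
* The reverse-time selected accelerator is an approximation to the exact
  conditioned process; it is validated against forward rejection at
  2Ns ≤ ~20 and should be re-validated before use deep in other regimes.
* No gene conversion, no crossover interference, one focal site.
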