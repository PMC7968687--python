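# Methods

This note documents the generative models, algorithms, parameter choices
and numerical conventions behind `meicross`, and what the synthetic data do
and do not establish about real experiments.

## Meiosis simulator

### Chromosome geometry

Six chromosomes default to *C. elegans* reference-assembly (ce11) lengths.
Each `ChromosomeSpec` carries an arm/center domain split and a
pairing-center (PC) end. The default center domain is the central half of
the chromosome (L/4..3L/4) — a generic placeholder; analyses that compare
against an empirical recombination map should supply that map's own domain
boundaries through the YAML config. The PC end defaults to `left` for all
chromosomes and is configurable per chromosome.

### Crossover formation

Per meiosis and per chromosome:

1. **Morphology.** One of `zipped` / `forked` / `unpaired` is drawn from
   per-chromosome probabilities. Unpaired chromosomes form no crossovers.
   Forked chromosomes restrict crossovers to a zipped segment of fraction
   `forked_zipped_fraction` (default 0.5) anchored at the PC end, where
   synapsis initiates.
2. **CO number and position.** Three models:
   * `obligate_one` — exactly one CO (wild-type regime);
   * `poisson` — CO count ~ Poisson(rate), positions i.i.d.;
   * `gamma_renewal` — a stationary gamma-renewal point process on the
     genetic scale of the eligible region. Inter-event gaps are
     Gamma(ν, scale = 1/(ν·λ)), giving intensity λ; the first event uses
     the equilibrium (forward-recurrence) delay, sampled exactly as
     U·G with G from the length-biased gap distribution Gamma(ν + 1,
     same scale). ν = 1 recovers a homogeneous Poisson process; larger ν
     concentrates gaps near 1/λ, the standard statistical idealization of
     crossover interference.

   For forked chromosomes the expected count is scaled by the
   placement-weight mass of the zipped segment relative to the whole
   chromosome. Positions are mapped from the unit genetic scale to
   physical bp by the inverse CDF of a piecewise-constant arm/center
   placement density, so placement weights change *where* COs fall without
   changing how many.
3. **Transmission.** Each bivalent CO involves two of the four chromatids;
   with no chromatid interference, the transmitted chromatid carries each
   CO independently with probability 1/2, and its starting parental
   identity (Bristol/Hawaiian) is uniform. Consequences the suite
   verifies: a single obligate CO is transmitted half the time (per-
   chromosome recombinant fraction 0.5), and a double-CO bivalent
   transmits both COs together a quarter of the time — the dilution factor
   between cytological and genetic double-crossover frequencies.

### Genotyping model

Backcross design: a marker call is heterozygous where the transmitted
haplotype is Bristol and homozygous-recurrent where Hawaiian, switching
exactly at transmitted CO positions. Noise is per-marker i.i.d.: a call is
flipped with `genotyping_error_rate` and set missing with `missing_rate`.
No read-depth or genotype-likelihood modeling: the pipeline starts from
hard calls, as emitted by an upstream variant caller.

### Preset regimes

`wildtype_params()`: all chromosomes zipped, obligate single CO.

`mutant_params()` emulates a partially synapsing mutant. Values were fixed
once against the study conditions this package models and are not fitting
targets:

| parameter | value | rationale |
|---|---|---|
| zipping success per chromosome | I 0.35, II 1.0, III 0.60, IV 0.70, V 0.80, X 0.90 | spreads per-chromosome transmitted recombinant fractions over ~0.32–0.52, emulating the wide per-chromosome crossover-rate variation of such mutants |
| failed-zipping split | 75% forked / 25% unpaired | forks are the commoner partial-synapsis outcome |
| co_model, co_rate | gamma_renewal, 1.2 per zipped bivalent | with thinning, ~6% of transmitted chromatids carry double COs — rare doubles |
| interference ν | 4 | residual-but-weakened interference; ν is a free calibration parameter (no measured value exists), chosen so doubles are clearly separated from a random-pairing null at realistic sample sizes |
| placement weights | arm 1.0 / center 2.5 | center-skewed crossover landscape characteristic of synapsis mutants (>2-fold center enrichment) |
| genotyping error / missing | 0.002 / 0.02 | low-coverage short-read genotyping noise |

### Cytological foci and dose response

`simulate_foci` places one focus per bivalent CO on zipped/forked
chromosomes and, optionally, Poisson(`unpaired_focus_rate`) foci on
unpaired chromosomes (modeling regimes where unpaired axes recruit
crossover-factor foci). Positions are reported on a standardized 7 μm
chromosome.

`simulate_dose_response` draws breaks per homolog pair ~ Poisson(c·dose)
independently for `f_max` pairs; the focus count is the number of pairs
with ≥ 1 break. Its mean equals `expected_foci` exactly, which the suite
checks by Monte Carlo.

`dapi_body_count(k) = 12 − k` converts the number of crossover-linked
pairs (of 6) into diakinesis DAPI-body counts: each linked pair condenses
into one bivalent, each unlinked pair into two univalents.

## Crossover caller

Semantics (exactly implemented by a dynamic program over runs of
informative calls, missing calls transparent):

* a segmentation assigns maximal blocks of informative markers to
  alternating genotypes;
* a block is valid only if it contains a *support window* — ≥ `min_run`
  concordant markers in which each interruption by discordant markers is ≤
  `max_background` long;
* discordant markers inside a block cost 1 each; the caller returns the
  valid segmentation with minimum total cost, ties broken by fewest
  segments, then by switch position (`tie_break`, leftmost by default).

Defaults `min_run = 5`, `max_background = 1` make a false segment require
≥ 5 wrong calls within a short window — vanishingly unlikely at sub-percent
error rates — while a real switch on a 1,000-marker chromosome is almost
always supported. The suite verifies equivalence with an exhaustive
enumeration oracle on short vectors and < 1% false calls at 0.5% error.

Numerical conventions and degenerate inputs:

* **Breakpoint interval.** An event spans from the last marker of the
  preceding segment to the first marker of the following segment. When
  several boundary placements tie in cost (e.g. a genotyping error
  adjacent to a true boundary), the interval spans *all* minimum-cost
  placements — the honest localization of the ambiguity, and what keeps
  calls mirror-symmetric under marker-order reversal. Midpoints of these
  intervals feed all distance statistics.
* **Edge crossovers.** A crossover with fewer than `min_run` informative
  markers between it and the end of the marker span (or a neighboring
  crossover) cannot satisfy the support rule and is not called; this is a
  property of the decision rule itself, not an implementation limit.
* An all-missing vector yields an empty segmentation (flagged); a vector
  on which no genotype attains a support window falls back to a single
  majority-genotype segment (flagged); chromosomes with < `min_run`
  informative markers yield no calls.

## Interference statistics

* Distances are between breakpoint-interval midpoints, in Mb, for
  chromosomes with exactly two events.
* The random-pairing null draws, per resample, a chromosome with
  probability proportional to its weight (default: its observed double-CO
  count), then two *distinct* mapped crossovers uniformly without
  replacement — self-pairing would contribute spurious zero distances.
  The pool includes all mapped crossovers, singles included. Default
  2,100 resamples, fully seeded.
* `compare_observed_to_null` reports both medians, shared-bin histograms
  and a one-sided Wilcoxon rank-sum p-value for observed > null. The rank
  test is this package's addition for programmatic comparison; the suite
  shows its p-value is uniform when the simulator has no interference
  (ν = 1) and detects ν = 10 at ~30 observed doubles with > 80% power.
* Binned statistics divide a chromosome into 6 equal intervals (half-open
  bins; a position exactly at the end goes to the last bin) and use the
  signed difference (bin of 2nd) − (bin of 1st) for pairs.
* Arm/center rates: domain cM = 100 × midpoints-in-domain / n_meioses;
  rate = cM per domain Mb; optional ratios against supplied reference
  rates. Left arm, center and right arm are reported separately.

## Cytological statistics

* Focus merging is single-linkage and transitive: foci chained by gaps
  < 0.3 μm (default) collapse to their mean. Merging is idempotent:
  cluster means inherit ≥-threshold separation from the cluster gaps.
* Normalization maps traced positions onto a standard 7 μm chromosome
  divided into 6 equal bins; binning is scale-invariant by construction.
* The focus-pairing null draws 24 (default) ordered pairs of distinct foci
  and keeps the signed bin difference.
* Fork-junction proximity uses 1-D arc-length distance along the traced
  axis (< 1 μm default radius). This is the reproducible desk-scale
  analogue of a 3-D imaging measurement and will undercount separations
  that are large in 3-D but small along the axis.

## Break-induction model

E[foci](d) = f_max·(1 − e^(−c·d)) — the Poisson-assurance form: a homolog
pair shows a focus iff it receives at least one break. f_max defaults to 5
(unsynapsed X excluded). The fit minimizes RMSD between per-dose *mean*
counts and the curve, by bounded scalar minimization on c ∈ [0, c_hi] with
c_hi = ln(10⁶)/d_min_pos so the bracket always contains the optimum
interior (xatol 1e-12); the suite cross-checks against a dense grid
search. Degenerate inputs: all-zero counts at positive doses return c = 0
with a warning; single-dose data are rejected. Break-number conversions
report both scales — c·d per homolog pair and c·d/2 per chromosome —
because published values appear on both.

## Problem sizes

Default problem sizes (84 individuals × 1,000 markers/chromosome for the
demo; 10,000 meioses for prevalence estimates; 200 nuclei/dose for the
dose-response fit; 2,100/24 resamples for the nulls; 200 replicates for
calibration checks) were chosen so every statistic is estimated with
Monte-Carlo error well below its decision threshold while a full run
completes in seconds on a laptop.

## What passing tests show — and what they do not

The synthetic data reproduce the *statistical structure* the analysis
assumes: hard biallelic genotype calls with i.i.d. error/missingness,
exact CO-to-focus correspondence, independent chromatid choice, and a
known generative interference model. Real data violate several of these:
genotyping error is locally correlated (alignment artifacts, coverage
troughs), marker density is uneven, focus detection has its own
false-positive/negative structure, and the true interference process is
not literally gamma-renewal. Passing tests therefore validate the
*algorithms and their calibration under the stated model*, not the
biological accuracy of any particular parameter value. The caller's
recall bound, in particular, is conditional on the i.i.d.-error model;
correlated error bursts longer than `max_background` would produce false
calls at a higher rate.

## Known limitations

* No genotype-likelihood/HMM calling; F2 intercross (het × het) designs
  are out of scope.
* No coefficient-of-coincidence maps and no maximum-likelihood estimation
  of ν from data (ν is a simulator input only).
* Arm/center default boundaries are placeholders, not an empirical map.
* 1-D fork-proximity as noted above.
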