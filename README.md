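# meicross

Meiotic crossover mapping, crossover-interference statistics, and
break-induction modeling for *C. elegans* backcross experiments.

## The problem

During meiosis each pair of homologous chromosomes normally receives exactly
one crossover (CO). Mutants that compromise synapsis — the zipping of
homologs by the synaptonemal complex — perturb both the number and the
placement of crossovers: chromosomes may stay unpaired (no CO), zip
partially ("forked"), or carry multiple COs with weakened interference.
Two complementary readouts quantify this:

* **Genetic mapping.** A Bristol/Hawaiian F1 hybrid backcrossed to the
  Hawaiian (recurrent) parent yields F2 progeny whose SNP genotypes along
  each chromosome — heterozygous (Bristol haplotype) vs homozygous-recurrent
  (Hawaiian) — read out one transmitted gamete. Each genotype switch marks a
  crossover.
* **Cytology.** COSA-1 foci mark designated crossover sites, one per
  chromosome in the wild type; focus counts and positions along traced
  chromosome axes report the crossover landscape directly.

`meicross` implements this analysis end to end as a tested, reusable
pipeline working on synthetic data with the statistical structure of a real
experiment: a forward simulator of meioses and their genetic/cytological
readouts, a crossover caller, interference statistics with resampling
nulls, cytological focus statistics, and a saturating X-ray break-induction
model.

## Models and statistics

**Crossover formation.** Per bivalent, a synapsis morphology (zipped /
forked / unpaired) is drawn; CO positions come from an obligate-single-CO
model, a Poisson process, or a stationary gamma-renewal process on the
genetic scale with shape ν ≥ 1 (ν = 1 is Poisson; larger ν widens inter-CO
spacing, i.e. interference). An arm/center placement-weight density
reshapes positions by inverse-CDF transform. Each bivalent CO enters the
single transmitted chromatid independently with probability 1/2 (no
chromatid interference), so a double-CO bivalent transmits both COs on one
chromatid a quarter of the time — the factor relating cytological to
genetic double-crossover frequencies.

**Crossover calling.** A genotype switch is accepted only when backed by a
support window of ≥ `min_run` concordant informative markers (interruptions
of ≤ `max_background` discordant markers tolerated); stray discordant
markers are absorbed as genotyping background. Among valid segmentations an
exact dynamic program returns the one with the fewest discordant markers.
Breakpoints are reported as flanking-marker intervals.

**Interference.** For chromosomes with exactly two COs, the observed
midpoint distance distribution is compared against a random-pairing null:
2,100 synthetic "double crossovers" built by pairing two mapped crossovers
from one chromosome, chromosomes weighted by their observed double-CO
counts. A one-sided Wilcoxon rank-sum test quantifies whether observed
spacings are stochastically larger than the null.

**Break induction.** With endogenous breaks absent, X-rays create breaks
per homolog pair ~ Poisson(c·dose); a pair focuses iff it receives ≥ 1
break, so E[foci] = F_max·(1 − e^(−c·d)) with F_max = 5 focus-competent
autosome pairs in a *him-8* background. The constant c
(breaks·rad⁻¹·pair⁻¹) is fitted by RMSD minimization over per-dose mean
counts; c·d gives mean breaks per pair and c·d/2 per chromosome.

## Worked example

One seeded command simulates a full experiment (84 F2 progeny, 1,000 SNPs
per chromosome, 60 nuclei, a 7-dose irradiation series), calls crossovers,
and runs every analysis:

```
meicross demo --seed 7 --out demo_out
```

or in Python:

```python
from meicross.io import default_config
from meicross.pipeline import run_demo

summary = run_demo(default_config(seed=7), "demo_out")
```

Key numbers from `demo_out/summary.json` at seed 7:

```
caller        recall 0.985, false-call rate 0.000  (268 calls / 272 truth COs)
interference  double-CO prevalence 6.5% (33 of 504 chromosomes)
              observed median spacing 6.15 Mb vs 3.74 Mb random-pairing null
              one-sided rank-sum p = 2.3e-4
break model   c fitted 0.002833 vs truth 0.0028 (rmsd 0.061 foci)
cytology      5.87 ± 1.74 foci per nucleus
```

Read: the caller recovers essentially every simulated breakpoint without
false calls; double crossovers are rare (~6% of chromosomes) and spaced
nearly twice as far apart as random pairing would predict — residual
interference — and the dose-response fit recovers the generating
break-induction constant to ~1%. Individual steps are exposed as
`simulate`, `call`, `interference`, `cytology` and `breakfit` subcommands,
and as library functions (`simulate_meiosis`, `call_crossovers`,
`random_pairing_null`, `fit_break_constant`, ...).

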