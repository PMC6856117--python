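# cabalsim

Population-genetic models of conflict between "trait distorters" — selfish
genetic elements that bias an organism trait away from the individual
optimum to gain a transmission advantage — and the rest of the genome, which
is selected to suppress them.  Following Leigh's parliament-of-genes
imagery, the minority of loci that share a distorter's transmission interest
form a *cabal* (fraction θ of the genome) and the opposing majority the
*commonwealth*.

The package is aimed at evolutionary geneticists who want to ask, for a
given distorter strength, cost structure and genome architecture: does a
distorter invade, does a costly suppressor catch it, how long does the
conflict distort the trait, and how much distortion does an organism
experience on average over evolutionary time?

## Models

All deterministic engines track gamete frequencies in an infinite,
randomly mating diploid population with non-overlapping generations.

* **Single locus.** A dominant distorter allele D1 of strength *k* drives at
  meiosis, reaching a fraction (1 + *t*(*k*))/2 of a heterozygote's gametes,
  and costs its carrier *c*_trait(*k*) in viability.  It invades iff
  *c*_trait(*k*) < *t*(*k*)(1 − *c*_trait(*k*)), and then always fixes.
* **Distorter + suppressor.** An unlinked, dominant, facultatively
  expressed suppressor S1 silences D1 at individual cost *c*_sup.  The
  leading eigenvalue of the invasion Jacobian at the distorter-fixation
  equilibrium is (1 − *c*_sup)/(1 − *c*_trait(*k*)): the suppressor invades
  iff *c*_trait(*k*) > *c*_sup, after which expressed distortion collapses
  and the distorter is purged.  An obligate (constitutive) suppressor
  variant fixes instead, retaining the distorter as a neutral passenger.
* **Mutant distorters.** A six-gamete system with a resident D1 and mutant
  D2 of strength *k̂*.  Stronger dominant mutants invade iff
  Δ*t*(1 − *c*_trait(*k̂*)) > Δ*c*_trait; weaker ones are recessive and
  never do.  Under δ-weak selection an adaptive walk climbs to the
  gene-level optimum *k*_target solving
  d*t*/d*k* (1 − *c*_trait) = d*c*_trait/d*k*.
* **Introduction cycles.** New distorters arise every
  1/(θγρ_D1) generations and their dedicated suppressors
  1/((1 − θ)γρ_S1) generations later.  Distortion cycles between peaks of
  *k* and troughs of 0; under a separation of timescales the
  evolutionary-time average is *k*θρ_D1/((1 − θ)ρ_S1) — independent of
  genome size γ and of the baseline mutation rate.
* **Agent-based simulators.** Stochastic finite-*N* engines: a single-locus
  model with continuously evolving distorter/suppressor strengths, and
  genome-wide multilocus models (fixed-strength "discrete" and freely
  evolving "continuous") with stochastic locus activation, background
  (generalist) suppression *z*, inter-locus dominance, and waste costs from
  inter-locus-recessive distorters.

## Worked example

```python
import cabalsim as cs

tr = cs.TraitResponse.power(0.87, 1.0, 0.9, 1.5)   # t = 0.87k, c = 0.9 k^1.5
print(cs.distorter_invades(tr, 0.3))                # True
print(cs.k_target(tr).k)                            # 0.30102098067271577

params = cs.ConflictParams(c_sup=0.15, k=0.6)
lam = cs.leading_eigenvalue(cs.suppressor_jacobian(tr, params))
print(lam)                                          # 1.461189604360808

res = cs.time_to_purge(tr, params)
print(res.generations)                              # 57
```

A distorter of strength 0.3 invades (its transmission gain outweighs its
carrier cost); left free to evolve, distorter strength climbs to the
gene-level optimum ≈ 0.301.  A distorter of strength 0.6 is costly enough
(c_trait ≈ 0.418 > c_sup = 0.15) that the suppressor's invasion eigenvalue
is 1.46 > 1 — in fact at that strength the cost already violates the
distorter's own invasion criterion, so a joint introduction from rarity
sees it flushed out within 57 generations.  Weaker distorters that do
invade are held in the population far longer: at k = 0.35, just above the
suppression threshold, the purge outlives a million-generation cap
(`cap=1_000_000` returns `capped=True`), which is the non-equilibrium
window the purge-time experiment maps.

The figure-level experiments are scripted:

```sh
cabalsim list                      # fig1a fig1b fig2a fig2b fig4a fig4b fig5a fig5b
cabalsim run fig1a --out results/  # tidy CSVs + manifest.json
cabalsim sweep --method approx     # (k, theta) average-distortion table
cabalsim check                     # fast invariant battery
```

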