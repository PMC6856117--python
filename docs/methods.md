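# Methods

## Model family

The package studies a two-party conflict inside a diploid genome.  A *trait
distorter* allele of strength k ∈ [0, 1] biases an organism trait away from
the individual optimum; the bias buys the allele a meiotic transmission
advantage, (1 + t(k))/2 in heterozygotes, and costs its carrier c_trait(k)
in viability.  An unlinked *suppressor* allele silences the distorter
(cancelling both the drive and the trait cost) at its own constant carrier
cost c_sup.  Both t and c_trait are monotone non-decreasing maps of [0, 1]
into [0, 1]; the constructor verifies this on a 201-point grid and the
built-in power-law family t = a·k^b, c_trait = c·k^d covers every
configuration the bundled experiments use.  Suppression is *facultative* by
default (expressed, and paid for, only when the target distorter is present
in the same individual); an *obligate* mode expresses it constitutively.

Deterministic engines iterate exact gamete-frequency recursions (4 gamete
classes for distorter + suppressor; 6 with a resident and a mutant
distorter), normalising each generation by the population mean fitness.
The facultative steppers are direct transcriptions of the published
polynomial systems; the obligate and additive-gene-action variants come
from a general mating-table engine (random union of gametes → genotype
viability → drive-biased meiosis) that reproduces the same polynomials in
the facultative dominant case.  The obligate system differs from the
facultative one in exactly two terms — the distorter-free matings that
carry S1 (D0S0 × D0S1 and D0S1 × D0S1) acquire the (1 − c_sup) factor —
because a genotype containing both a distorter and a suppressor expresses
the suppressor in either mode.

Key closed forms, each verified against iteration or numerical
linear algebra in the test suite:

* distorter invasion: c_trait(k) < t(k)(1 − c_trait(k)); an invading
  distorter always fixes (no negative frequency dependence);
* suppressor invasion: the Jacobian at the distorter-fixation equilibrium
  has leading eigenvalue (1 − c_sup)/(1 − c_trait(k)), so invasion iff
  c_trait(k) > c_sup.  As printed, the matrix also carries eigenvalues
  1 − t and (1 − c_sup)/(2(1 − c_trait)); the closed form is the leading
  one whenever (1 − c_sup)/(1 − c_trait) > 1 − t, which always holds in the
  invasion-relevant regime c_trait > c_sup;
* dominant mutant invasion: Δt(1 − c_trait(k̂)) > Δc_trait for k̂ > k;
  weaker mutants are recessive in the resident heterozygote and never
  invade.  The additive rule Δt(2 − c_trait(k) − c_trait(k̂)) > Δc_trait is
  reproduced exactly by a mating-table system in which a genotype's cost is
  the mean of its two allele costs and the drive bias is t(k_i) − t(k_j);
  linearising that system at resident fixation gives the printed criterion,
  which is how the additive engine is cross-checked;
* gene-level optimum: k_target solves t′(k)(1 − c_trait(k)) = c_trait′(k)
  (factor 2 on the benefit under additive action), found by Brent's method
  to 1e-10 after a 400-point sign scan; one-signed balance functions return
  the 0/1 boundary with a flag, multiple roots return the smallest with a
  warning.

## Long-term dynamics

New distorters arise deterministically every 1/(θγρ_D1) generations (θ =
proportional cabal size ≤ 0.5, γ = genome size, ρ_D1 = per-locus
introduction probability) and each dedicated suppressor follows after a lag
of 1/((1 − θ)γρ_S1) generations, rounded to the nearest whole generation.
One cycle is solved exactly: the single-locus recursion for the lag, then
the two-locus recursions until the distorter is purged (combined D1 gamete
frequency < 1e-9).  Mean individual distortion is computed from gamete
frequencies under random union: an individual expresses distortion k iff it
carries ≥ 1 distorter allele and no suppressor allele, so the population
mean is k((x00 + x10)² − x00²).  The evolutionary-time average weights the
within-cycle mean by the fraction of time a distorter segregates,
X·θγρ_D1; equivalently it is θγρ_D1 times the summed distortion series,
which makes it insensitive to how long the near-zero tail of the purge
phase is tracked.  Under the separation-of-timescales limit this average
collapses to kθρ_D1/((1 − θ)ρ_S1) for suppressed distorters
(c_sup < c_trait(k)) and is simply k below the suppression threshold.

## Numerical behaviour near fixation boundaries

Two float64 phenomena shape the defaults, and both are features of the
model's boundary structure rather than of any particular tolerance:

1. After a long unsuppressed phase the wild-type frequency 1 − p decays
   geometrically; over the ~2×10⁵-generation lags of the cycle model its
   exact value (~10⁻⁹⁰⁰⁰) is far below float64 range, so p becomes exactly
   1 and the literal allele-loss criterion is unreachable.  The cycle
   therefore also terminates once expressed distortion falls below 1e-9
   (flagged `truncated_tail`); the omitted tail contributes < 1e-4 of the
   distortion sum, leaving peak, trough and the evolutionary average
   unchanged.
2. When the suppressor arrives very late (distorter frequency ≥ 0.99) or
   very rare (≤ 1e-4), drive grinds the D0 reservoir to ~1e-10 or below
   before suppression catches up; the system then parks in a
   quasi-equilibrium with the suppressor fixed and the now-silenced
   distorter retained, whose exact-arithmetic resolution takes ≳1e10
   generations.  The individual-level outcome — expressed distortion ≈ 0
   whenever c_trait(k) > c_sup — is identical in both end states, and the
   tests assert that outcome.  The same applies after a mutant distorter
   triggers suppression in the six-gamete system.  For clean purge
   equilibria the pipeline introduces the suppressor at distorter
   frequency 0.9 with total suppressor frequency 1e-3.

The non-equilibrium purge-time experiment introduces distorter (1e-6) and
suppressor (1e-3) simultaneously and iterates the two-locus system until
the distorter drops below 1e-9, capped at 2×10⁷ generations; this handles
distorters too strong to satisfy their own invasion criterion, which are
flushed out quickly — the reason purge time is monotone non-increasing in k
across the full strength range.

## Agent-based simulators

All three engines share the reproduction scheme: N hermaphroditic diploids,
non-overlapping generations, 2N fitness-proportional parent draws with
replacement (selfing permitted; a flag disables it), one offspring per
pair, fitness clamped at 0 for sampling.  Defaults are the bundled
experiments' study conditions: N = 2000; per-allele mutation probability
0.01 per generation with a normal kernel of variance 0.2 centred on the
current value and truncated to [0, 1] by clamping (a resampling mode
exists); 0.001 functional/neutral flips in the discrete multilocus mode;
20 000 (single-locus) or 30 000 (multilocus) generations.

Single-locus: allele strengths k_a, k_b (distorter) and m_a, m_b
(suppressor); fitness 1 − c_trait(max(k_a,k_b))(1 − max(m_a,m_b)) −
c_sup·max(m_a,m_b) when a distorter is present, 1 otherwise; the k_a allele
displaces k_b with probability (1 + (t(k_a) − t(k_b))(1 − max(m_a,m_b)))/2;
suppressor alleles segregate in Mendelian fashion.  With mutation off and
strengths restricted to {0, k} × {0, 1} the engine is a finite-population
realisation of the two-locus recursions, which the tests exploit.

Multilocus: loci are held sparsely — only activated loci are materialised.
Dormant cabal and commonwealth loci activate per generation with
probabilities ρ_D1 and ρ_S1 (binomially over the dormant counts);
commonwealth activation is gated so dedicated suppressors never outnumber
distorter loci, and commonwealth locus i targets cabal locus i.  Activation
seeds one functional allele (strength k / 1 in discrete mode; one
truncated-kernel draw from 0 in continuous mode) on a random haplotype of a
random individual — the dormant drift phase is collapsed into the
activation event.  A suppressor is expressed only when its target distorter
is present in the same individual.  Total suppression of distorter i is
TotSup_i = 1 if its dedicated suppressor is present, else min(z·q, 1)
(discrete; q = number of expressed suppressors), or
min(max(m_ai, m_bi) + z·Σ_{j≠i} max(m_aj, m_bj), 1) (continuous).
Background suppression z is 0.5 for low-sophistication distorters and 0 for
high-sophistication ones (whose introduction rate is half the
low-sophistication rate).  The least-suppressed distorter is inter-locus
dominant: Dist = max_i (1 − TotSup_i)·k_i; the remainder contribute
Waste = Σ_{i≠i_dom} (1 − TotSup_i)·k_i.  The recessive-distorter cost is a
function of the waste pool, c_rec = r·c_trait(Dist)·Waste/Dist with r = 1
(low sophistication) and 3/5 (high) — so each fully unsuppressed recessive
distorter costs r·c_trait(Dist), the stated per-distorter proportionality,
while a silenced distorter, which adds nothing to the pool, costs nothing
here (it still incurs its c_sup term).  Ties in i_dom resolve to the
lowest locus index.
Fitness is 1 − c_trait(Dist) − c_rec − c_sup·ΣTotSup_i.  Heterozygous
distorters drive as one unit, transmitted with probability
(1 + max_i (1 − TotSup_i)·d_i)/2 where d_i is t(k) at heterozygous loci
(discrete) or t(max) − t(min) across the homologous pair (continuous) —
the drive bias is passed through the transmission-bias function so the
engines stay consistent with the single-locus rule; under the experiments'
t = k this is exactly the raw-strength form.  Suppressor loci segregate
Mendelian-independently.  Replicate r of a run is seeded seed + r with its
own generator.

## What the generators emulate — and what they do not

The simulators emulate the study conditions of the deterministic theory:
unlinked loci, random mating, constant N, fixed trait-response functions.
They do not model linkage or physical chromosome structure, sexes or
overlapping generations, spatial structure, frequency-dependent responses,
or the sequence-level drift of dormant loci.  Agreement between the ABMs
and the recursions therefore demonstrates internal consistency of the
model family at finite N, not realism of any particular biological system.

## Problem sizes

The test suite runs the deterministic engines at full precision and the
stochastic ones at desk scale: the single-locus coevolution check uses
N = 2000 over 6000 generations × 3 replicates, the recursion-agreement
check N = 4000 over 100 generations × 10 replicates, and the genome-size
sweep compresses γ by 500× with ρ scaled up 500× — statistically
equivalent, since only activated loci are materialised and per-generation
activation rates are preserved along with the full 30 000-generation
horizon — at N = 500, with 3–8 replicates per cell (more where
introduction events are sparse).  The figure runners default to
reference-scale parameters with a `--scale` multiplier for replicates and
horizons.

## Known limitations

* The quasi-equilibria described above mean that *allele-level* endpoint
  claims (purge vs retention of a silenced distorter) depend on how much
  wild-type background remains when suppression starts; *individual-level*
  distortion outcomes do not.
* The closed-form cycle average assumes no co-segregation
  (X·θγρ_D1 ≤ 1); `cycle_exact` warns when its parameters violate this.
* The multilocus engines' γ-dependence at large θ is sensitive to N, the
  horizon and the activation-to-purge timescale ratio; desk-scale runs
  preserve per-generation rates rather than absolute locus counts.
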