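# Methods

This note records the models, conventions and numerical choices behind
`popgenkit`, and their known limitations. Every quantitative claim here is
checked by the test suite (`tests/`) or computed by
`scripts/acceptance.py`.

## Scaling conventions

All rates and times follow the standard coalescent-simulator convention:

* time is measured in units of 4N₀ generations, where N₀ is the reference
  (present-day) effective population size;
* in a population of relative size `x`, each pair of lineages coalesces at
  rate 2/x, so E[TMRCA] = 0.5 for n = 2 and the expected total tree length
  for n copies is the harmonic number a₍ₙ₋₁₎ = Σᵢ₌₁ⁿ⁻¹ 1/i;
* θ = 4N₀μ per locus: mutations fall on the genealogy as a Poisson process
  of rate θ per unit branch length, so E[S] = θ·a₍ₙ₋₁₎;
* ρ = 4N₀r per locus: each lineage recombines at rate ρ × (breadth of its
  ancestral material), with breakpoints uniform on the unit interval;
* migration rates are 4N₀m (expected immigrant lineages per scaled time
  unit per lineage).

These identities are verified against both closed forms and an
independent coalescent implementation (msprime, test-only dependency) at
3-standard-error statistical tolerance.

## Sequence data model

Sequences are upper-case nucleotide strings over `ACGT` plus the missing
symbols `N`, `?` and `-` (all three are treated identically as missing).
FASTA headers may carry a population label (`name@2`) or an outgroup flag
(`name@#`); untagged records are ingroup population 0. Newick trees are
parsed by a recursive-descent parser that reports the character position
of a syntax error; writing then re-parsing a tree is a fixed point.

### Missing-data filter

Every per-site statistic works on the *retained* columns for a tolerance
`max_missing`: a column is retained when the fraction of missing ingroup
calls is ≤ `max_missing`. On a retained column the statistic uses the
`n_e` non-missing calls, e.g. per-site π = n_e/(n_e−1) · (1 − Σ p²).
Watterson's θ_W and Tajima's D constants use the full ingroup n: with no
missing data this is the classical estimator, and with missing data the
filter (not a per-site re-weighting) is the instrument, matching the
behaviour explored in the fixed-S detection experiment: at tolerance 0 a
single missing call hides a site; raising the tolerance recovers it.

### Polarised statistics

Fay & Wu's θ_H = Σ 2i²/(n_e(n_e−1)) sums over derived-allele counts
i < n_e at sites where the outgroup allele is present in the site's
observed alleles; fixed differences (i = n_e) are divergence, not
polymorphism, and are excluded, as are sites the outgroup cannot polarise.
H = π − θ_H is computed over the same polarisable sites.

### F-statistics

F<sub>ST</sub> uses the Weir–Cockerham variance-component estimator for
haploid data: per site and per allele, among-population (MSP) and
within-population (MSG) mean squares give a = (MSP − MSG)/n_c and b = MSG;
θ_WC = Σa / Σ(a+b) over sites and alleles. The panmictic null is centred
on 0 and complete differentiation gives exactly 1.

## Coalescent simulator

The simulator builds an ancestral recombination graph (ARG) by competing
exponentials: coalescence (per population), migration, recombination and
scheduled demographic events (size changes, exponential growth, migration
changes, population merges, instantaneous bottlenecks, selfing changes).
Each lineage carries its ancestral material as a sorted list of segments
of the unit interval; a segment is retired when only one carrier remains
(its local MRCA is reached), and the output is the sequence of marginal
trees with their supporting intervals. Under exponential growth the
waiting time is drawn by inverting the inhomogeneous rate integral in
closed form. A configuration from which coalescence is unreachable
(isolated populations with no migration or merge) raises an error rather
than looping.

### Partial selfing

Selfing at rate s gives inbreeding F = s/(2−s) and shrinks the effective
size by 1/(1+F). By default sampled gene copies are treated as coming
from distinct individuals, so selfing acts purely as this rate rescaling
— the mean-S ratio at s = 0.99 versus s = 0 is 1/(1+F) ≈ 0.505, which the
tests verify at 3 SE. An opt-in diploid mode (`diploid=True`) samples
pairs of copies within individuals and adds the instantaneous
within-individual coalescence (probability F) appropriate for that
design.

### Mutation models

* `infinite_site`: every mutation creates a new column (ancestral `A`,
  derived `T`), positioned uniformly; no homoplasy.
* `fixed_S`: exactly S mutations placed on branches with probability
  proportional to branch length — simulation conditioned on the observed
  number of polymorphic sites.
* `finite_allele`: a fixed number of sites, each evolving as a jump chain:
  mutation events occur at a state-independent Poisson rate (θ/n_sites per
  unit branch length) and the target state is drawn proportionally to the
  weight-matrix row of the current state. Long-run state frequencies
  therefore follow the stationary distribution of the row-normalised
  chain; the root state is drawn from it.
* `stepwise`: integer microsatellite alleles, ±1 per mutation event.

## Approximate Bayesian Computation

### Sampling

`abc_sample` streams a tab-separated table (one metadata line, a header,
one row of parameters + statistics per simulation); rows are written as
produced and nothing is accumulated, so arbitrarily large tables cost no
memory. Reproducibility is per-batch: the generator for each batch is
seeded from (seed, starting row). Values are written with 17 significant
digits so files re-read losslessly.

For the standard neutral model with SFS-derived statistics the sampler
uses a vectorised kernel that simulates unfolded site-frequency spectra
for thousands of parameter draws at once (exponential epoch times and
multinomial mutation placement in numpy), bypassing per-replicate tree
construction. The generic and vectorised routes are verified to produce
statistically indistinguishable S, π and D distributions.

### Fitting

`abc_fit` streams the table twice with bounded memory (line batches
parsed by numpy; a bounded heap holds the acceptance set):

1. estimate each used statistic's standard deviation (and drop rows with
   undefined statistics, logged);
2. compute standardised Euclidean distances to the observed vector and
   keep the closest ⌈tolerance·N⌉ rows, ties broken by row order.

`loclinear` then applies the local-linear regression adjustment: a
weighted least-squares regression of parameters on (statistics −
observed) over the accepted rows with Epanechnikov weights
w = 1 − (d/d_max)², shifting each accepted draw by its fitted statistic
effect. Parameters with bounded priors are adjusted on transformed scales
(log for positive scale parameters, logit for doubly bounded ones) and
back-transformed, which keeps adjusted draws inside their support. The
fit falls back to plain rejection when the accepted set is smaller than
the statistic count + 2 or the design is singular. On a noiseless linear
parameter–statistic relation the adjustment recovers the generating
parameter to machine precision; on calibrated pseudo-observed data the
central 95% adjusted posterior covers the truth at the nominal rate
(0.96 observed over 50 replicates in the acceptance script; ≥ 0.90
asserted over 100 replicates in the tests).

### Summary-statistic sets

* `SDZ`: mean S, mean Tajima's D and (with an outgroup) mean Fay & Wu's H
  across loci; per-locus undefined values (S = 0) are excluded from the
  averages.
* `SFS`: the site frequency spectrum pooled across loci in 8 equal-width
  bins, unfolded (derived-allele frequency) with an outgroup, folded
  (minor-allele frequency on (0, ½]) without; normalised to sum to 1.

## Numerical and engineering choices

* Distances, scales and regressions are double precision throughout;
  posterior files store 17 significant digits and round-trip to 1e-12.
* Every stochastic entry point accepts either a seed or a numpy
  `Generator`; identical seeds give byte-identical outputs.
* The command-line tool writes output atomically (temporary file +
  rename), logs to stderr, and uses exit codes 0 (success), 1 (usage
  error), 2 (data error).

## Limitations

* The coalescent is neutral: no selection, and no gene conversion; the
  recombination model is uniform crossover on a continuous locus.
* `finite_allele` sites evolve independently given the marginal tree at
  their position; rate heterogeneity among sites is not modelled.
* The vectorised ABC kernel covers the single-population constant-size
  model only; structured models run through the per-replicate simulator
  and are accordingly slower.
* The regression adjustment is linear and local; with very wide
  tolerances or strongly non-linear parameter–statistic maps the
  rejection posterior may be preferable (`adjust="rejection"`).
* The missing-data filter treats `N`, `?` and `-` identically; alignment
  gaps are not distinguished from unknown bases.
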