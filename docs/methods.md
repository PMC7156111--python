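# Methods

## The model

`gfgcoal` simulates coevolution between one haploid host species and one
haploid parasite species, each with a single bi-allelic functional locus,
under a gene-for-gene (GFG) interaction: the infective parasite allele
(`INF`) infects every host; the non-infective allele (`ninf`) infects only
susceptible (`res`) hosts, while resistant (`RES`) hosts block it.  The
within-season epidemiology is polycyclic with two parasite infection
cycles per discrete host generation and auto-infection (the second cycle
re-infects the host attacked in the first).

Fitness costs (all dimensionless, in `[0, 1)`):

| symbol | meaning | default role |
| --- | --- | --- |
| `s` | cost of infection; `s1 = s` if infected in cycle 1, `s2 = s/2` if only in cycle 2 | free parameter, priors `U(0.1, 0.9)` |
| `c_H` | cost of carrying `RES` | 0.05 (scenario 1) or `U(0.01, 0.35)` (scenario 2) |
| `c_P` | cost of carrying `INF` | 0.1 (scenario 1) or `U(0.01, 0.35)` (scenario 2) |

One deterministic host generation maps `(R, a1)` to `(R', a1')` through
three coupled recursions (second-cycle parasite frequency `a2`, next-season
parasite frequency, next-season host frequency).  Coevolutionary cycling
requires `s > c_H`; otherwise the susceptible host allele fixes
immediately and the dynamics are degenerate.

The internal equilibrium is, with `s1 = s`, `s2 = s/2`:

```
a_hat = [s2 + s1 − sqrt((s2 + s1)^2 − 4 s2 (s1 − c_H))] / (2 s2 (1 − c_H))
R_hat = c_P / (2 − c_P − a_hat)
```

These closed forms are approximations to the true fixed point (they drop
`O(c_P)` terms in the host equation); the package treats the identity
`R_hat (2 − c_P − a_hat) = c_P` as exact (it is, algebraically) and the
agreement with the iterated recursion as approximate: the truncation
error grows with `c_P` (within 0.05 at `c_P = 0.1`, up to ~0.09 at
`c_P = 0.3`), while the iteration itself matches the root-refined exact
fixed point of the recursion to numerical precision.  A widely
circulated alternative reading of the equilibrium, `R_hat =
c_P/(2 − c_P) − a_hat`, is algebraically inconsistent with the recursions
(it yields negative host frequencies throughout the trench-warfare regime)
and is not used.

Because cycles persist around the equilibrium, the numerical equilibrium
of a long run is summarised as the mean over the trailing 10% of
generations, never the final state (a pointwise value would alias cycle
phase).

## Forward simulation

Finite populations of fixed haploid sizes `N_H`, `N_P` evolve by, per host
generation: (1) the deterministic recursion (selection), (2) binomial
resampling of `N` individuals from the post-selection frequency (drift),
(3) recurrent functional mutation, drawn as binomial counts of switching
individuals at per-individual rates (`mu = 1e-5` per host generation for
all four directions by default) so the state stays integer-valued.  The
parasite is drifted and mutated once per host generation on the carried
state `a_{g+1,1}`; the second-cycle frequency is deterministic within the
generation.  The recorded *frequency path* entry is the post-drift,
post-mutation count at the start of each generation.

Runs last `g_max = max(3 N_H, 3 N_P)` generations from initial frequencies
`R0 = a0 = 0.2`, long enough for sweep and balancing signatures to
establish.  Replicate histories ("repetitions of the same coevolutionary
history") are fully independent paths at identical parameters, driven by
child RNG streams spawned from one master seed.

Dynamics classification: a history is *trench warfare* if both species
still segregate at the final generation; *arms race* if at least one
species is fixed/lost at the end and some derived allele reached fixation
during the history (recurrent sweeps); *degenerate* otherwise (alleles
lost without ever sweeping, e.g. `s < c_H`).  The "ever swept" clause is
this package's resolution of the boundary between arms race and
degeneracy; deterministic trajectories use fixation bands of `1/(2N)` so
matched deterministic/stochastic runs get the same label.

## Backward simulation (trajectory-conditioned coalescent)

For each species a sample of `n = 50` haplotypes is drawn at present;
hypergeometric sampling splits it between the two allelic classes
according to the final allele count.  Going backward one host generation
at a time, the two classes behave as two demes whose sizes are the
integer counts stored in the path:

1. *Migration*: a lineage in class `i` jumps to class `j` with probability
   `min(1, mu_{j->i} X_j(g−1) / X_i(g))` — the backward shadow of forward
   functional mutation.
2. *Allele origin*: if a class size hits 0 at `g−1`, its remaining
   lineages coalesce into the founding mutant, which migrates to the other
   class.
3. *Coalescence*: lineages pick uniform parents among the `X(g−1)` class
   members; identical picks merge (true Wright–Fisher mechanics, so
   simultaneous and multiple mergers occur, and bottlenecks force mergers
   with no special-casing).

Older than the path, all lineages join one panmictic class of size `N`
and coalesce as a discrete Kingman process; the implementation jumps
between events with geometric waiting times, which is exact because the
class size is constant there.  No continuous-time rescaling is used
anywhere: the process is exact for the discrete model at `O(g_max)` cost
per genealogy (~5–20 ms at the default sizes).

Neutral mutations are dropped on the genealogy under infinite sites:
`Poisson(b · L · mu_site)` per branch of length `b` generations, with
`L = 2500` bp and `mu_site = 1e-7` (`theta = 2 N L mu_site`, = 5 at
`N = 10,000`); positions are uniform on `[0, 1)` in the ms convention.
The result is a polarized haplotype-by-site 0/1 matrix.

The package's own validation shows the machinery behaves as theory
demands: conditioning on a monomorphic constant path is
KS-indistinguishable from an independent coalescent simulator; a path held
at frequency 0.5 for `4N` generations yields strongly positive Tajima's D
(balancing selection), a recent-sweep path strongly negative D.

## Summary statistics

Per species, eight statistics of the unfolded site frequency spectrum:
`S`, Watterson's `theta_W`, nucleotide diversity `pi`, Tajima's D, Fu &
Li's D and F (unfolded variant, derived singletons as the external-branch
class, with the corrected F variance), Fay & Wu's `theta_H`, and Zeng's
normalized `H'`.  Cross-species: the Pairwise Manhattan Distance,

```
PMD = sum_i | xi_H,i / S_H − xi_P,i / S_P |  in [0, 2],
```

computed on proportion-normalized spectra so it measures spectrum *shape*
divergence rather than doubling as another `theta` estimator, and stays
comparable when population sizes differ; a monomorphic species contributes
a zero vector (PMD = 1 against any polymorphic partner).  The
normalization choice is isolated in one function
(`pairwise_manhattan_distance`) so an alternative binning can be swapped
in.  Monomorphic samples set all statistics to 0, so replicate averages
are always over exactly `r` values (arms-race histories do produce `S = 0`
samples).  The ABC datapoint is the elementwise mean of the 17 statistics
over `r` replicate histories.

## ABC inference

Two scenarios: (1) infer `s, N_H, N_P` with costs known (`c_H = 0.05`,
`c_P = 0.1`; population sizes log-uniform on [2,000, 40,000]); (2) infer
`s, c_H, c_P` with sizes known (`N = 10,000`, `theta = 5`).  The neutral
model runs unconditioned discrete Kingman genealogies per species at the
same `n`, `L`, `mu_site` and the same replicate averaging; its scenario-1
rows draw the two population sizes from the same priors, its scenario-2
rows have no free parameters.  Reference-table rows for the coevolution
model are r-replicate averages exactly like the pseudo-observed data
(symmetry between table and observation).

*Model choice*: statistics are standardized by the per-column median
absolute deviation over the pooled two-model table (zero-MAD columns
dropped with a warning); the `ceil(0.01 · rows)` nearest rows in Euclidean
distance are retained and each model's posterior is its share.  Retention
is over the pooled table, so equal row counts per model encode equal prior
model probabilities.  Leave-one-out cross-validation classifies by the
larger posterior, breaking exact ties with a fair coin (a deterministic
tie rule measurably biases the confusion matrix), and reports the
false-negative rate (coevolving pairs called neutral) and false-positive
rate (neutral pairs called coevolving) in percent.

*Parameter estimation*: the `n_retain` coevolution rows nearest in
*unnormalized* Euclidean distance on the selected statistic columns (all
17, host 8, or parasite 8; PMD joins only the joint set) are retained; a
local-linear regression of each parameter on those statistics shifts the
retained values to the observed statistics; adjusted values are clamped to
the prior support, smoothed with a Gaussian kernel of width 0.01 on the
prior-range-normalized parameter scale, and summarised by the posterior
median.  The regression adjustment is an unweighted local-linear fit
(isolated behind one interface so a full GLM post-adjustment could be
substituted); constant columns are dropped, with pure rejection as the
last-resort fallback.

## Problem sizes and what the tests show

The published study rests on ~100,000 reference rows per model and
500 validation rows.  The packaged acceptance checks and the
`scripts/acceptance.py` report run the identical pipeline at a few hundred rows per model (400 in the
test suite, 300 in the acceptance script; r = 30), 250-300 validation
rows, `n_retain` of 120-150, and 45 + 24 PODs — sizes chosen so the whole suite completes on one CPU in
tens of minutes.  Two consequences are worth keeping in mind:

* With 1% retention, 400 + 400 rows retain only 8 neighbours, so the
  cross-validated FNR/FPR carry both binomial noise and a genuine
  small-table penalty: borderline datasets that a dense table would
  classify correctly become near coin flips.  Roughly 11% of scenario-2
  coevolution draws have `s < c_H` and are *irreducibly*
  neutral-indistinguishable (the susceptible allele fixes immediately);
  they bound the attainable FNR from below at any table size.  Measured
  rates at this scale are therefore well above the full-scale study's
  single-digit percentages, while preserving its structure: FPR is small,
  FNR degrades from r = 30 to r = 10, and errors concentrate where the
  dynamics genuinely mimic neutrality (high `s` arms races, `s ≈ c_H`).
* Parameter-recovery correlations are attenuated by the few-hundred-row table for
  the same reason; the qualitative ordering (joint > parasite-only >
  host-only for `s`; `c_P` recoverable from host but not parasite data)
  is robust at this scale.

The synthetic-data generator *is* the study design: no real sequence data
enters.  What passing tests demonstrate is internal consistency of the
forward–backward machinery and the inference layer under the model's own
assumptions — panmictic constant-size populations, one non-recombining
2.5 kb locus per species, perfect ancestral/derived polarization, no
population structure, no eco-evolutionary feedback on `N`.  Real data
violate several of these (misestimated polarization skews the unfolded
SFS; recombination and demography move all 17 statistics), so test
performance here does not certify field performance.

## Numerical choices

* Double precision throughout; recursion denominators below `1e-300` with
  a nonzero numerator raise a domain error (unreachable for costs `< 1`),
  while `0/0` corners (empty classes) evaluate to frequency 0.
* Initial counts are `round(N · f0)`; deterministic fixation bands are
  `1/(2N)`.
* Kernel-density posterior medians are read off a 2048-point CDF grid on
  the normalized support.
* Hot loops (forward path, conditioned genealogy) are numba-compiled;
  every kernel call is seeded from `numpy.random.SeedSequence` spawns, so
  all outputs are bit-reproducible from one master seed and replicates are
  independent by construction.
* Site-position collisions (probability ~`S^2 / 2^53`) are re-drawn to
  keep the infinite-sites contract exact.

## Known limitations

* Only the two-cycle auto-infection interaction is implemented; the
  within-generation parasite update is a single function
  (`gfgcoal._kernels.gfg_step`), which is the plug-in point for
  alternative epidemiologies (more parasite generations per season,
  allo-infection), but no such variant ships.
* No recombination within the locus and no haplotype/LD statistics.
* One backward step per *host* generation for both species; the parasite's
  two within-generation infection cycles are not resolved in the
  genealogy, matching the recorded path's resolution.
* The regression adjustment is local-linear, not the full ABC-GLM; at
  published retention sizes the posterior medians are insensitive to this,
  but the full GLM would differ in the posterior tails.
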