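# Methods

This note records the models the package implements, the conventions and
defaults it fixes where the underlying methods literature leaves choices
open, and what the synthetic-data generator does and does not emulate.

## Units and parameter conventions

All demographic quantities use the conventions standard in diffusion-based
joint-SFS inference:

| symbol | meaning | units / range |
| --- | --- | --- |
| `nu1, nu2, nu3` | deme sizes | relative to the ancestral reference N_ref (ancestral deme = 1) |
| `Ts` | parental split time | 2·N_ref generations |
| `Tam`, `Tsc` | duration of the ancient-migration / secondary-contact phase | same; constrained inside (0, Ts) |
| `Th` | hybrid-lineage origin time | same; constrained < Ts |
| `M12, M21, m13, …` | scaled migration, 2·N_ref·m, donor→recipient **forward** in time | ≥ 0 |
| `me12, me21` | migration for the restricted locus class | ≥ 0 |
| `P` | fraction of loci in the restricted class | [0, 1] |
| `O` | probability a site's ancestral/derived orientation is correct | [0, 1] |
| `f` | ancestry fraction from parent 1 at the hybrid origin | [0, 1] |
| `theta` | 4·N_ref·μ·L | profiled analytically, never optimized |

Backward in time, a lineage currently in the recipient deme jumps to the
donor at rate M/2 per unit time; pairs in a deme of size `nu` coalesce at
rate 1/`nu`.  With these dynamics the symmetric two-deme equilibrium has
Hudson-style Fst exactly 1/(1+2M), which the engine tests exploit.

## Model space

Two-population models: SI, IM, AM, SC; each with a growth variant (suffix
G) and, for the models with migration, two-locus-class variants (suffix
2m, plus 2mG).  AM places its migration window adjacent to the split
(duration `Tam`), i.e. gene flow during early divergence and none
afterwards; SC places it adjacent to the present (duration `Tsc`).  G
variants put an exponential size trajectory on the terminal epoch, from
the ancestral size (1) at the split to `nu_i` at present; this is a shape
flag, not an extra free parameter, so e.g. IM and IMG have the same k.
2m variants are a mixture of two locus classes with weights (1−P, P)
sharing every parameter except the migration rates, and additionally
estimate the orientation parameter `O`; the expected spectrum is mixed
as S' = O·S + (1−O)·reverse(S) after combining classes.  Free-parameter
counts follow from the lists above, e.g. IM2m: nu1, nu2, M12, M21, me12,
me21, Ts, P, O → k = 9; AM2m adds Tam → k = 10.

Three-population models (demes: parent 1, parent 2, hybrid): HS founds the
hybrid deme at `Th` by a punctual admixture pulse (each lineage reassigned
to parent 1 with probability `f`, else parent 2) with no later gene flow;
HSp1/HSp2/HS2p add migration between the hybrid and parent 1 / parent 2 /
both; SGF1/SGF2 split the hybrid from parent 1 / parent 2 at `Th` and allow
migration with both parents.  The parents do not exchange genes directly in
these models; the exact epoch structure of the published model variants is
not fully specified in the methods literature, so this parameterization is
fixed here and used consistently.

## Expected spectra by Monte-Carlo branch-length averaging

The expected JAFS per unit θ is estimated by simulating structured-
coalescent genealogies under the compiled schedule and crediting every
branch's length to the cell indexed by its descendant-leaf counts per
population (divided by two, so that a single constant-size population
yields the classical θ/i law).  Branch-length weighting uses each
genealogy fully and has far lower variance than Poisson mutation
sampling.  Growth epochs are discretized into 16 piecewise-constant
slices.  Replicates use independent seed-derived streams per (replicate,
locus class); with a fixed seed the result is bit-reproducible.

This engine replaces diffusion-PDE numerics: the package's claims are
statistical (Monte-Carlo agreement with closed forms and recovery of
generating parameters), not numerical identity with any particular solver.

## Fitting and model selection

The Poisson composite likelihood is evaluated over unmasked cells with the
analytically optimal θ; model cells below 1e−12 are clamped so likelihoods
stay finite at finite Monte-Carlo resolution.  Optimization works on
log-transformed positive parameters and logit-transformed fractions;
sub-times (`Tam`, `Tsc`, `Th`) are optimized as fractions of `Ts` so the
chronology constraints hold by construction.

Each restart fixes a simulation seed (common random numbers), making the
objective a deterministic but jagged function of the parameters.  Three
numerical choices matter on such a surface and were set after direct
experimentation:

* a small differential-evolution stage (population ≥ 16, coarse
  quarter-resolution objective) provides the global search — plain
  restarted Nelder–Mead reliably stalled far from the optimum;
* Nelder–Mead refinement runs with an explicit wide initial simplex
  (steps of 0.4 then 0.15 in transformed space): the default
  few-percent simplex is smaller than the Monte-Carlo jitter and the
  search stalls at its starting point otherwise;
* refinement is chained, ending at full Monte-Carlo resolution.

`fit_model_set` fits a model collection in order with nested warm starts
(each model initialized from the best fit so far, restricted to shared
parameter names), the usual practice when fitting nested SFS model
hierarchies.  The default protocol is 10 restarts per model; the test
suite and acceptance script use 1–3 restarts at reduced Monte-Carlo
resolution (problem sizes below).

AIC uses the composite likelihood directly (no small-sample correction),
ΔAIC < 10 defines retention, the model score is (Δmax − ΔAIC)/Δmax, and
Akaike weights are exp(−ΔAIC/2) normalized over the compared set.  If all
models tie (Δmax = 0) every score is defined as 1 and a warning is issued.

## Genotype filtering

Filters apply in a fixed order: (1) RAD-tag present (≥ 1 genotyped
individual) in at least 3 species; (2) locus genotyped in at least 40% of
all individuals (global, not per species; boundary inclusive); (3) minor
allele frequency ≥ 1% over all genotyped individuals (boundary inclusive);
(4) one SNP per tag, keeping the SNP with fewest missing calls, then the
first within-tag position (input order; the matrices carry no coordinates),
then the lexicographically smallest id.  Filtering is idempotent and the
per-rule drop counts sum to the total.

## Spectra

Projection to smaller sample sizes is the exact hypergeometric
expectation, applied independently per axis; per-site missing data are
absorbed by downsampling each site from its genotyped chromosomes.
Masked corners are zeroed before projection, so mass in masked cells never
re-enters the likelihood.  Folding collapses each cell onto its
minor-allele image with self-conjugate cells halved.  The default analysis
keeps unfolded ref/alt orientation and lets 2m-class models estimate the
misorientation parameter `O`; folded mode is the fallback when orientation
is meaningless.

## Hybrid index and interspecific heterozygosity

Per locus, each of an individual's two gene copies carries the alternate
allele with probability q(h) = (1−h)·pA + h·pB, so the genotype is
Binomial(2, q(h)); the MLE is located on a 1e−3 grid and refined by
bounded scalar optimization, reported at 1e−4 resolution, with a
2-log-likelihood-unit support interval (≈ 95%).  Markers need not be fixed
differences.  Interspecific heterozygosity is the mean posterior
probability that the two copies descend from different parental species,
with configuration prior ((1−h)², 2h(1−h), h²).  These closed-form
definitions are this package's own; numeric identity with other hybrid-
index software is not claimed.  Recent hybrids are flagged when *h* lies
in [0.2, 0.8] **and** heterozygosity exceeds the zone's background (90th
percentile of the individuals outside the window by default); both
thresholds are configurable because any such rule is a judgment call.
A zone summary reports the bimodality fraction (share of individuals with
h < 0.1 or h > 0.9) to separate bimodal zones (strong isolation, rare
recent hybrids) from unimodal long-standing hybrid zones.

## Fst and niche overlap

Nei-style Gst with unweighted group means and no sample-size correction,
aggregated as a ratio of sums over loci with Ht > 0 (the exact variant
behind published tables is rarely stated; this one is fixed and
documented).  Niche overlap standardizes five bioclimatic variables on the
pooled occurrences, projects onto the two leading principal axes, smooths
each species' occupancy with a Gaussian kernel (Scott's rule) on a shared
100×100 grid, and reports Schoener's D = 1 − ½Σ|z1 − z2|.  Densities are
smoothed in environment space only — no geographic background correction —
which is a simplification of the full niche-comparison framework.

## Synthetic data: what it does and does not emulate

`gen_species_complex` simulates one genealogy per locus (a pure-Python
structured coalescent that tracks leaf identity, independent of the
branch-length engine) and places at most one infinite-sites mutation per
locus proportionally to branch length; with `theta_locus` set, loci
segregate with probability 1 − exp(−θT/2) and monomorphic loci appear.
Diploids pair consecutive haplotypes; missingness is injected uniformly at
random.  The default four-taxon design uses two parentals diverging with
heterogeneous gene flow (M = 2, me = 0.2, P = 0.3, Ts = 2), a hybrid
lineage founded at Th = 0.5 with f = 0.5, and a daughter split at 0.15 —
1,000 loci and 15 diploids per taxon, mirroring a ddRAD study design at
desk scale.  `gen_contact_zone` builds individuals by explicit gamete
formation (true h per class: pure 0/1, F1 and F2 0.5, backcrosses
0.25/0.75) with unlinked loci.  `gen_occurrences` draws Gaussian niches in
the 5-variable climate space.

Not emulated: linkage and recombination within or between loci, non-random
missingness (real RAD dropout is allele- and depth-biased), sequencing
error, selection, and more than four demes.  Passing tests therefore
demonstrate correctness of the estimators under the stated models, not
robustness to these real-data complications.

## Problem sizes used by the tests and the acceptance script

Engine checks: n = 20 haploids, 50,000 genealogies (θ/i and island-model
Fst).  Parameter recovery: 2,000-SNP Poisson spectra at 20/20 haploids
(generated from 30,000-genealogy expected spectra), 2 restarts at 8,000
(SI) and 20,000 (IM) genealogies per likelihood evaluation — the IM
scenario has a shallow split-time/migration ridge that only resolves at
the higher Monte-Carlo resolution.  Model
recovery: 10 replicate 2,000-SNP spectra at 14/14 haploids generated under
a clear secondary-contact history (Ts = 2, Tsc = 0.2, M = 5), fitted with
{SI: 1, IM: 1, AM: 1, SC: 2} restarts at 2,000 genealogies per evaluation.
Contact zones: 200–500 diagnostic loci.  These sizes were chosen once as
desk-scale settings that keep the full suite runnable on a single CPU.

## Known limitations

* Composite-likelihood AICs are valid for ranking, not absolute inference;
  no parameter uncertainties (bootstrap/Godambe) are provided.
* Monte-Carlo noise in the objective limits achievable precision of MLEs;
  tolerances in the tests (20% parameter recovery) reflect that.
* The orientation model for `O` (convex mixture with the reversed
  spectrum) is one reasonable reading of misorientation; alternatives
  (e.g. outgroup-calibrated polarization) are out of scope.
* Two-deme and three-deme inference only; the four-taxon generator exists
  to produce data, not to be fitted directly.
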