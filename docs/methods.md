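# Methods

## Model

Sequences evolve under the Tamura–Nei (TN93) substitution model: stationary
base frequencies π = (π_A, π_C, π_G, π_T), distinct exchange rates for the
two transitions (A↔G, C↔T) and a shared transversion rate.  Rates across
sites follow a discrete Gamma: Gamma(α, α) (mean 1) cut into n equal-
probability categories (default n = 5), each represented by its band-
conditional mean, so the category rates average exactly 1.  The generator
is normalised so branch lengths are expected substitutions per site at
stationarity.  Transition matrices come from the symmetric
eigendecomposition of the reversible generator (D^{1/2} Q D^{−1/2} with
D = diag π), which for a 4×4 reversible matrix is exact and stable; all
edges and categories are exponentiated in one batched call.  A numba-
compiled pruning kernel evaluates the likelihood over compressed site
patterns; a pure-numpy path gives identical values (to ~1e-12) and serves
as the fallback and the basis for ancestral-state reconstruction.

Invariant-sites mixtures, codon models, partitioned models and relaxed
clocks are out of scope.

## Fitting

Two nested models are fitted per topology:

* **no clock** — one free length per edge (2n−3 parameters);
* **strict clock** — rooted, ultrametric, one height per internal node
  (n−1 parameters), all tips treated as contemporaneous.  Sample ages of a
  century or two are negligible against split depths of tens of kiloyears
  and are ignored.

Base frequencies are empirical (counted from the alignment, ambiguity
codes fractionally, one pseudocount).  The remaining free parameters —
log branch lengths, or log root height plus a (0,1) depth fraction
h_node/h_parent per non-root internal node, optionally log exchange rates
and log α — are optimised jointly by L-BFGS-B.  The fraction
parameterisation turns the ultrametric ordering constraints into box
bounds, which removed the slow zigzag that alternating height/model
coordinate ascent exhibited.  Convergence tolerance is Δℓ ≈ 1e-6 by
default; the simulation experiments loosen it to 1e-4 (documented below)
since RELL weighting and dating are insensitive at that scale.

Initial heights are UPGMA-style (half the mean cross-clade Jukes–Cantor
distance); initial terminal branch lengths come from half the smallest
pairwise distance involving that taxon.

**Gamma-shape identifiability.** On a single ~5–15 kb alignment whose only
deep divergence is the outgroup edge, the unconstrained ML of α
occasionally collapses to the lower bound (α ≈ 0.02) with compensating
rate/branch-length inflation — a saturation-driven ridge in the
likelihood.  Under the strict-clock constraint this pathology essentially
disappears, because heights cannot inflate freely.  The simulation
experiments therefore estimate the substitution model once per dataset by
a strict-clock fit and share it across candidate topologies; the pipeline
default remains full re-optimisation per topology.

## Clock test

statistic = 2(ℓ_free − ℓ_clock), df = n − 2 (2n−3 branch lengths versus
n−1 heights), p from the upper χ² tail.  The worked example with the
published log-likelihood pair (−29341.106115, −29345.873227; 7 taxa) gives
statistic 9.534, df 5, p = 0.090.  Under clock-true simulations with the
substitution model held at its generating values the p-values are
uniform (KS check in the acceptance suite); estimating the model in both
fits adds a small conservative distortion at these sample sizes.

## Root-height uncertainty

The SE of the ML root height is (−d²ℓ_profile/dh²)^{−1/2}: the root height
is displaced ±5% around its ML value, all other heights re-optimised
(model fixed), and the curvature taken by central second difference.  The
centre point is re-evaluated with the same re-optimisation so that minor
non-convergence of the original fit cannot produce a spuriously convex
profile; if the curvature is still non-negative the step widens (×3, twice)
before erroring.  Replicate simulations show the reported SE within ~30%
of the empirical scatter of the estimator.

## Topology enumeration and weighting

All (2n−5)!! unrooted binary topologies (n ≤ 10) are generated by stepwise
addition, deduplicated and ordered by a canonical min-lexicographic key,
optionally filtered to contain a required clade.  Outgroup-rooting happens
only at the dating step; topologies in which the outgroup is not
monophyletic are excluded there (and only there).

bp-RELL: per-site log-likelihoods of every fitted topology are bootstrap
resampled (multinomial over sites); a topology's weight is the fraction of
replicates in which it attains the highest resampled total, exact ties
split equally.  Sites with identical log-likelihood profiles across all
topologies are exchangeable and are collapsed before resampling, which
makes 10,000 replicates essentially free.  Default n_bootstrap = 10,000
(~0.5% Monte-Carlo error near a weight of 0.9); the generator is a
counter-based Philox stream, so a fixed seed reproduces weights
bit-identically across platforms.  These weights are bootstrap
proportions, not Bayesian posteriors, although they are used as
posterior-like mixture weights downstream.

## Calibrated dating

The calibration (point, 95% CI) is fitted with a skew-normal whose
(2.5, 50, 97.5)% quantiles match the inputs by least squares; the
asymmetric CI of the felid calibration (4.92 My, 3.86–6.92) yields a
right-skewed density (shape ≈ 4.4) reproducing the quantiles to < 0.1%.
Root-height uncertainty is Normal(ĥ, se).  On a default 400×400 grid —
h over ĥ ± 5 se (floored at a small positive value), d over the
calibration's 0.001–0.999 quantiles — the density product weights the
implied rate μ = h/d; weighted rates are binned into 2000 log-spaced bins.
Node ages follow as h_node/μ over the rate masses.  Grid quantiles agree
with 10⁶-draw Monte-Carlo sampling to ≲0.1% at the 2.5/50/97.5% points,
comfortably inside the 1% the tests demand.

Non-root node heights enter as fixed ML values: only root-height and
calibration uncertainty are propagated.  This mirrors the construction
whose outputs the package reports; its known consequence is that nominal
95% intervals ignore the sampling noise of shallow node heights (a ~70 ky
node in 15 kb of mtDNA carries only ~10 substitutions of signal), so
empirical coverage runs a few points below nominal — see Validation.

Per-clade dates are reported for the best topology and as the top-K
(default 10) RELL-weighted mixture, with 2.5/50/97.5% quantiles; discrete
quantiles use the classic inverse-CDF convention (smallest grid value with
CDF ≥ q).  An HPD extractor is provided alongside equal-tail intervals;
equal-tail is the default since that is how the calibration itself is
specified.  Reports round to 0.1 ky.  For a queried clade that is not
monophyletic in some topology, that topology contributes the date of the
MRCA of the clade's taxa — necessarily a deeper node.

## numt screen

A window (default 1000 bp, step 100, or step = window for tiling) slides
along a pre-aligned query/reference pair; the mismatch rate counts only
positions where both sequences have unambiguous bases, and windows with
fewer than 200 called positions are masked.  Candidate chimeric intervals
merge consecutive windows exceeding fold × background (default fold 4).
Coordinates are 0-based half-open (BED-compatible).  Alignment of the pair
is the caller's responsibility.

## Synthetic data

The generator evolves sites independently down a rooted time tree
(site-wise forward simulation with per-category transition matrices — the
exact model the likelihood assumes), scaled by a clock rate in
substitutions/site/year.  The default 7-taxon scenario emulates the felid
mtDNA study system:

| parameter | value | note |
|---|---|---|
| root (outgroup vs ingroup) | 4.92 My | the calibration node |
| within-outgroup split | 4.17 My | puma–jaguarundi-like |
| ingroup crown | 138.9 ky | NE-Africa vs rest |
| India vs SE-Africa | 72.2 ky | the focal split |
| within-SE pair | 20 ky; NE pair 60 ky | shallow diversity |
| clock rate | 1.1e-8 subs/site/yr | gives ~6 variants/3.7 kb at the focal depth |
| model | π=(0.32,0.27,0.14,0.27), AG=20, CT=40, α=0.25, 5 cat | felid mtDNA-like |
| length | 15,000 | coding-region scale |

One taxon ("India1") carries contiguous missing-data masks leaving exactly
3675 called sites, emulating a degraded historical specimen; a second
taxon is half-masked.  What the simulator does not emulate: indels,
sequencing error, post-mortem damage, within-site rate autocorrelation,
recombination-free-but-linked nuclear contamination.  Passing recovery
tests therefore validates the inference chain under its own model
assumptions, not robustness to real-data artefacts.  A chimera helper
mutates a chosen segment at a given per-base divergence and records the
realised count, providing ground truth for the numt screen.

## Validation experiments

* **Clock-test null** (200 replicates, 1.5 kb, model fixed at truth):
  p-values uniform by KS test.
* **End-to-end coverage** (100 replicates, 15 kb): per replicate the
  candidate set is the 15 topologies preserving the outgroup and NE-pair
  cherries — a scaled stand-in for the full enumeration that keeps free
  exactly the axis the analysis has to resolve: where the India-like
  lineage attaches, including inside the SE-African pair.  Candidates are
  weighted by bp-RELL and dated as a top-10 mixture.  The 95% interval
  covers the true 72.2 ky split in ≈ 90-95% of replicates.  Residual
  misses have an understood source: shallow-node sampling noise is not
  propagated (by construction, above), so a replicate whose node-height
  draw lands far from its expectation can carry the whole interval past
  the true value.  An earlier design that also froze the SE pair as a
  cherry under-covered (~84%), because it excluded the India-inside-SE
  arrangements whose shallow clade MRCAs supply the mixture's lower tail.
* Problem sizes (1.5–15 kb, 15-topology candidate set, 100–200 replicates)
  were chosen to keep the full suite runnable on a single core in well
  under half an hour while leaving Monte-Carlo error small relative to the
  margins being tested.

## Numerical choices and edge cases

* Branch lengths bounded to [1e-9, 10] subs/site; height fractions to
  [1e-6, 1−1e-6]; α to [0.02, 50]; exchange rates to e^{±[−6.9, 6.9]}.
* Likelihood scaling rescales partials per pattern when the maximum drops
  below 1e-80 (irrelevant for ≤10 taxa, kept for safety).
* MAP ancestral states break ties alphabetically (A < C < G < T).
* Degenerate distributions (point masses, zero node heights) are handled
  explicitly; duplicate grid points merge their mass.
* All stochastic components (simulator, RELL) use numpy's Philox
  counter-based generator; seeds are taken mod 2³¹.

## Known limitations

* Strict clock only; heterochronous tips are not modelled.
* The topology-averaged intervals understate total uncertainty (no
  shallow-node height error, no model-parameter error).
* ML estimation of α on single small alignments is fragile without the
  clock constraint; the pipeline exposes both choices.
* Enumeration is exhaustive by design and impractical beyond ~10 taxa.
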