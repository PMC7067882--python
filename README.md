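# mtclock

Calibrated molecular-clock divergence dating for small mitochondrial DNA
alignments.

`mtclock` is built for the situation where a handful of full mtDNA coding
regions (≤ ~10 taxa, typically 3–17 kb) must be dated against a single
external calibration — for example, placing historical museum specimens of
an endangered felid against reference mitogenomes, calibrated by the
puma–cheetah split.  At that scale heuristic tree search is unnecessary:
every possible topology can be enumerated and weighted, and the dominant
uncertainties (tree depth, fossil calibration, topology) can be propagated
into divergence-date distributions explicitly.

## What it computes

For an alignment with taxa ${1..n}$ and an outgroup calibration date
$T_{\mathrm{cal}}$ with asymmetric CI:

1. **Model & likelihood.** TN93 substitution model with 5-category
   discrete-Gamma rate heterogeneity (α, π, two transition rates, shared
   transversion rate); Felsenstein pruning over compressed site patterns;
   missing data and IUPAC ambiguity codes enter as partial likelihoods.
2. **Clock test.** ML fits without a clock ($2n-3$ branch lengths) and
   under a strict clock ($n-1$ node heights); the LRT statistic
   $2(\ell_{\mathrm{free}} - \ell_{\mathrm{clock}})$ is referred to
   $\chi^2_{n-2}$.
3. **Topology weighting.** All $(2n-5)!!$ unrooted topologies are
   enumerated (optionally under a clade constraint), fitted, and weighted
   by bp-RELL: bootstrap resampling of per-site log-likelihoods, weight =
   fraction of replicates a topology wins.
4. **Calibrated dating.** A skew-normal density is fitted to
   $T_{\mathrm{cal}}$'s (2.5, 50, 97.5)% quantiles; the ML root height
   $\hat h$ (substitutions/site) carries a profile-likelihood standard
   error.  On a grid over (root height $h$, calibration date $d$) the
   product Normal$(h;\hat h, \mathrm{se})\cdot$SkewNormal$(d)$ weights the
   implied clock rate $\mu = h/d$, giving a mutation-rate distribution;
   node heights convert to age distributions via $t = h_{\mathrm{node}}/\mu$,
   and per-topology age distributions mix by RELL weight.
5. **numt screen.** A sliding-window (default 1000 bp) mismatch profile of
   a query against a trusted reference flags diverged segments typical of
   chimeric nuclear-mitochondrial (numt) assemblies; windows with < 200
   called bp are masked.

A seeded simulator (`mtclock.simulate`) generates 7-taxon cheetah-like
alignments — outgroup pair splitting at 4.92 My, shallow ingroup splits at
~139/72/20 ky, historical-specimen missing-data masks — so the whole chain
is testable without any downloads.

## Worked example

```python
from mtclock import clock_lrt, offset_lognormal_quantiles

stat, df, p = clock_lrt(-29341.106115, -29345.873227, n_taxa=7)
print(f"LRT statistic {stat:.3f}, df {df}, p = {p:.3f}")

lo, med, hi = offset_lognormal_quantiles(0.82, 0.33, 2.65)
print(f"root prior: median {med:.3f} My  (95% {lo:.2f}-{hi:.2f} My)")
```

```
LRT statistic 9.534, df 5, p = 0.090
root prior: median 4.920 My  (95% 3.84-6.99 My)
```

The clock test cannot reject rate homogeneity (p = 0.09 > 0.05), so a
strict clock is a defensible basis for dating; the offset-lognormal line
shows how a Bayesian root-calibration prior with median 4.92 My is
assembled.

An end-to-end run on simulated data:

```bash
mtclock simulate --seed 7 --length 15000          # writes cheetah_sim.fasta
mtclock run --config config.yaml                  # enumerate/fit/RELL/date
```

with `config.yaml`:

```yaml
alignment: cheetah_sim.fasta
outgroup: [Puma, Jaguarundi]
constraint: [Puma, Jaguarundi]
calibration: {point: 4.92e6, ci_low: 3.86e6, ci_high: 6.92e6}
clades:
  india_se: [India1, SEAfr1, SEAfr2]
seed: 7
```

The report lists, per queried clade, the best-topology date with its 95%
interval and the topology-averaged date mixing the top-10 topologies by
RELL weight, in years (TSV/JSON, plus the full age distributions).

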