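# Methods

## The empty-piece probability curve and the uniformity exponent

The unit of observation is a resin piece with mass `m` (recorded to
0.01 g) and an arthropod inclusion count. The statistic of interest is
the conditional probability `P(empty | m)` that a piece of mass `m`
contains no inclusions. It is estimated by binning masses, computing the
mass distribution of empty pieces `f(m | empty)`, the overall mass
distribution `f(m)`, and the marginal `P(empty)`, and applying Bayes'
theorem per bin. Algebraically this reduces to the direct frequency
`n_empty / n_total` in each bin, and the implementation is tested for
that identity; the Bayes route is kept because it makes explicit which
two distributions are being compared.

A power law `P(empty|m) = a·m^b` is then fitted by ordinary least
squares on `log P` vs `log m`. The slope `b` (negative for decreasing
curves) is the **uniformity exponent**:

* `b = 0` — inclusions concentrated: a piece's mass carries no
  information about whether it is empty.
* `b` strongly negative — uniform trapping. The exact uniform (Poisson)
  model gives `P(empty|m) = exp(−λ m^β)`, which is steeper than any
  power law, so an ever-more-uniform process drives the fitted `|b|`
  upward without bound.

`analytic_empty_prob` exposes the Poisson closed form as an oracle.

### Binning choices

* Default: linear bins of width 0.01 g, **centred on the recording
  grid** — a recorded mass `m` stands for the interval
  `[m − 0.005, m + 0.005)`, so grid values are exact bin midpoints and
  exact-power-law inputs are recovered to machine precision.
* Logarithmic binning (`log_bins=N`, geometric-midpoint abscissa) is
  recommended below ~10³ pieces, where 0.01 g bins are mostly
  singletons; the choice is recorded in the fit's settings.
* Bins with `P(empty|m) = 0` cannot enter a log fit and are dropped,
  never pseudo-counted — pseudo-counts would bias the slope. Their
  number is recorded.
* A fit needs ≥ 3 usable bins; a collection with no inclusions at all
  has no defined uniformity and raises.
* `min_mass_g` discards pieces below a cutoff before binning. This
  mirrors field practice: collectors under-sample tiny fragments, which
  bends the small-mass end of the curve, and a 0.5 g cutoff is the
  documented choice for intensely-trapping collections whose smallest
  pieces dominate the sample.
* The OLS slope standard error is reported by default; because binned
  points are not independent, a piece-level bootstrap (resample pieces,
  re-bin, re-fit; seeded) is available and preferred for inference.

The sign convention is fixed by the uniformity reading: `b` is the OLS
slope itself, so decreasing curves give negative values.

## Accumulation power laws

Locality totals `(m, N)` are fitted with `N = c·m^β`, `β ∈ [2/3, 1]`.
The lower bound corresponds to trapping proportional to a lump's surface
(`area ∝ m^(2/3)`), the upper to its volume; we document this reading as
the package's interpretation of the bounds. Fitting is OLS in log-log
space with clip-and-refit: if the unconstrained slope leaves the box,
`β` is fixed at the violated bound and only `log c` refitted (the
profile optimum of the separable least-squares problem, confirmed
against a brute-force grid search in the tests). Zero-count localities
are dropped from the log fit (and counted); an alternative Poisson-GLM
mode (log link, same clamp rule, closed-form `c = ΣN / Σm^β` at a fixed
bound) keeps zeros in the likelihood for sparse synthetic data.
`se_β` is a case-resampling bootstrap (default 1000 replicates, seeded),
which respects the constraint; bands at one bootstrap SD correspond to
68% coverage. The packaged 27-locality table pools conifer-derived
sources (Agathis, Agathis-like, Cheirolepidiaceae — chemically similar
resins) against Hymenaea. Localities whose published mass is a range are
stored with both bounds and fitted at the midpoint; "ca." masses carry
an approximate flag but are included by default.

## Composition analyses

Counts are converted to profiles with a 0.5 pseudocount per cell
(Jeffreys-style; configurable, 0 allowed for textbook checks) so absent
taxa never zero the Bhattacharyya coefficient. `D = −ln BC` with
`BC = Σ√(pᵢqᵢ)` clipped to `(0, 1]`; `BC = 0` (possible only at
pseudocount 0) maps to a finite cap (default 50) so ordination stays
finite. The distance is symmetric and zero iff profiles match but does
not satisfy the triangle inequality; classical MDS absorbs this by
truncating negative eigenvalues and reporting their total magnitude.

MDS is the classical/metric (Torgerson) algorithm — double-centre
`−½ J D² J`, eigendecompose, scale eigenvectors by `√λ` — because
per-axis "variance explained" is defined by eigenvalues; per-axis
variance is `λᵢ / Σ(positive λ)`. (A reference PCoA implementation
normalises by the sum of *all* eigenvalues; coordinates agree exactly,
only the normalisation differs, and the package's convention keeps the
proportions in `[0, 1]`.)

Clustering operates on samples under `1 − Spearman ρ` (average ranks on
ties) with complete linkage, delegated to scipy's agglomerative
implementation; heights are monotone by construction and dendrograms
export to Newick. The flying/non-flying contrast aggregates counts by a
taxon→{flying, non_flying, excluded} map (default: winged insect orders
flying; Collembola, Zygentoma and Formicidae non-flying; non-insect
arthropods excluded) and applies Pearson's chi-square without continuity
correction, with standardized residuals `(O−E)/√E`; a seeded
permutation p-value is available for small expected counts.

## The synthetic generator

`simulate_pieces` draws lognormal masses (default log-mean 0, log-sd 1:
a heavy-tailed lump-size distribution centred on 1 g, matching the
orders-of-magnitude spread seen in field collections), floors and rounds
them to the 0.01 g grid, and assigns counts under four models sharing
mean `λ·m^β`:

* `poisson` — uniform trapping (the exponential empty-curve limit);
* `negative_binomial` — Poisson-gamma mixture with dispersion `k`; the
  canonical continuous knob from clustered (`k → 0`) to uniform
  (`k → ∞`);
* `episodic` — with probability `p` a piece was exuded during the
  sticky window and traps Poisson counts, otherwise nothing; realizes
  the fast-drying narrative directly;
* `concentrated` — the same expected total, all in one uniformly chosen
  piece (`b = 0` limit).

Default intensity `λ = 1 g⁻¹` gives roughly one inclusion per gram,
between the sparse (~0.02 g⁻¹) and rich (~2 g⁻¹) field densities in the
locality table. Episodic `p` and dispersion `k` defaults are chosen for
testability of the regime contrast, not inferred from field data. All
draws come from one seeded generator per call; identical configs give
byte-identical CSV output. `simulate_taxon_counts` draws one multinomial
row per sample from its trap type's profile.

What the simulator does *not* emulate: taxon-specific attraction or
repulsion to resin chemistry, within-lump spatial structure, resin flow
or re-exudation over a lump, collection bias against small pieces
(users model it via `min_mass_g`), and temporal autocorrelation between
neighbouring trees. Passing tests therefore show the estimators recover
the statistical regimes they target, not that field collections satisfy
those regimes.

## Numerical and design notes

* Mass rounding is half-up on the value the parsed double actually
  holds (so `"1.005"`, stored as 1.00499…, rounds to 1.00); masses are
  exact multiples of 0.01 after ingest.
* Problem sizes in the default test run — 10⁴ pieces for the Poisson
  limit, 5·10³ per sweep point, 100 replicates for separation and
  constraint sweeps — are chosen so each property check resolves its
  effect at 3-sigma while the full suite stays interactive.
* Degenerate inputs: all-identical masses make the log-log design
  singular (raised as such); an all-empty or all-occupied collection
  has no fittable curve; a constant taxon row has undefined Spearman
  rank correlation (raised).
* Tie-breaks in clustering follow scipy's deterministic nearest-pair
  ordering; merge heights at equal distances are stable across runs.
* Floats in reports are serialized at 12 significant digits; re-running
  a report from its echoed settings reproduces every number exactly.

## Known limitations

* The uniformity exponent of a *binned* finite sample depends on the
  binning; exponents from differently-binned analyses are comparable
  only qualitatively. The package records all binning settings in the
  fit for that reason.
* The locality-table fits treat each locality as one point; within-
  locality piece structure (which the uniformity analysis uses) is not
  propagated into the accumulation bootstrap.
* Bhattacharyya-distance MDS of few samples with many rare taxa is
  pseudocount-sensitive; report the pseudocount alongside coordinates.
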