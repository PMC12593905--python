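# resintrap

Quantitative taphonomy of arthropod entrapment in tree resins.

Fossil resin (amber) preserves arthropods, but different resin-producing
trees trap very differently: slow-drying, long-sticky resins (e.g.
*Hymenaea*, the source of most Miocene ambers) accumulate abundant,
spatially uniform inclusions, while fast-drying conifer resins (e.g.
*Agathis* and its Cretaceous relatives) trap few arthropods, concentrated
in a handful of lumps. Whether an amber assemblage reflects the living
forest community therefore depends on which trapping regime produced it.
`resintrap` packages the statistics needed to quantify that bias from
piece-level collections, locality totals, and trap-comparison surveys,
for palaeoecologists and actuotaphonomists.

## What it computes

**Uniformity exponent `b`.** For a collection of resin pieces with
measured masses (0.01 g resolution) and inclusion counts, the package
estimates the probability that a piece is empty given its mass,
`P(empty | m)`, by Bayes inversion of binned mass frequencies
(`P(empty|m) = f(m|empty) P(empty) / f(m)`, which per bin reduces to
`n_empty / n_total`), then fits `log P = log a + b log m` by ordinary
least squares. `b ≈ 0` means inclusions concentrated in few pieces;
strongly negative `b` means uniform trapping, whose Poisson limit
`P(empty|m) = exp(−λ m^β)` decays faster than any power law.

**Accumulation power laws.** Locality totals (mass, inclusion count) are
fitted with `N = c·m^β`, β box-constrained to `[2/3, 1]`
(surface- vs volume-proportional trapping); the prefactor `c` measures
trapping efficiency. A 27-locality summary table of published
amber/copal/Defaunation-resin collections ships as a packaged fixture.

**Assemblage composition.** Samples-by-taxa count matrices are compared
with the Bhattacharyya distance `D = −ln Σᵢ √(pᵢqᵢ)` and ordinated by
classical (Torgerson) MDS with per-axis variance explained from the
eigenvalues; samples are clustered under `1 − Spearman ρ` with complete
linkage (Newick export); a Pearson chi-square contrasts flying vs
non-flying insect counts across trap types.

**Synthetic trapping regimes.** A seeded simulator draws lognormal piece
masses and inclusion counts under Poisson (uniform), negative-binomial
(overdispersed), episodic "sticky-window" (clustered), and fully
concentrated models — the regimes the exponent `b` is designed to
separate — plus multinomial taxon profiles per trap type.

## Worked example

```sh
python examples/uniformity_exponent.py
```

```
uniform (slow-drying)    b = -1.100 +/- 0.127  (r^2 = 0.799, 8 bins, 16406 inclusions in 5000 pieces)
episodic (fast-drying)   b = -0.010 +/- 0.019  (r^2 = 0.093, 12 bins, 16239 inclusions in 5000 pieces)
```

Both simulations trap about the same number of arthropods, but the
uniform regime spreads them across pieces — large pieces are almost
never empty, so `P(empty|m)` falls steeply (`b = −1.10`) — while the
sticky-window regime leaves the curve flat (`b = −0.01`): mass tells you
almost nothing about whether a piece is empty when inclusions are
clustered. The other examples fit the packaged locality table
(`accumulation_fits.py`: the *Hymenaea* curve predicts ~353 inclusions
per 1000 g against ~17 for the conifer group), ordinate simulated trap
assemblages (`assemblage_composition.py`), and sweep the sticky-window
fraction (`trapping_regime_sweep.py`).

A thin CLI mirrors the library: `resintrap {table1, uniformity,
accumulation, mds, cluster, flying, simulate, run}`.

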