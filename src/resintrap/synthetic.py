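"""Synthetic resin-trapping and assemblage generators.

The piece simulator realizes the statistical regimes the uniformity
exponent is designed to separate:

* ``poisson`` — spatially uniform trapping: each piece of mass m traps
  N ~ Poisson(lambda * m^beta) arthropods independently. The empty-piece
  probability is then exactly exp(-lambda * m^beta), an exponential
  decay (the "effectively infinite exponent" limit).
* ``negative_binomial`` — overdispersed trapping with the same mean and
  dispersion k; k -> infinity recovers Poisson, small k clusters
  inclusions into few pieces.
* ``episodic`` — the sticky-window regime of a fast-drying resin: only
  a fraction p of pieces were exuded while still able to trap, so with
  probability p a piece traps Poisson(lambda * m^beta) and otherwise
  traps nothing. Small p concentrates inclusions and drives b toward 0.
* ``concentrated`` — the degenerate limit: the whole assemblage's
  inclusions land in one uniformly chosen piece (exponent b = 0).

Piece masses are lognormal, floored and rounded to the 0.01 g recording
grid. The mass-scaling exponent beta in [2/3, 1] spans surface- versus
volume-proportional trapping.

The composition simulator draws multinomial taxon profiles per trap
type (resin, yellow sticky trap, Malaise trap), the structure the
distance/ordination analyses assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import MASS_RESOLUTION_G, PieceCollection, ResinPiece, TaxonCountMatrix, round_mass
from .uniformity import InsufficientDataError, uniformity_exponent

TRAP_MODELS = ("poisson", "negative_binomial", "episodic", "concentrated")


@dataclass
class TrapSimConfig:
    """Configuration of one simulated piece collection.

    Defaults give a medium-sized Defaunation-resin collection: 1000
    pieces with lognormal masses centred on 1 g (log-sd 1, so masses
    span roughly 0.05-20 g) and about one inclusion per gram under
    volume-proportional uniform trapping.
    """

    n_pieces: int = 1000
    mass_log_mean: float = 0.0
    mass_log_sd: float = 1.0
    lambda_per_g: float = 1.0
    beta: float = 1.0
    model: str = "poisson"
    dispersion_k: float | None = None  # negative_binomial only
    sticky_fraction_p: float | None = None  # episodic only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in TRAP_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not (2.0 / 3.0 - 1e-12 <= self.beta <= 1.0 + 1e-12):
            raise ValueError("beta must lie in [2/3, 1]")
        if self.lambda_per_g < 0:
            raise ValueError("lambda_per_g must be non-negative")
        if self.model == "negative_binomial" and not (self.dispersion_k and self.dispersion_k > 0):
            raise ValueError("negative_binomial model requires dispersion_k > 0")
        if self.model == "episodic" and not (
            self.sticky_fraction_p and 0 < self.sticky_fraction_p <= 1
        ):
            raise ValueError("episodic model requires sticky_fraction_p in (0, 1]")


@dataclass
class CompositionSimConfig:
    """Multinomial assemblage simulator: one taxon profile per trap type,
    ``n_samples`` replicate samples per type with ``total`` counts each."""

    taxon_ids: list[str]
    profiles: dict[str, np.ndarray]  # trap type -> probability vector over taxa
    totals: dict[str, int]
    n_samples: dict[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in self.profiles.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (len(self.taxon_ids),):
                raise ValueError(f"profile {name!r} length does not match taxon list")
            if not np.isclose(p.sum(), 1.0):
                raise ValueError(f"profile {name!r} does not sum to 1")
            self.profiles[name] = p


def simulate_pieces(config: TrapSimConfig) -> PieceCollection:
    """Draw a piece collection under the configured trapping model.

    Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    masses = rng.lognormal(config.mass_log_mean, config.mass_log_sd, size=config.n_pieces)
    masses = np.maximum(masses, MASS_RESOLUTION_G)
    masses = np.array([round_mass(m) for m in masses])
    mean_counts = config.lambda_per_g * masses**config.beta

    if config.model == "poisson":
        counts = rng.poisson(mean_counts)
    elif config.model == "negative_binomial":
        k = config.dispersion_k
        # NB as Poisson-gamma mixture: mean mu, variance mu + mu^2/k
        counts = rng.poisson(rng.gamma(k, mean_counts / k))
    elif config.model == "episodic":
        sticky = rng.random(config.n_pieces) < config.sticky_fraction_p
        counts = np.where(sticky, rng.poisson(mean_counts), 0)
    else:  # concentrated: same expected total, all in one piece
        total = rng.poisson(mean_counts.sum())
        counts = np.zeros(config.n_pieces, dtype=int)
        counts[rng.integers(config.n_pieces)] = total

    pieces = [
        ResinPiece(f"sim{i:05d}", float(m), int(c)) for i, (m, c) in enumerate(zip(masses, counts))
    ]
    return PieceCollection(
        label=f"sim_{config.model}_seed{config.seed}",
        tree_group="other",
        resin_class="defaunation",
        pieces=pieces,
    )


def simulate_taxon_counts(config: CompositionSimConfig) -> TaxonCountMatrix:
    """Draw a samples x taxa matrix: each sample is one multinomial draw
    from its trap type's profile."""
    rng = np.random.default_rng(config.seed)
    sample_ids, rows = [], []
    for trap_type in config.profiles:
        total = config.totals[trap_type]
        for r in range(config.n_samples[trap_type]):
            sample_ids.append(f"{trap_type}_{r}")
            rows.append(rng.multinomial(total, config.profiles[trap_type]))
    return TaxonCountMatrix(
        sample_ids=sample_ids,
        taxon_ids=list(config.taxon_ids),
        counts=np.array(rows, dtype=int),
    )


@dataclass
class SweepRow:
    knob: float
    b: float | None
    error: str | None = None


def uniformity_sweep(
    base: TrapSimConfig,
    grid: list[float],
    knob: str = "auto",
    log_bins: int = 15,
    min_mass_g: float | None = None,
) -> list[SweepRow]:
    """Run simulate_pieces + uniformity_exponent across a grid of the
    model's uniformity knob (dispersion_k for negative_binomial,
    sticky_fraction_p for episodic), sharing the base seed stream.

    The grid should be sorted ascending in uniformity; |b| is expected
    to be non-decreasing along it.
    """
    if knob == "auto":
        knob = {"negative_binomial": "dispersion_k", "episodic": "sticky_fraction_p"}.get(base.model)
        if knob is None:
            raise ValueError(f"model {base.model!r} has no uniformity knob; pass one explicitly")
    rows: list[SweepRow] = []
    for value in grid:
        cfg = TrapSimConfig(**{**base.__dict__, knob: value})
        coll = simulate_pieces(cfg)
        try:
            fit = uniformity_exponent(coll, log_bins=log_bins, min_mass_g=min_mass_g)
            rows.append(SweepRow(knob=float(value), b=fit.b))
        except InsufficientDataError as err:
            rows.append(SweepRow(knob=float(value), b=None, error=str(err)))
    return rows
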