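"""Spatial-uniformity analysis of arthropod inclusions via the empty-piece
probability curve.

The central statistic is P(empty | m): the probability that a resin piece
of mass m contains no arthropod inclusions. Pieces are binned by mass,
the conditional mass distribution of empty pieces f(m | empty) and the
overall mass distribution f(m) are estimated from bin frequencies, and
Bayes' theorem inverts them:

    P(empty | m) = f(m | empty) * P(empty) / f(m)

which algebraically reduces, per bin, to n_empty / n_total — the direct
empirical conditional frequency. A power law is then fitted by ordinary
least squares in log-log space, log P = log a + b log m. The slope b is
the *uniformity exponent*: b near 0 means inclusions concentrated in a
few pieces (large pieces are as likely to be empty as small ones), while
strongly negative b means spatially uniform trapping; the uniform-Poisson
limit gives an exponential decay, i.e. an effectively unbounded exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import PieceCollection, ResinPiece


class InsufficientDataError(ValueError):
    """Raised when too few usable mass bins remain for a power-law fit."""


@dataclass
class EmptyMassPDF:
    """Binned estimate of P(no inclusions | mass).

    ``p_empty_given_m`` is NaN for bins containing no pieces (undefined).
    """

    bin_edges: np.ndarray
    p_empty_given_m: np.ndarray
    n_total_per_bin: np.ndarray
    n_empty_per_bin: np.ndarray
    p_empty_marginal: float
    log_bins: bool = False

    @property
    def bin_midpoints(self) -> np.ndarray:
        """Arithmetic midpoints; geometric midpoints for logarithmic bins."""
        lo, hi = self.bin_edges[:-1], self.bin_edges[1:]
        if self.log_bins:
            return np.sqrt(lo * hi)
        return 0.5 * (lo + hi)

    @property
    def defined(self) -> np.ndarray:
        return self.n_total_per_bin > 0


@dataclass
class PowerLawFit:
    """Result of a log-log least-squares power-law fit P(empty|m) = a * m^b.

    ``b`` is the fitted slope of log P against log m; negative for
    decreasing curves (the printed convention for the uniformity exponent).
    """

    log_a: float
    b: float
    se_b: float
    r_squared: float
    n_bins_used: int
    mass_range_g: tuple[float, float]
    n_bins_dropped_zero: int = 0
    settings: dict = field(default_factory=dict)

    def predict(self, m) -> np.ndarray:
        """Fitted P(empty | m) on the original scale."""
        return np.exp(self.log_a + self.b * np.log(np.asarray(m, dtype=float)))


def analytic_empty_prob(lambda_per_g: float, beta: float, m) -> float | np.ndarray:
    """Closed-form P(empty | m) = exp(-lambda * m^beta) for uniform Poisson
    trapping with intensity lambda per gram^beta; the oracle for the
    uniform limit."""
    if lambda_per_g < 0:
        raise ValueError("lambda_per_g must be non-negative")
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive")
    out = np.exp(-lambda_per_g * m**beta)
    return float(out) if out.ndim == 0 else out


def estimate_empty_pdf(
    collection: PieceCollection,
    bin_width_g: float = 0.01,
    min_mass_g: float | None = None,
    log_bins: int | None = None,
) -> EmptyMassPDF:
    """Estimate P(empty | m) from a piece collection by Bayes inversion of
    binned mass frequencies.

    Parameters
    ----------
    bin_width_g
        Width of linear mass bins in grams (default 0.01 g, the mass
        recording resolution).
    min_mass_g
        If set, pieces lighter than this are discarded before binning
        (used to remove collection bias against tiny pieces).
    log_bins
        If set, use this many logarithmically spaced bins spanning the
        observed mass range instead of linear bins. Recommended for
        collections with fewer than ~1000 pieces, where 0.01 g bins are
        mostly singletons.
    """
    if bin_width_g <= 0:
        raise ValueError("bin_width_g must be positive")
    masses = collection.masses
    counts = collection.counts
    if min_mass_g is not None:
        keep = masses >= min_mass_g
        masses, counts = masses[keep], counts[keep]
    if masses.size == 0:
        raise InsufficientDataError("no pieces remain after the mass cutoff")

    if log_bins is not None:
        lo, hi = masses.min(), masses.max()
        if lo == hi:
            lo, hi = lo * 0.999, hi * 1.001
        edges = np.geomspace(lo, hi, log_bins + 1)
        edges[-1] = np.nextafter(edges[-1], np.inf)
    else:
        # Bins centred on the recording grid: a mass recorded as m stands
        # for the interval [m - w/2, m + w/2), so grid values are midpoints.
        w = bin_width_g
        k_lo = int(round(masses.min() / w))
        k_hi = int(round(masses.max() / w))
        edges = (np.arange(k_lo, k_hi + 2) - 0.5) * w

    empty = counts == 0
    n_total, _ = np.histogram(masses, bins=edges)
    n_empty, _ = np.histogram(masses[empty], bins=edges)

    p_empty = empty.mean()  # P(empty)
    n_pieces, n_empty_tot = masses.size, int(empty.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        # f(m|empty) * P(empty) / f(m); bin widths cancel between the
        # two density estimates so counts can be used directly.
        f_m_given_empty = n_empty / n_empty_tot if n_empty_tot else np.zeros_like(n_empty, float)
        f_m = n_total / n_pieces
        p_given_m = f_m_given_empty * p_empty / f_m
    p_given_m = np.where(n_total > 0, p_given_m, np.nan)
    if n_empty_tot == 0:
        p_given_m = np.where(n_total > 0, 0.0, np.nan)

    return EmptyMassPDF(
        bin_edges=edges,
        p_empty_given_m=p_given_m,
        n_total_per_bin=n_total,
        n_empty_per_bin=n_empty,
        p_empty_marginal=float(p_empty),
        log_bins=log_bins is not None,
    )


def fit_power_law(pdf: EmptyMassPDF, min_mass_g: float | None = None) -> PowerLawFit:
    """Ordinary least squares of log P(empty|m) on log m over usable bins.

    Bins that are undefined (no pieces) or have P = 0 cannot enter a log
    fit and are dropped; the number of zero-probability bins dropped is
    recorded. At least 3 usable bins are required.
    """
    mids = pdf.bin_midpoints
    p = pdf.p_empty_given_m
    usable = pdf.defined & np.isfinite(p)
    if min_mass_g is not None:
        usable &= mids >= min_mass_g
    n_zero = int((usable & (p <= 0)).sum())
    usable &= p > 0
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"only {int(usable.sum())} usable bins (need >= 3) for the log-log fit"
        )
    x = np.log(mids[usable])
    y = np.log(p[usable])
    res = stats.linregress(x, y)
    return PowerLawFit(
        log_a=float(res.intercept),
        b=float(res.slope),
        se_b=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
        n_bins_used=int(usable.sum()),
        mass_range_g=(float(mids[usable].min()), float(mids[usable].max())),
        n_bins_dropped_zero=n_zero,
    )


def uniformity_exponent(
    collection: PieceCollection,
    bin_width_g: float = 0.01,
    min_mass_g: float | None = None,
    log_bins: int | None = None,
    bootstrap: int = 0,
    seed: int | None = None,
) -> PowerLawFit:
    """Single-call pipeline: bin, Bayes-invert, and fit the uniformity
    exponent b for one piece collection.

    With ``bootstrap > 0`` the standard error of b is re-estimated by
    resampling pieces with replacement, re-binning and re-fitting
    (binned points violate the independence assumption behind the OLS
    standard error).
    """
    if collection.total_inclusions == 0:
        raise InsufficientDataError(
            "collection has no inclusions; the uniformity exponent is undefined"
        )
    pdf = estimate_empty_pdf(collection, bin_width_g=bin_width_g, min_mass_g=min_mass_g, log_bins=log_bins)
    fit = fit_power_law(pdf, min_mass_g=min_mass_g)
    fit.settings = {
        "bin_width_g": bin_width_g,
        "min_mass_g": min_mass_g,
        "log_bins": log_bins,
        "n_pieces": len(collection),
        "binning": "logarithmic" if log_bins else "linear",
        "abscissa": "geometric midpoint" if log_bins else "arithmetic midpoint",
    }
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        slopes = []
        pieces = collection.pieces
        for _ in range(bootstrap):
            idx = rng.integers(0, len(pieces), size=len(pieces))
            resampled = PieceCollection(
                label=collection.label,
                tree_group=collection.tree_group,
                resin_class=collection.resin_class,
                pieces=[pieces[i] for i in idx],
            )
            try:
                bpdf = estimate_empty_pdf(
                    resampled, bin_width_g=bin_width_g, min_mass_g=min_mass_g, log_bins=log_bins
                )
                slopes.append(fit_power_law(bpdf, min_mass_g=min_mass_g).b)
            except InsufficientDataError:
                continue
        if len(slopes) >= 2:
            fit.se_b = float(np.std(slopes, ddof=1))
            fit.settings["bootstrap"] = {"replicates": bootstrap, "usable": len(slopes), "seed": seed}
    return fit
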