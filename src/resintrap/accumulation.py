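"""Count-versus-mass accumulation fits with a box-constrained exponent.

Locality totals (inclusion count N against resin mass m) are fitted with
a power law N = c * m^beta, with beta constrained to [2/3, 1]. The
bounds express the two limiting trapping geometries: beta = 2/3 when
trapping scales with the surface of a lump (area ~ m^(2/3)) and beta = 1
when it scales with its volume. Fitting is ordinary least squares in
log-log space; if the unconstrained slope leaves the box it is clamped
at the violated bound and the prefactor refitted alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import LocalitySummary
from .uniformity import InsufficientDataError

BETA_BOUNDS = (2.0 / 3.0, 1.0)
_BOUND_TOL = 1e-9


@dataclass
class AccumulationFit:
    """Constrained power-law fit N = c * m^beta for one tree group."""

    group: str
    c: float
    beta: float
    se_beta: float
    n_samples: int
    active_bound: str = "none"  # none | lower | upper
    n_zero_dropped: int = 0
    bounds: tuple[float, float] = BETA_BOUNDS

    def predict(self, m) -> np.ndarray:
        return self.c * np.asarray(m, dtype=float) ** self.beta


def _constrained_loglog_fit(log_m: np.ndarray, log_n: np.ndarray, bounds):
    lo, hi = bounds
    res = stats.linregress(log_m, log_n)
    beta, intercept = float(res.slope), float(res.intercept)
    active = "none"
    if beta < lo:
        beta, active = lo, "lower"
    elif beta > hi:
        beta, active = hi, "upper"
    if active != "none":
        intercept = float(np.mean(log_n - beta * log_m))
    return beta, intercept, active


def _constrained_poisson_fit(m: np.ndarray, n: np.ndarray, bounds):
    """Poisson GLM with log link, N ~ Poisson(c * m^beta), beta boxed.

    Keeps zero counts in the likelihood, so it suits sparse synthetic
    data. Clamp-and-refit: for fixed beta the MLE of c is closed-form,
    sum(N) / sum(m^beta).
    """
    import statsmodels.api as sm

    lo, hi = bounds
    X = sm.add_constant(np.log(m))
    fit = sm.GLM(n, X, family=sm.families.Poisson()).fit()
    intercept, beta = float(fit.params[0]), float(fit.params[1])
    active = "none"
    if beta < lo:
        beta, active = lo, "lower"
    elif beta > hi:
        beta, active = hi, "upper"
    if active != "none":
        intercept = float(np.log(n.sum() / (m**beta).sum()))
    return beta, intercept, active


def fit_accumulation(
    points,
    group: str = "all",
    bounds: tuple[float, float] = BETA_BOUNDS,
    bootstrap: int = 1000,
    seed: int | None = None,
    method: str = "loglog",
) -> AccumulationFit:
    """Fit N = c * m^beta to (mass_g, n_inclusions) points with beta boxed
    to ``bounds``.

    With the default ``method="loglog"``, zero-count points cannot enter
    the log-space fit and are dropped (their number is recorded);
    ``method="poisson"`` fits a Poisson GLM with log link instead, which
    keeps zeros in the likelihood (for zero-heavy synthetic data). The
    standard error of beta comes from a case-resampling bootstrap, which
    respects the constraint.
    """
    pts = np.asarray([(float(m), float(n)) for m, n in points], dtype=float)
    if pts.size and (pts[:, 0] <= 0).any():
        raise ValueError("masses must be positive")
    if method == "loglog":
        nonzero = pts[:, 1] > 0 if pts.size else np.array([], bool)
        used = pts[nonzero] if pts.size else pts
    elif method == "poisson":
        used = pts
    else:
        raise ValueError(f"unknown method {method!r}")
    n_zero = int(len(pts) - len(used))
    if len(used) < 3:
        raise InsufficientDataError(f"{len(used)} usable points (need >= 3) for group {group!r}")
    if np.unique(used[:, 0]).size < 2:
        raise np.linalg.LinAlgError(f"degenerate fit: all masses identical in group {group!r}")

    def _fit(sub):
        if method == "poisson":
            return _constrained_poisson_fit(sub[:, 0], sub[:, 1], bounds)
        return _constrained_loglog_fit(np.log(sub[:, 0]), np.log(sub[:, 1]), bounds)

    beta, intercept, active = _fit(used)

    se_beta = 0.0
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        betas = []
        n = len(used)
        for _ in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            sub = used[idx]
            if np.unique(sub[:, 0]).size < 2 or (method == "loglog" and (sub[:, 1] <= 0).any()):
                continue
            try:
                b, _, _ = _fit(sub)
            except Exception:
                continue
            betas.append(b)
        if len(betas) >= 2:
            se_beta = float(np.std(betas, ddof=1))

    return AccumulationFit(
        group=group,
        c=float(np.exp(intercept)),
        beta=beta,
        se_beta=se_beta,
        n_samples=len(used),
        active_bound=active if abs(beta - bounds[0]) < _BOUND_TOL or abs(beta - bounds[1]) < _BOUND_TOL else "none",
        n_zero_dropped=n_zero,
        bounds=bounds,
    )


# Default pooling: conifer-derived resins (Agathis, Agathis-like,
# Cheirolepidiaceae) against the angiosperm Hymenaea group.
DEFAULT_GROUPING = {
    "agathis": "agathis_family",
    "agathis_like": "agathis_family",
    "cheirolepidiaceae": "agathis_family",
    "hymenaea": "hymenaea",
}


def fit_groups(
    summaries: list[LocalitySummary],
    grouping: dict[str, str] | None = None,
    bounds: tuple[float, float] = BETA_BOUNDS,
    bootstrap: int = 1000,
    seed: int | None = None,
) -> dict[str, AccumulationFit]:
    """Fit one accumulation power law per pooled tree group.

    ``grouping`` maps each summary's tree_group to a fit group; every
    tree_group present must be mapped. Groups with fewer than 3 usable
    points raise per-group but do not block other groups: their entry
    holds the raised error.
    """
    grouping = DEFAULT_GROUPING if grouping is None else grouping
    by_group: dict[str, list] = {}
    for s in summaries:
        if s.tree_group not in grouping:
            raise KeyError(f"locality {s.locality!r}: tree_group {s.tree_group!r} not in grouping map")
        by_group.setdefault(grouping[s.tree_group], []).append((s.total_mass_g, s.total_inclusions))
    out: dict[str, AccumulationFit] = {}
    for i, (g, pts) in enumerate(sorted(by_group.items())):
        sub_seed = None if seed is None else seed + i
        try:
            out[g] = fit_accumulation(pts, group=g, bounds=bounds, bootstrap=bootstrap, seed=sub_seed)
        except InsufficientDataError as err:
            out[g] = err  # caller inspects; other groups still fitted
    return out
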