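"""Assemblage composition comparison across trap types and deposits.

Samples (resin collections, yellow sticky traps, Malaise traps) are
compared as taxon frequency profiles. Tools:

* Bhattacharyya distance D = -ln( sum_i sqrt(p_i q_i) ) between profiles;
* classical (Torgerson) metric MDS with per-axis variance explained,
  computed from the eigenvalues of the double-centred squared-distance
  matrix;
* agglomerative clustering of samples under 1 - Spearman rank
  correlation with complete linkage, exportable as Newick;
* a flying vs. non-flying contingency analysis (Pearson chi-square with
  standardized residuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_model import TaxonCountMatrix, ValidationError

#: Distance assigned when the Bhattacharyya coefficient underflows to 0
#: (disjoint supports, only possible with pseudocount 0); keeps MDS finite.
BC_ZERO_DISTANCE_CAP = 50.0


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("non-finite distances")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValidationError("distance matrix must be symmetric with zero diagonal")


@dataclass
class MDSResult:
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    variance_explained: np.ndarray  # per retained axis, from positive eigenvalues
    negative_eigenvalue_magnitude: float
    ids: list[str]
    axes_truncated: bool = False


@dataclass
class Dendrogram:
    """Agglomerative merge history: (cluster_i, cluster_j, height) triples,
    scipy linkage-style cluster numbering (leaves 0..n-1)."""

    merges: list[tuple[int, int, float]]
    leaf_ids: list[str]
    linkage_matrix: np.ndarray

    def to_newick(self) -> str:
        n = len(self.leaf_ids)
        nodes = {i: self.leaf_ids[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for k, (i, j, h) in enumerate(self.merges):
            li, lj = h - heights[i], h - heights[j]
            nodes[n + k] = f"({nodes[i]}:{li:.6g},{nodes[j]}:{lj:.6g})"
            heights[n + k] = h
        return nodes[n + len(self.merges) - 1] + ";"


@dataclass
class ContingencyResult:
    table: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    chi2: float
    df: int
    p_value: float
    std_residuals: np.ndarray
    expected: np.ndarray
    p_value_mc: float | None = None


# ---------------------------------------------------------------------------


def normalize_profiles(matrix: TaxonCountMatrix, pseudocount: float = 0.5) -> np.ndarray:
    """Convert counts to per-sample probability profiles.

    A pseudocount (default 0.5, Jeffreys-style) is added to every cell
    before normalization so that taxa absent from one sample do not
    force a zero Bhattacharyya coefficient.
    """
    if matrix.n_taxa == 0:
        raise ValidationError("empty taxon set")
    counts = matrix.counts.astype(float) + pseudocount
    row_sums = counts.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValidationError("sample with zero total and zero pseudocount cannot be normalized")
    return counts / row_sums


def bhattacharyya_distance(p, q, zero_cap: float = BC_ZERO_DISTANCE_CAP) -> float:
    """D = -ln BC with BC = sum_i sqrt(p_i * q_i); 0 iff the profiles match.

    BC is clipped to (0, 1]: values above 1 from rounding map to
    distance 0, and BC = 0 (disjoint supports) maps to ``zero_cap``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError(f"profile length mismatch: {p.shape} vs {q.shape}")
    bc = float(np.sqrt(p * q).sum())
    if bc <= 0:
        return zero_cap
    return -np.log(min(bc, 1.0))


def _spearman_dissimilarity(x, y) -> float:
    rho = stats.spearmanr(x, y).statistic
    if not np.isfinite(rho):  # constant row: rank correlation undefined
        raise ValidationError("Spearman correlation undefined for a constant profile")
    d = 1.0 - float(rho)
    return 0.0 if abs(d) < 1e-12 else d


def distance_matrix(
    matrix: TaxonCountMatrix, metric: str = "bhattacharyya", pseudocount: float = 0.5
) -> DistanceMatrix:
    """Pairwise sample distances under the chosen assemblage metric."""
    if matrix.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    n = matrix.n_samples
    d = np.zeros((n, n))
    if metric == "bhattacharyya":
        prof = normalize_profiles(matrix, pseudocount=pseudocount)
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = bhattacharyya_distance(prof[i], prof[j])
    elif metric == "one_minus_spearman":
        counts = matrix.counts
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _spearman_dissimilarity(counts[i], counts[j])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(ids=list(matrix.sample_ids), d=d, metric_name=metric)


def classical_mds(D: DistanceMatrix, k: int = 2) -> MDSResult:
    """Classical (Torgerson) metric MDS.

    Double-centre B = -1/2 J D^2 J, eigendecompose, and scale the top-k
    eigenvectors by sqrt(eigenvalue). Variance explained per axis is
    lambda_i over the sum of positive eigenvalues; negative eigenvalues
    (the distance not being Euclidean, e.g. Bhattacharyya) are truncated
    and their total magnitude reported.
    """
    n = len(D.ids)
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.d**2) @ J
    B = 0.5 * (B + B.T)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    if k_eff:
        coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    else:  # e.g. all-zero distance matrix: a single point, all coords 0
        coords = np.zeros((n, k))
    pos_sum = eigvals[pos].sum()
    var_exp = eigvals[:k_eff] / pos_sum if pos_sum > 0 else np.zeros(k_eff)
    return MDSResult(
        coordinates=coords,
        eigenvalues=eigvals,
        variance_explained=var_exp,
        negative_eigenvalue_magnitude=float(-eigvals[eigvals < -tol].sum()),
        ids=list(D.ids),
        axes_truncated=k_eff < k,
    )


def hierarchical_cluster(D: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of samples; complete linkage merges at the
    maximum pairwise distance between clusters, making heights monotone."""
    if not np.all(np.isfinite(D.d)):
        raise ValidationError("non-finite distances")
    Z = hierarchy.linkage(squareform(D.d, checks=False), method=linkage)
    merges = [(int(r[0]), int(r[1]), float(r[2])) for r in Z]
    return Dendrogram(merges=merges, leaf_ids=list(D.ids), linkage_matrix=Z)


# Default winged/wingless classification at order level. Worker ants
# (Formicidae) are wingless, so where family data allow, Hymenoptera
# trapped as Formicidae count as non-flying; non-insect arthropods are
# excluded from the insect flight contrast.
DEFAULT_FLIGHT_CLASSES = {
    "Diptera": "flying",
    "Hymenoptera": "flying",
    "Formicidae": "non_flying",
    "Hemiptera": "flying",
    "Thysanoptera": "flying",
    "Coleoptera": "flying",
    "Lepidoptera": "flying",
    "Psocoptera": "flying",
    "Blattodea": "flying",
    "Collembola": "non_flying",
    "Zygentoma": "non_flying",
    "Acari": "excluded",
    "Araneae": "excluded",
    "Pseudoscorpiones": "excluded",
    "Isopoda": "excluded",
    "Myriapoda": "excluded",
}


def flying_contingency(
    matrix: TaxonCountMatrix,
    classification: dict[str, str] | None = None,
    monte_carlo: int = 0,
    seed: int | None = None,
) -> ContingencyResult:
    """Pearson chi-square contrast of flying vs. non-flying insect counts
    across sample groups.

    Every taxon must be classified (``excluded`` removes it, e.g. Acari,
    which are not insects). ``monte_carlo > 0`` adds a permutation
    p-value for tables with small expected counts.
    """
    classification = DEFAULT_FLIGHT_CLASSES if classification is None else classification
    missing = [t for t in matrix.taxon_ids if t not in classification]
    if missing:
        raise KeyError(f"taxa missing from flight classification: {missing}")
    cols = {"flying": 0, "non_flying": 1}
    table = np.zeros((matrix.n_samples, 2))
    for j, taxon in enumerate(matrix.taxon_ids):
        cls = classification[taxon]
        if cls == "excluded":
            continue
        if cls not in cols:
            raise ValueError(f"bad class {cls!r} for taxon {taxon!r}")
        table[:, cols[cls]] += matrix.counts[:, j]
    return contingency_test(table, row_ids=list(matrix.sample_ids),
                            col_ids=["flying", "non_flying"],
                            monte_carlo=monte_carlo, seed=seed)


def contingency_test(
    table,
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
    monte_carlo: int = 0,
    seed: int | None = None,
) -> ContingencyResult:
    """Pearson chi-square test on a groups x categories count table, with
    standardized residuals (O - E) / sqrt(E) per cell."""
    table = np.asarray(table, dtype=float)
    row_ids = row_ids or [f"row{i}" for i in range(table.shape[0])]
    col_ids = col_ids or [f"col{j}" for j in range(table.shape[1])]
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected == 0):
        raise ValidationError("degenerate table: expected count of 0 in some cell")
    resid = (table - expected) / np.sqrt(expected)
    p_mc = None
    if monte_carlo > 0:
        rng = np.random.default_rng(seed)
        row_tot = table.sum(axis=1).astype(int)
        col_p = table.sum(axis=0) / table.sum()
        hits = 0
        for _ in range(monte_carlo):
            sim = np.array([rng.multinomial(r, col_p) for r in row_tot], dtype=float)
            e = np.outer(sim.sum(1), sim.sum(0)) / sim.sum()
            with np.errstate(invalid="ignore", divide="ignore"):
                s = np.nansum(np.where(e > 0, (sim - e) ** 2 / e, 0.0))
            hits += s >= chi2
        p_mc = (hits + 1) / (monte_carlo + 1)
    return ContingencyResult(
        table=table, row_ids=row_ids, col_ids=col_ids,
        chi2=float(chi2), df=int(df), p_value=float(p),
        std_residuals=resid, expected=expected, p_value_mc=p_mc,
    )
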