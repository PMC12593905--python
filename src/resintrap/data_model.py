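"""Domain types and I/O for resin-piece and taxon-count data.

The unit of observation is a *resin piece*: one lump of exuded (or
fossilised) resin with a measured mass and a count of arthropod
inclusions. Collections of pieces are the input to the uniformity
analysis; locality-level summaries (total mass, total inclusion count)
feed the accumulation fits; samples-by-taxa count matrices feed the
composition analyses.

Masses are recorded to 0.01 g resolution and are re-rounded to that
grid on ingest so that binning at 0.01 g is exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TREE_GROUPS = ("agathis", "agathis_like", "hymenaea", "cheirolepidiaceae", "other")
# Resin age classes: amber is fossil resin older than 2.58 Ma, copal spans
# 2.58 Ma to 1760 AD, Defaunation resin was produced after 1760 AD.
RESIN_CLASSES = ("amber", "copal", "defaunation")

MASS_RESOLUTION_G = 0.01


class ValidationError(ValueError):
    """Raised when ingested data violates a domain invariant."""


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


def round_mass(mass_g: float) -> float:
    """Round a mass to the 0.01 g recording grid.

    Rounds half-up on the value actually held in the double (so a
    parsed "1.005", stored as 1.00499…, rounds down to 1.00).
    """
    return float(Decimal(float(mass_g)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ResinPiece:
    """A single resin piece: mass in grams and its arthropod inclusion count."""

    piece_id: str
    mass_g: float
    n_inclusions: int

    def __post_init__(self) -> None:
        if self.mass_g < MASS_RESOLUTION_G:
            raise ValidationError(
                f"piece {self.piece_id!r}: mass {self.mass_g} g below the "
                f"{MASS_RESOLUTION_G} g recording resolution"
            )
        if self.n_inclusions < 0:
            raise ValidationError(f"piece {self.piece_id!r}: negative inclusion count")


@dataclass
class PieceCollection:
    """A labelled set of resin pieces from one source tree group and resin class."""

    label: str
    tree_group: str
    resin_class: str
    pieces: list[ResinPiece] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tree_group not in TREE_GROUPS:
            raise ValidationError(f"unknown tree_group {self.tree_group!r}")
        if self.resin_class not in RESIN_CLASSES:
            raise ValidationError(f"unknown resin_class {self.resin_class!r}")

    def __len__(self) -> int:
        return len(self.pieces)

    @property
    def masses(self) -> np.ndarray:
        return np.array([p.mass_g for p in self.pieces], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([p.n_inclusions for p in self.pieces], dtype=int)

    @property
    def total_mass_g(self) -> float:
        return float(self.masses.sum()) if self.pieces else 0.0

    @property
    def total_inclusions(self) -> int:
        return int(self.counts.sum()) if self.pieces else 0


@dataclass(frozen=True)
class LocalitySummary:
    """One locality-level row: total resin mass and total inclusion count.

    Masses published as a range ("35,000 to 40,000 g") carry both bounds;
    ``total_mass_g`` is then the midpoint, which downstream fits use by
    default. ``mass_approximate`` flags "ca." masses.
    """

    locality: str
    age: str
    tree_taxon: str
    tree_group: str
    resin_class: str
    total_mass_g: float
    total_inclusions: int
    citation: str
    mass_min_g: float | None = None
    mass_max_g: float | None = None
    mass_approximate: bool = False

    def __post_init__(self) -> None:
        if self.total_mass_g <= 0:
            raise ValidationError(f"{self.locality!r}: non-positive total mass")
        if self.total_inclusions < 0:
            raise ValidationError(f"{self.locality!r}: negative inclusion count")


@dataclass
class TaxonCountMatrix:
    """Samples-by-taxa count matrix (arthropod orders or Diptera families)."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    level: str = "order"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon ids")
        if (self.counts < 0).any():
            raise ValidationError("negative counts in taxon matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


# ---------------------------------------------------------------------------
# I/O

PIECE_COLUMNS = ("piece_id", "mass_g", "n_inclusions")


def read_piece_table(
    path, label: str, tree_group: str = "other", resin_class: str = "defaunation"
) -> PieceCollection:
    """Read a piece-level CSV (piece_id, mass_g, n_inclusions) into a collection.

    Masses are rounded to the 0.01 g recording grid; row order is preserved.
    """
    df = pd.read_csv(path, dtype={"piece_id": str})
    missing = [c for c in PIECE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    pieces = []
    for i, row in enumerate(df.itertuples(index=False)):
        mass = float(row.mass_g)
        if mass <= 0:
            raise ValidationError(f"{path} row {i + 1}: non-positive mass {row.mass_g}")
        count = int(row.n_inclusions)
        if count < 0:
            raise ValidationError(f"{path} row {i + 1}: negative count {row.n_inclusions}")
        pieces.append(ResinPiece(str(row.piece_id), round_mass(mass), count))
    return PieceCollection(label=label, tree_group=tree_group, resin_class=resin_class, pieces=pieces)


def write_piece_table(collection: PieceCollection, path) -> None:
    """Write a collection back to the canonical piece CSV layout."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PIECE_COLUMNS)
        for p in collection.pieces:
            writer.writerow([p.piece_id, f"{p.mass_g:.2f}", p.n_inclusions])


def read_taxon_counts(path, level: str = "order") -> TaxonCountMatrix:
    """Read a samples-by-taxa CSV: first column sample id, one column per taxon."""
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    taxa_header = header[1:]
    dupes = sorted({t for t in taxa_header if taxa_header.count(t) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicated taxon column(s) {dupes}")
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicated sample id(s)")
    counts = df.to_numpy()
    if (counts < 0).any():
        raise ValidationError(f"{path}: negative cell value")
    return TaxonCountMatrix(
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
        counts=counts.astype(int),
        level=level,
    )


def write_taxon_counts(matrix: TaxonCountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, index_label="sample_id")


def load_table1_fixture() -> list[LocalitySummary]:
    """Load the packaged 27-locality summary table (mass and inclusion count
    per amber/copal/Defaunation-resin collection)."""
    ref = resources.files("resintrap").joinpath("data/table1.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            LocalitySummary(
                locality=row.locality,
                age=row.age,
                tree_taxon=row.tree_taxon,
                tree_group=row.tree_group,
                resin_class=row.resin_class,
                total_mass_g=float(row.total_mass_g),
                total_inclusions=int(row.total_inclusions),
                citation=row.citation,
                mass_min_g=None if pd.isna(row.mass_min_g) else float(row.mass_min_g),
                mass_max_g=None if pd.isna(row.mass_max_g) else float(row.mass_max_g),
                mass_approximate=bool(row.mass_approximate),
            )
        )
    return out


def inclusion_density(obj: LocalitySummary | PieceCollection | Iterable) -> float:
    """Inclusion density: total arthropod inclusions per gram of resin."""
    if isinstance(obj, LocalitySummary):
        total_inc, total_mass = obj.total_inclusions, obj.total_mass_g
    elif isinstance(obj, PieceCollection):
        total_inc, total_mass = obj.total_inclusions, obj.total_mass_g
    else:  # an iterable of summaries or collections: pooled density
        items = list(obj)
        total_inc = sum(x.total_inclusions for x in items)
        total_mass = sum(x.total_mass_g for x in items)
    if total_mass <= 0:
        raise ValidationError("inclusion density undefined for zero total mass")
    return total_inc / total_mass
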