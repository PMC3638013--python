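"""Algebra of two-locus compositional-epistasis models.

A compositional (Bateson-style) epistasis model is a 3x3 table of binary
risk levels: rows are the genotypes of the first SNP, columns the genotypes
of the second, genotype order AA, Aa, aa. Each of the 2^9 = 512 tables is
identified by the decimal value of its row-major 9-bit string
(p11 p12 p13 p21 p22 p23 p31 p32 p33); e.g. the dominant model
(rows 000 / 011 / 011) has label 27.

Two tables describe the same biological pattern when one maps onto the
other by relabelling alleles at either locus (row or column reversal),
swapping the roles of the two SNPs (transpose), or exchanging which level
is called "high risk" (complement). These four generators produce a group
of 16 symmetries whose orbits partition the 512 tables into 51 equivalence
classes; a class is named after its smallest member label (M1, M27, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "N_LABELS",
    "PenetranceTable",
    "ModelClass",
    "label_of",
    "table_of_label",
    "complement",
    "orbit",
    "enumerate_classes",
    "nondegenerate_classes",
    "risk_partition",
]

N_LABELS = 512

# Powers of two for the row-major bit layout p11..p33 (p11 is the high bit).
_BIT_WEIGHTS = 2 ** np.arange(8, -1, -1, dtype=np.int64)


@dataclass(frozen=True)
class PenetranceTable:
    """A 3x3 binary (low/high risk) penetrance table.

    Parameters
    ----------
    values : array-like of shape (3, 3)
        Risk levels, 0 = low, 1 = high. Rows index the first SNP's
        genotypes (AA, Aa, aa), columns the second SNP's.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.int8)
        if arr.shape != (3, 3):
            raise ValueError(f"penetrance table must be 3x3, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("penetrance table entries must be 0 or 1")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_label(cls, label: int) -> "PenetranceTable":
        return table_of_label(label)

    @property
    def label(self) -> int:
        return label_of(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PenetranceTable):
            return NotImplemented
        return bool(np.array_equal(self.values, other.values))

    def __hash__(self) -> int:
        return hash(self.label)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        rows = "/".join("".join(str(v) for v in row) for row in self.values)
        return f"PenetranceTable({rows}, label={self.label})"


def label_of(table: PenetranceTable | np.ndarray) -> int:
    """Decimal label of a table: value of the row-major 9-bit string p11..p33."""
    values = table.values if isinstance(table, PenetranceTable) else np.asarray(table)
    return int(values.reshape(9).astype(np.int64) @ _BIT_WEIGHTS)


def table_of_label(label: int) -> PenetranceTable:
    """Inverse of :func:`label_of`."""
    label = int(label)
    if not 0 <= label < N_LABELS:
        raise ValueError(f"label must be in [0, 511], got {label}")
    bits = (label >> np.arange(8, -1, -1)) & 1
    return PenetranceTable(bits.reshape(3, 3))


def complement(table: PenetranceTable) -> PenetranceTable:
    """Swap the low/high risk levels (0 <-> 1)."""
    return PenetranceTable(1 - table.values)


def _orbit_labels(values: np.ndarray) -> frozenset[int]:
    seen: set[int] = set()
    for flip_rows in (False, True):
        for flip_cols in (False, True):
            for transpose in (False, True):
                for invert in (False, True):
                    v = values
                    if flip_rows:
                        v = v[::-1, :]
                    if flip_cols:
                        v = v[:, ::-1]
                    if transpose:
                        v = v.T
                    if invert:
                        v = 1 - v
                    seen.add(label_of(v))
    return frozenset(seen)


def orbit(table: PenetranceTable) -> frozenset[int]:
    """Labels of all images of ``table`` under the 16-element symmetry group."""
    return _orbit_labels(np.asarray(table.values))


@dataclass(frozen=True)
class ModelClass:
    """One equivalence class of penetrance tables under the symmetry group."""

    canonical_label: int
    members: frozenset[int] = field(repr=False)

    @property
    def name(self) -> str:
        return f"M{self.canonical_label}"

    @property
    def orbit_size(self) -> int:
        return len(self.members)

    @property
    def is_degenerate(self) -> bool:
        """True for the constant class {0, 511}, whose risk table has an empty column."""
        return self.canonical_label == 0

    def canonical_table(self) -> PenetranceTable:
        return table_of_label(self.canonical_label)


@lru_cache(maxsize=1)
def enumerate_classes() -> tuple[ModelClass, ...]:
    """All 51 model classes, sorted by canonical label.

    Exhaustively applies the symmetry group to every one of the 512 labels
    and merges orbits. The constant class {0, 511} is included (it is one
    of the 51) but carries ``is_degenerate`` so callers can skip it.
    """
    assigned = np.full(N_LABELS, False)
    classes: list[ModelClass] = []
    for lab in range(N_LABELS):
        if assigned[lab]:
            continue
        members = orbit(table_of_label(lab))
        for m in members:
            assigned[m] = True
        classes.append(ModelClass(canonical_label=min(members), members=members))
    classes.sort(key=lambda c: c.canonical_label)
    return tuple(classes)


def nondegenerate_classes() -> tuple[ModelClass, ...]:
    """The 50 classes actually tested per pair (constant class excluded)."""
    return tuple(c for c in enumerate_classes() if not c.is_degenerate)


def risk_partition(
    table: PenetranceTable,
) -> tuple[frozenset[tuple[int, int]], frozenset[tuple[int, int]]]:
    """Partition of the 9 genotype cells into (low, high) risk sets.

    Cells are 1-based (i, j) pairs matching the genotype codes 1..3 used in
    the documentation tables (internal genotype codes are 0..2).
    """
    low = frozenset(
        (i + 1, j + 1) for i in range(3) for j in range(3) if table.values[i, j] == 0
    )
    high = frozenset(
        (i + 1, j + 1) for i in range(3) for j in range(3) if table.values[i, j] == 1
    )
    return low, high
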