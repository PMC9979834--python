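"""Compositional algebra on the simplex.

Percent-cover data from point counts carry only relative information, so all
analyses operate on the simplex with the Aitchison geometry: closure,
perturbation, and isometric logratio (ilr) coordinates built from an
orthonormal contrast (balance) matrix.  The default five-part composition is
(*A. aurita* on panel, bare panel, *Botrylloides* spp., *Bugula* spp.,
*Molgula tubifera*), and the default basis splits it into an orthogonal
block for (polyps, bare | competitors) and a block for the competitor
subcomposition, which makes the two ternary projections used for display
coordinate sub-blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Absolute tolerance for closure and orthonormality checks.
CLOSURE_TOL = 1e-12

FIVE_PART_NAMES = (
    "aurita_panel",
    "bare",
    "botrylloides",
    "bugula",
    "molgula",
)

#: Competitor parts (0-based indices) within the five-part composition.
COMPETITOR_PARTS = (2, 3, 4)


class CompositionError(ValueError):
    """Invalid input for a compositional operation."""


@dataclass(frozen=True)
class Composition:
    """A point of the D-part simplex: strictly positive parts summing to 1."""

    parts: np.ndarray

    def __post_init__(self) -> None:
        parts = np.asarray(self.parts, dtype=float)
        if parts.ndim != 1 or parts.size < 2:
            raise CompositionError("a composition needs >=2 parts in a 1-D vector")
        if not np.all(np.isfinite(parts)) or np.any(parts <= 0):
            raise CompositionError("composition parts must be finite and > 0")
        if abs(parts.sum() - 1.0) > 1e-8:
            parts = parts / parts.sum()
        object.__setattr__(self, "parts", parts)
        assert abs(self.parts.sum() - 1.0) <= CLOSURE_TOL * self.parts.size * 1e4

    @property
    def D(self) -> int:
        return self.parts.size

    def __array__(self, dtype=None, copy=None):
        return np.array(self.parts, dtype=dtype)


@dataclass(frozen=True)
class ContrastMatrix:
    """Orthonormal (D-1) x D contrast matrix defining an ilr basis.

    Each row is a balance from a sequential binary partition: rows sum to
    zero and the matrix times its transpose is the identity.
    """

    matrix: np.ndarray
    partition_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] - 1:
            raise CompositionError("contrast matrix must be (D-1) x D")
        if np.abs(m.sum(axis=1)).max() > CLOSURE_TOL * 10:
            raise CompositionError("contrast matrix rows must sum to zero")
        gram = m @ m.T
        if np.abs(gram - np.eye(m.shape[0])).max() > 1e-10:
            raise CompositionError("contrast matrix rows must be orthonormal")
        object.__setattr__(self, "matrix", m)

    @property
    def D(self) -> int:
        return self.matrix.shape[1]

    def to_text(self) -> str:
        lines = []
        for i, row in enumerate(self.matrix):
            label = self.partition_labels[i] if i < len(self.partition_labels) else ""
            lines.append("\t".join([label] + [format(float(v), ".17g") for v in row]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ContrastMatrix":
        labels, rows = [], []
        for line in text.strip().splitlines():
            cells = line.split("\t")
            labels.append(cells[0])
            rows.append([float(v) for v in cells[1:]])
        return cls(np.array(rows), tuple(labels))


def balance_basis(partitions: Sequence[tuple[Sequence[int], Sequence[int]]],
                  D: int,
                  labels: Sequence[str] | None = None) -> ContrastMatrix:
    """Build an orthonormal contrast matrix from a sequential binary partition.

    Each partition is a pair (numerator_indices, denominator_indices); the
    corresponding balance row carries +sqrt(s/(r(r+s))) on the r numerator
    parts and -sqrt(r/(s(r+s))) on the s denominator parts.
    """
    rows = np.zeros((len(partitions), D))
    for i, (num, den) in enumerate(partitions):
        r, s = len(num), len(den)
        if r == 0 or s == 0:
            raise CompositionError("each partition side must be non-empty")
        rows[i, list(num)] = np.sqrt(s / (r * (r + s)))
        rows[i, list(den)] = -np.sqrt(r / (s * (r + s)))
    if labels is None:
        labels = [f"({'+'.join(map(str, n))})|({'+'.join(map(str, d))})"
                  for n, d in partitions]
    return ContrastMatrix(rows, tuple(labels))


def default_basis() -> ContrastMatrix:
    """Basis for the five-part cover composition.

    Sequential binary partition: (polyps, bare) vs the three competitor taxa;
    polyps vs bare; Botrylloides vs (Bugula, Molgula); Bugula vs Molgula.
    Coordinates 1-2 and 3-4 are then exactly the two ternary projections
    (amalgamated display and competitor subcomposition).
    """
    return balance_basis(
        [((0, 1), (2, 3, 4)), ((0,), (1,)), ((2,), (3, 4)), ((3,), (4,))],
        D=5,
        labels=(
            "(aurita,bare)|(botrylloides,bugula,molgula)",
            "aurita|bare",
            "botrylloides|(bugula,molgula)",
            "bugula|molgula",
        ),
    )


def amalgamation_basis() -> ContrastMatrix:
    """Ternary basis aligned with the gm-amalgamated projection.

    Under the default five-part basis, ilr of (A. aurita, bare,
    gm(competitors)) in this basis equals five-part ilr coordinates 1-2,
    up to the factor 3/sqrt(5) on the first coordinate (the geometric mean
    replaces three parts by one).
    """
    return balance_basis([((0, 1), (2,)), ((0,), (1,))], D=3)


def subcomposition_basis() -> ContrastMatrix:
    """Ternary basis aligned with the competitor subcomposition.

    ilr of (Botrylloides, Bugula, Molgula) in this basis equals five-part
    ilr coordinates 3-4 exactly.
    """
    return balance_basis([((0,), (1, 2)), ((1,), (2,))], D=3)


def ternary_basis() -> ContrastMatrix:
    """Default basis for three-part compositions (display projections)."""
    return amalgamation_basis()


def close(raw: Sequence[float] | np.ndarray) -> Composition:
    """Closure: rescale a nonnegative vector to sum to one."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or np.any(raw < 0) or not np.all(np.isfinite(raw)):
        raise CompositionError("closure needs a finite nonnegative vector")
    total = raw.sum()
    if total <= 0:
        raise CompositionError("closure of an all-zero vector is undefined")
    return Composition(raw / total)


def zero_replace(counts: Sequence[float] | np.ndarray,
                 replacement: float = 0.5) -> Composition:
    """Replace zero counts by ``replacement`` (default 1/2), then close.

    Display-only convention for plotting observed count compositions with
    zeros; model likelihoods never use it.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise CompositionError("counts must be nonnegative")
    if not np.any(counts > 0):
        raise CompositionError("all-zero counts cannot be closed")
    if replacement <= 0:
        raise CompositionError("replacement must be positive")
    filled = np.where(counts == 0, replacement, counts)
    return close(filled)


def ilr(c: Composition | np.ndarray, basis: ContrastMatrix) -> np.ndarray:
    """Isometric logratio coordinates: basis @ log(parts).

    Row sums of the basis are zero, so this equals the projection of the clr
    onto the basis.  Works on a single composition or an (N, D) array of
    strictly positive rows (closed or not; closure is a clr constant that the
    zero row sums annihilate).
    """
    parts = np.asarray(c, dtype=float)
    if np.any(parts <= 0):
        raise CompositionError("ilr needs strictly positive parts; zero-replace first")
    if parts.shape[-1] != basis.D:
        raise CompositionError("basis dimension mismatch")
    return np.log(parts) @ basis.matrix.T


def ilr_inv(z: np.ndarray, basis: ContrastMatrix) -> Composition | np.ndarray:
    """Inverse ilr: close(exp(basis^T @ z)).  Vectorized over leading axes."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise CompositionError("ilr_inv needs finite coordinates")
    if z.shape[-1] != basis.D - 1:
        raise CompositionError("coordinate length must be D-1")
    expo = np.exp(z @ basis.matrix - np.max(z @ basis.matrix, axis=-1, keepdims=True))
    parts = expo / expo.sum(axis=-1, keepdims=True)
    if parts.ndim == 1:
        return Composition(parts)
    return parts


def perturb(a: Composition, b: Composition) -> Composition:
    """Aitchison perturbation: closure of the elementwise product."""
    if a.D != b.D:
        raise CompositionError("perturbation needs equal dimensions")
    return close(a.parts * b.parts)


def inverse(c: Composition) -> Composition:
    """Perturbation inverse: close(1/parts)."""
    return close(1.0 / c.parts)


def aitchison_distance(a: Composition, b: Composition,
                       basis: ContrastMatrix | None = None) -> float:
    if basis is None:
        basis = balance_basis(
            [(tuple(range(i + 1)), (i + 1,)) for i in range(a.D - 1)], a.D)
    return float(np.linalg.norm(ilr(a, basis) - ilr(b, basis)))


def subcomposition(c: Composition, part_indices: Sequence[int]) -> Composition:
    """Closure of a subset of parts; ratios of retained parts are unchanged."""
    idx = list(part_indices)
    if len(idx) < 2:
        raise CompositionError("a subcomposition needs >=2 parts")
    if len(set(idx)) != len(idx):
        raise CompositionError("duplicate part indices")
    if min(idx) < 0 or max(idx) >= c.D:
        raise CompositionError("part index out of range")
    return close(c.parts[idx])


def gm_amalgamate(c: Composition,
                  group_indices: Sequence[int] = COMPETITOR_PARTS) -> Composition:
    """Project to (part1, part2, geometric mean of the competitor group).

    With the geometric mean (not the sum) as the third part, this projection
    and the competitor subcomposition are orthogonal coordinate blocks under
    the default balance basis, so together they display the full five-part
    composition without loss.
    """
    if c.D != 5:
        raise CompositionError("gm amalgamation is defined for 5-part compositions")
    idx = sorted(group_indices)
    if idx != list(COMPETITOR_PARTS):
        raise CompositionError("group_indices must be the competitor parts (2,3,4)")
    rest = [i for i in range(5) if i not in idx]
    gm = float(np.exp(np.mean(np.log(c.parts[idx]))))
    return close(np.array([c.parts[rest[0]], c.parts[rest[1]], gm]))
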