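"""Training-time augmentation: cube rotations and bounded displacement.

Mirror flips would change protein chirality, so augmentation is restricted
to the 24 proper rotational symmetries of the cube (axis permutations with
sign flips of determinant +1) plus a random displacement of the render
center within +/- 6 Angstrom per axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np

from .tensorize import VoxelGrid


@dataclass(frozen=True)
class Orientation:
    """One proper rotation of the cube.

    The implied rotation matrix M maps x to y with ``y[a] = axis_signs[a] *
    x[axis_permutation[a]]``; its determinant is always +1.
    """

    axis_permutation: tuple[int, int, int]
    axis_signs: tuple[int, int, int]

    @property
    def matrix(self) -> np.ndarray:
        m = np.zeros((3, 3))
        for a in range(3):
            m[a, self.axis_permutation[a]] = self.axis_signs[a]
        return m

    def compose(self, other: "Orientation") -> "Orientation":
        """Rotation equal to applying ``other`` first, then ``self``."""
        m = self.matrix @ other.matrix
        return _orientation_from_matrix(m)

    def inverse(self) -> "Orientation":
        return _orientation_from_matrix(self.matrix.T)


def _orientation_from_matrix(m: np.ndarray) -> Orientation:
    perm, signs = [], []
    for a in range(3):
        j = int(np.argmax(np.abs(m[a])))
        perm.append(j)
        signs.append(int(np.sign(m[a, j])))
    return Orientation(tuple(perm), tuple(signs))


def _perm_parity(perm) -> int:
    inversions = sum(1 for i in range(3) for j in range(i + 1, 3)
                     if perm[i] > perm[j])
    return -1 if inversions % 2 else 1


def enumerate_rotations() -> list[Orientation]:
    """The 24 proper rotations of the cube, in a stable order.

    All 6 axis permutations x 8 sign patterns are enumerated and the 24
    with determinant +1 retained (reflections are excluded).  The identity
    is first.
    """
    out = []
    for perm in sorted(permutations(range(3))):
        for signs in product((1, -1), repeat=3):
            if _perm_parity(perm) * signs[0] * signs[1] * signs[2] == 1:
                out.append(Orientation(perm, signs))
    out.sort(key=lambda o: (o.axis_permutation != (0, 1, 2)
                            or o.axis_signs != (1, 1, 1),
                            o.axis_permutation,
                            tuple(-s for s in o.axis_signs)))
    return out


def rotate_values(values: np.ndarray, o: Orientation) -> np.ndarray:
    """Rotate a (n, n, n, channels) voxel array about the grid center."""
    if not (values.ndim == 4
            and values.shape[0] == values.shape[1] == values.shape[2]):
        raise ValueError("rotation requires a cubic (n, n, n, c) grid")
    out = values.transpose(o.axis_permutation + (3,))
    for axis, sign in enumerate(o.axis_signs):
        if sign < 0:
            out = np.flip(out, axis=axis)
    return np.ascontiguousarray(out)


def apply_rotation(g: VoxelGrid, o: Orientation) -> VoxelGrid:
    """Rotate a voxel grid about its center; channels are untouched.

    Applying an orientation followed by its inverse restores the grid
    exactly (cells are permuted, never interpolated).
    """
    return VoxelGrid(values=rotate_values(g.values, o), origin=g.origin,
                     center=g.center, encoding=g.encoding)


def random_displacement(center, max_shift: float = 6.0,
                        seed=None) -> tuple[float, float, float]:
    """Shift a render center by independent uniform draws in [-max_shift, +max_shift].

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    shift = rng.uniform(-max_shift, max_shift, size=3)
    c = np.asarray(center, dtype=float) + shift
    return tuple(float(x) for x in c)


def random_integer_shift(values: np.ndarray, max_cells: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Integer-cell displacement of a cached tensor with zero fill.

    An approximation of center displacement for pipelines that augment
    pre-rendered tensors instead of re-rendering at a shifted center.
    """
    shifts = rng.integers(-max_cells, max_cells + 1, size=3)
    out = values
    for axis, sh in enumerate(shifts):
        if sh == 0:
            continue
        out = np.roll(out, int(sh), axis=axis)
        idx = [slice(None)] * out.ndim
        idx[axis] = slice(0, sh) if sh > 0 else slice(sh, None)
        out = out.copy() if out is values else out
        out[tuple(idx)] = 0.0
    return out
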