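"""Voxel tensorization of two-chain complexes.

A preprocessed complex is rendered into a ``(64, 64, 64, 8)`` tensor covering
a 64 x 64 x 64 Angstrom cube of 1 Angstrom cells centered on the interface.
The channel axis is element x chain: ``[C_A, N_A, O_A, S_A, C_B, N_B, O_B,
S_B]`` (hydrogen is excluded; it is not part of the predicted main
structure).  Three encodings are supported:

one-hot
    The cell containing each atom's coordinates is set to 1.
volume
    Each cell stores the intersection volume between the cell cube and the
    atom's van der Waals sphere.  The reference implementation integrates
    the overlap exactly (circle-rectangle areas integrated along z); a
    seeded Monte-Carlo estimator (default 10^6 points per cell) is provided
    as the fast stand-in the exact integral validates.
distance
    Each cell stores the Euclidean distance from the cell center to the
    nearest atom of the channel, capped at 12 Angstrom; cells farther than
    the cap from every atom stay 0.  Occupied cells are clamped to 1e-3 so
    "distance ~ 0" remains distinguishable from "empty".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.spatial import cKDTree

from .structure_io import ComplexStructure, ELEMENTS

#: van der Waals radii (Angstrom), half the atomic diameters tabulated for
#: the heavy elements of amino acids (C 1.40, N 1.30, O 1.20, S 2.00).
ATOM_RADII = {"C": 0.70, "N": 0.65, "O": 0.60, "S": 1.00}

CHANNELS = tuple(f"{e}_{c}" for c in "AB" for e in ELEMENTS)

ENCODINGS = ("one_hot", "volume", "distance")


@dataclass(frozen=True)
class EncodingConfig:
    """Rendering configuration.

    ``grid_side * cell_size`` defines the cube edge (64 Angstrom by default).
    ``max_render_distance`` applies to distance encoding only; ``mc_points``
    to the Monte-Carlo volume estimator only.
    """

    encoding: str = "distance"
    grid_side: int = 64
    cell_size: float = 1.0
    max_render_distance: float = 12.0
    mc_points: int = 1_000_000
    atom_radii: dict = field(default_factory=lambda: dict(ATOM_RADII))
    distance_clamp: float = 1e-3
    volume_method: str = "integral"  # or "mc"
    seed: int = 0

    def __post_init__(self):
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.grid_side <= 0 or self.cell_size <= 0:
            raise ValueError("grid_side and cell_size must be positive")

    @property
    def box_edge(self) -> float:
        return self.grid_side * self.cell_size


@dataclass
class VoxelGrid:
    """A rendered voxel tensor plus its placement and provenance.

    ``origin`` is the corner of cell (0, 0, 0); cell (i, j, k) covers the
    half-open box [origin + i*cs, origin + (i+1)*cs) per axis.
    """

    values: np.ndarray
    origin: tuple[float, float, float]
    center: tuple[float, float, float]
    encoding: str

    @property
    def grid_side(self) -> int:
        return self.values.shape[0]

    def cell_centers_axis(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        cs = 1.0  # cell size is reconstructible from origin/center if needed
        return np.asarray(self.origin)[axis] + (np.arange(n) + 0.5) * cs

    def save(self, path) -> None:
        meta = {"origin": list(self.origin), "center": list(self.center),
                "encoding": self.encoding}
        np.savez_compressed(path, values=self.values,
                            meta=np.frombuffer(
                                json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            return cls(values=data["values"],
                       origin=tuple(meta["origin"]),
                       center=tuple(meta["center"]),
                       encoding=meta["encoding"])


def _channel_index(chain_idx: int, element: str) -> int:
    return 4 * chain_idx + ELEMENTS.index(element)


def _grid_origin(center, cfg: EncodingConfig) -> np.ndarray:
    return np.asarray(center, dtype=float) - cfg.box_edge / 2.0


# ---------------------------------------------------------------------------
# sphere-cell intersection geometry
# ---------------------------------------------------------------------------

def _chord_integral(a: np.ndarray, b: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Integral of sqrt(r^2 - X^2) dX from a to b, with a, b in [-r, r]."""
    r = np.maximum(r, 0.0)
    safe_r = np.where(r > 0, r, 1.0)

    def antideriv(x):
        x = np.clip(x, -r, r)
        ratio = np.clip(x / safe_r, -1.0, 1.0)
        return 0.5 * (x * np.sqrt(np.maximum(r * r - x * x, 0.0))
                      + r * r * np.arcsin(ratio))

    return np.where(r > 0, antideriv(b) - antideriv(a), 0.0)


def circle_rect_area(x0, x1, y0, y1, r):
    """Exact area of the disk X^2 + Y^2 <= r^2 within [x0,x1] x [y0,y1].

    Fully vectorized; all arguments broadcast.
    """
    x0, x1, y0, y1, r = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (x0, x1, y0, y1, r)))

    def q(x, y):
        """Area of disk within {X <= x, Y <= y}."""
        xp = np.clip(x, -r, r)
        s = np.sqrt(np.maximum(r * r - y * y, 0.0))
        v = np.clip(xp, -s, s)
        mid = _chord_integral(-s, v, r) + y * (v + s)
        left = 2.0 * _chord_integral(-r, np.minimum(xp, -s), r)
        right = 2.0 * _chord_integral(s, np.maximum(xp, s), r)
        inner = np.where(y >= 0, left + mid + right, mid)
        full = 2.0 * _chord_integral(-r, xp, r)  # y >= r: no vertical cut
        return np.where(y >= r, full, np.where(y <= -r, 0.0, inner))

    area = q(x1, y1) - q(x0, y1) - q(x1, y0) + q(x0, y0)
    return np.maximum(area, 0.0)


_GL_NODES = 64
_gl_x, _gl_w = leggauss(_GL_NODES)


def _sphere_box_volumes(cell_corner: np.ndarray, atom_center: np.ndarray,
                        radius: np.ndarray, cell_size: float = 1.0) -> np.ndarray:
    """Exact sphere-box overlap volumes, vectorized over leading dimension.

    Integrates the exact circle-rectangle cross-section area along z using
    Gauss-Legendre quadrature under the substitution z = R sin(theta), which
    removes the square-root edge singularity of the sphere surface.
    """
    cell_corner = np.atleast_2d(np.asarray(cell_corner, dtype=float))
    atom_center = np.atleast_2d(np.asarray(atom_center, dtype=float))
    radius = np.atleast_1d(np.asarray(radius, dtype=float))

    rel = cell_corner - atom_center  # cell corner in atom frame
    z0 = np.clip(rel[:, 2], -radius, radius)
    z1 = np.clip(rel[:, 2] + cell_size, -radius, radius)
    safe_r = np.where(radius > 0, radius, 1.0)
    t0 = np.arcsin(np.clip(z0 / safe_r, -1.0, 1.0))
    t1 = np.arcsin(np.clip(z1 / safe_r, -1.0, 1.0))

    # theta nodes: (M, K)
    half = 0.5 * (t1 - t0)
    mid = 0.5 * (t1 + t0)
    theta = mid[:, None] + half[:, None] * _gl_x[None, :]
    rz = safe_r[:, None] * np.cos(theta)  # cross-section circle radius

    area = circle_rect_area(
        rel[:, 0, None], rel[:, 0, None] + cell_size,
        rel[:, 1, None], rel[:, 1, None] + cell_size, rz)
    # dz = R cos(theta) dtheta
    integrand = area * safe_r[:, None] * np.cos(theta)
    vol = (integrand * _gl_w[None, :]).sum(axis=1) * half
    return np.where((radius > 0) & (t1 > t0), np.maximum(vol, 0.0), 0.0)


def intersection_volume_integral(cell_corner, atom_center, radius,
                                 cell_size: float = 1.0) -> float:
    """Exact intersection volume (Angstrom^3) of a sphere and a cubic cell.

    Serves as the deterministic oracle for the Monte-Carlo estimator.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return float(_sphere_box_volumes(
        np.asarray(cell_corner, dtype=float)[None, :],
        np.asarray(atom_center, dtype=float)[None, :],
        np.asarray([radius], dtype=float), cell_size)[0])


def intersection_volume_mc(cell_corner, atom_center, radius,
                           n_points: int = 1_000_000, seed: int = 0,
                           cell_size: float = 1.0) -> float:
    """Monte-Carlo estimate of the sphere-cell intersection volume.

    Draws ``n_points`` uniform points inside the cell and counts the
    fraction falling inside the sphere.  Deterministic given ``seed``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    corner = np.asarray(cell_corner, dtype=float)
    center = np.asarray(atom_center, dtype=float)
    hits = 0
    remaining = int(n_points)
    chunk = 500_000
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.random((m, 3)) * cell_size + corner
        d2 = ((pts - center) ** 2).sum(axis=1)
        hits += int((d2 <= radius * radius).sum())
        remaining -= m
    return hits / n_points * cell_size ** 3


def mc_integral_agreement(n_configs: int = 100, n_points: int = 1_000_000,
                          seed: int = 0) -> tuple[float, int]:
    """Percent agreement of the Monte-Carlo estimator with the exact
    integral over random atom/cell configurations.

    For each configuration an atom with a randomly chosen element radius is
    placed at a random position near a unit cell and every intersecting
    cell is evaluated with both methods.  Agreement is
    ``100 * (1 - sum|MC - exact| / sum(exact))``, an aggregate relative
    absolute difference; per-cell ratios are not averaged because they are
    ill-conditioned for sliver intersections whose exact volume approaches
    zero.  Returns (percent, number of cells compared).
    """
    rng = np.random.default_rng(seed)
    radii = sorted(ATOM_RADII.values())
    total_abs = total_vol = 0.0
    n_cells = 0
    for _ in range(n_configs):
        radius = radii[rng.integers(len(radii))]
        center = rng.uniform(0.0, 1.0, 3)
        lo = np.floor(center - radius).astype(int)
        hi = np.floor(center + radius).astype(int)
        for i in range(lo[0], hi[0] + 1):
            for j in range(lo[1], hi[1] + 1):
                for k in range(lo[2], hi[2] + 1):
                    exact = intersection_volume_integral((i, j, k), center,
                                                         radius)
                    if exact <= 0.0:
                        continue
                    mc = intersection_volume_mc(
                        (i, j, k), center, radius, n_points,
                        seed=int(rng.integers(2 ** 31)))
                    total_abs += abs(mc - exact)
                    total_vol += exact
                    n_cells += 1
    return 100.0 * (1.0 - total_abs / total_vol), n_cells


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

def _iter_channels(s: ComplexStructure):
    for chain_idx, chain in enumerate(s.chains):
        for element in ELEMENTS:
            mask = chain.element == element
            if mask.any():
                yield _channel_index(chain_idx, element), element, \
                    chain.coords[mask]


def encode_one_hot(s: ComplexStructure, center, cfg: EncodingConfig) -> VoxelGrid:
    """Mark the cell containing each atom with 1 in its element x chain channel."""
    n = cfg.grid_side
    origin = _grid_origin(center, cfg)
    values = np.zeros((n, n, n, len(CHANNELS)), dtype=np.float32)
    for ch, _, coords in _iter_channels(s):
        idx = np.floor((coords - origin) / cfg.cell_size).astype(int)
        ok = np.all((idx >= 0) & (idx < n), axis=1)
        idx = idx[ok]
        values[idx[:, 0], idx[:, 1], idx[:, 2], ch] = 1.0
    return VoxelGrid(values, tuple(origin), tuple(np.asarray(center, float)),
                     "one_hot")


def encode_volume(s: ComplexStructure, center, cfg: EncodingConfig) -> VoxelGrid:
    """Store per cell the summed sphere-cell intersection volume per channel."""
    n = cfg.grid_side
    cs = cfg.cell_size
    origin = _grid_origin(center, cfg)
    values = np.zeros((n, n, n, len(CHANNELS)), dtype=np.float32)
    for ch, element, coords in _iter_channels(s):
        radius = cfg.atom_radii[element]
        # sphere entirely outside the box contributes nothing
        inside = np.all((coords + radius > origin)
                        & (coords - radius < origin + n * cs), axis=1)
        coords = coords[inside]
        if len(coords) == 0:
            continue
        cells, atom_centers = [], []
        for atom in coords:
            lo = np.floor((atom - radius - origin) / cs).astype(int)
            hi = np.floor((atom + radius - origin) / cs).astype(int)
            lo = np.maximum(lo, 0)
            hi = np.minimum(hi, n - 1)
            if np.any(hi < lo):
                continue
            gx, gy, gz = np.meshgrid(*(np.arange(a, b + 1)
                                       for a, b in zip(lo, hi)), indexing="ij")
            cell_idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
            cells.append(cell_idx)
            atom_centers.append(np.repeat(atom[None, :], len(cell_idx), axis=0))
        if not cells:
            continue
        cell_idx = np.concatenate(cells)
        atom_centers = np.concatenate(atom_centers)
        corners = origin + cell_idx * cs
        if cfg.volume_method == "integral":
            vols = _sphere_box_volumes(
                corners, atom_centers,
                np.full(len(corners), radius), cs)
        else:
            ss = np.random.SeedSequence([cfg.seed, ch])
            seeds = ss.generate_state(len(corners))
            vols = np.array([
                intersection_volume_mc(c, a, radius, cfg.mc_points, int(sd), cs)
                for c, a, sd in zip(corners, atom_centers, seeds)])
        np.add.at(values, (cell_idx[:, 0], cell_idx[:, 1], cell_idx[:, 2],
                           np.full(len(cell_idx), ch)), vols.astype(np.float32))
    return VoxelGrid(values, tuple(origin), tuple(np.asarray(center, float)),
                     "volume")


def encode_distance(s: ComplexStructure, center, cfg: EncodingConfig) -> VoxelGrid:
    """Store per cell the distance (cell center to nearest atom) per channel.

    Distances are capped at ``max_render_distance`` (cells beyond the cap
    stay 0) and clamped below at ``distance_clamp``.
    """
    n = cfg.grid_side
    cs = cfg.cell_size
    origin = _grid_origin(center, cfg)
    values = np.zeros((n, n, n, len(CHANNELS)), dtype=np.float32)
    coords_1d = [origin[d] + (np.arange(n) + 0.5) * cs for d in range(3)]
    gx, gy, gz = np.meshgrid(*coords_1d, indexing="ij")
    cell_centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    for ch, _, coords in _iter_channels(s):
        tree = cKDTree(coords)
        dist, _ = tree.query(cell_centers,
                             distance_upper_bound=cfg.max_render_distance)
        vals = np.where(np.isfinite(dist),
                        np.maximum(dist, cfg.distance_clamp), 0.0)
        values[..., ch] = vals.reshape(n, n, n).astype(np.float32)
    return VoxelGrid(values, tuple(origin), tuple(np.asarray(center, float)),
                     "distance")


_ENCODERS = {"one_hot": encode_one_hot, "volume": encode_volume,
             "distance": encode_distance}


def render(s: ComplexStructure, cfg: EncodingConfig,
           center=None) -> VoxelGrid:
    """Convenience pipeline: interface -> center -> configured encoder.

    ``center`` overrides the interface center (used by displacement
    augmentation, which re-renders at a shifted center).
    """
    from .preprocess import compute_interface

    if center is None:
        center = compute_interface(s).center
    return _ENCODERS[cfg.encoding](s, center, cfg)
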