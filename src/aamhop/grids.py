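"""Voxel-grid data model for amino-acid interaction fields.

An interaction-field descriptor lives on a regular isotropic 3D grid whose
frame origin coincides with the compound's center of mass.  This module
provides the grid container, the 10 Å spherical evaluation mask, rigid
transforms and their discrete search lattice, masked first/second moments,
and OpenDX scalar-field I/O.

Conventions
-----------
* Voxel center of index ``(i, j, k)`` is ``origin + spacing * (i, j, k)``.
* Euler angles use the Z-Y-Z convention, ``R = Rz(alpha) @ Ry(beta) @ Rz(gamma)``,
  angles in degrees, ``alpha, gamma in [0, 360)``, ``beta in [0, 180]``.
* Integrals are discretized as voxel-center sums times ``spacing**3``; the
  volume factor cancels in every moment/correlation ratio, so moments are
  plain means and field files need no renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation


class GridExtentError(ValueError):
    """A masked lookup would fall outside the grid extent."""


class GridParseError(ValueError):
    """An OpenDX file could not be parsed as a supported scalar field."""


@dataclass
class VoxelGrid:
    """Regular isotropic scalar field.

    Parameters
    ----------
    origin : (3,) array-like
        Cartesian position (Å) of the center of voxel (0, 0, 0).
    spacing : float
        Isotropic voxel edge length in Å.
    values : ndarray, shape (nx, ny, nz)
        Scalar field sampled at voxel centers.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center coordinates, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape).transpose(1, 2, 3, 0)
        return self.origin + self.spacing * idx

    def upper_corner(self) -> np.ndarray:
        """Center of the last voxel along each axis."""
        return self.origin + self.spacing * (np.asarray(self.shape) - 1)

    def copy_with(self, values: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(self.origin.copy(), self.spacing, values)

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) <= tol
            and bool(np.all(np.abs(self.origin - other.origin) <= tol))
        )


@dataclass(frozen=True)
class SphericalMask:
    """Sharp spherical cutoff of radius 10 Å (default) around the frame origin."""

    radius: float = 10.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("mask radius must be positive")


@dataclass(frozen=True)
class RigidTransform:
    """Z-Y-Z Euler rotation (degrees) plus a translation (Å)."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    s: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def rotation_matrix(self) -> np.ndarray:
        return euler_zyz_matrix(self.alpha, self.beta, self.gamma)

    def sort_key(self) -> tuple[float, ...]:
        return (self.alpha, self.beta, self.gamma, *self.s)


IDENTITY = RigidTransform()


def euler_zyz_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix for intrinsic Z-Y-Z Euler angles in degrees."""
    return Rotation.from_euler("ZYZ", [alpha, beta, gamma], degrees=True).as_matrix()


@dataclass
class SearchGrid:
    """Discrete lattice of rigid transforms for the similarity grid search.

    Defaults follow a 10 degree angular step and a 1 Å translation step with
    a ±5 Å range per axis.  The identity transform is always a lattice member.
    Gimbal-redundant Euler triples (beta = 0 or 180, where only alpha+gamma or
    alpha−gamma matters) are deduplicated.
    """

    angle_step: float = 10.0
    trans_step: float = 1.0
    trans_range: float = 5.0

    def __post_init__(self) -> None:
        if self.angle_step <= 0 or self.trans_step <= 0:
            raise ValueError("search steps must be positive")
        if self.trans_range < 0:
            raise ValueError("translation range must be non-negative")

    def euler_angles(self) -> list[tuple[float, float, float]]:
        """Sampled (alpha, beta, gamma), deduplicated, identity first."""
        alphas = np.arange(0.0, 360.0, self.angle_step)
        betas = np.arange(0.0, 180.0 + 0.5 * self.angle_step, self.angle_step)
        betas = betas[betas <= 180.0 + 1e-9]
        out: list[tuple[float, float, float]] = []
        seen: set[tuple[float, float]] = set()
        for beta in betas:
            if abs(beta) < 1e-9 or abs(beta - 180.0) < 1e-9:
                # only alpha ± gamma matters; sample gamma = 0 with all alphas
                for alpha in alphas:
                    key = (round(float(alpha), 6), round(float(beta), 6))
                    if key not in seen:
                        seen.add(key)
                        out.append((float(alpha), float(beta), 0.0))
            else:
                for alpha in alphas:
                    for gamma in alphas:
                        out.append((float(alpha), float(beta), float(gamma)))
        out.sort()
        return out

    def translations(self) -> list[tuple[float, float, float]]:
        """Sampled translation vectors, lexicographic, containing the origin."""
        n = int(np.floor(self.trans_range / self.trans_step + 1e-9))
        axis = self.trans_step * np.arange(-n, n + 1)
        out = [
            (float(x), float(y), float(z)) for x in axis for y in axis for z in axis
        ]
        return out

    def transforms(self) -> list[RigidTransform]:
        """Full lattice, sorted lexicographically by (alpha,beta,gamma,X,Y,Z)."""
        return [
            RigidTransform(a, b, g, s)
            for (a, b, g) in self.euler_angles()
            for s in self.translations()
        ]

    @property
    def n_rotations(self) -> int:
        return len(self.euler_angles())

    @property
    def n_translations(self) -> int:
        return len(self.translations())


@dataclass(frozen=True)
class MaskedMoments:
    """First and second moments of a field over a (shifted) spherical mask."""

    first: float
    second: float

    @property
    def variance(self) -> float:
        return self.second - self.first * self.first


def mask_voxels(
    grid: VoxelGrid,
    mask: SphericalMask,
    center_offset: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Indices of voxels whose centers r satisfy ``|r + s| <= radius``.

    The mask sphere is centered at ``-center_offset`` in the grid frame.

    Returns
    -------
    ndarray of shape (n_voxels, 3), integer indices.

    Raises
    ------
    GridExtentError
        If the sphere is not fully contained in the voxel-center bounding box;
        the message names the padding required per axis.
    """
    s = np.asarray(center_offset, dtype=float)
    center = -s
    lo = grid.origin
    hi = grid.upper_corner()
    deficit_lo = np.maximum(lo - (center - mask.radius), 0.0)
    deficit_hi = np.maximum((center + mask.radius) - hi, 0.0)
    if np.any(deficit_lo > 1e-9) or np.any(deficit_hi > 1e-9):
        raise GridExtentError(
            f"mask sphere (center {center.tolist()}, radius {mask.radius}) exceeds "
            f"the grid extent; pad by {np.maximum(deficit_lo, deficit_hi).round(3).tolist()} Å per axis"
        )
    centers = grid.voxel_centers()
    d2 = np.sum((centers + s) ** 2, axis=-1)
    idx = np.argwhere(d2 <= mask.radius**2 + 1e-12)
    return idx


def masked_moments(
    grid: VoxelGrid,
    mask: SphericalMask,
    s: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> MaskedMoments:
    """Mean and mean-square of the field over the shifted mask.

    Discrete analogue of the normalized integrals defining the shifted
    library moments and the central reference moments: the voxel-volume
    factor cancels between numerator and denominator.
    """
    idx = mask_voxels(grid, mask, s)
    if idx.shape[0] == 0:
        raise ValueError("mask contains no voxels")
    vals = grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return MaskedMoments(first=float(vals.mean()), second=float(np.mean(vals**2)))


def rotate_field(grid: VoxelGrid, angles: tuple[float, float, float]) -> VoxelGrid:
    """Resample the field after rotating the frame about the origin.

    The returned grid h satisfies ``h(p) = g(R(alpha,beta,gamma) @ p)`` at every
    voxel center p, with trilinear interpolation; sample points outside the
    extent read as zero.  Grid geometry is unchanged.
    """
    if all(abs(a) < 1e-12 for a in angles):
        return grid.copy_with(grid.values.copy())
    R = euler_zyz_matrix(*angles)
    centers = grid.voxel_centers()  # (nx,ny,nz,3)
    sample = centers @ R.T  # g evaluated at R @ p
    coords = (sample - grid.origin) / grid.spacing
    # snap to the lattice where rounding noise would push a lattice-exact
    # rotation (90° multiples) infinitesimally outside the extent
    near = np.rint(coords)
    coords = np.where(np.abs(coords - near) < 1e-9, near, coords)
    vals = map_coordinates(
        grid.values, coords.transpose(3, 0, 1, 2), order=1, mode="constant", cval=0.0
    )
    return grid.copy_with(vals)


@dataclass
class AAMDescriptor:
    """Per-compound amino-acid interaction map.

    One probe-center-of-mass density field per amino-acid side-chain probe,
    all on a shared grid whose frame origin is the compound's center of mass.
    """

    compound_id: str
    fields: dict[str, VoxelGrid] = field(default_factory=dict)
    conformer_id: int = 0

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("descriptor must contain at least one probe field")
        grids = list(self.fields.values())
        ref = grids[0]
        for name, g in self.fields.items():
            if not ref.same_geometry(g):
                raise ValueError(f"probe field {name!r} has mismatched grid geometry")
            if np.min(g.values) < -1e-12:
                raise ValueError(f"probe field {name!r} has negative density values")

    @property
    def probes(self) -> list[str]:
        return list(self.fields.keys())

    @property
    def geometry(self) -> VoxelGrid:
        """Any member grid (they all share geometry)."""
        return next(iter(self.fields.values()))


# ---------------------------------------------------------------------------
# OpenDX scalar-field I/O (isotropic regular grids only)
# ---------------------------------------------------------------------------

def write_grid(grid: VoxelGrid, path, probe: str | None = None) -> None:
    """Write a grid as an OpenDX scalar field (regular positions, one component)."""
    nx, ny, nz = grid.shape
    lines = []
    if probe is not None:
        lines.append(f"# probe: {probe}")
    lines.append(f"object 1 class gridpositions counts {nx} {ny} {nz}")
    lines.append("origin {:.6f} {:.6f} {:.6f}".format(*grid.origin))
    lines.append(f"delta {grid.spacing:.6f} 0.000000 0.000000")
    lines.append(f"delta 0.000000 {grid.spacing:.6f} 0.000000")
    lines.append(f"delta 0.000000 0.000000 {grid.spacing:.6f}")
    lines.append(f"object 2 class gridconnections counts {nx} {ny} {nz}")
    lines.append(
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows"
    )
    flat = grid.values.ravel(order="C")
    for i in range(0, flat.size, 3):
        chunk = flat[i : i + 3]
        lines.append(" ".join(f"{v:.10g}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_grid(path) -> tuple[VoxelGrid, str | None]:
    """Read an OpenDX scalar field written by :func:`write_grid` or compatible.

    Returns the grid and the probe name from a ``# probe:`` comment, if any.
    Only isotropic regular grids with a single scalar component are accepted;
    parse errors carry the offending line number.
    """
    probe: str | None = None
    counts: tuple[int, int, int] | None = None
    origin: np.ndarray | None = None
    deltas: list[np.ndarray] = []
    data: list[float] = []
    n_items: int | None = None
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("# probe:"):
                    probe = line.split(":", 1)[1].strip()
                continue
            structural = line.startswith(("object", "attribute", "origin", "delta"))
            if in_data and n_items is not None and len(data) < n_items and not structural:
                try:
                    data.extend(float(t) for t in line.split())
                except ValueError as exc:
                    raise GridParseError(f"line {lineno}: bad data token ({exc})")
                continue
            if line.startswith("object") and "gridpositions" in line:
                toks = line.split()
                try:
                    counts = tuple(int(t) for t in toks[-3:])  # type: ignore[assignment]
                except ValueError:
                    raise GridParseError(f"line {lineno}: bad gridpositions counts")
            elif line.startswith("origin"):
                try:
                    origin = np.array([float(t) for t in line.split()[1:4]])
                except ValueError:
                    raise GridParseError(f"line {lineno}: bad origin")
            elif line.startswith("delta"):
                try:
                    deltas.append(np.array([float(t) for t in line.split()[1:4]]))
                except ValueError:
                    raise GridParseError(f"line {lineno}: bad delta")
            elif line.startswith("object") and "class array" in line:
                toks = line.split()
                if "items" not in toks:
                    raise GridParseError(f"line {lineno}: array header missing items")
                try:
                    n_items = int(toks[toks.index("items") + 1])
                except (ValueError, IndexError):
                    raise GridParseError(f"line {lineno}: bad item count")
                in_data = "data" in toks and "follows" in toks
                if not in_data:
                    raise GridParseError(f"line {lineno}: only 'data follows' supported")
            elif line.startswith("attribute") or line.startswith("object"):
                continue
    if counts is None or origin is None or len(deltas) != 3 or n_items is None:
        raise GridParseError("incomplete OpenDX header (counts/origin/deltas/items)")
    D = np.array(deltas)
    off_diag = D - np.diag(np.diag(D))
    if np.any(np.abs(off_diag) > 1e-9):
        raise GridParseError("non-axis-aligned deltas are not supported")
    diag = np.diag(D)
    if np.any(diag <= 0) or np.max(np.abs(diag - diag[0])) > 1e-9:
        raise GridParseError(
            f"anisotropic spacing {diag.tolist()} not supported; grids must be isotropic"
        )
    if n_items != counts[0] * counts[1] * counts[2]:
        raise GridParseError(
            f"item count {n_items} != product of shape {counts}"
        )
    if len(data) != n_items:
        raise GridParseError(f"expected {n_items} data values, found {len(data)}")
    values = np.array(data).reshape(counts, order="C")
    return VoxelGrid(origin=origin, spacing=float(diag[0]), values=values), probe
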