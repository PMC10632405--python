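"""The interaction-field similarity score and its SVD-accelerated search.

The score between a reference and a library compound is the maximum over
rigid transforms (R, s) of the probe-averaged, spherically masked cosine

    cos(R, s) = (1/N_a) Σ_a  Σ_m [G_a(r_m) − Ḡ_a(s)] [g_a(R(r_m+s)) − ḡ_a]
                             / ( M σ_G(s) σ_g )

where the sum runs over the M voxels with |r + s| ≤ radius, Ḡ_a(s)/σ_G(s)
are the library field's mean/std over the shifted mask, and ḡ_a/σ_g are the
reference field's mean/std over the central mask (s-independent).  Because
translations are lattice-exact, the set {r + s} over the shifted mask is
exactly the central-mask voxel set, so the rotated reference is only ever
sampled on the central sphere.

The brute-force search evaluates cos on the full transform lattice.  The
accelerated path factorizes the stack of rotated reference fields (one row
per sampled rotation, restricted to the central mask) with a truncated SVD,

    g_a(R(·)) − ḡ_a = Σ_μ V_aμ(R) Ξ_aμ U_aμ(·),

truncated at the smallest rank whose cumulative explained-variance ratio
exceeds the cutoff (0.99 by default), and reconstructs every cos(R, s) from
the per-translation projections λ_aμ(s) by a cheap double sum — reducing the
field integrations from N_a·N_R·N_s to N_a·N_μ·N_s.

Because the library-side term is centered on the shared mask, any constant
offset of the reference rows cancels exactly in the numerator; centering the
SVD stack by ḡ_a therefore changes no score (the mean-cancellation identity)
and only improves truncation behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import (
    AAMDescriptor,
    RigidTransform,
    SearchGrid,
    SphericalMask,
    mask_voxels,
    rotate_field,
)


class DegenerateFieldError(ValueError):
    """Zero masked variance makes the correlation undefined for a probe."""


@dataclass
class SimilarityResult:
    """Score, maximizing transform, and per-probe correlations at the argmax."""

    score: float
    argmax_transform: RigidTransform
    per_probe: dict[str, float]
    method: str

    def __post_init__(self) -> None:
        if abs(self.score) > 1 + 1e-9:
            raise ValueError(f"score {self.score} outside [-1, 1]")


@dataclass
class SVDBasis:
    """Truncated factorization of the rotated-reference field stack.

    Per probe ``a``: spatial modes ``U`` (n_modes × M mask voxels), singular
    values ``xi`` (descending), rotation coefficients ``V`` (n_rotations ×
    n_modes, unit-norm columns), and explained-variance ratios of the full
    spectrum.  Shared: the rotation list, central-mask indices, and the
    reference central moments.
    """

    rotations: list[tuple[float, float, float]]
    mask: SphericalMask
    center_idx: np.ndarray  # (M, 3)
    probes: list[str]
    U: dict[str, np.ndarray] = field(default_factory=dict)
    xi: dict[str, np.ndarray] = field(default_factory=dict)
    V: dict[str, np.ndarray] = field(default_factory=dict)
    evr: dict[str, np.ndarray] = field(default_factory=dict)
    n_modes: dict[str, int] = field(default_factory=dict)
    g1: dict[str, float] = field(default_factory=dict)
    g_std: dict[str, float] = field(default_factory=dict)
    reconstruction_error: dict[str, float] = field(default_factory=dict)


def _grid_values_at(grid, idx: np.ndarray) -> np.ndarray:
    return grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]


def _shift_to_lattice(s, spacing: float) -> np.ndarray:
    sv = np.asarray(s, dtype=float)
    steps = sv / spacing
    rounded = np.rint(steps)
    if np.max(np.abs(steps - rounded)) > 1e-6:
        raise ValueError(
            f"translation {sv.tolist()} is not a multiple of the grid spacing "
            f"{spacing}; translations must be lattice-exact"
        )
    return rounded.astype(int)


def _check_geometry(ref: AAMDescriptor, lib: AAMDescriptor) -> None:
    if set(ref.probes) != set(lib.probes):
        raise ValueError(
            f"probe sets differ: {sorted(ref.probes)} vs {sorted(lib.probes)}"
        )
    if not ref.geometry.same_geometry(lib.geometry):
        raise ValueError("descriptors must share grid geometry")


def _center_mask(descriptor: AAMDescriptor, mask: SphericalMask) -> np.ndarray:
    return mask_voxels(descriptor.geometry, mask, (0.0, 0.0, 0.0))


def _lib_mask_idx(
    center_idx: np.ndarray, shift_vox: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Voxel indices where the library field is read for translation s.

    The masked voxels in r-space are r = m − s for central-mask points m;
    in index space that is the central-mask indices minus the shift.
    """
    idx = center_idx - shift_vox[None, :]
    if idx.min() < 0 or np.any(idx >= np.asarray(shape)[None, :]):
        raise ValueError(
            "shifted mask leaves the grid; enlarge the grid padding "
            "(mask radius + translation range)"
        )
    return idx


def _ref_center_stats(
    ref: AAMDescriptor, center_idx: np.ndarray
) -> tuple[dict[str, float], dict[str, float]]:
    g1, g_std = {}, {}
    for name in ref.probes:
        vals = _grid_values_at(ref.fields[name], center_idx)
        g1[name] = float(vals.mean())
        var = float(np.mean(vals**2) - vals.mean() ** 2)
        g_std[name] = float(np.sqrt(max(var, 0.0)))
        if g_std[name] <= 1e-300:
            raise DegenerateFieldError(
                f"reference probe field {name!r} has zero masked variance"
            )
    return g1, g_std


def _lib_centered(
    lib: AAMDescriptor,
    center_idx: np.ndarray,
    shift_vox: np.ndarray,
    skip_degenerate: bool,
) -> dict[str, np.ndarray] | None:
    """Per probe, the centered library values over the shifted mask, or None
    when degenerate and skipping is enabled."""
    out = {}
    idx = _lib_mask_idx(center_idx, shift_vox, lib.geometry.shape)
    for name in lib.probes:
        vals = _grid_values_at(lib.fields[name], idx)
        mean = vals.mean()
        var = float(np.mean(vals**2) - mean**2)
        std = np.sqrt(max(var, 0.0))
        if std <= 1e-300:
            if skip_degenerate:
                return None
            raise DegenerateFieldError(
                f"library probe field {name!r} has zero variance under the "
                f"mask shifted by {(-shift_vox).tolist()} voxels"
            )
        out[name] = (vals - mean) / std
    return out


def cos_at(
    ref: AAMDescriptor,
    lib: AAMDescriptor,
    t: RigidTransform,
    mask: SphericalMask = SphericalMask(),
) -> float:
    """Masked, probe-averaged cosine at a single rigid transform."""
    result = _cos_at_detailed(ref, lib, t, mask)
    return result[0]


def _cos_at_detailed(ref, lib, t, mask):
    _check_geometry(ref, lib)
    geom = ref.geometry
    center_idx = _center_mask(ref, mask)
    g1, g_std = _ref_center_stats(ref, center_idx)
    shift_vox = _shift_to_lattice(t.s, geom.spacing)
    lib_c = _lib_centered(lib, center_idx, shift_vox, skip_degenerate=False)
    M = center_idx.shape[0]
    per_probe = {}
    for name in ref.probes:
        rot = rotate_field(ref.fields[name], t.angles)
        gvals = _grid_values_at(rot, center_idx)
        # lib_c is centered and divided by its std already
        num = float(np.dot(lib_c[name], gvals - g1[name]))
        per_probe[name] = num / (M * g_std[name])
    score = float(np.mean(list(per_probe.values())))
    return score, per_probe


def aam_score_bruteforce(
    ref: AAMDescriptor,
    lib: AAMDescriptor,
    search: SearchGrid = SearchGrid(),
    mask: SphericalMask = SphericalMask(),
    skip_degenerate: bool = False,
) -> SimilarityResult:
    """Exhaustive maximum of the masked cosine over the transform lattice.

    Ties are broken by lexicographic (alpha, beta, gamma, X, Y, Z) order with
    the identity first, so results are deterministic.
    """
    _check_geometry(ref, lib)
    geom = ref.geometry
    center_idx = _center_mask(ref, mask)
    M = center_idx.shape[0]
    g1, g_std = _ref_center_stats(ref, center_idx)
    rotations = search.euler_angles()
    translations = search.translations()
    probes = ref.probes

    # Library side: centered/normalized values per translation (N_s × M).
    lib_rows: list[dict[str, np.ndarray] | None] = []
    for s in translations:
        shift_vox = _shift_to_lattice(s, geom.spacing)
        lib_rows.append(_lib_centered(lib, center_idx, shift_vox, skip_degenerate))
    valid_s = [i for i, row in enumerate(lib_rows) if row is not None]
    if not valid_s:
        raise DegenerateFieldError("library field degenerate at every translation")
    lib_mat = {
        name: np.stack([lib_rows[i][name] for i in valid_s]) for name in probes
    }  # (n_valid_s, M)

    best_score = -np.inf
    best: tuple[int, int] | None = None  # (rotation index, valid-s index)
    per_rot_scores = np.empty(len(valid_s))
    best_per_probe: dict[str, float] = {}
    for ri, angles in enumerate(rotations):
        per_rot_scores[:] = 0.0
        probe_cols = {}
        for name in probes:
            rot = rotate_field(ref.fields[name], angles)
            gc = (_grid_values_at(rot, center_idx) - g1[name]) / (M * g_std[name])
            probe_cols[name] = lib_mat[name] @ gc
            per_rot_scores += probe_cols[name]
        per_rot_scores /= len(probes)
        si = int(np.argmax(per_rot_scores))
        if per_rot_scores[si] > best_score + 1e-15:
            best_score = float(per_rot_scores[si])
            best = (ri, si)
            best_per_probe = {name: float(probe_cols[name][si]) for name in probes}
    ri, si = best
    a, b, g = rotations[ri]
    t = RigidTransform(a, b, g, translations[valid_s[si]])
    return SimilarityResult(
        score=float(np.clip(best_score, -1.0, 1.0)),
        argmax_transform=t,
        per_probe=best_per_probe,
        method="bruteforce",
    )


def build_svd_basis(
    ref: AAMDescriptor,
    rotations: list[tuple[float, float, float]] | SearchGrid,
    mask: SphericalMask = SphericalMask(),
    variance_cutoff: float = 0.99,
) -> SVDBasis:
    """Factorize the rotated-reference stack per probe and truncate.

    Rows are the reference field under each sampled rotation, restricted to
    the central mask and centered by the reference's central mean; the
    truncation keeps the smallest rank whose cumulative explained-variance
    ratio (squared singular values) exceeds ``variance_cutoff``.
    """
    if isinstance(rotations, SearchGrid):
        rotations = rotations.euler_angles()
    if len(rotations) == 0:
        raise ValueError("at least one rotation is required")
    center_idx = _center_mask(ref, mask)
    g1, g_std = _ref_center_stats(ref, center_idx)
    basis = SVDBasis(
        rotations=list(rotations),
        mask=mask,
        center_idx=center_idx,
        probes=list(ref.probes),
        g1=g1,
        g_std=g_std,
    )
    for name in ref.probes:
        rows = np.stack(
            [
                _grid_values_at(rotate_field(ref.fields[name], angles), center_idx)
                - g1[name]
                for angles in rotations
            ]
        )  # (N_R, M)
        Umat, S, Vh = np.linalg.svd(rows, full_matrices=False)
        power = S**2
        total = power.sum()
        evr = power / total if total > 0 else power
        if total <= 0:
            raise DegenerateFieldError(f"reference probe field {name!r} is all zero")
        if variance_cutoff >= 1.0 - 1e-12:
            k = int(np.sum(S > S[0] * 1e-12)) if S.size else 1
        else:
            k = int(np.searchsorted(np.cumsum(evr), variance_cutoff) + 1)
        k = max(1, min(k, S.size))
        basis.V[name] = Umat[:, :k]  # rotation coefficients, unit-norm columns
        basis.xi[name] = S[:k]
        basis.U[name] = Vh[:k, :]  # spatial modes on the mask
        basis.evr[name] = evr
        basis.n_modes[name] = k
        recon = basis.V[name] @ np.diag(basis.xi[name]) @ basis.U[name]
        basis.reconstruction_error[name] = float(np.max(np.abs(recon - rows)))
    return basis


def lambda_field(
    lib: AAMDescriptor,
    basis: SVDBasis,
    s,
    mask: SphericalMask | None = None,
) -> dict[str, np.ndarray]:
    """Per-probe projections λ_aμ(s) of the centered library field onto the
    spatial modes, normalized like the brute-force cosine denominator."""
    spacing = lib.geometry.spacing
    shift_vox = _shift_to_lattice(s, spacing)
    M = basis.center_idx.shape[0]
    lib_c = _lib_centered(lib, basis.center_idx, shift_vox, skip_degenerate=False)
    out = {}
    for name in basis.probes:
        out[name] = (basis.U[name] @ lib_c[name]) / (M * basis.g_std[name])
    return out


def aam_score_svd(
    basis: SVDBasis,
    lib: AAMDescriptor,
    search: SearchGrid = SearchGrid(),
    mask: SphericalMask | None = None,
    skip_degenerate: bool = False,
) -> SimilarityResult:
    """Lattice maximum of the cosine reconstructed through the SVD basis.

    λ is computed once per (probe, mode, translation); cos(R, s) for every
    rotation follows from the cheap double sum Σ_a Σ_μ V_aμ(R) Ξ_aμ λ_aμ(s).
    Tie-breaking matches the brute-force path.
    """
    rotations = search.euler_angles()
    if rotations != basis.rotations:
        raise ValueError("basis rotations must equal the search rotations")
    translations = search.translations()
    spacing = lib.geometry.spacing
    probes = basis.probes
    if set(lib.probes) != set(probes):
        raise ValueError("library probes differ from basis probes")
    M = basis.center_idx.shape[0]

    lam_rows: list[dict[str, np.ndarray] | None] = []
    for s in translations:
        shift_vox = _shift_to_lattice(s, spacing)
        lib_c = _lib_centered(lib, basis.center_idx, shift_vox, skip_degenerate)
        if lib_c is None:
            lam_rows.append(None)
            continue
        lam_rows.append(
            {
                name: (basis.U[name] @ lib_c[name]) / (M * basis.g_std[name])
                for name in probes
            }
        )
    valid_s = [i for i, row in enumerate(lam_rows) if row is not None]
    if not valid_s:
        raise DegenerateFieldError("library field degenerate at every translation")

    n_rot = len(rotations)
    scores = np.zeros((n_rot, len(valid_s)))
    per_probe_scores = {}
    for name in probes:
        lam = np.stack([lam_rows[i][name] for i in valid_s])  # (n_s, k)
        contrib = (basis.V[name] * basis.xi[name][None, :]) @ lam.T  # (N_R, n_s)
        per_probe_scores[name] = contrib
        scores += contrib
    scores /= len(probes)
    flat = int(np.argmax(scores))
    ri, si = divmod(flat, len(valid_s))
    a, b, g = rotations[ri]
    t = RigidTransform(a, b, g, translations[valid_s[si]])
    return SimilarityResult(
        score=float(np.clip(scores[ri, si], -1.0, 1.0)),
        argmax_transform=t,
        per_probe={n: float(per_probe_scores[n][ri, si]) for n in probes},
        method="svd",
    )


def aam_score(
    ref: AAMDescriptor,
    lib: AAMDescriptor,
    search: SearchGrid = SearchGrid(),
    mask: SphericalMask = SphericalMask(),
    method: str = "svd",
    svd_cutoff: float = 0.99,
    skip_degenerate: bool = False,
    basis: SVDBasis | None = None,
) -> SimilarityResult:
    """Convenience front end selecting the brute-force or SVD path."""
    if method == "bruteforce":
        return aam_score_bruteforce(ref, lib, search, mask, skip_degenerate)
    if method == "svd":
        if basis is None:
            basis = build_svd_basis(ref, search, mask, svd_cutoff)
        return aam_score_svd(basis, lib, search, mask, skip_degenerate)
    raise ValueError(f"unknown method {method!r}")
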