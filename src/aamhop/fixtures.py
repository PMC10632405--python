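"""Synthetic descriptor generators for testing and benchmarking.

Every stage of the screen can be exercised without molecules or downloads:
parametric sum-of-Gaussian "blob" descriptors stand in for probe densities,
and a planted library (near-duplicates of a reference plus independent
decoys) stands in for an annotated screening library.

The test-scale geometry keeps full brute-force-versus-SVD sweeps fast on a
single CPU while exercising every code path: 13³ voxels at 1 Å spacing, a
4 Å mask, coarse 45–90° angular steps and a ±2 Å translation range.  The
4 Å radius is the largest for which every mask shifted by ±2 Å stays inside
a 13³ grid.  Production-scale settings remain available through the screen
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import AAMDescriptor, SearchGrid, SphericalMask, VoxelGrid

DEFAULT_PROBE_NAMES = ("ASN", "CYM", "PHE", "THR")


def fixture_geometry(n: int = 13, spacing: float = 1.0) -> VoxelGrid:
    """The 13³ test-scale grid, centered on the origin."""
    half = (n - 1) // 2
    origin = -spacing * half * np.ones(3)
    return VoxelGrid(origin=origin, spacing=spacing, values=np.zeros((n, n, n)))


def fixture_mask() -> SphericalMask:
    return SphericalMask(radius=4.0)


def fixture_search(angle_step: float = 45.0, trans_range: float = 2.0) -> SearchGrid:
    return SearchGrid(angle_step=angle_step, trans_step=1.0, trans_range=trans_range)


@dataclass
class BlobSpec:
    """Recipe for one sum-of-Gaussians field: (center Å, width Å, amplitude)."""

    blobs: list[tuple[tuple[float, float, float], float, float]]
    geometry: VoxelGrid = field(default_factory=fixture_geometry)
    seed: int = 0

    def __post_init__(self) -> None:
        for center, width, amp in self.blobs:
            if width <= 0:
                raise ValueError("blob widths must be positive")
            if amp < 0:
                raise ValueError("blob amplitudes must be non-negative")


def blob_field(
    blobs: list[tuple[tuple[float, float, float], float, float]],
    geometry: VoxelGrid,
) -> VoxelGrid:
    """Sum of isotropic Gaussians sampled at voxel centers, unit-max scaled."""
    pts = geometry.voxel_centers()
    vals = np.zeros(geometry.shape)
    for center, width, amp in blobs:
        d2 = np.sum((pts - np.asarray(center)) ** 2, axis=-1)
        vals += amp * np.exp(-d2 / (2.0 * width**2))
    peak = vals.max()
    if peak > 0:
        vals = vals / peak
    return geometry.copy_with(vals)


def blob_descriptor(
    spec: BlobSpec,
    probes: tuple[str, ...] = DEFAULT_PROBE_NAMES,
    compound_id: str = "blob",
) -> AAMDescriptor:
    """Descriptor with the same blob field on every probe channel.

    An empty or all-zero blob list yields a degenerate (flat) field, which
    the similarity layer rejects by design.
    """
    f = blob_field(spec.blobs, spec.geometry)
    return AAMDescriptor(
        compound_id=compound_id, fields={p: f.copy_with(f.values.copy()) for p in probes}
    )


def _random_blobs(
    rng: np.random.Generator,
    n_blobs: int,
    center_range: float,
    width_range: tuple[float, float] = (0.7, 1.1),
) -> list[tuple[tuple[float, float, float], float, float]]:
    centers = rng.uniform(-center_range, center_range, size=(n_blobs, 3))
    widths = rng.uniform(*width_range, size=n_blobs)
    amps = rng.uniform(0.5, 1.0, size=n_blobs)
    return [
        (tuple(c), float(w), float(a)) for c, w, a in zip(centers, widths, amps)
    ]


def random_descriptor(
    seed: int,
    probes: tuple[str, ...] = DEFAULT_PROBE_NAMES,
    geometry: VoxelGrid | None = None,
    n_blobs: int = 8,
    center_range: float = 3.0,
    compound_id: str | None = None,
) -> AAMDescriptor:
    """Independent random blob field per probe channel (deterministic per seed)."""
    geometry = geometry or fixture_geometry()
    rng = np.random.default_rng(seed)
    fields = {
        p: blob_field(_random_blobs(rng, n_blobs, center_range), geometry)
        for p in probes
    }
    return AAMDescriptor(
        compound_id=compound_id or f"rand-{seed}", fields=fields
    )


@dataclass
class PlantedEntry:
    compound_id: str
    descriptor: AAMDescriptor
    is_planted_hit: bool


def planted_library(
    n_hits: int = 5,
    n_decoys: int = 20,
    perturbation: float = 0.3,
    seed: int = 0,
    probes: tuple[str, ...] = DEFAULT_PROBE_NAMES,
    geometry: VoxelGrid | None = None,
    n_blobs: int = 8,
) -> tuple[AAMDescriptor, list[PlantedEntry]]:
    """A reference descriptor plus a labeled library of hits and decoys.

    The reference carries an independent random blob set per probe.  Hits
    are the reference recipe with every blob center jittered by an isotropic
    Gaussian of scale ``perturbation`` Å (zero perturbation reproduces the
    reference exactly); decoys carry freshly drawn blob sets.  Labels are
    returned so recovery can be checked against the screen's hit flags.
    """
    if perturbation < 0:
        raise ValueError("perturbation must be non-negative")
    geometry = geometry or fixture_geometry()
    rng = np.random.default_rng(seed)
    ref_blobs = {p: _random_blobs(rng, n_blobs, center_range=3.0) for p in probes}
    reference = AAMDescriptor(
        compound_id="reference",
        fields={p: blob_field(ref_blobs[p], geometry) for p in probes},
    )
    entries: list[PlantedEntry] = []
    for i in range(n_hits):
        fields = {}
        for p in probes:
            jittered = [
                (
                    tuple(np.asarray(c) + rng.normal(0.0, perturbation, 3)),
                    w,
                    a,
                )
                for c, w, a in ref_blobs[p]
            ]
            fields[p] = blob_field(jittered, geometry)
        entries.append(
            PlantedEntry(f"hit-{i:02d}", AAMDescriptor(f"hit-{i:02d}", fields), True)
        )
    for i in range(n_decoys):
        fields = {
            p: blob_field(_random_blobs(rng, n_blobs, center_range=3.0), geometry)
            for p in probes
        }
        entries.append(
            PlantedEntry(
                f"decoy-{i:02d}", AAMDescriptor(f"decoy-{i:02d}", fields), False
            )
        )
    return reference, entries


# A small library of drug-like molecules with both charge classes, used by
# molecule-level tests; structure chosen so Tanimoto relations are obvious
# (homologues similar, unrelated scaffolds dissimilar).
TOY_MOLECULES: list[tuple[str, str]] = [
    ("ethanol", "CCO"),
    ("propanol", "CCCO"),
    ("butanol", "CCCCO"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("acetamide", "CC(N)=O"),
    ("methylammonium", "C[NH3+]"),
    ("ethylammonium", "CC[NH3+]"),
    ("pyridinium", "c1cc[nH+]cc1"),
]


def toy_molecule_set() -> list[tuple[str, str]]:
    """(id, SMILES) pairs: ≥10 small molecules, neutral and monocationic."""
    return list(TOY_MOLECULES)
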