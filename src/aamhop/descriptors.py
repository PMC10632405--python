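"""Molecule handling, amino-acid probes, and surrogate descriptor fields.

Compounds are standardized (desalted, normalized) with RDKit, assigned a
charge class (neutral or monocation — the two classes the screen covers),
and embedded into 3D conformers.  Amino-acid side-chain probes (backbone
removed) are built from side-chain SMILES with deterministic embedding.

Descriptor fields are produced by a deterministic Boltzmann-inversion
surrogate: the probe's center of mass is placed at each voxel, the analytic
Lennard-Jones + Coulomb interaction energy with the compound is averaged
over a fixed set of quasi-uniform probe orientations, and the Boltzmann
factor exp(-E/kT) at 300 K (unit-max scaled) becomes the density.  This
reproduces the structure of an MD-derived probe center-of-mass distribution
while remaining analytic, fast and exactly reproducible; precomputed fields
in OpenDX format can be supplied instead via :func:`aamhop.grids.read_grid`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize
from scipy.spatial.transform import Rotation

from .grids import AAMDescriptor, VoxelGrid

COULOMB_K = 332.0637  # kcal·Å/(mol·e²)
BOLTZMANN_K = 0.0019872041  # kcal/(mol·K)
DEFAULT_ENERGY_CAP = 100.0  # kcal/mol
DEFAULT_N_ORIENTATIONS = 32
PROBE_EMBED_SEED = 1923  # fixed: probe geometries must be identical everywhere

# Element Lennard-Jones parameters (epsilon kcal/mol, sigma Å): a compact
# general-purpose table in the GAFF/OPLS range, sufficient for a smooth PES.
ELEMENT_LJ: dict[str, tuple[float, float]] = {
    "H": (0.0157, 2.50),
    "C": (0.0860, 3.40),
    "N": (0.1700, 3.25),
    "O": (0.2100, 2.96),
    "S": (0.2500, 3.56),
    "P": (0.2000, 3.74),
    "F": (0.0610, 3.12),
    "Cl": (0.2650, 3.47),
    "Br": (0.3200, 3.62),
    "I": (0.4000, 3.83),
}


class StandardizationError(ValueError):
    """A library record could not be parsed/standardized; carries its index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class UnsupportedChargeError(ValueError):
    """Net charge outside the screened classes {0, +1}."""


class ChargeClass(enum.Enum):
    NEUTRAL = "neutral"
    MONOCATION = "monocation"


@dataclass
class Molecule:
    """A standardized compound (topology only; conformers generated on demand)."""

    compound_id: str
    rdkit_mol: Chem.Mol
    net_charge: int

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.rdkit_mol)


@dataclass
class Molecule3D:
    """One 3D conformer with per-atom nonbonded parameters, COM at the origin."""

    compound_id: str
    elements: list[str]
    coords: np.ndarray  # (n, 3) Å
    charges: np.ndarray  # (n,) e
    epsilons: np.ndarray  # (n,) kcal/mol
    sigmas: np.ndarray  # (n,) Å
    net_charge: int
    conformer_id: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.elements) == 0:
            raise ValueError("molecule must have at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")


@dataclass
class ProbeDefinition:
    """A rigid amino-acid side-chain fragment, center of mass at the origin."""

    name: str
    elements: list[str]
    coords: np.ndarray
    charges: np.ndarray
    epsilons: np.ndarray
    sigmas: np.ndarray
    net_charge: int
    notes: str = ""


# Side chains with the backbone removed; the C-alpha attachment is capped
# with H.  Charge variants carry their own residue-style names.
SIDE_CHAIN_SMILES: dict[str, tuple[str, str]] = {
    "ALA": ("C", "alanine side chain (methane cap)"),
    "ARG": ("CCCNC(N)=[NH2+]", "arginine, guanidinium cation"),
    "ASN": ("CC(N)=O", "asparagine amide"),
    "ASP": ("CC(=O)[O-]", "aspartate carboxylate anion"),
    "ASH": ("CC(=O)O", "aspartic acid, protonated"),
    "CYS": ("CS", "cysteine thiol"),
    "CYM": ("C[S-]", "cysteine, deprotonated thiolate"),
    "GLN": ("CCC(N)=O", "glutamine amide"),
    "GLU": ("CCC(=O)[O-]", "glutamate carboxylate anion"),
    "GLH": ("CCC(=O)O", "glutamic acid, protonated"),
    "HID": ("Cc1c[nH]cn1", "histidine, delta-protonated neutral tautomer"),
    "HIE": ("Cc1cnc[nH]1", "histidine, epsilon-protonated neutral tautomer"),
    "HIP": ("Cc1c[nH]c[nH+]1", "histidine, doubly protonated cation"),
    "ILE": ("CCC(C)C", "isoleucine side chain"),
    "LEU": ("CC(C)C", "leucine side chain"),
    "LYS": ("CCCC[NH3+]", "lysine ammonium cation"),
    "LYN": ("CCCCN", "lysine, neutral amine"),
    "MET": ("CCSC", "methionine thioether"),
    "PHE": ("Cc1ccccc1", "phenylalanine (toluene)"),
    "PRO": ("C1CCNC1", "proline ring (pyrrolidine)"),
    "SER": ("CO", "serine hydroxyl (methanol)"),
    "THR": ("CCO", "threonine side chain (H-capped)"),
    "TRP": ("Cc1c[nH]c2ccccc12", "tryptophan (3-methylindole)"),
    "TYR": ("Cc1ccc(O)cc1", "tyrosine (p-cresol)"),
    "VAL": ("CCC", "valine side chain (propane)"),
}

# Fixed, documented probe orders per charge class: the four-probe core for
# monocationic references, plus doubly protonated histidine for neutral ones.
MONOCATION_PROBES = ("ASN", "CYM", "PHE", "THR")
NEUTRAL_PROBES = ("ASN", "CYM", "PHE", "THR", "HIP")


def standardize_molecule(raw, compound_id: str | None = None,
                         record_index: int | None = None) -> Molecule:
    """Desalt and normalize one SMILES string or RDKit mol.

    The largest organic fragment is retained (counter-ions dropped), the
    structure is normalized, and atoms are renumbered canonically.
    """
    if isinstance(raw, Chem.Mol):
        mol = Chem.Mol(raw)
        name = compound_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "mol")
    else:
        text = str(raw).strip()
        mol = Chem.MolFromSmiles(text)
        name = compound_id or text
        if mol is None:
            raise StandardizationError(
                f"unparsable record {name!r}", record_index=record_index
            )
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol = rdMolStandardize.FragmentParent(mol)  # desalting
    except Exception as exc:  # pragma: no cover - rdkit-internal failures
        raise StandardizationError(
            f"standardization failed for {name!r}: {exc}", record_index=record_index
        )
    order = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    mol = Chem.RenumberAtoms(mol, [int(i) for i in np.argsort(order)])
    net = Chem.GetFormalCharge(mol)
    return Molecule(compound_id=str(name), rdkit_mol=mol, net_charge=int(net))


def assign_charge_class(mol: Molecule | Molecule3D) -> ChargeClass:
    """Map net charge to the screened classes: 0 → neutral, +1 → monocation."""
    q = mol.net_charge
    if q == 0:
        return ChargeClass.NEUTRAL
    if q == 1:
        return ChargeClass.MONOCATION
    raise UnsupportedChargeError(
        f"net charge {q:+d} of {mol.compound_id!r} is outside the screened "
        "classes (neutral, monocation)"
    )


def _lj_params(symbol: str) -> tuple[float, float]:
    try:
        return ELEMENT_LJ[symbol]
    except KeyError:
        raise ValueError(f"no Lennard-Jones parameters for element {symbol!r}")


def _mol3d_from_conformer(mol: Chem.Mol, conf_id: int, compound_id: str,
                          out_id: int) -> Molecule3D:
    conf = mol.GetConformer(conf_id)
    coords = np.array(conf.GetPositions(), dtype=float)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    masses = np.array([a.GetMass() for a in mol.GetAtoms()])
    coords = coords - np.average(coords, axis=0, weights=masses)
    charges = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()]
    )
    charges = np.nan_to_num(charges, nan=0.0, posinf=0.0, neginf=0.0)
    lj = np.array([_lj_params(e) for e in elements])
    return Molecule3D(
        compound_id=compound_id,
        elements=elements,
        coords=coords,
        charges=charges,
        epsilons=lj[:, 0],
        sigmas=lj[:, 1],
        net_charge=Chem.GetFormalCharge(mol),
        conformer_id=out_id,
    )


def generate_conformers(mol: Molecule, n: int, seed: int = 0) -> list[Molecule3D]:
    """Embed up to ``n`` distance-geometry conformers, centered at their COM.

    Deterministic for a fixed seed.  Gasteiger partial charges and element
    Lennard-Jones parameters are attached per atom.
    """
    if n < 1:
        raise ValueError("number of conformers must be >= 1")
    m = Chem.AddHs(Chem.Mol(mol.rdkit_mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.pruneRmsThresh = 0.25
    params.numThreads = 1
    ids = AllChem.EmbedMultipleConfs(m, numConfs=int(n), params=params)
    if len(ids) == 0:
        raise RuntimeError(f"conformer embedding failed for {mol.compound_id!r}")
    AllChem.ComputeGasteigerCharges(m)
    return [
        _mol3d_from_conformer(m, cid, mol.compound_id, k)
        for k, cid in enumerate(ids)
    ]


@lru_cache(maxsize=None)
def get_probe(name: str) -> ProbeDefinition:
    """Build one rigid probe from its side-chain SMILES (deterministic)."""
    key = name.upper()
    if key not in SIDE_CHAIN_SMILES:
        raise KeyError(f"unknown probe {name!r}; known: {sorted(SIDE_CHAIN_SMILES)}")
    smiles, notes = SIDE_CHAIN_SMILES[key]
    m = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = PROBE_EMBED_SEED
    params.numThreads = 1
    if AllChem.EmbedMolecule(m, params) != 0:
        raise RuntimeError(f"failed to embed probe {name!r}")
    AllChem.MMFFOptimizeMolecule(m, maxIters=500)
    AllChem.ComputeGasteigerCharges(m)
    conf = m.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    elements = [a.GetSymbol() for a in m.GetAtoms()]
    masses = np.array([a.GetMass() for a in m.GetAtoms()])
    coords = coords - np.average(coords, axis=0, weights=masses)
    charges = np.nan_to_num(
        np.array([float(a.GetProp("_GasteigerCharge")) for a in m.GetAtoms()]),
        nan=0.0, posinf=0.0, neginf=0.0,
    )
    lj = np.array([_lj_params(e) for e in elements])
    return ProbeDefinition(
        name=key,
        elements=elements,
        coords=coords,
        charges=charges,
        epsilons=lj[:, 0],
        sigmas=lj[:, 1],
        net_charge=Chem.GetFormalCharge(m),
        notes=notes,
    )


def default_probe_set(charge_class: ChargeClass) -> list[ProbeDefinition]:
    """The screened probe sets: {Asn, Cys⁻, Phe, Thr}, plus His(+) for neutrals."""
    names = (
        MONOCATION_PROBES
        if charge_class is ChargeClass.MONOCATION
        else NEUTRAL_PROBES
    )
    return [get_probe(n) for n in names]


def probe_library() -> list[str]:
    """All packaged probe names (canonical side chains plus charge variants)."""
    return sorted(SIDE_CHAIN_SMILES)


# ---------------------------------------------------------------------------
# Analytic potential energy surface and Boltzmann-inversion surrogate
# ---------------------------------------------------------------------------

def default_grid_geometry(
    mol: Molecule3D,
    mask_radius: float = 10.0,
    trans_range: float = 5.0,
    spacing: float = 1.0,
) -> VoxelGrid:
    """A zero grid padding the compound by mask radius + translation range.

    Guarantees every shifted spherical-mask lookup during the transform
    search is in-bounds.
    """
    reach = float(np.max(np.abs(mol.coords))) if mol.coords.size else 0.0
    half = int(np.ceil((reach + mask_radius + trans_range) / spacing))
    n = 2 * half + 1
    origin = -spacing * half * np.ones(3)
    return VoxelGrid(origin=origin, spacing=spacing, values=np.zeros((n, n, n)))


def _pair_energy(
    points: np.ndarray,
    q_probe: float,
    eps_probe: float,
    sigma_probe: float,
    mol: Molecule3D,
    cap: float,
) -> np.ndarray:
    """LJ 12-6 (Lorentz-Berthelot) + Coulomb energy of one probe atom at
    ``points`` (m, 3) against all molecule atoms; capped above at ``cap``."""
    d = np.linalg.norm(points[:, None, :] - mol.coords[None, :, :], axis=-1)
    d = np.maximum(d, 1e-6)  # voxel on an atom center: cap applies anyway
    e = np.zeros_like(d)
    if eps_probe > 0:
        sig = 0.5 * (sigma_probe + mol.sigmas[None, :])
        eps = np.sqrt(eps_probe * mol.epsilons[None, :])
        sr6 = (sig / d) ** 6
        e += 4.0 * eps * (sr6 * sr6 - sr6)
    e += COULOMB_K * q_probe * mol.charges[None, :] / d
    return np.minimum(e.sum(axis=1), cap)


def compute_pes(
    mol: Molecule3D,
    probe_atom: tuple[float, float, float],
    grid_geometry: VoxelGrid,
    cap: float = DEFAULT_ENERGY_CAP,
) -> VoxelGrid:
    """Analytic interaction energy of a single probe atom on the grid.

    ``probe_atom`` is (partial charge e, epsilon kcal/mol, sigma Å).  The
    energy at each voxel center is the Lennard-Jones 12-6 plus Coulomb sum
    over all molecule atoms, capped above at ``cap`` kcal/mol (a voxel that
    coincides with an atom center reads exactly the cap).
    """
    q, eps, sigma = probe_atom
    pts = grid_geometry.voxel_centers().reshape(-1, 3)
    e = _pair_energy(pts, q, eps, sigma, mol, cap)
    return grid_geometry.copy_with(e.reshape(grid_geometry.shape))


def surrogate_descriptor_field(
    mol: Molecule3D,
    probe: ProbeDefinition,
    grid_geometry: VoxelGrid,
    temperature_K: float = 300.0,
    n_orientations: int = DEFAULT_N_ORIENTATIONS,
    seed: int = 0,
    cap: float = DEFAULT_ENERGY_CAP,
) -> VoxelGrid:
    """Boltzmann-inverted probe center-of-mass density on the grid.

    For each of ``n_orientations`` quasi-uniform rigid orientations of the
    probe, the probe COM is placed at every voxel center and the pairwise
    LJ+Coulomb energy with the compound is summed over probe atoms.  The
    density is the orientation average of exp(-E/kT), scaled to unit
    maximum.  Deterministic for a fixed seed.
    """
    kT = BOLTZMANN_K * temperature_K
    pts = grid_geometry.voxel_centers().reshape(-1, 3)
    rots = Rotation.random(n_orientations, random_state=int(seed) % (2**31 - 1))
    boltz = np.zeros(pts.shape[0])
    for rot in rots:
        offsets = rot.apply(probe.coords)
        e = np.zeros(pts.shape[0])
        for off, q, eps, sigma in zip(
            offsets, probe.charges, probe.epsilons, probe.sigmas
        ):
            e += _pair_energy(pts + off, q, eps, sigma, mol, cap)
        e = np.clip(e, -cap, cap)
        boltz += np.exp(-e / kT)
    boltz /= n_orientations
    peak = boltz.max()
    if peak > 0:
        boltz = boltz / peak
    return grid_geometry.copy_with(boltz.reshape(grid_geometry.shape))


def build_descriptor(
    mol: Molecule3D,
    probes: list[ProbeDefinition],
    grid_geometry: VoxelGrid | None = None,
    mask_radius: float = 10.0,
    trans_range: float = 5.0,
    spacing: float = 1.0,
    temperature_K: float = 300.0,
    n_orientations: int = DEFAULT_N_ORIENTATIONS,
    seed: int = 0,
) -> AAMDescriptor:
    """Full per-probe descriptor for one conformer."""
    if grid_geometry is None:
        grid_geometry = default_grid_geometry(mol, mask_radius, trans_range, spacing)
    fields = {
        p.name: surrogate_descriptor_field(
            mol, p, grid_geometry,
            temperature_K=temperature_K,
            n_orientations=n_orientations,
            seed=seed,
        )
        for p in probes
    }
    return AAMDescriptor(
        compound_id=mol.compound_id, fields=fields, conformer_id=mol.conformer_id
    )
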