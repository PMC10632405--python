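"""The end-to-end virtual screen.

Preprocess a compound library (desalt/normalize, with per-record failure
bookkeeping), keep only compounds in the reference's charge class, score
every compound's conformers against the reference descriptor, and flag hits
whose similarity strictly exceeds the 0.7 threshold.

The scikit-learn-style :class:`AAMScreener` is the core object: ``fit``
takes the reference (a molecule or a precomputed descriptor) and builds the
rotated-reference SVD basis; ``predict`` returns hit flags for library
descriptors and ``score_samples`` their similarity scores.  The
module-level :func:`screen` is a thin wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import descriptors as desc
from .descriptors import (
    ChargeClass,
    Molecule,
    Molecule3D,
    StandardizationError,
    assign_charge_class,
    build_descriptor,
    default_probe_set,
    generate_conformers,
    standardize_molecule,
)
from .grids import AAMDescriptor, SearchGrid, SphericalMask, VoxelGrid
from .similarity import (
    DegenerateFieldError,
    SimilarityResult,
    aam_score_bruteforce,
    aam_score_svd,
    build_svd_basis,
)

logger = logging.getLogger("aamhop.screening")


@dataclass
class ScreenConfig:
    """Screen parameters; the defaults are the published operating point.

    hit_threshold 0.7 (strict >), 10 Å mask, 10° angular and 1 Å translation
    steps, SVD explained-variance cutoff 0.99, up to 100 conformers per
    library compound aggregated by the maximum score, probe densities at
    300 K.  Only the translation search range (±5 Å) and the surrogate
    descriptor's orientation sampling are choices of this package.
    """

    hit_threshold: float = 0.7
    mask_radius_A: float = 10.0
    angle_step_deg: float = 10.0
    trans_step_A: float = 1.0
    trans_range_A: float = 5.0
    svd_variance_cutoff: float = 0.99
    n_conformers: int = 100
    conformer_aggregation: str = "max"
    temperature_K: float = 300.0
    n_orientations: int = 32
    seed: int = 0
    method: str = "svd"
    skip_degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.hit_threshold < 1:
            raise ValueError("hit threshold must lie in (0, 1)")
        if min(self.angle_step_deg, self.trans_step_A, self.mask_radius_A) <= 0:
            raise ValueError("steps and mask radius must be positive")
        if self.conformer_aggregation != "max":
            raise ValueError("only 'max' conformer aggregation is supported")
        if self.method not in ("svd", "bruteforce"):
            raise ValueError(f"unknown method {self.method!r}")

    def search_grid(self) -> SearchGrid:
        return SearchGrid(
            angle_step=self.angle_step_deg,
            trans_step=self.trans_step_A,
            trans_range=self.trans_range_A,
        )

    def mask(self) -> SphericalMask:
        return SphericalMask(radius=self.mask_radius_A)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class FailureRecord:
    record_index: int
    compound_id: str
    reason: str


@dataclass
class ScreeningRecord:
    """One library compound's outcome."""

    compound_id: str
    best_conformer_id: int
    aam_similarity: float
    is_hit: bool
    alpha: float
    beta: float
    gamma: float
    X: float
    Y: float
    Z: float
    charge_class: str
    tanimoto_to_reference: float | None = None


def records_to_frame(records: list[ScreeningRecord]) -> pd.DataFrame:
    cols = [
        "compound_id", "conformer_id", "aam_similarity", "is_hit",
        "alpha", "beta", "gamma", "X", "Y", "Z", "charge_class", "tanimoto",
    ]
    rows = [
        (
            r.compound_id, r.best_conformer_id, r.aam_similarity, r.is_hit,
            r.alpha, r.beta, r.gamma, r.X, r.Y, r.Z, r.charge_class,
            r.tanimoto_to_reference,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)


def preprocess_library(
    records,
) -> tuple[list[Molecule], list[FailureRecord]]:
    """Standardize an iterable of (id, SMILES) pairs or bare SMILES strings.

    Failures are collected, not raised; duplicate ids are kept with a
    numeric suffix and a warning.  Input order is preserved.
    """
    mols: list[Molecule] = []
    failures: list[FailureRecord] = []
    seen: dict[str, int] = {}
    for i, rec in enumerate(records):
        if isinstance(rec, tuple):
            cid, raw = rec
        else:
            cid, raw = None, rec
        try:
            mol = standardize_molecule(raw, compound_id=cid, record_index=i)
        except StandardizationError as exc:
            failures.append(FailureRecord(i, str(cid or raw), str(exc)))
            continue
        if mol.compound_id in seen:
            seen[mol.compound_id] += 1
            new_id = f"{mol.compound_id}__{seen[mol.compound_id]}"
            logger.warning(
                "duplicate compound id %r kept as %r", mol.compound_id, new_id
            )
            mol.compound_id = new_id
        else:
            seen[mol.compound_id] = 0
        mols.append(mol)
    return mols, failures


def charge_filter(
    library: list[Molecule], reference: Molecule | Molecule3D
) -> list[Molecule]:
    """Compounds in the reference's charge class (neutral or monocation)."""
    ref_class = assign_charge_class(reference)
    out = []
    for mol in library:
        try:
            if assign_charge_class(mol) is ref_class:
                out.append(mol)
        except desc.UnsupportedChargeError:
            continue
    return out


class AAMScreener(BaseEstimator):
    """Scaffold-hopping screen against one reference compound.

    Parameters mirror :class:`ScreenConfig`.  ``fit`` accepts the reference
    as a precomputed :class:`AAMDescriptor`, a 3D conformer
    (:class:`Molecule3D`, e.g. a ligand extracted from a cocrystal — used
    as-is), or a standardized :class:`Molecule` (the lowest-index embedded
    conformer is used).  ``predict``/``score_samples``/``transform`` accept
    library descriptors; :meth:`screen` runs the full molecule pipeline.

    Attributes
    ----------
    reference_descriptor_ : AAMDescriptor
    basis_ : SVDBasis or None (brute-force mode)
    charge_class_ : ChargeClass or None (descriptor-only fit)
    probe_names_ : list of str
    """

    def __init__(
        self,
        hit_threshold: float = 0.7,
        mask_radius_A: float = 10.0,
        angle_step_deg: float = 10.0,
        trans_step_A: float = 1.0,
        trans_range_A: float = 5.0,
        svd_variance_cutoff: float = 0.99,
        n_conformers: int = 100,
        conformer_aggregation: str = "max",
        temperature_K: float = 300.0,
        n_orientations: int = 32,
        seed: int = 0,
        method: str = "svd",
        skip_degenerate: bool = False,
    ):
        self.hit_threshold = hit_threshold
        self.mask_radius_A = mask_radius_A
        self.angle_step_deg = angle_step_deg
        self.trans_step_A = trans_step_A
        self.trans_range_A = trans_range_A
        self.svd_variance_cutoff = svd_variance_cutoff
        self.n_conformers = n_conformers
        self.conformer_aggregation = conformer_aggregation
        self.temperature_K = temperature_K
        self.n_orientations = n_orientations
        self.seed = seed
        self.method = method
        self.skip_degenerate = skip_degenerate

    # -- configuration ----------------------------------------------------
    def config(self) -> ScreenConfig:
        return ScreenConfig.from_dict(self.get_params())

    @classmethod
    def from_config(cls, cfg: ScreenConfig) -> "AAMScreener":
        return cls(**{
            k: v for k, v in cfg.to_dict().items()
            if k in cls().get_params()
        })

    # -- fitting -----------------------------------------------------------
    def fit(self, reference, y=None):
        cfg = self.config()
        self.charge_class_: ChargeClass | None = None
        self.reference_molecule_: Molecule | None = None
        if isinstance(reference, AAMDescriptor):
            ref_desc = reference
        else:
            if isinstance(reference, Molecule):
                self.reference_molecule_ = reference
                self.charge_class_ = assign_charge_class(reference)
                conf = generate_conformers(reference, 1, seed=cfg.seed)[0]
            elif isinstance(reference, Molecule3D):
                self.charge_class_ = assign_charge_class(reference)
                conf = reference
            else:
                raise TypeError(
                    "reference must be an AAMDescriptor, Molecule or Molecule3D"
                )
            probes = default_probe_set(self.charge_class_)
            ref_desc = build_descriptor(
                conf, probes,
                mask_radius=cfg.mask_radius_A,
                trans_range=cfg.trans_range_A,
                temperature_K=cfg.temperature_K,
                n_orientations=cfg.n_orientations,
                seed=cfg.seed,
            )
        self.reference_descriptor_ = ref_desc
        self.probe_names_ = ref_desc.probes
        self.search_ = cfg.search_grid()
        self.mask_ = cfg.mask()
        if cfg.method == "svd":
            self.basis_ = build_svd_basis(
                ref_desc, self.search_, self.mask_, cfg.svd_variance_cutoff
            )
        else:
            self.basis_ = None
        return self

    # -- scoring -----------------------------------------------------------
    def score_one(self, descriptor: AAMDescriptor) -> SimilarityResult:
        if self.basis_ is not None:
            return aam_score_svd(
                self.basis_, descriptor, self.search_, self.mask_,
                skip_degenerate=self.skip_degenerate,
            )
        return aam_score_bruteforce(
            self.reference_descriptor_, descriptor, self.search_, self.mask_,
            skip_degenerate=self.skip_degenerate,
        )

    def score_samples(self, X) -> np.ndarray:
        """Similarity scores for a sequence of library descriptors."""
        return np.array([self.score_one(d).score for d in X])

    def transform(self, X) -> np.ndarray:
        return self.score_samples(X).reshape(-1, 1)

    def predict(self, X) -> np.ndarray:
        """Hit flags: similarity strictly greater than the threshold."""
        return self.score_samples(X) > self.hit_threshold

    # -- full molecule pipeline -------------------------------------------
    def _grid_geometry_for(self, mols: list[Molecule3D]) -> VoxelGrid:
        """Shared geometry covering the reference grid (library descriptors
        must match the reference's grid)."""
        return self.reference_descriptor_.geometry.copy_with(
            np.zeros(self.reference_descriptor_.geometry.shape)
        )

    def screen_descriptors(
        self, entries: list[tuple[str, AAMDescriptor]],
        tanimoto: dict[str, float] | None = None,
        charge_class: str = "",
    ) -> list[ScreeningRecord]:
        records = []
        for cid, d in entries:
            try:
                res = self.score_one(d)
            except DegenerateFieldError as exc:
                logger.warning("skipping %s: %s", cid, exc)
                continue
            t = res.argmax_transform
            records.append(
                ScreeningRecord(
                    compound_id=cid,
                    best_conformer_id=d.conformer_id,
                    aam_similarity=res.score,
                    is_hit=bool(res.score > self.hit_threshold),
                    alpha=t.alpha, beta=t.beta, gamma=t.gamma,
                    X=t.s[0], Y=t.s[1], Z=t.s[2],
                    charge_class=charge_class,
                    tanimoto_to_reference=(tanimoto or {}).get(cid),
                )
            )
        records.sort(key=lambda r: (-r.aam_similarity, r.compound_id))
        return records

    def screen(self, library: list[Molecule]) -> list[ScreeningRecord]:
        """Score every library compound (max over conformers) and flag hits."""
        from .evaluate import tanimoto_morgan

        cfg = self.config()
        if self.charge_class_ is not None:
            library = [
                m for m in library
                if _charge_class_or_none(m) is self.charge_class_
            ]
        geometry = self._grid_geometry_for([])
        probes = [desc.get_probe(p) for p in self.probe_names_]
        entries: list[tuple[str, AAMDescriptor]] = []
        tanimoto: dict[str, float] = {}
        charge_classes: dict[str, str] = {}
        for mol in library:
            try:
                confs = generate_conformers(mol, cfg.n_conformers, seed=cfg.seed)
            except RuntimeError as exc:
                logger.warning("conformer generation failed: %s", exc)
                continue
            best: tuple[float, AAMDescriptor] | None = None
            for conf in confs:
                d = build_descriptor(
                    conf, probes, grid_geometry=geometry,
                    temperature_K=cfg.temperature_K,
                    n_orientations=cfg.n_orientations,
                    seed=cfg.seed,
                )
                try:
                    score = self.score_one(d).score
                except DegenerateFieldError as exc:
                    logger.warning("degenerate field for %s: %s", mol.compound_id, exc)
                    continue
                if best is None or score > best[0]:
                    best = (score, d)
            if best is None:
                continue
            entries.append((mol.compound_id, best[1]))
            charge_classes[mol.compound_id] = assign_charge_class(mol).value
            if self.reference_molecule_ is not None:
                tanimoto[mol.compound_id] = tanimoto_morgan(
                    self.reference_molecule_, mol
                )
        records = self.screen_descriptors(entries, tanimoto)
        for r in records:
            r.charge_class = charge_classes.get(r.compound_id, "")
        return records


def _charge_class_or_none(mol) -> ChargeClass | None:
    try:
        return assign_charge_class(mol)
    except desc.UnsupportedChargeError:
        return None


def screen(
    reference,
    library: list[Molecule],
    config: ScreenConfig | None = None,
) -> list[ScreeningRecord]:
    """One-call screen: fit a screener on the reference, score the library."""
    cfg = config or ScreenConfig()
    screener = AAMScreener.from_config(cfg).fit(reference)
    return screener.screen(library)
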