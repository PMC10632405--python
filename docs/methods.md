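# Methods

## Descriptor model

A compound's descriptor is a set of scalar fields on a shared regular
voxel grid (isotropic, 1 Å spacing by default), one per amino-acid
side-chain probe, with the compound's center of mass at the grid-frame
origin. Each field is the probe's center-of-mass density around the
compound — a proxy for where that residue type would sit when the compound
binds a protein. Probes are side chains only (backbone atoms removed, the
Cα attachment capped with hydrogen), treated as rigid fragments. The
screened probe sets are {Asn, Cys⁻, Phe, Thr} for monocationic references
and the same four plus doubly protonated His for neutral references; a
larger library of 19 canonical side chains plus protonation variants
(Asp⁻/AspH, Glu⁻/GluH, Lys⁺/Lys⁰, Cys/Cys⁻, Hid/Hie/Hip, Arg⁺) is packaged
for data-driven probe selection. Glycine is omitted: with the backbone
removed its "side chain" is a lone hydrogen atom.

### Surrogate field generation

Reference descriptor fields of this kind are classically estimated by
explicit-solvent molecular dynamics of compound–probe pairs, which is far
too expensive for a library screen. `aamhop` generates fields with a
deterministic Boltzmann-inversion surrogate instead:

1. Probe geometries are embedded once from side-chain SMILES (ETKDG with a
   fixed seed, MMFF-relaxed), Gasteiger partial charges, and a small
   element-level Lennard-Jones table (ε, σ for H/C/N/O/S/P/halogens).
2. For each of 32 quasi-uniform rigid probe orientations (seeded
   `Rotation.random`), the probe's center of mass is placed at every voxel
   center and the pairwise interaction energy with the compound is summed
   over probe atoms: Lennard-Jones 12-6 with Lorentz–Berthelot combining
   plus Coulomb k·q₁q₂/d, k = 332.0637 kcal·Å/(mol·e²). Energies are capped
   at ±100 kcal/mol; a voxel coinciding with an atom center reads exactly
   the cap.
3. The density is the orientation average of exp(−E/kT) at T = 300 K,
   scaled to unit maximum.

This reproduces the essential structure of an MD-derived density — excluded
volume inside the molecular core, enhancement in attractive pockets, a flat
far field — while being analytic, desk-fast, and bitwise reproducible for a
fixed seed. What it does not model: probe flexibility, explicit solvent,
entropic effects, and many-body polarization. Precomputed fields (e.g. from
an external MD or learned generator) can be supplied as OpenDX files and
screened identically; the surrogate is the built-in default, not a
requirement.

Grids must pad the compound by mask radius + translation range so that
every masked lookup during the pose search stays in bounds; the
`default_grid_geometry` helper enforces this.

## Similarity score

Let g_a be the reference's field for probe a (of N_a probes) and G_a the
library compound's, both with their compound's center of mass at the
origin. θ(r) is the sharp spherical mask of radius 10 Å. The score at a
rigid transform (R, s) is the probe-averaged masked cosine

    cos(R, s) = (1/N_a) Σ_a Σ_m [G_a(r_m) − Ḡ_a(s)] [g_a(R(r_m + s)) − ḡ_a]
                              / (M σ_G(s) σ_g)

where the sum runs over the M voxels with |r + s| ≤ 10 Å, Ḡ_a(s), σ_G(s)
are the library field's mean and standard deviation over that shifted
mask, and ḡ_a, σ_g are the reference's over the central mask
(s-independent). The reported similarity is the maximum of cos over the
transform lattice; compounds with similarity strictly greater than 0.7 are
hits.

Numerical conventions:

* Integrals are voxel-center sums times spacing³; the volume factor
  cancels in every ratio, so moments are plain means and stored fields
  need no renormalization.
* Euler angles use the intrinsic Z-Y-Z convention,
  R = Rz(α)·Ry(β)·Rz(γ), α, γ ∈ [0, 360), β ∈ [0, 180], sampled at 10°.
  At β = 0 or 180 only α±γ matters; these gimbal-redundant triples are
  deduplicated (γ = 0 representative kept).
* Translations are sampled at 1 Å — the grid spacing — so shifts are
  lattice-exact and only rotations interpolate (trilinear, out-of-extent
  reads 0). Trilinear resampling error is O(h²/w²): a few percent for
  ~1 Å-scale field features, zero for 90°-multiple rotations.
* The translation range is ±5 Å per axis by default. Only the angular and
  translation step sizes are canonical; the range is this package's
  choice and is configurable.
* The per-probe average is used (the only reading of the score that is
  consistent with its SVD-factorized form).
* Tie-breaking on the lattice maximum is lexicographic in
  (α, β, γ, X, Y, Z) with the identity first, making results
  deterministic.
* A probe field with zero variance under a (shifted) mask makes the
  correlation undefined; this raises a degenerate-field error naming the
  probe by default, or skips that translation when `skip_degenerate` is
  set.

### SVD acceleration

The exhaustive search evaluates one masked integral per (probe, rotation,
translation). Factorizing the stack of rotated reference fields per probe
(rows = sampled rotations, columns = central-mask voxels, centered by the
reference's central mean ḡ_a),

    g_a(R(·)) − ḡ_a = Σ_μ V_aμ(R) Ξ_aμ U_aμ(·),

and truncating at the smallest rank whose cumulative explained-variance
ratio (squared singular values) exceeds 0.99, the score becomes

    cos(R, s) = (1/N_a) Σ_a Σ_μ V_aμ(R) Ξ_aμ λ_aμ(s),

with λ_aμ(s) the projection of the centered, normalized library field onto
the spatial mode U_aμ under the shifted mask. Integrals drop from
N_a·N_R·N_s to N_a·N_μ·N_s.

Because the library factor integrates to zero over the mask (it is
centered on exactly the summed voxel set), any constant offset of the
reference rows cancels in the numerator. This mean-cancellation identity
makes the centering of the SVD stack immaterial to the scores (verified
numerically to 10⁻⁹) and resolves what the centering constant "should" be:
we center by ḡ_a, which is optimal for truncation. At full rank the SVD
route reproduces the exhaustive search to 10⁻⁶ and the reconstruction of
the rotated stack is exact to 10⁻⁸; at the 0.99 cutoff score deviations
stay below 0.02 on the synthetic suite.

## Screening pipeline

1. **Standardization** — RDKit cleanup plus largest-organic-fragment
   selection (desalting), canonical atom renumbering. Failures are
   collected per record, never silently dropped; duplicate ids are kept
   with a numeric suffix.
2. **Charge classes** — net charge 0 (neutral) or +1 (monocation); other
   charges are outside the screen's scope and rejected. The library is
   filtered to the reference's class, which also fixes the probe set.
3. **Conformers** — ETKDG distance-geometry embedding (seeded, RMSD-pruned
   at 0.25 Å), up to 100 per compound by default. A reference supplied as
   a 3D structure (e.g. a cocrystal ligand) is used as-is.
4. **Scoring** — each conformer's descriptor is scored against the
   reference; a compound's similarity is the **maximum over its
   conformers** (best-achievable-pose logic; the reduction is this
   package's explicit choice). Records are sorted by similarity
   descending, ties by compound id.
5. **Hits** — similarity strictly greater than 0.7.

`AAMScreener` wraps steps 3–5 as a scikit-learn estimator: `fit` builds
the reference descriptor and its SVD basis, `score_samples`/`predict`
score library descriptors, `screen` runs the molecule pipeline.

## Probe selection

Candidate probes are compared by computing, per reference compound, each
probe's field and scoring probe pairs with the same masked cosine
(identity transform by default — probe fields share the reference's
frame; a full pose search is available). Distances 1 − (mean similarity
across references) are clustered hierarchically with average linkage
(UPGMA), cut at k clusters (k = 4 or 5 to mirror the screened sets; the
cut criterion is a required choice, not data-derived). Each cluster's
representative is the member whose field has the highest
identity-transform similarity to the cluster's voxel-wise mean field,
ties broken alphabetically. Linkage and the distance transform are this
package's choices; they are deterministic and permutation-invariant.

## Evaluation

* **Tanimoto novelty** — Morgan fingerprints, radius 2, 2048 bits; low
  Tanimoto among hits indicates scaffold hopping.
* **Extraction rate** — 100·B/A, one decimal: of A known same-target
  compounds, B recovered as hits.
* **Enrichment factor** — (same-target fraction of hits) / (same-target
  fraction of the charge-matched library); undefined when the library
  holds no same-target compound.
* **Chi-square** — Pearson test of independence on 2×2 hit/function
  tables, df = 1, **no Yates continuity correction** (the convention the
  published p-values pin down exactly). Compounds without a function
  label (e.g. a modulator that is neither agonist nor antagonist) are
  excluded from the cross-tab.
* **Two-sample test** — unpaired two-tailed t-test gated by a two-tailed
  F-test on the variances at α = 0.05 (pooled form when the F-test does
  not reject, Welch otherwise). Two constant equal samples give p = 1 by
  convention.

Annotations (known targets, same-target and same-function flags) are
user-supplied TSV; no external database is queried.

## Synthetic test data

The fixtures module generates descriptors as unit-max sums of isotropic
Gaussians ("blobs"): 8 blobs per probe channel, centers uniform in ±3 Å,
widths 0.7–1.1 Å, amplitudes 0.5–1. These values emulate the granularity
of orientation-averaged probe densities around a small molecule — several
distinct interaction loci per probe, sub-Å feature widths — and were fixed
once as the package's test conditions. Planted libraries jitter every blob
center of the reference recipe by an isotropic Gaussian (0.3 Å scale) to
make hits, and draw fresh blob sets for decoys; at 0.3 Å the expected
identity-transform correlation of a hit exceeds 0.9, while the maximum
decoy score over the full transform search stays well below the 0.7
threshold.

What passing these tests shows: the score, search, SVD acceleration,
threshold logic and bookkeeping behave correctly on fields with realistic
structure. What they do not show: that surrogate fields rank real
compound pairs as MD-derived fields would — that depends on the force
field and the surrogate's physics, not on this code path.

Test-scale geometry is 13³ voxels at 1 Å, mask radius 4 Å, 45–90° angular
steps, ±2 Å translations: the largest mask that stays in-bounds under
every ±2 Å shift of a 13³ grid, and small enough that full
brute-force-versus-SVD sweeps run in seconds on one CPU. The acceptance
script uses the same scale (20 score pairs, ten 25-compound planted
screens) so a complete reproduction stays under a minute.

## Known limitations

* Probes are rigid single rotamers; flexible side chains (Arg, Lys, Glu)
  are under-sampled.
* Gasteiger charges and an element-level LJ table are coarse compared to
  RESP/GAFF2 parameterization; absolute field magnitudes should not be
  over-interpreted, only their shapes.
* Charge states are taken from the standardized formal charge; no pKa
  prediction is attempted (supply an explicit charge to override).
* The sharp spherical mask makes scores slightly discontinuous in the
  translation when voxels enter or leave the sphere.
* Fourier-domain correlation and gradient pose refinement are out of
  scope; the search is a fixed lattice, so the reported maximum is a
  lattice maximum.
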