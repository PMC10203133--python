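"""Pseudo-atomic models, elastic-network normal modes and density rendering.

This module provides the "flexible specimen" half of the simulation-based
training-pair strategy: a macromolecule is represented as a cloud of point
masses, its low-frequency collective motions are computed with an anisotropic
elastic network model (ANM), and continuous conformational ensembles are drawn
by displacing the model along selected non-rigid modes with random amplitudes.
Models are rasterised onto cubic voxel grids as sums of isotropic Gaussians so
they can enter the tomographic forward model.

The ANM is the standard formulation: every atom pair closer than a distance
cutoff is joined by a harmonic spring of unit force constant, and the normal
modes are the eigenvectors of the resulting 3N x 3N Hessian.  Modes are
reported with 1-based indices; for a non-collinear model, modes 1-6 are the
zero-frequency rigid-body motions and deformational modes start at 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .tomo_forward import DensityVolume

__all__ = [
    "PseudoAtomModel",
    "NormalModeSet",
    "ModeAmplitudes",
    "generate_toy_model",
    "read_pdb_model",
    "write_pdb_model",
    "compute_enm_modes",
    "displace_along_modes",
    "sample_conformations",
    "mode_rmsd_per_unit_amplitude",
    "model_to_density",
]

#: numerical-zero threshold for rigid-body eigenvalues, relative to the
#: largest eigenvalue
_ZERO_MODE_REL_TOL = 1e-8


@dataclass
class PseudoAtomModel:
    """Point-mass model: ``N`` coordinates (Å) with non-negative weights.

    ``labels`` optionally tags atoms with region names (e.g. ``"core"`` /
    ``"arm0"``) so tests and analyses can reason about sub-structures.
    """

    atom_coords: np.ndarray
    atom_weights: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.atom_coords = np.asarray(self.atom_coords, dtype=float)
        self.atom_weights = np.asarray(self.atom_weights, dtype=float)
        if self.atom_coords.ndim != 2 or self.atom_coords.shape[1] != 3:
            raise ValueError("atom_coords must be an N x 3 array")
        if self.n_atoms < 1:
            raise ValueError("model must contain at least one atom")
        if self.atom_weights.shape != (self.n_atoms,):
            raise ValueError("atom_weights must have one entry per atom")
        if not np.all(np.isfinite(self.atom_coords)):
            raise ValueError("atom coordinates must be finite")
        if np.any(self.atom_weights < 0):
            raise ValueError("atom weights must be non-negative")
        if self.labels is not None and len(self.labels) != self.n_atoms:
            raise ValueError("labels must have one entry per atom")

    @property
    def n_atoms(self) -> int:
        return self.atom_coords.shape[0]

    def centered(self) -> "PseudoAtomModel":
        """Return a copy with the weighted centroid at the origin."""
        w = self.atom_weights
        total = w.sum()
        centroid = (
            (w[:, None] * self.atom_coords).sum(axis=0) / total
            if total > 0
            else self.atom_coords.mean(axis=0)
        )
        return PseudoAtomModel(self.atom_coords - centroid, w.copy(), self.labels)


@dataclass
class NormalModeSet:
    """Eigenpairs of an elastic-network Hessian.

    ``eigenvectors`` has shape ``(3N, M)`` with orthonormal columns;
    ``eigenvalues`` are non-decreasing.  ``mode_indexing`` is fixed at
    1-based: mode ``k`` is column ``k - 1``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    cutoff_A: float
    mode_indexing: str = "1-based"

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.eigenvectors.shape[0] // 3

    def n_zero_modes(self) -> int:
        """Count eigenvalues that are numerically zero (rigid-body modes)."""
        lam_max = float(self.eigenvalues[-1]) if self.n_modes else 0.0
        if lam_max <= 0:
            return self.n_modes
        return int(np.sum(self.eigenvalues < _ZERO_MODE_REL_TOL * lam_max))

    def mode_vector(self, mode_index: int) -> np.ndarray:
        """Displacement field of 1-based mode ``mode_index`` as ``(N, 3)``."""
        if not 1 <= mode_index <= self.n_modes:
            raise IndexError(f"mode index {mode_index} out of range 1..{self.n_modes}")
        return self.eigenvectors[:, mode_index - 1].reshape(self.n_atoms, 3)


@dataclass
class ModeAmplitudes:
    """Pairs of (1-based mode index >= 7, amplitude in model units)."""

    pairs: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for idx, amp in self.pairs:
            if idx <= 6:
                raise ValueError(
                    f"mode {idx} is a rigid-body mode (1-6); displacing along it "
                    "would translate or rotate the model, not deform it"
                )
            if not np.isfinite(amp):
                raise ValueError("amplitudes must be finite")


# ---------------------------------------------------------------------------
# toy model generation


def generate_toy_model(kind: str, n_atoms: int, seed: int) -> PseudoAtomModel:
    """Generate a deterministic synthetic pseudo-atomic model.

    Kinds:

    ``disc_with_arms``
        A nucleosome-like particle: a rigid disc-shaped core carrying two
        flexible linker arms that leave the disc tangentially.  Arm atoms are
        labelled ``arm0`` / ``arm1``, core atoms ``core``.
    ``helix``
        A single helical filament (elongated object).
    ``blob_cluster``
        A handful of globular blobs.

    All coordinates are in Å; weights are 1.  Output is a pure function of
    ``(kind, n_atoms, seed)``.
    """
    if n_atoms < 10:
        raise ValueError("n_atoms must be >= 10")
    rng = np.random.default_rng(seed)
    if kind == "disc_with_arms":
        return _toy_disc_with_arms(n_atoms, rng)
    if kind == "helix":
        return _toy_helix(n_atoms, rng)
    if kind == "blob_cluster":
        return _toy_blob_cluster(n_atoms, rng)
    raise ValueError(f"unknown toy model kind: {kind!r}")


#: disc radius of the toy nucleosome-like core, in Å
DISC_RADIUS_A = 26.0
#: disc half-thickness in Å
DISC_HALF_THICKNESS_A = 7.0
#: length of each flexible arm in Å
ARM_LENGTH_A = 28.0


def _toy_disc_with_arms(n_atoms: int, rng: np.random.Generator) -> PseudoAtomModel:
    n_arm = max(4, int(round(0.15 * n_atoms)))
    n_core = n_atoms - 2 * n_arm
    # core: uniform in a squat cylinder
    r = DISC_RADIUS_A * np.sqrt(rng.uniform(0, 1, n_core))
    phi = rng.uniform(0, 2 * np.pi, n_core)
    z = rng.uniform(-DISC_HALF_THICKNESS_A, DISC_HALF_THICKNESS_A, n_core)
    core = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    coords = [core]
    labels = ["core"] * n_core
    # two arms exiting tangentially on opposite rim sides, gently curving out
    # of the disc plane; small jitter keeps the chain non-degenerate
    for a, (phi0, sgn) in enumerate(((0.0, 1.0), (np.pi, -1.0))):
        t = np.linspace(0.0, 1.0, n_arm)
        anchor = np.array(
            [DISC_RADIUS_A * np.cos(phi0), DISC_RADIUS_A * np.sin(phi0), 0.0]
        )
        tangent = np.array([-np.sin(phi0), np.cos(phi0), 0.0]) * sgn
        radial = np.array([np.cos(phi0), np.sin(phi0), 0.0])
        arm = (
            anchor[None, :]
            + ARM_LENGTH_A * t[:, None] * (0.6 * tangent + 0.5 * radial)[None, :]
            + (0.35 * ARM_LENGTH_A) * (t**2)[:, None] * np.array([0.0, 0.0, sgn])
        )
        arm += rng.normal(0.0, 0.6, arm.shape)
        coords.append(arm)
        labels += [f"arm{a}"] * n_arm
    xyz = np.vstack(coords)
    return PseudoAtomModel(xyz, np.ones(len(xyz)), labels)


def _toy_helix(n_atoms: int, rng: np.random.Generator) -> PseudoAtomModel:
    turns = 4.0
    length = 3.0 * DISC_RADIUS_A  # elongated relative to the disc toy
    t = np.linspace(0.0, 1.0, n_atoms)
    phi = 2 * np.pi * turns * t
    radius = 8.0
    xyz = np.column_stack(
        [radius * np.cos(phi), radius * np.sin(phi), length * (t - 0.5)]
    )
    xyz += rng.normal(0.0, 0.4, xyz.shape)
    return PseudoAtomModel(xyz, np.ones(n_atoms), ["helix"] * n_atoms)


def _toy_blob_cluster(n_atoms: int, rng: np.random.Generator) -> PseudoAtomModel:
    n_blobs = 4
    centers = rng.uniform(-20.0, 20.0, (n_blobs, 3))
    which = rng.integers(0, n_blobs, n_atoms)
    xyz = centers[which] + rng.normal(0.0, 5.0, (n_atoms, 3))
    return PseudoAtomModel(xyz, np.ones(n_atoms), [f"blob{b}" for b in which])


# ---------------------------------------------------------------------------
# PDB interface


def read_pdb_model(path) -> PseudoAtomModel:
    """Read ATOM/HETATM records from a PDB file as a pseudo-atomic model.

    Occupancy is used as the atom weight (1.0 where absent/zero-filled).
    """
    import gemmi

    structure = gemmi.read_pdb(str(path))
    coords, weights, labels = [], [], []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    occ = float(atom.occ)
                    weights.append(occ if occ > 0 else 1.0)
                    labels.append(f"{chain.name}/{residue.seqid.num}/{atom.name}")
        break  # first model only
    if not coords:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return PseudoAtomModel(np.array(coords), np.array(weights), labels)


def write_pdb_model(model: PseudoAtomModel, path) -> None:
    """Write a pseudo-atomic model as fixed-width PDB ATOM records."""
    with open(path, "w") as fh:
        for i, ((x, y, z), w) in enumerate(
            zip(model.atom_coords, model.atom_weights), start=1
        ):
            serial = i % 100000
            resseq = ((i - 1) // 10) % 10000 + 1
            fh.write(
                f"ATOM  {serial:5d}  CA  ALA A{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{w:6.2f}  0.00           C\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# elastic network model


def enm_hessian(model: PseudoAtomModel, cutoff_A: float) -> np.ndarray:
    """Dense 3N x 3N anisotropic-network Hessian (unit spring constants).

    For each atom pair within ``cutoff_A``, the off-diagonal super-element is
    ``-(d d^T) / |d|^2`` with ``d`` the pair displacement; diagonal blocks
    accumulate the negated sum of the off-diagonals, which makes the three
    translations exact null vectors.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff_A must be positive")
    xyz = model.atom_coords
    n = model.n_atoms
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff_A, output_type="ndarray")
    hess = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        d = xyz[j] - xyz[i]
        r2 = float(d @ d)
        if r2 == 0.0:
            continue
        block = np.outer(d, d) / r2
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        hess[si, sj] -= block
        hess[sj, si] -= block
        hess[si, si] += block
        hess[sj, sj] += block
    return hess


def _spring_graph_components(model: PseudoAtomModel, cutoff_A: float) -> int:
    tree = cKDTree(model.atom_coords)
    pairs = tree.query_pairs(cutoff_A, output_type="ndarray")
    n = model.n_atoms
    if len(pairs) == 0:
        return n
    data = np.ones(len(pairs))
    adj = scipy.sparse.coo_matrix(
        (data, (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp


def compute_enm_modes(
    model: PseudoAtomModel, cutoff_A: float = 8.0, n_modes: int | None = None
) -> NormalModeSet:
    """Diagonalise the ANM Hessian and return the lowest ``n_modes`` modes.

    Raises if the spring graph is disconnected: extra connected components
    would silently contribute additional zero-frequency modes beyond the six
    rigid-body ones.
    """
    n = model.n_atoms
    if n_modes is None:
        n_modes = 3 * n
    if not 1 <= n_modes <= 3 * n:
        raise ValueError("n_modes must be in 1..3N")
    n_comp = _spring_graph_components(model, cutoff_A)
    if n_comp > 1:
        raise ValueError(
            f"spring graph is disconnected ({n_comp} components) at cutoff "
            f"{cutoff_A} Å; increase the cutoff"
        )
    hess = enm_hessian(model, cutoff_A)
    eigvals, eigvecs = scipy.linalg.eigh(hess, subset_by_index=(0, n_modes - 1))
    # clip tiny negative round-off so downstream log/sqrt users are safe
    eigvals = np.where(np.abs(eigvals) < 1e-12, np.abs(eigvals), eigvals)
    return NormalModeSet(eigvals, eigvecs, cutoff_A=float(cutoff_A))


def displace_along_modes(
    model: PseudoAtomModel, modes: NormalModeSet, amps: ModeAmplitudes
) -> PseudoAtomModel:
    """Linear displacement: ``x' = x + sum_k a_k v_k`` over requested modes."""
    disp = np.zeros_like(model.atom_coords)
    for idx, amp in amps.pairs:
        disp += amp * modes.mode_vector(idx)
    return PseudoAtomModel(
        model.atom_coords + disp, model.atom_weights.copy(), model.labels
    )


def sample_conformations(
    model: PseudoAtomModel,
    modes: NormalModeSet,
    n: int,
    mode_indices: Sequence[int],
    amplitude_range: tuple[float, float] = (-250.0, 250.0),
    seed: int = 0,
) -> list[PseudoAtomModel]:
    """Draw ``n`` conformations with independent uniform mode amplitudes.

    Each conformation draws one amplitude per listed mode, uniformly from
    ``amplitude_range``, producing a continuum of conformations along the
    span of the selected modes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(mode_indices) == 0:
        raise ValueError("mode_indices must not be empty")
    lo, hi = amplitude_range
    if lo > hi:
        raise ValueError("amplitude_range must satisfy lo <= hi")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        amps = ModeAmplitudes(
            [(int(k), float(rng.uniform(lo, hi))) for k in mode_indices]
        )
        out.append(displace_along_modes(model, modes, amps))
    return out


def mode_rmsd_per_unit_amplitude(modes: NormalModeSet, mode_index: int) -> float:
    """RMSD (Å) produced by unit amplitude along one mode.

    Amplitudes are in ENM-native units (eigenvectors are unit-norm over all
    3N components); this helper converts them to a physical displacement
    scale so amplitude ranges can be calibrated.
    """
    v = modes.mode_vector(mode_index)
    return float(np.sqrt(np.mean(np.sum(v**2, axis=1))))


# ---------------------------------------------------------------------------
# density rendering


def model_to_density(
    model: PseudoAtomModel,
    voxel_A: float,
    box: int,
    resolution_A: float = 12.0,
    center: bool = True,
) -> DensityVolume:
    """Rasterise a model onto a cubic grid as a sum of isotropic Gaussians.

    Each atom contributes ``weight`` times a Gaussian kernel of width
    ``sigma = resolution_A / (pi * sqrt(2))`` (the usual pdb2mrc-style
    mapping from nominal resolution to Gaussian width).  The kernel is
    normalised to unit discrete sum before clipping at the box edge, so the
    voxel sum equals the total weight minus the clipped fraction.

    Grid convention: values indexed ``[z, y, x]``, rotation centre at voxel
    ``box // 2`` on each axis, coordinates in Å relative to that voxel.
    """
    if voxel_A <= 0:
        raise ValueError("voxel_A must be positive")
    if resolution_A <= 0:
        raise ValueError("resolution_A must be positive")
    if box < 8:
        raise ValueError("box must be >= 8")
    m = model.centered() if center else model
    sigma_vox = (resolution_A / (np.pi * np.sqrt(2.0))) / voxel_A
    half = max(1, int(np.ceil(4.0 * sigma_vox)))
    k = np.arange(-half, half + 1)
    values = np.zeros((box, box, box))
    c = box // 2
    # nearest-voxel placement with sub-voxel offset folded into the kernel:
    # evaluate the separable Gaussian at (grid - exact position) per atom
    pos_vox = m.atom_coords[:, ::-1] / voxel_A + c  # (z, y, x) voxel coords
    for (pz, py, px), w in zip(pos_vox, m.atom_weights):
        iz, iy, ix = int(round(pz)), int(round(py)), int(round(px))
        gz = np.exp(-0.5 * ((iz + k - pz) / sigma_vox) ** 2)
        gy = np.exp(-0.5 * ((iy + k - py) / sigma_vox) ** 2)
        gx = np.exp(-0.5 * ((ix + k - px) / sigma_vox) ** 2)
        ker = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        s = ker.sum()
        if s <= 0:
            continue
        ker *= w / s
        z0, z1 = iz - half, iz + half + 1
        y0, y1 = iy - half, iy + half + 1
        x0, x1 = ix - half, ix + half + 1
        kz0, ky0, kx0 = max(0, -z0), max(0, -y0), max(0, -x0)
        kz1 = ker.shape[0] - max(0, z1 - box)
        ky1 = ker.shape[1] - max(0, y1 - box)
        kx1 = ker.shape[2] - max(0, x1 - box)
        if kz1 <= kz0 or ky1 <= ky0 or kx1 <= kx0:
            continue  # atom entirely outside the box
        values[
            max(0, z0) : min(box, z1),
            max(0, y0) : min(box, y1),
            max(0, x0) : min(box, x1),
        ] += ker[kz0:kz1, ky0:ky1, kx0:kx1]
    return DensityVolume(values, voxel_A=float(voxel_A))
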