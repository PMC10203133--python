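"""Cryo-ET forward model: rigid transforms, tilt projection, CTF, noise, WBP.

Conventions used throughout the package
---------------------------------------
* Volumes are cubic arrays indexed ``[z, y, x]``; ``z`` is the beam axis
  (the direction of missing information), ``y`` is the tilt axis.
* The rotation/shift centre is the voxel ``box // 2`` on each axis.
* Euler angles are intrinsic ZYZ ``(rot, tilt, psi)`` in degrees, matching
  the STAR-table columns used by subtomogram-averaging packages.
* A projection at tilt angle ``theta`` is the line integral along the beam
  after rotating the volume by ``-theta`` about the tilt axis; images are
  indexed ``[y, u]`` where ``u`` is the in-plane coordinate perpendicular to
  the tilt axis.

The projector/backprojector pair is built from per-angle sparse bilinear
interpolation operators acting on (z, x) planes, so backprojection is the
exact adjoint (matrix transpose) of projection.  Weighted back-projection
applies an exact ramp filter ``|k|`` along ``u`` before backprojecting and
scales by ``pi / (2 n_tilt)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.ndimage
import scipy.sparse

__all__ = [
    "DensityVolume",
    "RigidTransform",
    "TiltScheme",
    "CTFParams",
    "ProjectionStack",
    "WedgeMask",
    "euler_zyz_matrix",
    "apply_transform",
    "project",
    "backproject",
    "simulate_ctf",
    "electron_wavelength_A",
    "ctf_modulate",
    "phase_flip",
    "add_gaussian_noise",
    "wbp_reconstruct",
    "wedge_mask",
]


@dataclass
class DensityVolume:
    """Cubic 3D scalar grid with a physical voxel size.

    ``values`` is indexed ``[z, y, x]``; ``origin`` is the grid index of the
    rotation centre (defaults to ``box // 2`` on each axis).
    """

    values: np.ndarray
    voxel_A: float
    origin: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.voxel_A <= 0:
            raise ValueError("voxel_A must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")
        if self.origin is None:
            self.origin = self.values.shape[0] // 2

    @property
    def box(self) -> int:
        return self.values.shape[0]

    @property
    def is_cubic(self) -> bool:
        s = self.values.shape
        return s[0] == s[1] == s[2]

    def require_cubic(self) -> None:
        if not self.is_cubic:
            raise ValueError(f"operation requires a cubic volume, got {self.values.shape}")

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.values.copy(), self.voxel_A, self.origin)


@dataclass
class RigidTransform:
    """Intrinsic ZYZ Euler rotation (degrees) followed by a voxel shift."""

    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shift_vox: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (dx, dy, dz)

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.euler_deg)) and np.all(np.isfinite(self.shift_vox))):
            raise ValueError("transform parameters must be finite")

    def inverse(self) -> "RigidTransform":
        """Inverse transform (for shift-after-rotation semantics)."""
        rot, tilt, psi = self.euler_deg
        rinv = np.linalg.inv(euler_zyz_matrix(rot, tilt, psi))
        sx, sy, sz = self.shift_vox
        s_inv = -rinv @ np.array([sx, sy, sz])
        return RigidTransform((-psi, -tilt, -rot), tuple(s_inv))


@dataclass
class TiltScheme:
    """Symmetric or asymmetric single-axis tilt scheme, tilt axis = Y."""

    theta_min_deg: float
    theta_max_deg: float
    step_deg: float

    def __post_init__(self) -> None:
        if not self.theta_min_deg < self.theta_max_deg:
            raise ValueError("theta_min must be < theta_max")
        if self.step_deg <= 0:
            raise ValueError("step must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        n = int(np.floor((self.theta_max_deg - self.theta_min_deg) / self.step_deg + 1e-9))
        return self.theta_min_deg + self.step_deg * np.arange(n + 1)

    @property
    def n_tilt(self) -> int:
        return len(self.angles_deg)


@dataclass
class CTFParams:
    """Standard weak-phase contrast transfer function parameters.

    ``defocus_um`` is positive for underfocus; ``amplitude_contrast`` is the
    amplitude-contrast fraction ``A`` in [0, 1].  ``phase_flip`` requests
    multiplication by ``sign(CTF)`` after modulation (applied after noise in
    the simulation pipeline).
    """

    voltage_kV: float = 300.0
    defocus_um: float = 3.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    phase_flip: bool = True

    def __post_init__(self) -> None:
        if self.voltage_kV <= 0:
            raise ValueError("voltage must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")


@dataclass
class ProjectionStack:
    """Tilt-series images ``(n_tilt, H, W)`` with their angles and pixel size."""

    images: np.ndarray
    angles_deg: np.ndarray
    pixel_A: float

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be (n_tilt, H, W)")
        if len(self.angles_deg) != self.images.shape[0]:
            raise ValueError("one angle per image required")

    @property
    def n_tilt(self) -> int:
        return self.images.shape[0]

    def copy(self) -> "ProjectionStack":
        return ProjectionStack(self.images.copy(), self.angles_deg.copy(), self.pixel_A)


@dataclass
class WedgeMask:
    """Boolean Fourier-domain mask, True where the scheme samples."""

    mask: np.ndarray

    @property
    def missing_fraction(self) -> float:
        """Fraction of all voxels not sampled."""
        return float(1.0 - self.mask.mean())


# ---------------------------------------------------------------------------
# rigid transforms


def euler_zyz_matrix(rot_deg: float, tilt_deg: float, psi_deg: float) -> np.ndarray:
    """Rotation matrix for intrinsic ZYZ Euler angles, acting on (x, y, z)."""
    a, b, g = np.deg2rad([rot_deg, tilt_deg, psi_deg])

    def rz(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(a) @ ry(b) @ rz(g)


_FLIP = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)


def _xyz_matrix_to_index(mat: np.ndarray) -> np.ndarray:
    """Convert a matrix acting on (x, y, z) vectors to one acting on (z, y, x)."""
    return _FLIP @ mat @ _FLIP


def apply_transform(
    vol: DensityVolume, t: RigidTransform, order: str = "rotate_then_shift"
) -> DensityVolume:
    """Rotate about the origin voxel, then shift, with trilinear interpolation.

    Out-of-box samples are zero.  ``order`` is fixed to ``rotate_then_shift``
    (the convention used for mapping a reference into a particle's frame).
    """
    if order != "rotate_then_shift":
        raise ValueError("only rotate_then_shift is supported")
    vol.require_cubic()
    rot, tilt, psi = t.euler_deg
    r_xyz = euler_zyz_matrix(rot, tilt, psi)
    r_idx = _xyz_matrix_to_index(r_xyz)
    c = float(vol.origin)
    center = np.array([c, c, c])
    shift_idx = np.array([t.shift_vox[2], t.shift_vox[1], t.shift_vox[0]])
    # output(x) = input(R^-1 (x - shift - c) + c)
    rinv = np.linalg.inv(r_idx)
    offset = center - rinv @ (center + shift_idx)
    out = scipy.ndimage.affine_transform(
        vol.values.astype(float, copy=False),
        rinv,
        offset=offset,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return DensityVolume(out, vol.voxel_A, vol.origin)


# ---------------------------------------------------------------------------
# projection / backprojection (exact adjoint pair)


@lru_cache(maxsize=512)
def _ray_operator(box: int, angle_mdeg: int, origin: int) -> scipy.sparse.csr_matrix:
    """Sparse operator mapping a flattened (z, x) plane to the u-profile.

    For tilt angle theta, sample points along each ray are
    ``x = c + u' cos(t) + t' sin(t)``, ``z = c - u' sin(t) + t' cos(t)``
    (primed coordinates centred on ``origin``), gathered with bilinear
    weights and summed over the ray parameter.  The transpose of this matrix
    is the exact backprojection smear.
    """
    theta = np.deg2rad(angle_mdeg / 1000.0)
    c = float(origin)
    u = np.arange(box, dtype=float) - c
    t = np.arange(box, dtype=float) - c
    uu, tt = np.meshgrid(u, t, indexing="ij")  # (box_u, box_t)
    x = c + uu * np.cos(theta) + tt * np.sin(theta)
    z = c - uu * np.sin(theta) + tt * np.cos(theta)
    x0 = np.floor(x).astype(int)
    z0 = np.floor(z).astype(int)
    fx = x - x0
    fz = z - z0
    rows = np.repeat(np.arange(box), box)  # u index per sample point
    row_list, col_list, w_list = [], [], []
    for dz, dx, w in (
        (0, 0, (1 - fz) * (1 - fx)),
        (0, 1, (1 - fz) * fx),
        (1, 0, fz * (1 - fx)),
        (1, 1, fz * fx),
    ):
        zi = z0 + dz
        xi = x0 + dx
        valid = (zi >= 0) & (zi < box) & (xi >= 0) & (xi < box)
        row_list.append(rows[valid.ravel()])
        col_list.append((zi * box + xi)[valid])
        w_list.append(w[valid])
    mat = scipy.sparse.coo_matrix(
        (np.concatenate(w_list), (np.concatenate(row_list), np.concatenate(col_list))),
        shape=(box, box * box),
    )
    return mat.tocsr()


def project(vol: DensityVolume, scheme: TiltScheme) -> ProjectionStack:
    """Project a cubic volume along the beam for every angle of the scheme.

    Image ``i`` equals the line integral along the beam axis after rotating
    the volume by ``-angle_i`` about the tilt axis; at 0° this is exactly
    the sum over ``z``.
    """
    vol.require_cubic()
    angles = scheme.angles_deg
    if len(angles) == 0:
        raise ValueError("tilt scheme has no angles")
    box = vol.box
    planes = vol.values.astype(float, copy=False).transpose(0, 2, 1).reshape(box * box, box)
    # planes: rows = flattened (z, x), cols = y
    images = np.empty((len(angles), box, box))
    for i, ang in enumerate(angles):
        op = _ray_operator(box, int(round(ang * 1000)), vol.origin)
        images[i] = (op @ planes).T  # (u, y) -> (y, u)
    return ProjectionStack(images, angles, vol.voxel_A)


def backproject(stack: ProjectionStack, box: int, origin: int | None = None) -> DensityVolume:
    """Unfiltered backprojection: the exact adjoint of :func:`project`."""
    if stack.images.shape[1] != box or stack.images.shape[2] != box:
        raise ValueError("stack image size must equal box")
    if origin is None:
        origin = box // 2
    acc = np.zeros((box * box, box))  # flattened (z, x) rows, y cols
    for img, ang in zip(stack.images, stack.angles_deg):
        op = _ray_operator(box, int(round(ang * 1000)), origin)
        acc += op.T @ img.T  # img.T is (u, y)
    vol = acc.reshape(box, box, box).transpose(0, 2, 1)  # (z, x, y) -> (z, y, x)
    return DensityVolume(vol, stack.pixel_A, origin)


# ---------------------------------------------------------------------------
# CTF


def electron_wavelength_A(voltage_kV: float) -> float:
    """Relativistic electron wavelength in Å."""
    v = voltage_kV * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def simulate_ctf(freq2_grid: np.ndarray, p: CTFParams) -> np.ndarray:
    """Evaluate the CTF on a grid of squared spatial frequencies (1/Å²).

    ``CTF(f) = -sqrt(1 - A²) sin(chi) - A cos(chi)`` with phase aberration
    ``chi(f) = pi lambda dz f² - (pi/2) Cs lambda³ f⁴``.  At ``f = 0`` the
    value is exactly ``-A``.
    """
    lam = electron_wavelength_A(p.voltage_kV)
    dz = p.defocus_um * 1e4  # µm -> Å
    cs = p.cs_mm * 1e7  # mm -> Å
    f2 = np.asarray(freq2_grid, dtype=float)
    chi = np.pi * lam * dz * f2 - 0.5 * np.pi * cs * lam**3 * f2**2
    a = p.amplitude_contrast
    return -np.sqrt(1.0 - a * a) * np.sin(chi) - a * np.cos(chi)


def _ctf_grid(shape: tuple[int, int], pixel_A: float, p: CTFParams) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0], d=pixel_A)
    fx = np.fft.fftfreq(shape[1], d=pixel_A)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    return simulate_ctf(f2, p)


def ctf_modulate(
    stack: ProjectionStack, p: CTFParams, apply_phase_flip: bool | None = None
) -> ProjectionStack:
    """Multiply each image by the CTF in Fourier space.

    If phase flipping is requested (``apply_phase_flip``, defaulting to
    ``p.phase_flip``), the image is subsequently multiplied by
    ``sign(CTF)``, so the net transfer is ``|CTF|``.  The simulation
    pipeline instead calls this with flipping off, adds noise, and then
    applies :func:`phase_flip`, reproducing the modulate → noise → flip
    ordering of data collection followed by CTF correction.
    """
    if apply_phase_flip is None:
        apply_phase_flip = p.phase_flip
    ctf = _ctf_grid(stack.images.shape[1:], stack.pixel_A, p)
    transfer = ctf * np.sign(ctf) if apply_phase_flip else ctf
    spec = np.fft.fft2(stack.images, axes=(1, 2)) * transfer[None, :, :]
    out = np.real(np.fft.ifft2(spec, axes=(1, 2)))
    return ProjectionStack(out, stack.angles_deg.copy(), stack.pixel_A)


def phase_flip(stack: ProjectionStack, p: CTFParams) -> ProjectionStack:
    """Multiply each image by ``sign(CTF)`` in Fourier space (CTF correction)."""
    ctf = _ctf_grid(stack.images.shape[1:], stack.pixel_A, p)
    spec = np.fft.fft2(stack.images, axes=(1, 2)) * np.sign(ctf)[None, :, :]
    out = np.real(np.fft.ifft2(spec, axes=(1, 2)))
    return ProjectionStack(out, stack.angles_deg.copy(), stack.pixel_A)


# ---------------------------------------------------------------------------
# noise


def add_gaussian_noise(
    stack: ProjectionStack, target_snr: float, seed: int
) -> ProjectionStack:
    """Add white Gaussian noise at a target variance-ratio SNR.

    SNR is defined per stack as ``var(signal) / var(noise)``; the noise
    standard deviation is ``sqrt(var(images) / target_snr)``.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    sig_var = float(np.var(stack.images))
    if sig_var == 0:
        raise ValueError("stack has zero signal variance")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(sig_var / target_snr)
    noisy = stack.images + rng.normal(0.0, sigma, stack.images.shape)
    return ProjectionStack(noisy, stack.angles_deg.copy(), stack.pixel_A)


# ---------------------------------------------------------------------------
# weighted back-projection


def _ramp_filter(images: np.ndarray, rolloff: bool = False) -> np.ndarray:
    """Apply an exact ramp ``|k|`` along the last (u) axis of the images."""
    n = images.shape[-1]
    k = np.abs(np.fft.fftfreq(n)) * n  # ramp in index units
    if rolloff:
        k = k * (0.5 * (1.0 + np.cos(np.pi * np.abs(np.fft.fftfreq(n)) / 0.5)))
    spec = np.fft.fft(images, axis=-1) * k
    return np.real(np.fft.ifft(spec, axis=-1))


def wbp_reconstruct(
    stack: ProjectionStack,
    scheme: TiltScheme | None = None,
    box: int | None = None,
    rolloff: bool = False,
    enforce_support: bool = True,
) -> DensityVolume:
    """Weighted back-projection: ramp filter each image, backproject, scale.

    The scale ``pi / (2 n_tilt)`` makes the reconstruction approximate the
    original volume for a dense full-range scheme.  A single-tilt stack is
    a valid degenerate input (one smeared plane).

    With ``enforce_support`` (default), the reconstruction's Fourier
    transform is restricted to the region actually sampled by the tilt
    scheme.  Real-space smearing at finite box sizes otherwise bleeds sinc
    tails into the missing wedge; production reconstruction tools based on
    central-slice Fourier insertion have no such bleed, and the sharp empty
    wedge they produce is exactly the artefact the restoration network is
    trained to compensate.  The support mask is derived from ``scheme`` when
    given, else from the extreme angles present in the stack.
    """
    if box is None:
        box = stack.images.shape[1]
    if stack.images.shape[1] != box:
        raise ValueError("box must equal stack image size")
    filtered = _ramp_filter(stack.images, rolloff=rolloff)
    fstack = ProjectionStack(filtered, stack.angles_deg.copy(), stack.pixel_A)
    vol = backproject(fstack, box)
    vol.values *= np.pi / (2.0 * stack.n_tilt)
    if enforce_support:
        if scheme is None:
            lo, hi = float(np.min(stack.angles_deg)), float(np.max(stack.angles_deg))
            if hi - lo < 1e-9:  # degenerate single-tilt stack
                lo, hi = lo - 0.5, hi + 0.5
            scheme = TiltScheme(lo, hi, max(hi - lo, 1e-6))
        support = wedge_mask(box, scheme).mask
        if not support.all():
            spec = np.fft.fftn(vol.values)
            vol = DensityVolume(
                np.real(np.fft.ifftn(spec * support)), vol.voxel_A, vol.origin
            )
    return vol


# ---------------------------------------------------------------------------
# wedge geometry


def wedge_mask(box: int, scheme: TiltScheme) -> WedgeMask:
    """Boolean mask of the Fourier region sampled by a single-axis scheme.

    A frequency voxel is sampled iff the (signed, Friedel-wrapped) angle of
    its ``(k_x, k_z)`` component from the ``k_x`` axis lies within the tilt
    range; ``k_y`` (tilt axis) is unconstrained and the DC voxel is always
    sampled.  The mask is symmetrised with a logical OR so Friedel mates and
    the even-box Nyquist plane land in the sampled region.
    """
    if box < 2:
        raise ValueError("box must be >= 2")
    k = np.fft.fftfreq(box)
    kz = k[:, None, None]
    kx = k[None, None, :]
    # angle of the (kx, kz) direction from the +kx axis, wrapped to
    # (-90, 90] by Friedel symmetry (k and -k are equivalent)
    ang = np.degrees(np.arctan2(-kz, kx)) + np.zeros((1, box, 1))

    def _inrange(a):
        return (a >= scheme.theta_min_deg - 1e-9) & (a <= scheme.theta_max_deg + 1e-9)

    # a tilt at theta samples the same central plane as theta +/- 180
    sampled = _inrange(ang) | _inrange(ang - 180.0) | _inrange(ang + 180.0)
    # the ky axis (kx = kz = 0) is seen by every projection; atan2(0, 0) = 0
    # already satisfies symmetric schemes, make it explicit for asymmetric ones
    on_axis = (np.abs(kz) == 0) & (np.abs(kx) == 0)
    sampled = sampled | np.broadcast_to(on_axis, sampled.shape)
    # Friedel symmetrisation (OR): index -k via flip + roll on each axis
    refl = sampled[::-1, ::-1, ::-1]
    refl = np.roll(refl, (1, 1, 1), axis=(0, 1, 2))
    sampled = sampled | refl
    return WedgeMask(sampled)
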