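"""Quantitative evaluation of restored tomograms.

Four families of measurements:

* **Region-based SNR in dB.**  Because real tomograms have no ground truth,
  SNR is estimated from user-selected paired signal/background regions on a
  micrograph (an average of consecutive tomogram slices).  For each pair the
  background supplies a mean and variance; the "signal" is the signal region
  minus the background mean and its variance enters a log-ratio.  The
  estimate is the mean over pairs of ``10 (log10 v_s - log10 v_b)``.
* **Pearson correlation** between volumes — the fidelity metric for
  simulated data where ground truth exists.
* **Fourier wedge occupancy** — the fraction of spectral power inside the
  missing wedge, quantifying how much missing-wedge information a
  restoration has filled in.
* **Template matching** — exhaustive rotational/translational normalized
  cross-correlation to locate particles, plus coordinate-offset statistics
  against known ground-truth positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

from .tomo_forward import DensityVolume, TiltScheme, apply_transform, wedge_mask

__all__ = [
    "RegionPair",
    "SNREstimate",
    "MatchResult",
    "OffsetStats",
    "slice_average",
    "estimate_snr_db",
    "propose_region_pairs",
    "pearson_cc",
    "wedge_energy_fraction",
    "template_match",
    "offset_statistics",
]


@dataclass
class RegionPair:
    """Paired signal and background rectangles on a micrograph.

    Rectangles are ``(row0, col0, row1, col1)`` half-open pixel bounds; the
    two must not overlap and each must contain at least 16 pixels.
    """

    signal_box: tuple[int, int, int, int]
    background_box: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for box in (self.signal_box, self.background_box):
            r0, c0, r1, c1 = box
            if r1 <= r0 or c1 <= c0 or (r1 - r0) * (c1 - c0) < 16:
                raise ValueError(f"region {box} must contain at least 16 pixels")
        s, b = self.signal_box, self.background_box
        if not (s[2] <= b[0] or b[2] <= s[0] or s[3] <= b[1] or b[3] <= s[1]):
            raise ValueError("signal and background regions overlap")

    def pixels(self, micrograph: np.ndarray, which: str) -> np.ndarray:
        r0, c0, r1, c1 = self.signal_box if which == "signal" else self.background_box
        return micrograph[r0:r1, c0:c1]


@dataclass
class SNREstimate:
    """Region-based SNR estimate and its per-region intermediates."""

    per_region_db: list[float]
    mean_db: float
    n_regions: int
    intermediates: list[dict] = field(default_factory=list)


@dataclass
class MatchResult:
    """One template-matching peak."""

    peak_coord_vox: tuple[int, int, int]  # (x, y, z)
    euler_deg: tuple[float, float, float]
    cc: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.cc <= 1.0 + 1e-9:
            raise ValueError("cc must lie in [-1, 1]")


@dataclass
class OffsetStats:
    """Per-particle coordinate offsets (calculated − true) and summaries."""

    offsets: list[tuple[float, float, float]]
    matched_cc: list[float]
    truth_indices: list[int]
    unmatched_truth: list[tuple[int, int, int]]
    mean_xyz: tuple[float, float, float]
    rms_xyz: tuple[float, float, float]

    @property
    def n_matched(self) -> int:
        return len(self.offsets)


# ---------------------------------------------------------------------------
# SNR


def slice_average(tomogram: DensityVolume, z0: int, n: int = 10) -> np.ndarray:
    """Pixel-wise mean of ``n`` consecutive XY slices starting at ``z0``."""
    nz = tomogram.values.shape[0]
    if n < 1:
        raise ValueError("n must be >= 1")
    if z0 < 0 or z0 + n > nz:
        raise ValueError(f"slices [{z0}, {z0 + n}) out of range for {nz} slices")
    return tomogram.values[z0 : z0 + n].mean(axis=0)


def estimate_snr_db(
    micrograph: np.ndarray, regions: list[RegionPair]
) -> SNREstimate:
    """Region-based SNR estimate in dB.

    For each region pair, with background mean/variance ``mu_b, v_b`` and
    signal pixels ``x_s``, the signal is ``s = x_s - mu_b`` with variance
    ``v_s``, and the pair contributes ``10 (log10 v_s - log10 v_b)``; the
    estimate is the arithmetic mean over pairs.  Variances are unbiased
    (n−1) sample variances.
    """
    if len(regions) == 0:
        raise ValueError("at least one region pair is required")
    micrograph = np.asarray(micrograph, dtype=float)
    per_db, inter = [], []
    for rp in regions:
        bg = rp.pixels(micrograph, "background").ravel()
        sig = rp.pixels(micrograph, "signal").ravel()
        mu_b = float(bg.mean())
        v_b = float(bg.var(ddof=1))
        if v_b == 0.0:
            raise ValueError("background region has zero variance (log undefined)")
        s = sig - mu_b
        mu_s = float(s.mean())
        v_s = float(s.var(ddof=1))
        if v_s == 0.0:
            raise ValueError("signal region has zero variance (log undefined)")
        per_db.append(10.0 * (np.log10(v_s) - np.log10(v_b)))
        inter.append({"mu_b": mu_b, "v_b": v_b, "mu_s": mu_s, "v_s": v_s})
    return SNREstimate(per_db, float(np.mean(per_db)), len(per_db), inter)


def propose_region_pairs(
    micrograph: np.ndarray, n: int = 10, size: int = 32, seed: int = 0
) -> list[RegionPair]:
    """Auto-propose region pairs by tiling (convenience extension).

    The estimator itself takes user-chosen regions; this helper tiles the
    micrograph, ranks tiles by local variance, and pairs the ``n`` highest-
    variance tiles (signal) with the ``n`` lowest-variance tiles
    (background), nearest first.
    """
    h, w = micrograph.shape
    tiles = []
    for r in range(0, h - size + 1, size):
        for c in range(0, w - size + 1, size):
            tiles.append((float(np.var(micrograph[r : r + size, c : c + size])), r, c))
    if len(tiles) < 2 * n:
        raise ValueError("micrograph too small for the requested number of pairs")
    tiles.sort()
    lows, highs = tiles[:n], tiles[-n:]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    out = []
    for (_, br, bc), k in zip(lows, order):
        _, sr, sc = highs[k]
        out.append(
            RegionPair((sr, sc, sr + size, sc + size), (br, bc, br + size, bc + size))
        )
    return out


# ---------------------------------------------------------------------------
# correlation


def pearson_cc(
    a: DensityVolume | np.ndarray,
    b: DensityVolume | np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson correlation over (optionally masked) voxels."""
    av = a.values if isinstance(a, DensityVolume) else np.asarray(a)
    bv = b.values if isinstance(b, DensityVolume) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError("volumes must have equal shapes")
    if mask is not None:
        if mask.shape != av.shape:
            raise ValueError("mask shape must match volumes")
        av, bv = av[mask], bv[mask]
    av = av.ravel().astype(float)
    bv = bv.ravel().astype(float)
    if av.size < 2:
        raise ValueError("need at least 2 voxels")
    av = av - av.mean()
    bv = bv - bv.mean()
    na, nb = float(av @ av), float(bv @ bv)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero variance on one side; correlation undefined")
    return float(np.clip(av @ bv / np.sqrt(na * nb), -1.0, 1.0))


# ---------------------------------------------------------------------------
# wedge occupancy


def wedge_energy_fraction(vol: DensityVolume, scheme: TiltScheme) -> float:
    """Fraction of non-DC spectral power inside the scheme's missing wedge."""
    vol.require_cubic()
    mask = wedge_mask(vol.box, scheme).mask
    power = np.abs(np.fft.fftn(vol.values)) ** 2
    power[0, 0, 0] = 0.0
    total = power.sum()
    if total == 0.0:
        return 0.0
    return float(power[~mask].sum() / total)


# ---------------------------------------------------------------------------
# template matching


def _rotation_grid(step_deg: float) -> list[tuple[float, float, float]]:
    """Uniform ZYZ grid: rot, psi over [0, 360), tilt over [0, 180]."""
    if step_deg <= 0 or step_deg > 360:
        raise ValueError("angular step must be in (0, 360]")
    rots = np.arange(0.0, 360.0, step_deg)
    tilts = np.arange(0.0, 180.0 + 1e-9, step_deg)
    psis = np.arange(0.0, 360.0, step_deg)
    grid = []
    for tilt in tilts:
        degenerate = tilt % 180.0 == 0.0  # rot and psi collapse to their sum
        for rot in rots if not degenerate else [0.0]:
            for psi in psis:
                grid.append((float(rot), float(tilt), float(psi)))
    return grid


def ncc_map(tomogram: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of a template over all translations.

    Returns a map the size of the tomogram whose value at ``p`` is the NCC
    of the template centred at ``p`` (Fourier-accelerated box sums).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # flat background regions divide by ~0
        return match_template(
            np.ascontiguousarray(tomogram, dtype=np.float64),
            np.ascontiguousarray(template, dtype=np.float64),
            pad_input=True,
        )


def template_match_map(
    tomogram: DensityVolume, template: DensityVolume, angular_step_deg: float = 90.0
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float, float]]]:
    """Orientation-maximised NCC map of a template over a tomogram.

    Correlates the template in every orientation of a uniform ZYZ grid over
    all translations and keeps, per voxel, the best correlation and the
    orientation index achieving it.  Returns ``(best_cc, best_ori, grid)``.
    """
    if template.values.shape[0] > tomogram.values.shape[0]:
        raise ValueError("template must be smaller than the tomogram")
    best_cc = np.full(tomogram.values.shape, -np.inf)
    best_ori = np.zeros(tomogram.values.shape, dtype=np.int32)
    grid = _rotation_grid(angular_step_deg)
    from .tomo_forward import RigidTransform

    for oi, euler in enumerate(grid):
        rt = (
            template
            if euler == (0.0, 0.0, 0.0)
            else apply_transform(template, RigidTransform(euler))
        )
        cc = ncc_map(tomogram.values, rt.values)
        upd = cc > best_cc
        best_cc[upd] = cc[upd]
        best_ori[upd] = oi
    return best_cc, best_ori, grid


def template_match(
    tomogram: DensityVolume,
    template: DensityVolume,
    angular_step_deg: float = 90.0,
    cc_threshold: float = 0.2,
    min_separation_vox: int | None = None,
    precomputed: tuple | None = None,
) -> list[MatchResult]:
    """Locate template instances by exhaustive rotational NCC search.

    For every orientation on a uniform ZYZ grid the rotated template is
    correlated over all translations; per-voxel the best orientation is
    kept, and peaks above ``cc_threshold`` are extracted greedily with
    non-maximum suppression at ``min_separation_vox`` (default: half the
    template box).  Ties break toward lexicographically smaller (z, y, x).
    ``precomputed`` accepts the output of :func:`template_match_map` to
    avoid recomputing the search.
    """
    if cc_threshold >= 1.0:
        warnings.warn("cc_threshold >= 1 matches nothing", stacklevel=2)
        return []
    if min_separation_vox is None:
        min_separation_vox = template.values.shape[0] // 2
    best_cc, best_ori, grid = (
        precomputed
        if precomputed is not None
        else template_match_map(tomogram, template, angular_step_deg)
    )
    # greedy non-max suppression
    flat = best_cc.ravel()
    order = np.argsort(-flat, kind="stable")  # ties -> smaller flat index first
    shape = tomogram.values.shape
    accepted: list[tuple[int, int, int]] = []
    results: list[MatchResult] = []
    min_sep2 = float(min_separation_vox) ** 2
    for fi in order:
        v = flat[fi]
        if v < cc_threshold:
            break
        z, y, x = np.unravel_index(fi, shape)
        if any((z - az) ** 2 + (y - ay) ** 2 + (x - ax) ** 2 < min_sep2
               for az, ay, ax in accepted):
            continue
        accepted.append((int(z), int(y), int(x)))
        results.append(
            MatchResult(
                (int(x), int(y), int(z)),
                grid[int(best_ori[z, y, x])],
                float(np.clip(v, -1.0, 1.0)),
            )
        )
    return results


def offset_statistics(
    matches: list[MatchResult],
    truth: list[tuple[int, int, int]],
    match_radius_vox: float,
) -> OffsetStats:
    """Pair matched peaks to ground-truth coordinates and summarise offsets.

    Peaks are visited in decreasing cc; each claims its nearest unclaimed
    truth point within ``match_radius_vox`` (one-to-one).  Offsets are
    calculated − true, per axis.
    """
    if len(truth) == 0:
        raise ValueError("truth list must not be empty")
    if len(set(truth)) != len(truth):
        raise ValueError("duplicate ground-truth coordinates")
    truth_arr = np.asarray(truth, dtype=float)
    claimed = np.zeros(len(truth), dtype=bool)
    offsets, ccs, tidx = [], [], []
    for m in sorted(matches, key=lambda r: -r.cc):
        d2 = np.sum((truth_arr - np.asarray(m.peak_coord_vox, dtype=float)) ** 2, axis=1)
        d2[claimed] = np.inf
        j = int(np.argmin(d2))
        if d2[j] <= match_radius_vox**2:
            claimed[j] = True
            off = np.asarray(m.peak_coord_vox, dtype=float) - truth_arr[j]
            offsets.append(tuple(off))
            ccs.append(m.cc)
            tidx.append(j)
    unmatched = [t for t, c in zip(truth, claimed) if not c]
    if offsets:
        arr = np.asarray(offsets)
        mean = tuple(arr.mean(axis=0))
        rms = tuple(np.sqrt((arr**2).mean(axis=0)))
    else:
        mean = rms = (float("nan"),) * 3
    return OffsetStats(offsets, ccs, tidx, unmatched, mean, rms)
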