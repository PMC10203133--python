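"""Training-pair construction for restoration networks.

Two strategies produce (low-quality input, high-quality target) volume pairs:

* **Strategy 1** starts from an experimentally averaged map (subtomogram
  averaging result).  For every raw particle with known alignment
  parameters, the average is rotated and shifted into the particle's frame
  and used as that particle's ground truth; the raw subtomogram is the input.
* **Strategy 2** is fully simulated: pseudo-atomic conformations are rendered
  to density, randomly oriented (ground truth), then degraded through the
  tomographic forward model — tilt-limited projection, CTF modulation,
  Gaussian noise, phase flipping and weighted back-projection (input).

Pairs are z-score normalized per volume, the convention the restoration
network trains under.  Every stochastic draw is recorded in a
:class:`PairSetManifest` from which the identical pair set can be rebuilt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .structure_dynamics import PseudoAtomModel, model_to_density
from .tomo_forward import (
    CTFParams,
    DensityVolume,
    RigidTransform,
    TiltScheme,
    add_gaussian_noise,
    apply_transform,
    ctf_modulate,
    phase_flip,
    project,
    wbp_reconstruct,
)

__all__ = [
    "OrientationRecord",
    "TrainingPair",
    "PairSetManifest",
    "make_ground_truth_strategy1",
    "build_pairs_strategy1",
    "build_pairs_strategy2",
    "normalize_volume",
    "extract_subvolumes",
    "random_transform",
    "split_pairs",
]

MANIFEST_FORMAT_VERSION = 1


@dataclass
class OrientationRecord:
    """Alignment parameters of one particle in a source tomogram."""

    particle_id: str
    transform: RigidTransform
    source_tomogram: str = ""
    center_vox: tuple[int, int, int] = (0, 0, 0)


@dataclass
class TrainingPair:
    """One (input, target) couple the network learns from."""

    input_vol: DensityVolume
    target_vol: DensityVolume
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input_vol.values.shape != self.target_vol.values.shape:
            raise ValueError("input and target must have equal shapes")
        if abs(self.input_vol.voxel_A - self.target_vol.voxel_A) > 1e-6:
            raise ValueError("input and target must have equal voxel sizes")


@dataclass
class PairSetManifest:
    """Reproducibility record: every pair regenerates from its entry."""

    format_version: int
    strategy: str
    params: dict
    entries: list[dict]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PairSetManifest":
        d = json.loads(text)
        return cls(d["format_version"], d["strategy"], d["params"], d["entries"])


# ---------------------------------------------------------------------------
# normalization


def normalize_volume(vol: DensityVolume) -> DensityVolume:
    """Per-volume z-score: zero mean, unit sample standard deviation.

    A constant input cannot be scaled; it maps to all zeros and the output
    carries ``degenerate=True`` in its ``origin``-preserving copy (exposed
    via the returned volume's ``values`` being all zero and the attribute
    ``degenerate`` set on the instance).
    """
    v = vol.values.astype(float)
    mu = float(v.mean())
    sd = float(v.std())
    if sd == 0.0:
        out = DensityVolume(np.zeros_like(v), vol.voxel_A, vol.origin)
        out.degenerate = True
        return out
    out = DensityVolume((v - mu) / sd, vol.voxel_A, vol.origin)
    out.degenerate = False
    return out


# ---------------------------------------------------------------------------
# strategy 1


def make_ground_truth_strategy1(
    reference_map: DensityVolume, rec: OrientationRecord
) -> DensityVolume:
    """Transform the averaged reference into one particle's frame.

    The stored transform maps the reference frame to the particle frame, so
    the ground truth is the forward-transformed reference (the same
    convention as :func:`resttomo.tomo_forward.apply_transform`).
    """
    reference_map.require_cubic()
    return apply_transform(reference_map, rec.transform)


def build_pairs_strategy1(
    subtomograms: Sequence[DensityVolume],
    reference_map: DensityVolume,
    records: Sequence[OrientationRecord],
    particle_ids: Sequence[str] | None = None,
    normalized: bool = True,
    invert_transforms: bool = False,
) -> list[TrainingPair]:
    """Pair each raw subtomogram with the reference mapped to its orientation.

    ``particle_ids`` names the subtomograms (defaults to ``"0", "1", ...``);
    records are matched by id, so record order is irrelevant.
    ``invert_transforms`` accommodates packages that store the inverse
    convention (particle → reference).
    """
    if particle_ids is None:
        particle_ids = [str(i) for i in range(len(subtomograms))]
    if len(particle_ids) != len(subtomograms):
        raise ValueError("one particle_id per subtomogram required")
    by_id = {r.particle_id: r for r in records}
    missing = [pid for pid in particle_ids if pid not in by_id]
    if missing:
        raise KeyError(f"no orientation record for particle ids: {missing}")
    for sub in subtomograms:
        if abs(sub.voxel_A - reference_map.voxel_A) > 0.01 * reference_map.voxel_A:
            raise ValueError(
                f"voxel size mismatch: subtomogram {sub.voxel_A} Å vs "
                f"reference {reference_map.voxel_A} Å"
            )
    pairs = []
    for pid, sub in zip(particle_ids, subtomograms):
        rec = by_id[pid]
        t = rec.transform.inverse() if invert_transforms else rec.transform
        gt = make_ground_truth_strategy1(
            reference_map, OrientationRecord(pid, t, rec.source_tomogram, rec.center_vox)
        )
        inp, tgt = (normalize_volume(sub), normalize_volume(gt)) if normalized else (sub, gt)
        pairs.append(
            TrainingPair(inp, tgt, {"strategy": "1", "particle_id": pid,
                                    "normalized": normalized})
        )
    return pairs


# ---------------------------------------------------------------------------
# strategy 2


def random_transform(
    rng: np.random.Generator, max_shift_vox: float
) -> RigidTransform:
    """Draw a uniform orientation (ZYZ, cos-uniform tilt) and uniform shifts."""
    rot = rng.uniform(0.0, 360.0)
    psi = rng.uniform(0.0, 360.0)
    tilt = np.degrees(np.arccos(rng.uniform(-1.0, 1.0)))
    shifts = rng.uniform(-max_shift_vox, max_shift_vox, 3)
    return RigidTransform((rot, tilt, psi), tuple(shifts))


def _simulate_one(
    gt: DensityVolume,
    scheme: TiltScheme,
    ctf: CTFParams | None,
    snr: float | None,
    noise_seed: int,
) -> DensityVolume:
    """Degrade one ground-truth volume through the forward model.

    Ordering follows the acquisition-then-correction pipeline: project,
    CTF-modulate, add noise, phase-flip, reconstruct.
    """
    stack = project(gt, scheme)
    if ctf is not None:
        stack = ctf_modulate(stack, ctf, apply_phase_flip=False)
    if snr is not None and snr < 1e8:
        stack = add_gaussian_noise(stack, snr, noise_seed)
    if ctf is not None and ctf.phase_flip:
        stack = phase_flip(stack, ctf)
    return wbp_reconstruct(stack, scheme=scheme)


def build_pairs_strategy2(
    conformations: Sequence[PseudoAtomModel],
    box: int,
    voxel_A: float,
    scheme: TiltScheme,
    ctf: CTFParams | None = None,
    snr: float | None = 0.1,
    n_per_conf: int = 1,
    seed: int = 0,
    resolution_A: float | None = None,
    max_shift_vox: float | None = None,
    normalized: bool = True,
) -> tuple[list[TrainingPair], PairSetManifest]:
    """Simulate training pairs from a conformational ensemble.

    For each conformation and repeat: draw a random rigid transform, render
    the model to density and transform it (ground truth), then degrade it
    through the forward model (input).  Returns the pairs and a manifest
    from which :func:`regenerate_from_manifest` rebuilds them bit-exactly.
    """
    if n_per_conf < 1:
        raise ValueError("n_per_conf must be >= 1")
    if resolution_A is None:
        resolution_A = 3.0 * voxel_A
    if max_shift_vox is None:
        max_shift_vox = box / 16.0
    rng = np.random.default_rng(seed)
    params = {
        "box": box,
        "voxel_A": voxel_A,
        "scheme": [scheme.theta_min_deg, scheme.theta_max_deg, scheme.step_deg],
        "ctf": None if ctf is None else asdict(ctf),
        "snr": snr,
        "n_per_conf": n_per_conf,
        "seed": seed,
        "resolution_A": resolution_A,
        "max_shift_vox": max_shift_vox,
        "normalized": normalized,
    }
    pairs: list[TrainingPair] = []
    entries: list[dict] = []
    for ci, conf in enumerate(conformations):
        for rep in range(n_per_conf):
            t = random_transform(rng, max_shift_vox)
            noise_seed = int(rng.integers(0, 2**31 - 1))
            pair, entry = _make_strategy2_pair(
                conf, ci, rep, t, noise_seed, params
            )
            pairs.append(pair)
            entries.append(entry)
    manifest = PairSetManifest(MANIFEST_FORMAT_VERSION, "2", params, entries)
    return pairs, manifest


def _make_strategy2_pair(conf, conf_index, rep, t, noise_seed, params):
    box, voxel_A = params["box"], params["voxel_A"]
    scheme = TiltScheme(*params["scheme"])
    ctf = None if params["ctf"] is None else CTFParams(**params["ctf"])
    base = model_to_density(conf, voxel_A, box, resolution_A=params["resolution_A"])
    gt = apply_transform(base, t)
    inp = _simulate_one(gt, scheme, ctf, params["snr"], noise_seed)
    if params["normalized"]:
        gt = normalize_volume(gt)
        inp = normalize_volume(inp)
    entry = {
        "conformation": conf_index,
        "repeat": rep,
        "euler_deg": list(t.euler_deg),
        "shift_vox": list(t.shift_vox),
        "noise_seed": noise_seed,
    }
    prov = {"strategy": "2", **entry, "normalized": params["normalized"]}
    return TrainingPair(inp, gt, prov), entry


def regenerate_from_manifest(
    manifest: PairSetManifest, conformations: Sequence[PseudoAtomModel]
) -> list[TrainingPair]:
    """Rebuild every pair bit-exactly from its manifest entry."""
    if manifest.strategy != "2":
        raise ValueError("only strategy-2 manifests can be regenerated here")
    pairs = []
    for entry in manifest.entries:
        t = RigidTransform(tuple(entry["euler_deg"]), tuple(entry["shift_vox"]))
        pair, _ = _make_strategy2_pair(
            conformations[entry["conformation"]],
            entry["conformation"],
            entry["repeat"],
            t,
            entry["noise_seed"],
            manifest.params,
        )
        pairs.append(pair)
    return pairs


def split_pairs(
    pairs: Sequence[TrainingPair], validation_fraction: float = 0.1, seed: int = 0
) -> tuple[list[TrainingPair], list[TrainingPair]]:
    """Seeded random train/validation split (default 90/10)."""
    if not 0.0 <= validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_val = int(round(validation_fraction * len(pairs)))
    val_idx = set(order[:n_val].tolist())
    train = [p for i, p in enumerate(pairs) if i not in val_idx]
    val = [p for i, p in enumerate(pairs) if i in val_idx]
    return train, val


def simulate_tomogram(
    conformations: Sequence[PseudoAtomModel],
    n_particles: int,
    box: int,
    voxel_A: float,
    scheme: TiltScheme,
    ctf: CTFParams | None = None,
    snr: float | None = 0.1,
    seed: int = 0,
    particle_box: int = 32,
    resolution_A: float | None = None,
    min_separation_vox: float | None = None,
    orientation_grid_deg: float | None = None,
) -> tuple[DensityVolume, DensityVolume, list[tuple[int, int, int]], list[RigidTransform]]:
    """Simulate a crowded tomogram with known particle positions.

    Particles (randomly chosen conformations, random orientations) are
    pasted at random, mutually separated integer centres into a clean
    ``box``³ volume, which is then degraded through the forward model
    exactly like a training-pair input.  Returns ``(degraded, ground_truth,
    centers_xyz, transforms)``.

    With ``orientation_grid_deg`` set, orientations are drawn uniformly
    from the ZYZ grid of that step instead of continuously.  Benchmarks
    that search the same grid use this to separate localisation error
    caused by noise and the missing wedge from the quantisation error of a
    coarse angular search.
    """
    if resolution_A is None:
        resolution_A = 3.0 * voxel_A
    if min_separation_vox is None:
        min_separation_vox = 1.25 * particle_box
    rng = np.random.default_rng(seed)
    margin = particle_box // 2 + 2
    centers: list[tuple[int, int, int]] = []
    attempts = 0
    while len(centers) < n_particles:
        attempts += 1
        if attempts > 10000 * n_particles:
            raise RuntimeError(
                "could not place particles with the requested separation"
            )
        cand = tuple(int(v) for v in rng.integers(margin, box - margin, 3))  # (x, y, z)
        if all(
            (cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 + (cand[2] - c[2]) ** 2
            >= min_separation_vox**2
            for c in centers
        ):
            centers.append(cand)
    gt = np.zeros((box, box, box))
    transforms: list[RigidTransform] = []
    half = particle_box // 2
    for cx, cy, cz in centers:
        conf = conformations[int(rng.integers(0, len(conformations)))]
        if orientation_grid_deg is None:
            t = random_transform(rng, max_shift_vox=0.0)
        else:
            g = orientation_grid_deg
            t = RigidTransform(
                (
                    g * float(rng.integers(0, max(1, int(360 / g)))),
                    g * float(rng.integers(0, max(1, int(180 / g)) + 1)),
                    g * float(rng.integers(0, max(1, int(360 / g)))),
                )
            )
        transforms.append(t)
        base = model_to_density(conf, voxel_A, particle_box, resolution_A=resolution_A)
        part = apply_transform(base, t)
        gt[
            cz - half : cz + half, cy - half : cy + half, cx - half : cx + half
        ] += part.values
    gt_vol = DensityVolume(gt, voxel_A)
    noise_seed = int(rng.integers(0, 2**31 - 1))
    degraded = _simulate_one(gt_vol, scheme, ctf, snr, noise_seed)
    return degraded, gt_vol, centers, transforms


# ---------------------------------------------------------------------------
# subvolume extraction


def extract_subvolumes(
    tomogram: DensityVolume,
    centers: Sequence[tuple[int, int, int]],
    box: int,
    pad_policy: str = "zero",
) -> list[DensityVolume]:
    """Crop ``box``³ subvolumes centred on integer voxel coordinates (x, y, z).

    With ``pad_policy="zero"`` out-of-bounds voxels are zero-filled; with
    ``"reject"`` an out-of-bounds centre raises.  The crop spans
    ``[c - box//2, c + box//2)`` on each axis, so re-inserting the crop at
    its centre reproduces the original region exactly.
    """
    if box % 2 != 0:
        raise ValueError("box must be even")
    if pad_policy not in ("zero", "reject"):
        raise ValueError("pad_policy must be 'zero' or 'reject'")
    shape = tomogram.values.shape  # (z, y, x)
    half = box // 2
    out = []
    for cx, cy, cz in centers:
        lo = np.array([cz - half, cy - half, cx - half])
        hi = lo + box
        if pad_policy == "reject" and (np.any(lo < 0) or np.any(hi > shape)):
            raise ValueError(f"subvolume at centre ({cx}, {cy}, {cz}) leaves the tomogram")
        crop = np.zeros((box, box, box), dtype=tomogram.values.dtype)
        src_lo = np.maximum(lo, 0)
        src_hi = np.minimum(hi, shape)
        dst_lo = src_lo - lo
        dst_hi = dst_lo + (src_hi - src_lo)
        if np.all(src_hi > src_lo):
            crop[
                dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]
            ] = tomogram.values[
                src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]
            ]
        out.append(DensityVolume(crop, tomogram.voxel_A))
    return out
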