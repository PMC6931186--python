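"""Brain-like 3D phantoms with known lesions.

Each phantom is an ellipsoidal "brain" support holding a smooth low-frequency
intensity field (a base level plus a few broad Gaussian bumps, so in-plane
and through-plane normalizations genuinely differ), an ellipsoidal lesion
with an intensity offset, and additive Gaussian noise inside the support.
Background outside the support is exactly zero, emulating skull-stripped
input.  Two modalities are produced from the same anatomy with different
lesion contrast (the primary emulating T1, where chronic lesions read dark,
and an auxiliary emulating FLAIR, where they read bright), plus the exact
voxelized lesion as ground truth.

Lesions are single connected components placed in the left hemisphere half
of the support, matching the study population the system targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import SizeClass, classify_lesion_size
from .volume_io import BrainVolume, LesionMask, VolumeValidationError

DEFAULT_SHAPE = (48, 64, 48)


@dataclass
class PhantomSpec:
    """Full description of one phantom; deterministic given ``seed``.

    Lengths are in mm; with the default 1 mm spacing, voxels and mm coincide.
    ``lesion_center`` is in voxel coordinates of the canonical
    (inferior-superior, posterior-anterior, left-right) array.
    """

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_radii_frac: tuple[float, float, float] = (0.42, 0.42, 0.42)
    base_intensity: float = 1.0
    n_bumps: int = 4
    bump_amplitude: float = 0.25
    lesion_center: tuple[float, float, float] = (24.0, 32.0, 14.0)
    lesion_radii_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    lesion_offset_a: float = -0.35
    lesion_offset_b: float = 0.45
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s % 16 for s in self.shape):
            raise VolumeValidationError(f"shape {self.shape} must be divisible by 16")
        if any(r <= 0 for r in self.lesion_radii_mm):
            raise VolumeValidationError("lesion radii must be positive")


@dataclass
class PhantomCase:
    """One generated case: two modalities, truth mask, and bookkeeping."""

    case_id: str
    volume_a: BrainVolume
    volume_b: BrainVolume
    mask: LesionMask
    spec: PhantomSpec
    size_class: SizeClass


def _grid(shape):
    return np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape),
                       indexing="ij")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    xs = _grid(shape)
    acc = np.zeros(shape, dtype=np.float64)
    for x, c, r in zip(xs, center, radii):
        acc += ((x - c) / r) ** 2
    return acc <= 1.0


def brain_support(spec: PhantomSpec) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in spec.shape]
    radii = [f * s for f, s in zip(spec.brain_radii_frac, spec.shape)]
    return _ellipsoid(spec.shape, center, radii)


def lesion_region(spec: PhantomSpec) -> np.ndarray:
    radii_vox = [r / sp for r, sp in zip(spec.lesion_radii_mm, spec.spacing)]
    return _ellipsoid(spec.shape, spec.lesion_center, radii_vox)


def generate_phantom(spec: PhantomSpec) -> tuple[BrainVolume, BrainVolume, LesionMask]:
    """Generate one phantom pair and its ground-truth mask.

    Raises :class:`VolumeValidationError` if the lesion is empty or extends
    outside the brain support.
    """
    rng = np.random.default_rng(spec.seed)
    support = brain_support(spec)
    lesion = lesion_region(spec)
    if not lesion.any():
        raise VolumeValidationError("lesion region voxelizes to empty")
    if (lesion & ~support).any():
        raise VolumeValidationError("lesion extends outside the brain support")

    field_ = np.full(spec.shape, spec.base_intensity, dtype=np.float64)
    xs = _grid(spec.shape)
    for _ in range(spec.n_bumps):
        amp = rng.uniform(-spec.bump_amplitude, spec.bump_amplitude)
        center = [rng.uniform(0.25 * s, 0.75 * s) for s in spec.shape]
        sigma = [rng.uniform(0.25 * s, 0.6 * s) for s in spec.shape]
        expo = np.zeros(spec.shape, dtype=np.float64)
        for x, c, sg in zip(xs, center, sigma):
            expo += ((x - c) / sg) ** 2
        field_ += amp * np.exp(-0.5 * expo)

    vols = []
    for offset in (spec.lesion_offset_a, spec.lesion_offset_b):
        intens = field_ + offset * lesion
        if spec.noise_sd > 0:
            intens = intens + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        intens = np.where(support, intens, 0.0)
        vols.append(BrainVolume(data=intens.astype(np.float32),
                                spacing=spec.spacing))
    mask = LesionMask(data=lesion.astype(np.uint8), spacing=spec.spacing)
    return vols[0], vols[1], mask


def _sample_lesion(rng: np.random.Generator, spec: PhantomSpec,
                   small: bool) -> tuple[tuple, tuple]:
    """Draw a lesion center (left half) and radii for one size class.

    Small lesions have all bounding-box extents strictly below the size-rule
    thresholds; large ones are elongated along the posterior-anterior axis so
    at least one extent meets its threshold.
    """
    shape = spec.shape
    brain_mm = [f * s * sp for f, s, sp in
                zip(spec.brain_radii_frac, shape, spec.spacing)]
    cIS = rng.uniform(0.38 * shape[0], 0.62 * shape[0])
    cPA = rng.uniform(0.38 * shape[1], 0.62 * shape[1])
    # left hemisphere: below the mid-sagittal index on the left-right axis
    cLR = rng.uniform(0.26 * shape[2], 0.40 * shape[2])
    if small:
        high = min(6.0, 0.35 * min(brain_mm))
        radii = tuple(rng.uniform(0.6 * high, high, size=3))
    else:
        # elongated along posterior-anterior so one bbox extent passes the
        # large threshold; infeasible on grids much smaller than the default
        if 0.5 * brain_mm[1] < 10.5:
            raise VolumeValidationError(
                f"grid {shape} too small to host large lesions; use "
                "size_mix=1.0 or a larger grid")
        radii = (rng.uniform(6.0, min(9.0, 0.4 * brain_mm[0])),
                 rng.uniform(10.5, min(13.0, 0.5 * brain_mm[1])),
                 rng.uniform(5.0, min(8.0, 0.35 * brain_mm[2])))
    return (cIS, cPA, cLR), radii


def generate_dataset(n: int, base_spec: PhantomSpec | None = None,
                     size_mix: float = 0.5, seed: int = 0,
                     id_prefix: str = "case") -> list[PhantomCase]:
    """Generate *n* randomized cases from a master seed.

    ``size_mix`` is the fraction of cases drawn small (round(size_mix * n)
    exactly, in shuffled order); lesion location, radii, and contrast jitter
    vary per case, with per-case seeds derived from the master seed.
    """
    if n < 1:
        raise VolumeValidationError("need at least one case")
    if not 0.0 <= size_mix <= 1.0:
        raise VolumeValidationError(f"size_mix must be in [0, 1], got {size_mix}")
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    n_small = int(round(size_mix * n))
    smalls = np.array([True] * n_small + [False] * (n - n_small))
    master.shuffle(smalls)
    case_seeds = master.integers(0, 2 ** 31 - 1, size=n)

    cases: list[PhantomCase] = []
    for i in range(n):
        rng = np.random.default_rng(int(case_seeds[i]))
        for attempt in range(64):
            center, radii = _sample_lesion(rng, base, bool(smalls[i]))
            jitter = rng.uniform(0.8, 1.2)
            spec = replace(
                base,
                lesion_center=center,
                lesion_radii_mm=radii,
                lesion_offset_a=base.lesion_offset_a * jitter,
                lesion_offset_b=base.lesion_offset_b * jitter,
                seed=int(case_seeds[i]) + attempt,
            )
            try:
                vol_a, vol_b, mask = generate_phantom(spec)
                break
            except VolumeValidationError:
                continue
        else:  # pragma: no cover - geometry makes this unreachable in practice
            raise VolumeValidationError(f"could not place lesion for case {i}")
        size = classify_lesion_size(mask.data, spec.spacing)
        cases.append(PhantomCase(case_id=f"{id_prefix}{i:03d}", volume_a=vol_a,
                                 volume_b=vol_b, mask=mask, spec=spec,
                                 size_class=size))
    return cases
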