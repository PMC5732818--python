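"""Seeded synthetic CT-like cohorts with class-conditional tumor texture.

The generator emulates the statistical structure the downstream analysis
assumes, at the scale of the study it mirrors: two response classes
(responders labelled CR/PR, nonresponders labelled SD) whose tumors differ
in intra-lesion texture rather than in gross geometry.  Each tumor is a
random ellipsoid filled with a correlated Gaussian random field (smoothed
white noise with a tunable correlation length) passed through a monotone
exponential skewing transform, so the two quantities the analysis keys on —
heterogeneity scale and intensity-histogram skewness — are independently
tunable per class.  A second observer's contour is emulated by a random
morphological perturbation of the true mask.

Everything is deterministic under the cohort seed: per-case child seeds are
spawned from it, so any case can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

RESPONDER_LABELS = frozenset({"CR", "PR"})
NONRESPONDER_LABELS = frozenset({"SD", "PD"})
VALID_LABELS = RESPONDER_LABELS | NONRESPONDER_LABELS


class InvalidCohortSpecError(ValueError):
    """Raised when a synthetic cohort specification is inconsistent."""


@dataclass
class TextureParams:
    """Intra-tumor texture model for one response class.

    Parameters
    ----------
    mean_intensity : float
        Mean in-mask intensity (HU-like).
    correlation_length : float
        Spatial smoothness of the heterogeneity field, in mm (Gaussian
        kernel scale of the smoothed white noise).
    skew_strength : float
        Strength of the monotone exponential skewing transform applied to
        the standardized field; 0 leaves the field Gaussian (skewness 0),
        positive values produce right-skewed intensity histograms.
    heterogeneity_sd : float
        Standard deviation of the textured component, in intensity units.
    """

    mean_intensity: float = 60.0
    correlation_length: float = 4.0
    skew_strength: float = 0.0
    heterogeneity_sd: float = 15.0

    def __post_init__(self) -> None:
        if self.correlation_length <= 0:
            raise InvalidCohortSpecError("correlation_length must be > 0")
        if self.heterogeneity_sd < 0:
            raise InvalidCohortSpecError("heterogeneity_sd must be >= 0")


@dataclass
class SyntheticCohortSpec:
    """Specification of a two-class synthetic cohort.

    Defaults mirror the cohort scale of the study being emulated: 33
    responders and 16 nonresponders, anisotropic 0.97×0.97×2.5 mm voxels,
    tumors 8–15 mm in radius.  Nonresponders carry a right-skewed, more
    coarsely correlated texture; responders a symmetric, finer one.
    """

    n_responders: int = 33
    n_nonresponders: int = 16
    volume_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_spacing: tuple[float, float, float] = (0.97, 0.97, 2.5)
    tumor_radius_range: tuple[float, float] = (8.0, 15.0)
    responder_texture: TextureParams = field(
        default_factory=lambda: TextureParams(
            mean_intensity=60.0, correlation_length=4.0,
            skew_strength=0.0, heterogeneity_sd=15.0))
    nonresponder_texture: TextureParams = field(
        default_factory=lambda: TextureParams(
            mean_intensity=60.0, correlation_length=8.0,
            skew_strength=1.2, heterogeneity_sd=15.0))
    noise_sd: float = 5.0
    # background emulates low-contrast peritumoral soft tissue (~15 HU
    # below the tumor mean): features are mask-restricted, but a perturbed
    # observer contour may include a thin background shell, and real
    # esophageal tumor boundaries are low-contrast
    background_intensity: float = 45.0
    observer_perturbation_mm: float = 1.0
    # between-patient variability: per-case texture parameters are jittered
    # around the class values (multiplicative lognormal with this sigma on
    # correlation length, heterogeneity, skew strength and noise; additive
    # Gaussian of mean_intensity_sd on the mean).  Real cohorts vary from
    # patient to patient; without this the between-case variance that
    # reproducibility analysis (ICC) measures against would be degenerate.
    between_case_variation: float = 0.25
    mean_intensity_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise InvalidCohortSpecError("each class needs at least one case")
        if any(s <= 0 for s in self.voxel_spacing):
            raise InvalidCohortSpecError("voxel_spacing must be strictly positive")
        lo, hi = self.tumor_radius_range
        if not 0 < lo <= hi:
            raise InvalidCohortSpecError("tumor_radius_range must be 0 < lo <= hi")
        extent = [n * s for n, s in zip(self.volume_shape, self.voxel_spacing)]
        if any(2 * hi >= e for e in extent):
            raise InvalidCohortSpecError(
                f"max tumor diameter {2 * hi} mm does not fit inside the "
                f"field of view {extent} mm")


@dataclass
class PatientCase:
    """One subject: volume, contour(s) and response label."""

    case_id: str
    volume: np.ndarray
    spacing: tuple[float, float, float]
    mask_primary: np.ndarray
    label: str
    mask_secondary: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"case {self.case_id}: unknown label {self.label!r}")
        if self.mask_primary.shape != self.volume.shape:
            raise ValueError(f"case {self.case_id}: mask/volume shape mismatch")
        if not self.mask_primary.any():
            raise ValueError(f"case {self.case_id}: empty primary mask")
        if (self.mask_secondary is not None
                and self.mask_secondary.shape != self.volume.shape):
            raise ValueError(f"case {self.case_id}: secondary mask shape mismatch")

    @property
    def responder(self) -> bool:
        """CR and PR are responders; SD and PD are nonresponders."""
        return self.label in RESPONDER_LABELS


def _ellipsoid_mask(shape, spacing, radius, rng) -> np.ndarray:
    """Random ellipsoid with mean radius ``radius`` mm, random orientation."""
    # semi-axes within +/-25% of the nominal radius, geometric mean preserved
    ratios = rng.uniform(0.75, 1.25, size=3)
    ratios /= ratios.prod() ** (1 / 3)
    semi = radius * ratios
    # random rotation from QR decomposition of a Gaussian matrix
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    center = np.array([(n - 1) / 2 * s for n, s in zip(shape, spacing)])
    coords = np.stack(np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                                  indexing="ij"), axis=-1) - center
    local = coords @ q  # rotate into ellipsoid frame
    return (np.sum((local / semi) ** 2, axis=-1) <= 1.0)


def _correlated_field(shape, spacing, correlation_length, rng) -> np.ndarray:
    """Unit-variance Gaussian field: white noise smoothed at a mm scale."""
    white = rng.normal(size=shape)
    sigma_vox = [correlation_length / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _skew_transform(z: np.ndarray, strength: float) -> np.ndarray:
    """Monotone exponential skewing; strength 0 is the identity.

    ``(exp(s z) - 1)/s`` is increasing in ``z`` for every ``s`` and tends to
    ``z`` as ``s → 0``; for ``s > 0`` it stretches the right tail, giving a
    right-skewed marginal from a symmetric input.
    """
    if strength == 0:
        return z
    return np.expm1(strength * z) / strength


def generate_tumor_volume(
    params: TextureParams,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    radius: float,
    seed: int,
    noise_sd: float = 5.0,
    # background emulates low-contrast peritumoral soft tissue (~15 HU
    # below the tumor mean): features are mask-restricted, but a perturbed
    # observer contour may include a thin background shell, and real
    # esophageal tumor boundaries are low-contrast
    background_intensity: float = 45.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one tumor volume and its true mask.

    The mask is a single connected random ellipsoid of nominal radius
    ``radius`` mm.  In-mask intensities are ``mean_intensity`` plus a
    skewed correlated field scaled to ``heterogeneity_sd``, plus
    independent Gaussian noise of ``noise_sd``.  Identical arguments and
    seed reproduce the volume bit-for-bit.
    """
    extent = [n * s for n, s in zip(shape, spacing)]
    if any(2 * radius >= e for e in extent):
        raise InvalidCohortSpecError(
            f"tumor diameter {2 * radius} mm exceeds field of view {extent} mm")
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(shape, spacing, radius, rng)
    texture = np.zeros(shape)
    if params.heterogeneity_sd > 0:
        z = _correlated_field(shape, spacing, params.correlation_length, rng)
        g = _skew_transform(z, params.skew_strength)
        g_roi = g[mask]
        g = (g - g_roi.mean()) / g_roi.std() if g_roi.std() > 0 else g - g_roi.mean()
        texture = params.heterogeneity_sd * g
    volume = np.full(shape, background_intensity, dtype=float)
    volume[mask] = params.mean_intensity + texture[mask]
    if noise_sd > 0:
        volume += rng.normal(scale=noise_sd, size=shape)
    return volume, mask


def perturb_mask(
    mask: np.ndarray,
    magnitude_mm: float,
    spacing: tuple[float, float, float],
    seed: int,
    max_attempts: int = 10,
) -> np.ndarray:
    """Randomly perturb a contour, emulating a second observer.

    A smooth random field with amplitude ``magnitude_mm`` is added to the
    signed Euclidean distance (mm) to the mask boundary and the surface is
    re-thresholded, producing correlated local dilations and erosions.
    ``magnitude_mm = 0`` returns the input unchanged; expected overlap
    (Dice) with the original decreases as the magnitude grows.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot perturb an empty mask")
    if magnitude_mm == 0:
        return mask.copy()
    spacing = tuple(float(s) for s in spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    signed = outside - inside  # negative inside, positive outside
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        field = _correlated_field(mask.shape, spacing, 3.0, rng)
        new_mask = (signed + magnitude_mm * field) < 0
        new_mask = ndimage.binary_closing(new_mask)
        if new_mask.any() and (new_mask & mask).any():
            return new_mask
    raise RuntimeError(
        f"perturbation of magnitude {magnitude_mm} mm emptied the mask "
        f"in {max_attempts} attempts")


def _case_labels(n_responders: int, n_nonresponders: int) -> list[str]:
    """CR/PR alternating (CR first) for responders; SD for nonresponders."""
    resp = ["CR" if i % 2 == 0 else "PR" for i in range(n_responders)]
    return resp + ["SD"] * n_nonresponders


def generate_cohort(spec: SyntheticCohortSpec) -> list[PatientCase]:
    """Generate the full two-class cohort described by ``spec``.

    Responders come first (labels alternating CR, PR, CR, …), then
    nonresponders (all SD).  Each case carries a secondary mask produced by
    :func:`perturb_mask` at ``spec.observer_perturbation_mm``.
    """
    labels = _case_labels(spec.n_responders, spec.n_nonresponders)
    ss = np.random.SeedSequence(spec.seed)
    case_seeds = [int(s) for s in
                  ss.generate_state(3 * len(labels)) % (2 ** 31)]
    rng = np.random.default_rng(ss.spawn(1)[0])
    cases = []
    for i, label in enumerate(labels):
        base = (spec.responder_texture if label in RESPONDER_LABELS
                else spec.nonresponder_texture)
        radius = rng.uniform(*spec.tumor_radius_range)
        jitter = np.exp(spec.between_case_variation * rng.normal(size=4))
        params = TextureParams(
            mean_intensity=base.mean_intensity
            + spec.mean_intensity_sd * rng.normal(),
            correlation_length=base.correlation_length * jitter[0],
            skew_strength=base.skew_strength * jitter[1],
            heterogeneity_sd=base.heterogeneity_sd * jitter[2],
        )
        volume, mask = generate_tumor_volume(
            params, spec.volume_shape, spec.voxel_spacing, radius,
            seed=case_seeds[3 * i], noise_sd=spec.noise_sd * jitter[3],
            background_intensity=spec.background_intensity)
        mask2 = perturb_mask(mask, spec.observer_perturbation_mm,
                             spec.voxel_spacing, seed=case_seeds[3 * i + 1])
        cases.append(PatientCase(
            case_id=f"case_{i:03d}", volume=volume, spacing=spec.voxel_spacing,
            mask_primary=mask, mask_secondary=mask2, label=label))
    return cases


# ---------------------------------------------------------------------------
# persistence

def write_cohort(cases: list[PatientCase], out_dir: str | Path,
                 spec: SyntheticCohortSpec | None = None,
                 splits: dict[str, str] | None = None) -> Path:
    """Write a cohort as NIfTI volumes/masks plus a cohort CSV table."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        affine = np.diag(list(case.spacing) + [1.0])
        nib.save(nib.Nifti1Image(case.volume.astype(np.float32), affine),
                 out_dir / f"{case.case_id}_volume.nii.gz")
        nib.save(nib.Nifti1Image(case.mask_primary.astype(np.uint8), affine),
                 out_dir / f"{case.case_id}_mask1.nii.gz")
        if case.mask_secondary is not None:
            nib.save(nib.Nifti1Image(case.mask_secondary.astype(np.uint8), affine),
                     out_dir / f"{case.case_id}_mask2.nii.gz")
        rows.append({"case_id": case.case_id, "label": case.label,
                     "responder": case.responder,
                     "split": (splits or {}).get(case.case_id, "")})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "cohort.csv", index=False)
    if spec is not None:
        payload = asdict(spec)
        with open(out_dir / "cohort_spec.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=list)
    return out_dir
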