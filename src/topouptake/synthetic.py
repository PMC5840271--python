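"""Synthetic two-group SPECT phantom cohorts.

The generator emulates the structure of a two-antibody uptake study:
8 subjects in two groups of four, each imaged at 3, 24, 48, and 72 hours
post-injection, yielding 32 images.  Each phantom is a connected
ellipsoidal tumor ROI with

* a brighter vascularized periphery (an outer shell of the ellipsoid with
  elevated baseline uptake),
* several Gaussian intensity bumps — local uptake maxima — some placed in
  the shell, the rest in the interior,
* multiplicative Gaussian noise with standard deviation proportional to
  local intensity (SPECT reconstruction noise is proportional to counts),
* per-group planted linear time trends of overall uptake, an extra trend
  on shell-bump amplitudes (planted high-region heterogeneity), and
* a per-subject scalar heart uptake following an exponential clearance
  curve.

Physical radioactive decay (In-111 half-life 67.32 h) is applied to the
emitted values by default, so the analysis pipeline's decay correction is
exercised; with ``apply_decay=False`` the generator emits decay-free
truth directly.

Everything is deterministic given ``PhantomParams.seed``: subject anatomy
(bump layout) is drawn from a subject-level stream and reused across
hours, while noise is drawn from per-(subject, hour) streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import IN111_HALF_LIFE_H, RawImage, RoiMask

__all__ = [
    "GroupEffects",
    "PhantomParams",
    "PlantedTruth",
    "CohortEntry",
    "Cohort",
    "generate_phantom",
    "generate_cohort",
]

HOURS = (3.0, 24.0, 48.0, 72.0)


@dataclass(frozen=True)
class GroupEffects:
    """Planted per-group effects, in units of the hour-24 interior baseline.

    Time trends are additive and uniform across the ROI: the whole image
    gains ``baseline * slope_per_hour * (t - 24)``.  A uniform additive
    trend gives every diagram coordinate the same expected slope, so
    "homogeneous uptake" means exactly equal high- and low-region trends
    under the absolute-slope comparison the analysis performs.  Planted
    heterogeneity is an *extra* additive growth of the vascularized-shell
    bump amplitudes, ``high_extra_slope_per_hour * (t - 24)``.
    """

    baseline: float = 1.0  # uptake scale at hour 24 (arbitrary µCi-proportional units)
    slope_per_hour: float = 0.0  # uniform uptake change per hour (fraction of baseline)
    high_extra_slope_per_hour: float = 0.0  # extra amplitude growth of shell bumps
    heart_clearance_rate: float = 0.02  # per hour; heart mean ∝ e^{-rate·t}
    heart_baseline: float = 2.0  # heart mean at t = 0 (same units as tumor)


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterization of the synthetic cohort generator."""

    shape: tuple[int, int, int] = (24, 24, 24)
    semi_axes: tuple[float, float, float] = (9.0, 8.0, 7.0)  # voxels
    shell_fraction: float = 0.3  # outer fraction of the radius forming the periphery
    shell_gain: float = 0.6  # relative brightness boost of the shell
    n_bumps: int = 30
    n_shell_bumps: int = 4
    bump_amp_range: tuple[float, float] = (0.25, 0.6)  # interior, relative to baseline
    shell_bump_amp_range: tuple[float, float] = (0.85, 1.05)
    bump_sigma_range: tuple[float, float] = (0.9, 1.4)  # voxels
    amp_jitter: float = 0.02  # per-hour relative amplitude fluctuation per bump
    noise_coeff: float = 0.05  # multiplicative noise SD as a fraction of intensity
    heart_noise_coeff: float = 0.03
    hours: tuple[float, ...] = HOURS
    n_subjects_per_group: int = 4
    group1: GroupEffects = GroupEffects(
        slope_per_hour=-0.004, high_extra_slope_per_hour=0.0, heart_clearance_rate=0.020
    )
    group2: GroupEffects = GroupEffects(
        slope_per_hour=0.004, high_extra_slope_per_hour=0.04, heart_clearance_rate=0.016
    )
    intensity_scale: float = 0.002  # µCi per voxel at unit baseline (sets realistic %ID/g)
    dose: float = 100.0  # injected dose, µCi
    voxel_size: tuple[float, float, float] = (0.4, 0.4, 0.4)  # mm
    half_life_hours: float = IN111_HALF_LIFE_H
    apply_decay: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.shell_fraction < 1:
            raise ValueError("shell_fraction must lie in (0, 1)")
        for name in ("shell_gain", "noise_coeff", "dose"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_shell_bumps > self.n_bumps:
            raise ValueError("n_shell_bumps cannot exceed n_bumps")

    def group_effects(self, group: int) -> GroupEffects:
        return self.group1 if group == 1 else self.group2


@dataclass(frozen=True)
class PlantedTruth:
    """Expected qualitative outcomes, derived deterministically from the params."""

    group_slope_diff_sign: int  # sign of (group1 - group2) overall uptake slope
    high_low_diff_sign_group1: int  # sign of planted high-vs-low slope difference
    high_low_diff_sign_group2: int
    expect_property_i: bool
    expect_property_iii: bool


@dataclass
class CohortEntry:
    image: RawImage
    roi: RoiMask
    heart_mean: float
    dose: float


@dataclass
class Cohort:
    params: PhantomParams
    entries: list[CohortEntry]
    truth: PlantedTruth

    def subjects(self) -> list[str]:
        return sorted({e.image.subject_id for e in self.entries})

    def for_subject(self, subject_id: str) -> list[CohortEntry]:
        return sorted(
            (e for e in self.entries if e.image.subject_id == subject_id),
            key=lambda e: e.image.hour,
        )


def _ellipsoid(params: PhantomParams):
    shape = params.shape
    center = [(n - 1) / 2.0 for n in shape]
    grids = np.indices(shape, dtype=float)
    rho2 = sum(
        ((grids[a] - center[a]) / params.semi_axes[a]) ** 2 for a in range(3)
    )
    rho = np.sqrt(rho2)
    mask = rho <= 1.0
    shell = mask & (rho >= 1.0 - params.shell_fraction)
    return mask, shell, center


def _subject_anatomy(params: PhantomParams, rng: np.random.Generator) -> dict:
    """Bump layout for one subject: positions, amplitudes, widths (hour-invariant)."""
    _, _, center = _ellipsoid(params)
    axes = np.asarray(params.semi_axes)
    inner = 1.0 - params.shell_fraction

    def sample_position(lo: float, hi: float) -> np.ndarray:
        # uniform direction, radial fraction uniform in [lo, hi]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        frac = rng.uniform(lo, hi)
        return np.asarray(center) + direction * frac * axes

    n_interior = params.n_bumps - params.n_shell_bumps
    positions, is_shell, amps = [], [], []
    for _ in range(params.n_shell_bumps):
        positions.append(sample_position(inner + 0.05, 0.85))
        is_shell.append(True)
        amps.append(rng.uniform(*params.shell_bump_amp_range))
    for _ in range(n_interior):
        positions.append(sample_position(0.0, max(inner - 0.05, 0.1)))
        is_shell.append(False)
        amps.append(rng.uniform(*params.bump_amp_range))
    sigmas = rng.uniform(*params.bump_sigma_range, size=params.n_bumps)
    heart_scale = rng.uniform(0.9, 1.1)  # subject-to-subject heart variation
    return {
        "positions": np.array(positions),
        "is_shell": np.array(is_shell),
        "amps": np.array(amps),
        "sigmas": sigmas,
        "heart_scale": heart_scale,
    }


def _offset(baseline: float, slope: float, hour: float) -> float:
    return baseline * slope * (hour - 24.0)


def generate_phantom(
    params: PhantomParams,
    subject: str,
    group: int,
    hour: float,
    anatomy_rng: np.random.Generator,
    noise_rng: np.random.Generator,
) -> tuple[RawImage, RoiMask, float]:
    """One phantom image, its tumor ROI mask, and the subject's heart-mean scalar.

    ``anatomy_rng`` must be freshly seeded identically for every hour of a
    subject (bump layout is the subject's anatomy); ``noise_rng`` varies
    per acquisition.
    """
    mask, shell, _ = _ellipsoid(params)
    if params.n_bumps > mask.sum():
        raise ValueError("more bumps requested than ROI voxels")
    eff = params.group_effects(group)
    anatomy = _subject_anatomy(params, anatomy_rng)

    base = eff.baseline
    trend_offset = _offset(base, eff.slope_per_hour, hour)
    extra_amp = _offset(base, eff.high_extra_slope_per_hour, hour)  # shell bumps only

    field_arr = base * (1.0 + params.shell_gain * shell.astype(float)) + trend_offset
    grids = np.indices(params.shape, dtype=float)
    for pos, shell_bump, amp, sigma in zip(
        anatomy["positions"], anatomy["is_shell"], anatomy["amps"], anatomy["sigmas"]
    ):
        jitter = 1.0 + params.amp_jitter * noise_rng.standard_normal()
        amp_t = base * amp + (extra_amp if shell_bump else 0.0)
        scale = max(amp_t * max(jitter, 0.0), 0.0)
        d2 = sum((grids[a] - pos[a]) ** 2 for a in range(3))
        field_arr += scale * np.exp(-d2 / (2.0 * sigma**2))

    field_arr *= mask
    if params.noise_coeff > 0:
        noise = 1.0 + params.noise_coeff * noise_rng.standard_normal(params.shape)
        field_arr *= np.clip(noise, 0.0, None)
    field_arr = np.clip(field_arr, 0.0, None)

    heart_mean = (
        eff.heart_baseline
        * anatomy["heart_scale"]
        * np.exp(-eff.heart_clearance_rate * hour)
    )
    if params.heart_noise_coeff > 0:
        heart_mean *= max(
            1.0 + params.heart_noise_coeff * noise_rng.standard_normal(), 1e-3
        )

    field_arr *= params.intensity_scale
    heart_mean *= params.intensity_scale
    if params.apply_decay:
        decay = np.exp(-np.log(2.0) / params.half_life_hours * hour)
        field_arr *= decay
        heart_mean *= decay

    image = RawImage(
        values=field_arr,
        voxel_size=params.voxel_size,
        hour=hour,
        subject_id=subject,
        group_id=str(group),
    )
    return image, RoiMask(mask=mask, kind="tumor"), float(heart_mean)


def planted_truth(params: PhantomParams) -> PlantedTruth:
    diff = params.group1.slope_per_hour - params.group2.slope_per_hour
    h1 = params.group1.high_extra_slope_per_hour
    h2 = params.group2.high_extra_slope_per_hour
    return PlantedTruth(
        group_slope_diff_sign=int(np.sign(diff)),
        high_low_diff_sign_group1=int(np.sign(h1)),
        high_low_diff_sign_group2=int(np.sign(h2)),
        expect_property_i=diff != 0,
        expect_property_iii=(h1 == 0) != (h2 == 0),
    )


def generate_cohort(params: PhantomParams) -> Cohort:
    """The full study set: 2 groups × n subjects × hours, plus the planted truth."""
    entries: list[CohortEntry] = []
    group_prefix = {1: "T", 2: "C"}
    for g in (1, 2):
        for s in range(params.n_subjects_per_group):
            subject = f"{group_prefix[g]}{s + 1}"
            subj_key = (g - 1) * params.n_subjects_per_group + s
            for h_idx, hour in enumerate(params.hours):
                anatomy_rng = np.random.default_rng(
                    np.random.SeedSequence(params.seed, spawn_key=(subj_key, 0))
                )
                noise_rng = np.random.default_rng(
                    np.random.SeedSequence(params.seed, spawn_key=(subj_key, 1 + h_idx))
                )
                image, roi, heart_mean = generate_phantom(
                    params, subject, g, hour, anatomy_rng, noise_rng
                )
                entries.append(
                    CohortEntry(image=image, roi=roi, heart_mean=heart_mean, dose=params.dose)
                )
    return Cohort(params=params, entries=entries, truth=planted_truth(params))
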