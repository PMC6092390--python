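"""Synthetic OCTA phantoms and DR cohorts with known ground truth.

Three generators make every downstream stage testable without clinical
images:

* **En-face phantoms** — a 3 x 3 mm, 320 x 320 px capillary-plexus image:
  a central avascular zone bounded by a truncated-Fourier radial contour
  r(theta) = r0 + sum_k a_k cos(k theta + phi_k) (analytic control of
  area/perimeter, hence circularity), and a vessel network grown by
  branching biased random walkers from the image edge, dilated to the
  requested width.  The walker centreline gives a true skeleton-length
  ground truth; the achieved vessel fraction is recomputed from the final
  raster, never echoed from the target.

* **Choroid phantoms** — a B-scan window of dark elliptical lumina on a
  bright stromal background inside a traced total-choroidal-area (TCA)
  band.  Lumina are laid out on a jittered grid with calibrated radii so
  stromal septa persist between them and the dark-pixel fraction lands
  within +-0.02 of the requested luminal fraction.

* **Cohorts** — per-eye metric tables over the six severity groups
  (healthy, no DR, mild/moderate/severe NPDR, PDR).  Default group sizes
  (42, 30, 22, 23, 42, 15; 174 eyes) and per-group metric means/SDs follow
  the reference clinical cohort this package models.  Each eye's metric is
  group mean + patient random intercept + residual, with the residual SD
  shrunk so the total within-group SD matches the requested SD; eyes of
  the same patient share the intercept.  Metrics are generated
  independently of each other and of the covariates (a documented
  limitation: adequate for exercising trend/ROC machinery, silent on
  cross-metric correlation).

Intensity model for images: 8-bit range, vessels/stroma at 200, background
/lumen at 30, optional additive Gaussian noise clipped to [0, 255].  All
generators are bit-reproducible for a fixed spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.draw import disk as _draw_disk
from skimage.morphology import disk as _disk_footprint

from .geometry import CalibratedImage, PolygonROI, pixels_per_mm

__all__ = [
    "EnFacePhantomSpec", "EnFacePhantom", "generate_enface_phantom",
    "ChoroidPhantomSpec", "ChoroidPhantom", "generate_choroid_phantom",
    "CohortSpec", "generate_cohort",
    "GROUP_SIZES", "GROUP_METRIC_MEANS", "GROUP_METRIC_SDS", "COVARIATE_MODEL",
]

VESSEL_INTENSITY = 200
BACKGROUND_INTENSITY = 30

# --- reference six-group cohort parameters --------------------------------
# Eyes per group: healthy, no DR, mild NPDR, moderate NPDR, severe NPDR, PDR.
GROUP_SIZES: tuple[int, ...] = (42, 30, 22, 23, 42, 15)

#: per-metric group means (same group order); units: FAZ area mm^2,
#: perimeter mm, circularity unitless, vessel density %, VLD mm^-1, CVI %.
GROUP_METRIC_MEANS: dict[str, tuple[float, ...]] = {
    "faz_area_scp":  (0.40, 0.42, 0.41, 0.42, 0.47, 0.50),
    "faz_perim_scp": (2.54, 2.89, 3.05, 3.13, 3.34, 3.42),
    "faz_circ_scp":  (0.77, 0.62, 0.55, 0.54, 0.54, 0.51),
    "vd_scp":        (35.95, 35.90, 35.73, 35.14, 35.27, 34.77),
    "vld_scp":       (15.75, 14.50, 13.32, 12.51, 13.37, 13.38),
    "faz_area_dcp":  (0.52, 0.55, 0.60, 0.63, 0.60, 0.64),
    "faz_perim_dcp": (2.87, 3.27, 3.80, 3.69, 3.80, 4.01),
    "faz_circ_dcp":  (0.79, 0.65, 0.52, 0.53, 0.53, 0.51),
    "vd_dcp":        (34.95, 35.03, 34.94, 34.72, 34.70, 34.32),
    "vld_dcp":       (18.78, 18.42, 16.89, 16.80, 16.48, 16.83),
    "cvi":           (69.21, 67.06, 66.60, 66.18, 66.15, 63.10),
}

GROUP_METRIC_SDS: dict[str, tuple[float, ...]] = {
    "faz_area_scp":  (0.13, 0.10, 0.10, 0.11, 0.10, 0.17),
    "faz_perim_scp": (0.42, 0.42, 0.40, 0.49, 0.48, 0.54),
    "faz_circ_scp":  (0.14, 0.08, 0.07, 0.06, 0.10, 0.09),
    "vd_scp":        (0.59, 0.81, 0.85, 0.79, 0.84, 0.70),
    "vld_scp":       (2.93, 3.49, 3.46, 3.25, 2.64, 2.86),
    "faz_area_dcp":  (0.14, 0.18, 0.22, 0.21, 0.15, 0.19),
    "faz_perim_dcp": (0.53, 0.69, 0.73, 0.73, 0.06, 0.65),
    "faz_circ_dcp":  (0.15, 0.10, 0.07, 0.09, 0.09, 0.08),
    "vd_dcp":        (0.72, 0.75, 0.61, 0.87, 0.98, 0.96),
    "vld_dcp":       (2.32, 2.59, 3.04, 2.56, 1.88, 2.53),
    "cvi":           (2.24, 3.98, 3.03, 3.04, 2.63, 3.45),
}

#: covariate distributions per group: age (years), diastolic BP (mmHg) as
#: (mean, sd); sex as the probability of female (coded sex = 0; male = 1).
#: The reference cohort reports no diastolic BP for healthy controls, so a
#: plausible normotensive 75.5 +- 9.0 mmHg is used there.
COVARIATE_MODEL: dict[str, tuple] = {
    "age":        ((51.7, 14.0), (55.9, 13.5), (60.0, 13.6),
                   (58.7, 12.9), (57.6, 10.4), (57.6, 9.9)),
    "dbp":        ((75.5, 9.0), (76.2, 9.4), (78.6, 8.2),
                   (74.5, 8.3), (76.4, 10.9), (76.1, 9.2)),
    "female_frac": (0.714, 0.567, 0.500, 0.478, 0.524, 0.467),
    "ssi":        (72.0, 6.0),  # signal strength index, shared across groups
}


# --- en-face phantom ------------------------------------------------------

@dataclass(frozen=True)
class EnFacePhantomSpec:
    """Parameters of a synthetic en-face capillary-plexus image.

    Defaults emulate a healthy 3 x 3 mm scan: FAZ mean radius 0.357 mm
    (area ~0.40 mm^2), mild contour irregularity, vessel fraction ~0.36,
    capillary width 3 px (~28 um at 106.67 px/mm).
    """

    image_px: int = 320
    extent_mm: float = 3.0
    faz_mean_radius: float = 0.357
    faz_harmonic_amps: tuple[float, ...] = (0.0, 0.02, 0.015)
    vessel_fraction_target: float = 0.36
    vessel_width_px: float = 3.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_px < 32:
            raise ValueError("image_px must be >= 32")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be > 0")
        if not 0 <= self.vessel_fraction_target < 1:
            raise ValueError("vessel_fraction_target must be in [0, 1)")
        if not self.faz_mean_radius < self.extent_mm / 2:
            raise ValueError("faz_mean_radius must be smaller than half the extent")
        if self.vessel_width_px <= 0:
            raise ValueError("vessel_width_px must be positive")


@dataclass(frozen=True)
class EnFacePhantom:
    """Rendered phantom plus its recomputed ground truth."""

    image: CalibratedImage
    truth_vessel_mask: np.ndarray
    truth_faz_polygon: PolygonROI
    truth_vessel_fraction: float
    truth_skeleton_length_mm: float
    spec: EnFacePhantomSpec


def _faz_radius_px(spec: EnFacePhantomSpec, phases: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """FAZ boundary radius (px) at polar angles theta."""
    scale = pixels_per_mm(spec.image_px, spec.extent_mm)
    r = np.full_like(theta, spec.faz_mean_radius)
    for k, (a, phi) in enumerate(zip(spec.faz_harmonic_amps, phases), start=1):
        r = r + a * np.cos(k * theta + phi)
    if (r <= 0).any():
        raise ValueError("harmonic amplitudes collapse the FAZ contour through the centre")
    return r * scale


def faz_polygon(spec: EnFacePhantomSpec, phases: np.ndarray, n_vertices: int = 256) -> PolygonROI:
    """Closed Fourier-perturbed FAZ contour sampled at ``n_vertices``."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    r = _faz_radius_px(spec, phases, theta)
    c = (spec.image_px - 1) / 2.0
    return PolygonROI(vertices=np.column_stack(
        [c + r * np.cos(theta), c + r * np.sin(theta)]), layer=None, image=None)


def generate_enface_phantom(spec: EnFacePhantomSpec) -> EnFacePhantom:
    """Grow a vessel-network phantom with a central avascular zone.

    Branching biased random walkers are launched from the image border and
    stepped until they leave the image or reach a keep-out margin around
    the FAZ contour; their rasterized centrelines, dilated to the vessel
    width, form the mask.  Walkers are added until the dilated foreground
    fraction reaches the target; the run errors out rather than silently
    clipping if the target is unreachable (the added area stalls).

    Ground-truth fields are recomputed from the final rasters:
    ``truth_vessel_fraction`` is the realised mask fraction (required to be
    within +-20% relative of the target) and ``truth_skeleton_length_mm``
    is the centreline pixel count times the pixel pitch — the same
    pixel-counting length metric the quantification pipeline reports.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_px
    phases = rng.uniform(0.0, 2.0 * math.pi, size=len(spec.faz_harmonic_amps))
    polygon = faz_polygon(spec, phases)
    centre = (n - 1) / 2.0

    # keep-out radius: walkers stop before the dilated tube can reach the FAZ
    margin_px = spec.vessel_width_px / 2.0 + 1.0

    def faz_keepout(x: float, y: float) -> bool:
        dx, dy = x - centre, y - centre
        rad = math.hypot(dx, dy)
        theta = math.atan2(dy, dx)
        r_b = float(_faz_radius_px(spec, phases, np.array([theta]))[0])
        return rad < r_b + margin_px

    centerline = np.zeros((n, n), dtype=bool)
    target = spec.vessel_fraction_target
    footprint = _disk_footprint(max(int(round(spec.vessel_width_px / 2.0)), 1))

    def dilated_fraction() -> float:
        return float(binary_dilation(centerline, structure=footprint).mean())

    if target > 0:
        faz_area_frac = math.pi * (spec.faz_mean_radius / spec.extent_mm) ** 2
        if target > 0.95 * (1.0 - faz_area_frac):
            raise ValueError(
                f"vessel_fraction_target {target} unreachable: avascular zone leaves "
                f"at most {1.0 - faz_area_frac:.2f} of the image available")
        # sprouting model: each round seeds a new vessel at a random point of
        # vessel-free space and grows two smooth walkers in opposite
        # directions; a walker stops when it anastomoses with (comes within
        # stop_dist of) a foreign vessel, leaves the image, or reaches the
        # FAZ keep-out.  Stopping on contact keeps tubes from running merged
        # in parallel, so the skeleton of the dilated network preserves the
        # laid-down centreline length.
        sigma, grace, trail_len, stop_dist, branch_p = 0.10, 6, 15, 2, 0.01
        seed_clear = stop_dist + 2

        def walk(x: float, y: float, ang: float, max_steps: int,
                 stack: list[tuple[float, float, float, int]]) -> None:
            recent: list[tuple[int, int]] = []
            steps, age = max_steps, 0
            while steps > 0:
                steps -= 1
                age += 1
                ang += rng.normal(0.0, sigma)
                x += math.cos(ang)
                y += math.sin(ang)
                if not (0 <= x <= n - 1 and 0 <= y <= n - 1):
                    return
                if faz_keepout(x, y):
                    return
                i, j = int(round(y)), int(round(x))
                hit = False
                if age > grace:
                    nb = centerline[max(i - stop_dist, 0):i + stop_dist + 1,
                                    max(j - stop_dist, 0):j + stop_dist + 1]
                    if nb.any():
                        own = sum(1 for (ii, jj) in recent
                                  if abs(ii - i) <= stop_dist and abs(jj - j) <= stop_dist)
                        if int(nb.sum()) > own:
                            hit = True
                centerline[i, j] = True
                recent.append((i, j))
                if len(recent) > trail_len:
                    recent.pop(0)
                if hit:
                    return
                if rng.random() < branch_p and len(stack) < 64:
                    stack.append((x, y,
                                  ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.1),
                                  steps))

        max_rounds, rounds = 3000, 0
        frac = 0.0
        while frac < target:
            rounds += 1
            if rounds > max_rounds:
                raise ValueError(
                    f"vessel_fraction_target {target} unreachable within the iteration "
                    f"budget (reached {frac:.3f})")
            # short sprouts near the target keep the overshoot small
            max_steps = 3 * n if target - frac > 0.05 else 80
            placed = False
            for _ in range(200):
                sx, sy = rng.uniform(0, n - 1), rng.uniform(0, n - 1)
                i, j = int(round(sy)), int(round(sx))
                free = not centerline[max(i - seed_clear, 0):i + seed_clear + 1,
                                      max(j - seed_clear, 0):j + seed_clear + 1].any()
                if free and not faz_keepout(sx, sy):
                    ang = rng.uniform(0.0, 2.0 * math.pi)
                    stack = [(sx, sy, ang, max_steps), (sx, sy, ang + math.pi, max_steps)]
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"vessel_fraction_target {target} unreachable: no vessel-free space "
                    f"left at fraction {frac:.3f}")
            while stack:
                walk(*stack.pop(), stack)
            frac = dilated_fraction()

    mask = binary_dilation(centerline, structure=footprint) if centerline.any() \
        else np.zeros((n, n), dtype=bool)
    achieved = float(mask.mean())
    if target > 0 and abs(achieved - target) > 0.2 * target:
        raise ValueError(
            f"achieved vessel fraction {achieved:.3f} deviates more than 20% from "
            f"target {target}")

    image = np.full((n, n), float(BACKGROUND_INTENSITY))
    image[mask] = float(VESSEL_INTENSITY)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    pixels = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    px_mm = spec.extent_mm / spec.image_px
    return EnFacePhantom(
        image=CalibratedImage(pixels=pixels, extent_mm=(spec.extent_mm, spec.extent_mm)),
        truth_vessel_mask=mask,
        truth_faz_polygon=polygon,
        truth_vessel_fraction=achieved,
        truth_skeleton_length_mm=float(centerline.sum()) * px_mm,
        spec=spec,
    )


# --- choroid phantom ------------------------------------------------------

@dataclass(frozen=True)
class ChoroidPhantomSpec:
    """Parameters of a synthetic subfoveal choroid B-scan window.

    Defaults emulate a healthy choroid (luminal fraction ~0.69) over a
    220 x 320 px window at 7 um/px laterally.  The same pitch is used
    axially — the CVI is a pixel-count ratio and does not depend on it.
    """

    window_px: tuple[int, int] = (220, 320)  # (height, width)
    lateral_scale_um_per_px: float = 7.0
    true_luminal_fraction: float = 0.69
    lumen_radius_px: float = 7.0
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.true_luminal_fraction < 1:
            raise ValueError("true_luminal_fraction must be in [0, 1)")
        if self.lateral_scale_um_per_px <= 0:
            raise ValueError("lateral_scale_um_per_px must be positive")
        if self.lumen_radius_px <= 0:
            raise ValueError("lumen_radius_px must be positive")


@dataclass(frozen=True)
class ChoroidPhantom:
    image: CalibratedImage
    truth_luminal_mask: np.ndarray
    tca_polygon: PolygonROI
    spec: ChoroidPhantomSpec


def _tca_band_polygon(h: int, w: int, rng: np.random.Generator) -> PolygonROI:
    """Gently undulating choroid band spanning the window width."""
    margin = max(int(0.08 * h), 6)
    xs = np.linspace(0, w - 1, 24)
    amp = 0.03 * h
    phase_t, phase_b = rng.uniform(0, 2 * math.pi, size=2)
    top = margin + amp * np.sin(2 * math.pi * xs / w + phase_t)
    bot = h - 1 - margin + amp * np.sin(2 * math.pi * xs / w + phase_b)
    verts = np.vstack([np.column_stack([xs, top]),
                       np.column_stack([xs[::-1], bot[::-1]])])
    return PolygonROI(vertices=verts)


def generate_choroid_phantom(spec: ChoroidPhantomSpec) -> ChoroidPhantom:
    """Dark lumina on bright stroma inside a traced TCA band.

    Circular lumina are centred on a jittered square grid whose spacing is
    set by the requested lumen radius and luminal fraction (spacing
    s = r * sqrt(pi / f)); the rasterized disk radius is calibrated so the
    per-cell dark fraction matches f, and grid cells beyond the TCA border
    still contribute their clipped disks so coverage is stationary up to
    the boundary.  Guarantees: the dark fraction inside the TCA raster is
    within +-0.02 absolute of ``true_luminal_fraction`` (checked, else an
    error), and stromal septa persist between grid cells so lumen pixels
    remain detectable by a local threshold.
    """
    from .vessel import rasterize_polygon  # local import to avoid cycle

    rng = np.random.default_rng(spec.seed)
    h, w = spec.window_px
    tca = _tca_band_polygon(h, w, rng)
    tca_raster = rasterize_polygon(tca, (h, w))
    tca_n = int(tca_raster.sum())
    if tca_n == 0:
        raise ValueError("degenerate TCA band")

    f = spec.true_luminal_fraction
    lumen = np.zeros((h, w), dtype=bool)
    if f > 0:
        if f > 0.75:
            raise ValueError(
                f"true_luminal_fraction {f} too high for non-degenerate lumina "
                "(requires disks overflowing their grid cells)")
        spacing = spec.lumen_radius_px * math.sqrt(math.pi / f)
        if spacing < 4:
            raise ValueError("lumen_radius_px too small for the requested fraction")
        # calibrate the drawn radius so the rasterized disk area hits f * s^2
        target_px = f * spacing * spacing
        radii = np.arange(1.0, spacing / 2.0 + 0.26, 0.05)
        areas = [len(_draw_disk((0.0, 0.0), r)[0]) for r in radii]
        radius = float(radii[int(np.argmin(np.abs(np.asarray(areas) - target_px)))])
        jitter = max(min(spacing / 2.0 - radius - 0.5, 1.5), 0.0)

        ys = np.arange(-spacing, h + spacing, spacing)
        xs = np.arange(-spacing, w + spacing, spacing)
        for gy in ys:
            for gx in xs:
                cy = gy + rng.uniform(-jitter, jitter)
                cx = gx + rng.uniform(-jitter, jitter)
                rr, cc = _draw_disk((cy, cx), radius, shape=(h, w))
                lumen[rr, cc] = True
        lumen &= tca_raster
        achieved = lumen.sum() / tca_n
        if abs(achieved - f) > 0.02:
            raise ValueError(
                f"achieved luminal fraction {achieved:.3f} misses target {f} by more "
                "than 0.02; adjust lumen_radius_px")

    image = np.full((h, w), float(VESSEL_INTENSITY))  # bright stroma
    image[lumen] = float(BACKGROUND_INTENSITY)        # dark lumina
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    pixels = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    extent_w = w * spec.lateral_scale_um_per_px / 1000.0
    extent_h = h * spec.lateral_scale_um_per_px / 1000.0
    return ChoroidPhantom(
        image=CalibratedImage(pixels=pixels, extent_mm=(extent_w, extent_h)),
        truth_luminal_mask=lumen,
        tca_polygon=tca,
        spec=spec,
    )


# --- cohort generator -----------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic six-group, per-eye cohort.

    ``patient_effect_sd`` is the between-patient random-intercept SD,
    either one value for all metrics or a per-metric mapping; ``None``
    resolves to 0.3 x the smallest group SD of each metric, keeping the
    residual variance positive everywhere.  ``fraction_bilateral`` is the
    probability a patient contributes both eyes (both in the same group).
    """

    group_sizes: tuple[int, ...] = GROUP_SIZES
    group_metric_means: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(GROUP_METRIC_MEANS))
    group_metric_sds: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(GROUP_METRIC_SDS))
    patient_effect_sd: float | Mapping[str, float] | None = None
    fraction_bilateral: float = 0.6
    covariate_model: Mapping[str, object] = field(
        default_factory=lambda: dict(COVARIATE_MODEL))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 6:
            raise ValueError("group_sizes must list six groups")
        if any(s < 0 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 0")
        if not 0 <= self.fraction_bilateral <= 1:
            raise ValueError("fraction_bilateral must be in [0, 1]")
        if set(self.group_metric_means) != set(self.group_metric_sds):
            raise ValueError("means and SDs must cover the same metrics")
        for m, sds in self.group_metric_sds.items():
            if any(s < 0 for s in sds):
                raise ValueError(f"negative SD for metric {m!r}")

    def resolve_patient_sd(self, metric: str) -> float:
        if self.patient_effect_sd is None:
            return 0.3 * min(self.group_metric_sds[metric])
        if isinstance(self.patient_effect_sd, Mapping):
            return float(self.patient_effect_sd[metric])
        return float(self.patient_effect_sd)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-eye cohort table with patient-shared random intercepts.

    Each eye's metric value is group mean + patient intercept
    (SD = patient_effect_sd) + residual with SD sqrt(group_sd^2 - tau^2),
    so the marginal within-group SD equals the requested group SD.  Raises
    if any requested patient SD exceeds a group SD (negative residual
    variance).  Covariates (age, sex, diastolic BP) are drawn per patient
    from the group-specific covariate model; the signal strength index is
    drawn per eye.
    """
    rng = np.random.default_rng(spec.seed)
    metrics = list(spec.group_metric_means)
    for m in metrics:
        tau = spec.resolve_patient_sd(m)
        for g, sd in enumerate(spec.group_metric_sds[m], start=1):
            if tau > sd:
                raise ValueError(
                    f"patient_effect_sd {tau:.4g} exceeds group {g} SD {sd:.4g} for "
                    f"{m!r}: residual variance would be negative")

    age_model = spec.covariate_model["age"]
    dbp_model = spec.covariate_model["dbp"]
    female_frac = spec.covariate_model["female_frac"]
    ssi_mean, ssi_sd = spec.covariate_model["ssi"]

    rows: list[dict] = []
    patient_no, eye_no = 0, 0
    for g, n_eyes in enumerate(spec.group_sizes, start=1):
        remaining = n_eyes
        while remaining > 0:
            patient_no += 1
            bilateral = remaining >= 2 and rng.random() < spec.fraction_bilateral
            n = 2 if bilateral else 1
            remaining -= n
            age = rng.normal(*age_model[g - 1])
            sex = int(rng.random() >= female_frac[g - 1])  # 0 = female, 1 = male
            dbp = rng.normal(*dbp_model[g - 1])
            intercepts = {m: rng.normal(0.0, spec.resolve_patient_sd(m)) for m in metrics}
            for _ in range(n):
                eye_no += 1
                row = {
                    "eye_id": f"E{eye_no:04d}",
                    "patient_id": f"P{patient_no:04d}",
                    "group": g,
                    "age": age,
                    "sex": sex,
                    "dbp": dbp,
                    "ssi": float(rng.normal(ssi_mean, ssi_sd)),
                }
                for m in metrics:
                    mean = spec.group_metric_means[m][g - 1]
                    sd = spec.group_metric_sds[m][g - 1]
                    tau = spec.resolve_patient_sd(m)
                    resid_sd = math.sqrt(max(sd * sd - tau * tau, 0.0))
                    row[m] = mean + intercepts[m] + rng.normal(0.0, resid_sd)
                rows.append(row)

    return pd.DataFrame(rows, columns=["eye_id", "patient_id", "group", "age",
                                       "sex", "dbp", "ssi", *metrics])
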