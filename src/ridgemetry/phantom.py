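"""Synthetic OCT phantoms, cohorts, grader labels, and treatment trajectories.

Real ultra-widefield OCT scans of premature infants are not publicly
distributable, so every downstream stage of this package is exercised on
synthetic data whose statistical structure matches what the analyses assume:

* **Phantom volumes** — a smooth retina (inner surface + RPE) with a
  localized fibrovascular ridge: a Gaussian-profile elevation of the inner
  surface along a circular arc in the en face plane, mimicking the elevated
  tissue at the vascular-avascular junction. Multiplicative gamma speckle
  (exponential at SNR 1, the fully-developed first-order speckle model)
  corrupts the intensities. Ground truth surfaces and the analytic maximum
  thickness accompany every volume.
* **Cohorts** — patients contribute two eyes, eyes contribute repeated
  sessions; thickness decomposes into a stage-conditional mean plus
  patient-, eye-, and measurement-level Gaussian components, so intereye and
  interexamination correlations are present by construction.
* **Grader labels** — two independent graders observe the true continuous
  stage with additive Gaussian error, quantized to 0.1 increments; this
  noise model is an assumption (grader behaviour is not described
  generatively anywhere) and is flagged as such in the docs.
* **Treatment trajectories** — thickness rises linearly to the treatment
  visit (week 0) and falls linearly after, plus per-visit noise.

All randomness flows through ``numpy.random.Generator``; identical
(params, seed) pairs reproduce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .records import ExamRecord, GraderLabels
from .stats import adjudicate
from .trace import RidgeTrace, resample_trace
from .volume import OCTVolume

# per-stage maximum-thickness calibration (um): stages 1, 2, 3
STAGE_MEANS_UM = (264.2, 334.2, 495.0)


def _as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# phantom volumes
# ---------------------------------------------------------------------------

@dataclass
class PhantomParams:
    """Geometry, optics, and noise of a single synthetic volume.

    The ridge sits on a circle of radius ``ridge_radius_px`` centred in the
    en face field, spanning ``ridge_extent_clock`` clock hours around
    ``ridge_center_clock`` (12 o'clock is up, i.e. decreasing slow index;
    clock positions advance clockwise). Its elevation decays as a Gaussian
    of width ``ridge_profile_sigma_um`` with en face distance from the arc.
    """

    n_axial: int = 1024
    n_fast: int = 256
    n_slow: int = 256
    axial_pixel_um: float = 4.4
    lateral_pixel_um: float = 15.0
    baseline_retina_um: float = 200.0
    ridge_height_um: float = 150.0
    ridge_center_clock: float = 3.0
    ridge_extent_clock: float = 2.0
    ridge_radius_px: float | None = None  # default: 0.35 * min lateral extent
    ridge_profile_sigma_um: float = 300.0
    rpe_depth_frac: float = 0.75
    speckle_snr: float = 3.0
    background_level: float = 10.0
    tissue_level: float = 100.0
    rpe_level: float = 255.0

    def __post_init__(self) -> None:
        for name in ("n_axial", "n_fast", "n_slow"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1; got {getattr(self, name)}")
        if not self.axial_pixel_um > 0:
            raise ValueError("axial_pixel_um must be > 0")
        if not self.lateral_pixel_um > 0:
            raise ValueError("lateral_pixel_um must be > 0")
        if self.ridge_height_um < 0:
            raise ValueError("ridge_height_um must be >= 0")
        if not 0 < self.ridge_extent_clock <= 12:
            raise ValueError("ridge_extent_clock must be in (0, 12] clock hours")
        if not self.tissue_level > self.background_level:
            raise ValueError("tissue_level must exceed background_level")
        if not self.rpe_level > self.tissue_level:
            raise ValueError("rpe_level must exceed tissue_level")
        if not self.speckle_snr > 0:
            raise ValueError("speckle_snr must be > 0 (use numpy.inf for noise-free)")
        if self.ridge_radius_px is None:
            self.ridge_radius_px = 0.35 * min(self.n_fast, self.n_slow)

    @property
    def true_max_thickness_um(self) -> float:
        """Analytic maximum thickness: baseline plus peak ridge elevation."""
        return self.baseline_retina_um + self.ridge_height_um


@dataclass
class PhantomTruth:
    """Ground-truth surfaces and maximum thickness for a rendered phantom.

    Surfaces are the integer axial rows actually rendered (as floats), so
    noise-free segmentation can recover them exactly;
    ``true_max_thickness_um`` is their brute-force maximum difference scaled
    to micrometres, which sits within one axial pixel of the analytic
    ``baseline + ridge_height``.
    """

    rpe_surface: np.ndarray  # (slow, fast) axial rows
    inner_surface: np.ndarray  # (slow, fast) axial rows
    true_max_thickness_um: float
    true_ridgeline: RidgeTrace

    def __post_init__(self) -> None:
        if self.rpe_surface.shape != self.inner_surface.shape:
            raise ValueError("truth surfaces must share a shape")
        if np.any(self.inner_surface > self.rpe_surface):
            raise ValueError("inner surface must lie at or above the RPE (row 0 is vitreous)")


def _clock_to_unit(clock_hours: np.ndarray | float) -> np.ndarray:
    """Unit direction (slow, fast) for a clock position; 12 is up, clockwise."""
    ang = np.asarray(clock_hours, dtype=np.float64) * (math.pi / 6.0)
    return np.stack([-np.cos(ang), np.sin(ang)], axis=-1)


def ridge_arc_points(params: PhantomParams, spacing_px: float = 0.5) -> np.ndarray:
    """Dense (slow, fast) samples of the ridge crest arc."""
    radius = float(params.ridge_radius_px)
    center = np.array([(params.n_slow - 1) / 2.0, (params.n_fast - 1) / 2.0])
    half = params.ridge_extent_clock / 2.0
    arc_len = radius * params.ridge_extent_clock * math.pi / 6.0
    n_pts = max(int(math.ceil(arc_len / spacing_px)) + 1, 2)
    clocks = np.linspace(
        params.ridge_center_clock - half, params.ridge_center_clock + half, n_pts
    )
    pts = center + radius * _clock_to_unit(clocks)
    return pts


def generate_phantom_volume(
    params: PhantomParams, seed: int | np.random.Generator = 0
) -> tuple[OCTVolume, PhantomTruth]:
    """Render a synthetic volume and its ground truth.

    The RPE is a flat plane at ``rpe_depth_frac`` of the axial range; the
    inner surface sits ``baseline_retina_um`` above it, further elevated by
    the ridge bump. Intensities: vitreous at ``background_level``, retina at
    ``tissue_level``, a 3-row bright band centred on the RPE row peaking at
    ``rpe_level``, background again below. Speckle multiplies the whole
    volume by unit-mean gamma variates with SD ``1/speckle_snr``.
    """
    rng = _as_rng(seed)
    arc = ridge_arc_points(params)
    n_slow, n_fast, n_axial = params.n_slow, params.n_fast, params.n_axial
    if (
        arc[:, 0].min() < 0
        or arc[:, 0].max() > n_slow - 1
        or arc[:, 1].min() < 0
        or arc[:, 1].max() > n_fast - 1
    ):
        raise ValueError(
            "ridge arc extends outside the en face field; shrink ridge_radius_px "
            "or the arc extent"
        )

    # en face distance of every lateral position to the crest arc
    ss, ff = np.meshgrid(np.arange(n_slow), np.arange(n_fast), indexing="ij")
    grid = np.column_stack([ss.ravel(), ff.ravel()]).astype(np.float64)
    dist_px, _ = cKDTree(arc).query(grid, k=1)
    dist_um = dist_px.reshape(n_slow, n_fast) * params.lateral_pixel_um

    sigma = params.ridge_profile_sigma_um
    bump_um = params.ridge_height_um * np.exp(-0.5 * (dist_um / sigma) ** 2)

    rpe_row = int(round(params.rpe_depth_frac * (n_axial - 1)))
    baseline_px = params.baseline_retina_um / params.axial_pixel_um
    inner_float = rpe_row - baseline_px - bump_um / params.axial_pixel_um
    inner_rows = np.rint(inner_float).astype(np.int64)
    if inner_rows.min() < 1:
        raise ValueError(
            "retina plus ridge does not fit above the RPE plane: increase n_axial "
            "or rpe_depth_frac, or reduce baseline/ridge height"
        )
    if rpe_row > n_axial - 2:
        raise ValueError("RPE bright band does not fit in the axial field; increase n_axial")

    ax = np.arange(n_axial)[None, :, None]
    inner_b = inner_rows[:, None, :]
    vol = np.full((n_slow, n_axial, n_fast), params.background_level, dtype=np.float32)
    tissue_mask = (ax >= inner_b) & (ax <= rpe_row - 2)
    vol[tissue_mask] = params.tissue_level
    edge_level = 0.5 * (params.tissue_level + params.rpe_level)
    vol[:, rpe_row - 1, :] = edge_level
    vol[:, rpe_row, :] = params.rpe_level
    if rpe_row + 1 <= n_axial - 1:
        vol[:, rpe_row + 1, :] = edge_level

    if np.isfinite(params.speckle_snr):
        shape = params.speckle_snr**2  # unit mean, SD = 1/snr; exponential at snr=1
        vol = vol * rng.gamma(shape, 1.0 / shape, size=vol.shape).astype(np.float32)

    rpe_surface = np.full((n_slow, n_fast), float(rpe_row))
    inner_surface = inner_rows.astype(np.float64)
    true_max = float((rpe_surface - inner_surface).max() * params.axial_pixel_um)
    ridgeline = resample_trace(RidgeTrace(points=arc, source="truth"), spacing_px=1.0)

    volume = OCTVolume(
        intensities=vol,
        axial_pixel_um=params.axial_pixel_um,
        lateral_pixel_um=params.lateral_pixel_um,
        metadata={"kind": "phantom"},
    )
    truth = PhantomTruth(
        rpe_surface=rpe_surface,
        inner_surface=inner_surface,
        true_max_thickness_um=true_max,
        true_ridgeline=ridgeline,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# grader labels
# ---------------------------------------------------------------------------

def generate_grader_labels(
    true_continuous_stage: float,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> GraderLabels:
    """Two independent noisy continuous labels on the 0.1 grid, with ordinals.

    Each grader observes ``true_continuous_stage`` plus Gaussian error of SD
    ``noise_sd``, quantized to 0.1 increments and clipped to [0, 3]; the
    ordinal label is the continuous one rounded to the nearest integer.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0; got {noise_sd}")
    rng = _as_rng(seed)
    a, b = true_continuous_stage + rng.normal(0.0, noise_sd, size=2) if noise_sd > 0 else (
        true_continuous_stage,
        true_continuous_stage,
    )
    return GraderLabels.from_continuous(float(a), float(b))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Shape and variance structure of a simulated screening cohort.

    Defaults mirror the emulated study population: 25 patients, both eyes
    imaged, a mean of ~2.6 sessions per eye (128 volumes / 50 eyes), stage
    mix 50/65/13 across stages 1/2/3, and per-stage mean maximum thickness
    264.2 / 334.2 / 495.0 um. An eye of ordinal stage k carries a true
    continuous severity ``k + delta`` (delta Gaussian, truncated to +-0.45
    so the continuous truth rounds back to k) and a latent thickness::

        stage_mean[k] + severity_slope_um * delta + N(0, stage_sd[k])
                      + N(0, within_patient_sd) + N(0, within_eye_sd)

    with the patient term shared by both eyes; each session adds independent
    ``N(0, measurement_sd)`` capture noise. The severity coupling makes
    thickness vary continuously with stage within an ordinal category, but
    because delta is symmetric with zero mean, the per-stage conditional
    mean still equals ``stage_mean[k]`` exactly — which is what the GEE
    parameter-recovery checks rely on.

    ``grader_noise_sd`` defaults to 0.18: under the Gaussian label-error
    model, two graders observing ``k + delta`` each cross an ordinal
    boundary with probability ~6%, giving ~88% expected exact agreement —
    the realistic operating point for experienced masked graders.
    """

    n_patients: int = 25
    eyes_per_patient: int = 2
    session_count_probs: Sequence[float] = (0.10, 0.40, 0.34, 0.16)  # counts 1..4
    stage_mix: Sequence[float] = (50 / 128, 65 / 128, 13 / 128)  # stages 1..3
    stage_thickness_means_um: Sequence[float] = STAGE_MEANS_UM
    stage_thickness_sd_um: Sequence[float] = (40.0, 45.0, 65.0)
    # secant slope of the calibrated stage means: (495.0 - 264.2) / 2 stages
    severity_slope_um: float = 115.4
    within_patient_sd_um: float = 40.0
    within_eye_sd_um: float = 20.0
    measurement_sd_um: float = 27.0
    grader_noise_sd: float = 0.18
    continuous_stage_sd: float = 0.2
    pma_mean_wk: float = 37.3
    pma_sd_wk: float = 3.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if abs(sum(self.stage_mix) - 1.0) > 1e-6:
            raise ValueError(f"stage_mix must sum to 1; got {sum(self.stage_mix)}")
        if abs(sum(self.session_count_probs) - 1.0) > 1e-6:
            raise ValueError("session_count_probs must sum to 1")
        for name in (
            "within_patient_sd_um",
            "within_eye_sd_um",
            "measurement_sd_um",
            "grader_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        means = list(self.stage_thickness_means_um)
        if not all(m2 > m1 for m1, m2 in zip(means, means[1:])):
            raise ValueError("per-stage thickness means must be strictly increasing")


def generate_cohort(params: CohortParams) -> list[ExamRecord]:
    """Simulate a nested screening cohort (thickness-only; no volumes rendered).

    Every eye is assigned an ordinal stage from ``stage_mix`` and a true
    continuous stage near it; each session emits an :class:`ExamRecord` with
    noisy grader labels and a noisy thickness measurement. Records respect
    the nesting: both eyes share a patient effect, sessions share an eye
    effect.
    """
    rng = np.random.default_rng(params.seed)
    stages = np.arange(1, len(params.stage_mix) + 1)
    records: list[ExamRecord] = []
    for p in range(params.n_patients):
        pid = f"P{p:03d}"
        patient_eff = rng.normal(0.0, params.within_patient_sd_um)
        pma0 = rng.normal(params.pma_mean_wk, params.pma_sd_wk)
        for e in range(params.eyes_per_patient):
            eye = "OD" if e % 2 == 0 else "OS"
            stage = int(rng.choice(stages, p=np.asarray(params.stage_mix)))
            eye_eff = rng.normal(0.0, params.within_eye_sd_um)
            stage_dev = rng.normal(0.0, params.stage_thickness_sd_um[stage - 1])
            # continuous severity: symmetric around the ordinal stage so it
            # rounds back to it and leaves the conditional mean unbiased
            delta = float(np.clip(rng.normal(0.0, params.continuous_stage_sd), -0.45, 0.45))
            cont_true = min(stage + delta, 3.0)
            base = (
                params.stage_thickness_means_um[stage - 1]
                + params.severity_slope_um * delta
                + stage_dev
                + patient_eff
                + eye_eff
            )
            n_sessions = int(
                rng.choice(np.arange(1, len(params.session_count_probs) + 1),
                           p=np.asarray(params.session_count_probs))
            )
            for s in range(n_sessions):
                thickness = max(base + rng.normal(0.0, params.measurement_sd_um), 1.0)
                labels = generate_grader_labels(cont_true, params.grader_noise_sd, rng)
                mean_cont, adj = adjudicate(labels)
                records.append(
                    ExamRecord(
                        patient_id=pid,
                        eye=eye,
                        session_id=f"S{s:02d}",
                        postmenstrual_week=pma0 + s,
                        labels=labels,
                        adjudicated_ordinal=adj,
                        mean_continuous=mean_cont,
                        max_thickness_um=float(thickness),
                        stage_true=stage,
                        true_thickness_um=float(base),
                    )
                )
    return records


def generate_repeat_captures(
    n_eyes: int = 20,
    n_captures: int = 2,
    mean_um: float = 330.0,
    between_eye_sd_um: float = 95.0,
    within_eye_sd_um: float = 23.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Same-session repeat captures for repeatability analysis.

    Eye ``i`` has a latent thickness ``mean + N(0, between_eye_sd)``; each
    capture adds independent ``N(0, within_eye_sd)``. Returns a tidy frame
    with columns ``eye_id``, ``capture``, ``max_thickness_um``.
    """
    if n_eyes < 1 or n_captures < 1:
        raise ValueError("need at least one eye and one capture")
    rng = _as_rng(seed)
    rows = []
    for i in range(n_eyes):
        latent = mean_um + rng.normal(0.0, between_eye_sd_um)
        for c in range(n_captures):
            rows.append(
                {
                    "eye_id": f"E{i:03d}",
                    "capture": c,
                    "max_thickness_um": max(latent + rng.normal(0.0, within_eye_sd_um), 1.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# treatment trajectories
# ---------------------------------------------------------------------------

@dataclass
class TreatmentParams:
    """Piecewise-linear rise-then-fall thickness trajectory around treatment.

    Thickness climbs at ``pre_slope_um_per_wk`` up to the treatment visit
    (week 0) and declines at ``post_decay_um_per_wk`` after it, emulating the
    rapid regression of the ridge after intravitreal anti-VEGF injection.
    """

    pre_slope_um_per_wk: float = 35.0
    post_decay_um_per_wk: float = 60.0
    observation_weeks: Sequence[float] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    visit_noise_sd_um: float = 15.0

    def __post_init__(self) -> None:
        if self.pre_slope_um_per_wk < 0:
            raise ValueError("pre_slope_um_per_wk must be >= 0")
        if self.post_decay_um_per_wk < 0:
            raise ValueError("post_decay_um_per_wk must be >= 0")
        if len(self.observation_weeks) == 0:
            raise ValueError("observation schedule must not be empty")
        if self.visit_noise_sd_um < 0:
            raise ValueError("visit_noise_sd_um must be >= 0")


def expected_trajectory_um(params: TreatmentParams, baseline_um: float, week: float) -> float:
    """Noise-free trajectory value; ``baseline_um`` is the week-0 thickness."""
    if week <= 0:
        value = baseline_um + params.pre_slope_um_per_wk * week
    else:
        value = baseline_um - params.post_decay_um_per_wk * week
    return max(value, 1.0)


def generate_treatment_trajectory(
    params: TreatmentParams,
    baseline_um: float,
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, float]]:
    """Sample a (week, thickness_um) trajectory for one treated eye."""
    rng = _as_rng(seed)
    out = []
    for week in params.observation_weeks:
        value = expected_trajectory_um(params, baseline_um, float(week))
        if params.visit_noise_sd_um > 0:
            value = max(value + rng.normal(0.0, params.visit_noise_sd_um), 1.0)
        out.append((float(week), float(value)))
    return out


def generate_treated_cohort(
    params: TreatmentParams | None = None,
    n_patients: int = 4,
    baseline_mean_um: float = 394.4,
    baseline_sd_um: float = 35.0,
    within_patient_sd_um: float = 25.0,
    grader_noise_sd: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> list[ExamRecord]:
    """Treated infants followed through the pre/at/post-treatment windows.

    Both eyes of an infant are treated at week 0 and share the infant's
    baseline; records carry ``weeks_from_treatment`` for windowed summaries.
    """
    params = params or TreatmentParams()
    rng = _as_rng(seed)
    records: list[ExamRecord] = []
    for p in range(n_patients):
        pid = f"T{p:03d}"
        patient_base = baseline_mean_um + rng.normal(0.0, baseline_sd_um)
        pma0 = rng.normal(36.7, 1.7)
        for e, eye in enumerate(("OD", "OS")):
            eye_base = patient_base + rng.normal(0.0, within_patient_sd_um)
            traj = generate_treatment_trajectory(params, eye_base, rng)
            cont_true = 2.0 + float(np.clip(rng.normal(0.0, 0.2), -0.45, 0.45))
            for s, (week, thickness) in enumerate(traj):
                labels = generate_grader_labels(cont_true, grader_noise_sd, rng)
                mean_cont, adj = adjudicate(labels)
                records.append(
                    ExamRecord(
                        patient_id=pid,
                        eye=eye,
                        session_id=f"S{s:02d}",
                        postmenstrual_week=pma0 + week,
                        labels=labels,
                        adjudicated_ordinal=adj,
                        mean_continuous=mean_cont,
                        max_thickness_um=thickness,
                        treated=True,
                        weeks_from_treatment=week,
                        stage_true=2,
                        true_thickness_um=expected_trajectory_um(params, eye_base, week),
                    )
                )
    return records
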