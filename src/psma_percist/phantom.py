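"""Synthetic PET phantoms and simulated therapy cohorts.

Every downstream stage of the pipeline (quantification, response
classification, inference) is exercised on data produced here, with known
ground truth.  Two generators are provided:

``generate_phantom``
    builds a 3-D SUV volume containing a noisy background, an aortic
    blood-pool cylinder and plateau-intensity ellipsoidal lesions, together
    with a ground-truth label volume and per-lesion table.

``simulate_cohort``
    draws a lesion/patient cohort with the statistical structure the
    inferential layer assumes: per-patient random intercepts on log SUVpeak,
    site-specific means, a responder/non-responder intensity ratio, PSA
    values coupled to the imaging response, and censored survival times.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .geometry import CylinderVoi, ellipsoid_mask
from .quant import SuvVolume

SITES = ("prostate", "lymph_node", "bone", "visceral")

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class LesionSpec:
    """An ellipsoidal lesion with a plateau SUV.

    ``center`` and ``radii`` are in mm, (z, y, x) order; a scalar radius
    denotes a sphere.  ``site`` is one of ``SITES``.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float
    site: str = "bone"

    def __post_init__(self) -> None:
        radii = self.radii
        if np.isscalar(radii):
            radii = (float(radii),) * 3
        radii = tuple(float(r) for r in radii)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if any(r <= 0 for r in radii):
            raise ValueError("lesion radii must be positive")
        if self.intensity < 0:
            raise ValueError("lesion intensity must be >= 0")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")

    def analytic_volume_ml(self) -> float:
        rz, ry, rx = self.radii
        return 4.0 / 3.0 * math.pi * rz * ry * rx / 1000.0


@dataclass(frozen=True)
class AortaSpec:
    """Blood-pool cylinder geometry plus its SUV distribution."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    diameter: float = 10.0
    length: float = 30.0
    mean: float = 2.0
    sd: float = 0.5

    def voi(self) -> CylinderVoi:
        return CylinderVoi(self.center, self.axis, self.diameter, self.length)


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (48, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_mean: float = 1.0
    background_sd: float = 0.1
    aorta: AortaSpec | None = None
    lesions: tuple[LesionSpec, ...] = ()
    smoothing_fwhm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.background_sd < 0 or self.background_mean < 0:
            raise ValueError("background parameters must be non-negative")
        object.__setattr__(self, "lesions", tuple(self.lesions))

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing))


@dataclass
class GroundTruth:
    """Label volume (0 = background, 1..K per lesion) plus per-lesion truth."""

    labels: np.ndarray
    table: pd.DataFrame
    aorta_mask: np.ndarray | None = None


def generate_phantom(spec: PhantomSpec) -> tuple[SuvVolume, GroundTruth]:
    """Render a phantom volume and its ground truth.

    Background voxels are Normal(mean, sd) clipped at zero, aorta voxels
    Normal(aorta.mean, aorta.sd) clipped at zero, lesion voxels are set to
    their plateau intensity.  Optional Gaussian smoothing (FWHM in mm) is
    applied last.  Lesions must lie fully inside the grid and must not
    overlap, otherwise the ground truth would be ambiguous.
    """
    shape, spacing = spec.grid_shape, spec.spacing
    extent = spec.extent_mm()
    ss = np.random.SeedSequence(spec.seed)
    bg_rng, aorta_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    if spec.background_sd > 0:
        values = bg_rng.normal(spec.background_mean, spec.background_sd, size=shape)
        np.clip(values, 0.0, None, out=values)
    else:
        values = np.full(shape, float(spec.background_mean))

    aorta_mask = None
    if spec.aorta is not None:
        aorta_mask = spec.aorta.voi().mask(shape, spacing)
        n_aorta = int(aorta_mask.sum())
        if n_aorta == 0:
            raise ValueError("aorta cylinder contains no voxel centers")
        if spec.aorta.sd > 0:
            values[aorta_mask] = np.clip(
                aorta_rng.normal(spec.aorta.mean, spec.aorta.sd, size=n_aorta), 0.0, None
            )
        else:
            values[aorta_mask] = spec.aorta.mean

    labels = np.zeros(shape, dtype=np.int32)
    voxel_ml = float(np.prod(spacing)) / 1000.0
    rows = []
    for i, lesion in enumerate(spec.lesions, start=1):
        for a in range(3):
            lo = lesion.center[a] - lesion.radii[a]
            hi = lesion.center[a] + lesion.radii[a]
            if lo < 0 or hi > extent[a]:
                raise ValueError(f"lesion {i} extends outside the grid on axis {a}")
        mask = ellipsoid_mask(shape, spacing, lesion.center, lesion.radii)
        if np.any(labels[mask] != 0):
            raise ValueError(f"lesion {i} overlaps a previous lesion")
        labels[mask] = i
        values[mask] = lesion.intensity
        rows.append(
            {
                "lesion_id": i,
                "site": lesion.site,
                "intensity": lesion.intensity,
                "true_volume_ml": int(mask.sum()) * voxel_ml,
                "analytic_volume_ml": lesion.analytic_volume_ml(),
                "center_z": lesion.center[0],
                "center_y": lesion.center[1],
                "center_x": lesion.center[2],
            }
        )

    if spec.smoothing_fwhm > 0:
        sigma = [spec.smoothing_fwhm / _FWHM_TO_SIGMA / s for s in spacing]
        values = gaussian_filter(values, sigma=sigma)
        np.clip(values, 0.0, None, out=values)

    table = pd.DataFrame(
        rows,
        columns=[
            "lesion_id",
            "site",
            "intensity",
            "true_volume_ml",
            "analytic_volume_ml",
            "center_z",
            "center_y",
            "center_x",
        ],
    )
    return SuvVolume(values, spacing), GroundTruth(labels, table, aorta_mask)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Site mix of the metastatic burden the generator emulates
#: (lymph node / bone / visceral metastases plus primary tumor).
DEFAULT_SITE_PROBS = {
    "lymph_node": 86 / 237,
    "bone": 119 / 237,
    "visceral": 17 / 237,
    "prostate": 15 / 237,
}

#: Site-specific means of log baseline SUVpeak (log of typical median values).
DEFAULT_SITE_LOG_MEANS = {
    "prostate": math.log(13.70),
    "lymph_node": math.log(7.40),
    "bone": math.log(6.84),
    "visceral": math.log(7.33),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a simulated radioligand-therapy cohort.

    For patient *i*, lesion *j*::

        log SUVpeak_ij = site_log_mean[site_ij] + b_i + beta * R_ij + eps_ij
        b_i   ~ Normal(0, tau^2)        (between-patient random intercept)
        eps_ij ~ Normal(0, sigma^2)     (residual)

    ``R`` is the lesion-level objective-response indicator, drawn as
    Bernoulli(expit(link_intercept + link_slope * (latent - site mean))).
    With the default ``link_slope = 0`` the response label is independent of
    the latent intensity, so ``responder_log_ratio`` is exactly the marginal
    log contrast a mixed model should recover.
    """

    n_patients: int = 32
    mean_lesions_per_patient: float = 7.4
    site_probs: dict = field(default_factory=lambda: dict(DEFAULT_SITE_PROBS))
    site_log_means: dict = field(default_factory=lambda: dict(DEFAULT_SITE_LOG_MEANS))
    tau: float = 0.4
    sigma: float = 0.5
    responder_log_ratio: float = math.log(1.80)
    response_rate: float = 149 / 237
    link_slope: float = 0.0
    p_icr_given_responder: float = 34 / 149
    p_ipd_given_nonresponder: float = 28 / 88
    suvmax_factor: float = 1.35
    volume_log_mean: float = math.log(2.0)
    volume_log_sd: float = 1.0
    psa_log_mean: float = math.log(210.0)
    psa_log_sd: float = 1.52
    psa_tl_coupling: float = 0.8
    psa_log_noise_sd: float = 0.4
    median_os_months: float = 8.0
    responder_hazard_ratio: float = 0.457
    censor_low_months: float = 6.0
    censor_high_months: float = 40.0
    new_lesion_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.tau < 0 or self.sigma < 0:
            raise ValueError("tau and sigma must be non-negative")
        if not 0.0 <= self.response_rate <= 1.0:
            raise ValueError("response_rate must be a probability")
        for name in ("responder_log_ratio", "tau", "sigma", "suvmax_factor"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.suvmax_factor < 1.0:
            raise ValueError("suvmax_factor must be >= 1 (SUVmax >= SUVpeak)")
        probs = np.asarray(list(self.site_probs.values()), dtype=float)
        if probs.min() < 0 or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("site_probs must sum to 1")


# Follow-up / baseline SUVpeak ratio ranges per response category.  iCR is
# complete tracer resolution (set to 0); the other ranges bracket the +/-30%
# classification boundaries so that labels and ratios stay consistent.
_FOLLOWUP_LOG_RATIO = {
    "iPR": (math.log(0.20), math.log(0.70)),
    "iSD": (math.log(0.71), math.log(1.29)),
    "iPD": (math.log(1.30), math.log(2.50)),
}


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw (lesion_table, patient_table) for one simulated cohort.

    The lesion table is long format: one row per lesion with baseline and
    follow-up SUVpeak, the lesion response category and the patient-level
    covariates repeated per row.  The patient table carries PSA, total
    burden (PSMA-TV, TL-PSMA at both timepoints), new-lesion flags and
    censored overall survival.  All draws come from one seeded generator, so
    a fixed seed reproduces the tables exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    sites = list(spec.site_probs)
    site_p = np.asarray([spec.site_probs[s] for s in sites], dtype=float)
    link_intercept = float(np.log(spec.response_rate / (1.0 - spec.response_rate)))

    lesion_rows = []
    patient_rows = []
    for i in range(1, spec.n_patients + 1):
        n_lesions = 1 + rng.poisson(max(spec.mean_lesions_per_patient - 1.0, 0.0))
        b_i = rng.normal(0.0, spec.tau)
        lesion_sites = rng.choice(sites, size=n_lesions, p=site_p)
        eps = rng.normal(0.0, spec.sigma, size=n_lesions)
        latent = np.array([spec.site_log_means[s] for s in lesion_sites]) + b_i + eps
        centered = latent - np.array([spec.site_log_means[s] for s in lesion_sites])
        p_resp = expit(link_intercept + spec.link_slope * centered)
        responder = rng.random(n_lesions) < p_resp
        log_suv = latent + spec.responder_log_ratio * responder
        suv_peak = np.exp(log_suv)
        suv_max = suv_peak * spec.suvmax_factor
        volumes = np.exp(rng.normal(spec.volume_log_mean, spec.volume_log_sd, n_lesions))

        categories = np.empty(n_lesions, dtype=object)
        icr = rng.random(n_lesions) < spec.p_icr_given_responder
        ipd = rng.random(n_lesions) < spec.p_ipd_given_nonresponder
        categories[responder] = np.where(icr[responder], "iCR", "iPR")
        categories[~responder] = np.where(ipd[~responder], "iPD", "iSD")

        ratios = np.empty(n_lesions)
        for j, cat in enumerate(categories):
            if cat == "iCR":
                ratios[j] = 0.0
            else:
                lo, hi = _FOLLOWUP_LOG_RATIO[cat]
                ratios[j] = math.exp(rng.uniform(lo, hi))
        suv_peak_t1 = suv_peak * ratios

        psma_tv = float(volumes.sum())
        tl0 = float((suv_peak * volumes).sum())
        tl1 = float((suv_peak_t1 * volumes).sum())
        new_lesion = bool(rng.random() < spec.new_lesion_prob)

        log_tl_ratio = math.log(max(tl1, 1e-6) / tl0)
        psa0 = float(np.exp(rng.normal(spec.psa_log_mean, spec.psa_log_sd)))
        psa1 = psa0 * math.exp(
            spec.psa_tl_coupling * log_tl_ratio
            + rng.normal(0.0, spec.psa_log_noise_sd)
        )

        # patient-level objective response (>=30% TL-PSMA drop, no new lesion)
        pat_responder = (tl1 <= 0.7 * tl0) and not new_lesion
        rate = math.log(2.0) / spec.median_os_months
        if pat_responder:
            rate *= spec.responder_hazard_ratio
        event_time = rng.exponential(1.0 / rate)
        censor_time = rng.uniform(spec.censor_low_months, spec.censor_high_months)
        os_months = min(event_time, censor_time)
        death = event_time <= censor_time

        age = float(np.clip(rng.normal(70.0, 6.75), 45.0, 90.0))
        ecog = int(rng.choice([0, 1, 2], p=[0.375, 0.50, 0.125]))

        for j in range(n_lesions):
            lesion_rows.append(
                {
                    "patient_id": i,
                    "lesion_id": f"P{i:03d}L{j + 1:02d}",
                    "site": lesion_sites[j],
                    "volume_ml": volumes[j],
                    "suv_peak_t0": suv_peak[j],
                    "suv_max_t0": suv_max[j],
                    "suv_peak_t1": suv_peak_t1[j],
                    "log_suv_peak": log_suv[j],
                    "log_suv_max": log_suv[j] + math.log(spec.suvmax_factor),
                    "response": categories[j],
                    "responder": bool(responder[j]),
                    "psma_tv": psma_tv,
                }
            )
        patient_rows.append(
            {
                "patient_id": i,
                "n_lesions": n_lesions,
                "age": age,
                "ecog": ecog,
                "psma_tv": psma_tv,
                "tl_psma_t0": tl0,
                "tl_psma_t1": tl1,
                "new_lesions": new_lesion,
                "psa_t0": psa0,
                "psa_t1": psa1,
                "suv_peak_most_avid": float(suv_peak.max()),
                "suv_max_most_avid": float(suv_max.max()),
                "os_months": float(os_months),
                "death": bool(death),
            }
        )

    return pd.DataFrame(lesion_rows), pd.DataFrame(patient_rows)


def cohort_spec_to_json(spec: CohortSpec) -> dict:
    """JSON-serializable dict of a CohortSpec (round-trips via from_json)."""
    return dataclasses.asdict(spec)


def cohort_spec_from_json(d: dict) -> CohortSpec:
    return CohortSpec(**d)
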