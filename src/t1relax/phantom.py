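"""Synthetic digital brain phantom and cohort simulator.

The phantom is a deliberately simple geometric stand-in for a brain:
nested ellipsoids give an outer gray-matter shell, a white-matter
interior and a CSF core, with optional spherical lesions embedded in the
white matter. Each tissue class carries a ground-truth T1 (ms) and a
proton-density factor; the signal volume is the noiseless forward
spoiled-gradient-echo model evaluated voxel-wise, so the T1-mapping
pipeline can be validated against exact ground truth. Anatomical realism
is a non-goal: the mapping method is voxel-wise, so geometry only needs
to supply well-separated ROIs.

``simulate_cohort`` emulates a two-timepoint longitudinal MS study:
per-subject compartment volumes (gray matter, white matter, thalamus,
corpus callosum), ROI T1 means, whole-brain percentage volume change
(PBVC, negative = loss) and clinical covariates, with configurable
per-compartment change and noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .signal_model import SequenceParams, forward_signal

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "Phantom",
    "CohortEffects",
    "LesionPlacementError",
    "generate_phantom",
    "add_noise",
    "simulate_cohort",
]

# Integer label codes of the phantom grid
BACKGROUND, CSF, GM, WM, LESION = 0, 1, 2, 3, 4


class LesionPlacementError(RuntimeError):
    """Raised when requested lesions cannot be placed without overlap."""


@dataclass(frozen=True)
class TissueClass:
    """One tissue class: label code, name, ground-truth T1 and relative
    proton density (1.0 = same as the references; values != 1 exist to
    measure the bias of the single-k calibration assumption)."""

    code: int
    name: str
    t1_ms: float
    proton_density_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t1_ms > 0):
            raise ValueError(f"t1_ms must be > 0, got {self.t1_ms}")
        if not (self.proton_density_factor > 0):
            raise ValueError("proton_density_factor must be > 0")


def default_classes() -> tuple[TissueClass, ...]:
    """WM 810 ms / GM 1350 ms (the 3 T literature calibration values),
    CSF 4000 ms, and a chronic-lesion class at 1040 ms (T1 elevated
    relative to WM, in the range reported for chronic black holes)."""
    return (
        TissueClass(CSF, "csf", 4000.0),
        TissueClass(GM, "gm", 1350.0),
        TissueClass(WM, "wm", 810.0),
        TissueClass(LESION, "lesion", 1040.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue properties and acquisition of a phantom.

    The three nested ellipsoids (semi-axes as fractions of the grid
    half-extent) are, outermost first: GM shell, WM interior, CSF core.
    Lesions are spheres placed uniformly at random inside WM, rejected
    on overlap with previous lesions or non-WM tissue.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    classes: tuple[TissueClass, ...] = field(default_factory=default_classes)
    lesion_count: int = 0
    lesion_radius_range: tuple[float, float] = (2.0, 4.0)
    k_true: float = 100.0
    seed: int = 0
    params: SequenceParams = field(default_factory=SequenceParams)
    gm_axes: tuple[float, float, float] = (0.90, 0.90, 0.90)
    wm_axes: tuple[float, float, float] = (0.70, 0.70, 0.70)
    csf_axes: tuple[float, float, float] = (0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be >= 0")
        if not (self.k_true > 0):
            raise ValueError("k_true must be > 0")
        if any(a <= 0 or a > 1 for ax in (self.gm_axes, self.wm_axes, self.csf_axes)
               for a in ax):
            raise ValueError("ellipsoid semi-axes must lie in (0, 1]")

    def t1_of(self, name: str) -> float:
        for c in self.classes:
            if c.name == name:
                return c.t1_ms
        raise KeyError(name)

    def to_json(self) -> str:
        d = asdict(self)
        d["params"] = {"tr": self.params.tr, "te": self.params.te,
                       "flip_angle": self.params.flip_angle}
        d["snr_reference"] = "noiseless WM class signal"
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class Phantom:
    """Generated phantom: label grid, ground-truth T1 grid, noiseless
    signal grid, and the spec that produced them."""

    labels: np.ndarray
    t1_truth: np.ndarray
    signal: np.ndarray
    spec: PhantomSpec

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def class_mask(self, name: str) -> np.ndarray:
        code = next(c.code for c in self.spec.classes if c.name == name)
        return self.labels == code

    @property
    def wm_reference_signal(self) -> float:
        """Noiseless WM class signal — the SNR reference intensity."""
        wm = self.spec.t1_of("wm")
        pd_f = next(c.proton_density_factor for c in self.spec.classes
                    if c.name == "wm")
        return pd_f * forward_signal(wm, self.spec.params, self.spec.k_true)


def _ellipsoid_mask(shape, axes_frac) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    semi = [f * (n - 1) / 2.0 for f, n in zip(axes_frac, shape)]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the label grid, assign per-class T1 and synthesize the
    noiseless signal volume ``pd_factor * S(T1; TR, theta, k_true)``.

    Deterministic for a given spec (lesion placement uses the spec seed).

    Raises
    ------
    LesionPlacementError
        If a lesion cannot be placed inside white matter without overlap
        after a bounded number of rejection-sampling attempts.
    """
    shape = tuple(spec.shape)
    labels = np.zeros(shape, dtype=np.int16)
    labels[_ellipsoid_mask(shape, spec.gm_axes)] = GM
    labels[_ellipsoid_mask(shape, spec.wm_axes)] = WM
    labels[_ellipsoid_mask(shape, spec.csf_axes)] = CSF

    rng = np.random.default_rng(spec.seed)
    if spec.lesion_count > 0:
        _place_lesions(labels, spec, rng)

    code_to_class = {c.code: c for c in spec.classes}
    present = set(np.unique(labels)) - {BACKGROUND}
    missing = present - set(code_to_class)
    if missing:
        raise ValueError(f"label codes {missing} have no TissueClass in spec")

    t1_truth = np.zeros(shape, dtype=float)
    pd_map = np.zeros(shape, dtype=float)
    for code in present:
        cls = code_to_class[code]
        sel = labels == code
        t1_truth[sel] = cls.t1_ms
        pd_map[sel] = cls.proton_density_factor

    signal = np.zeros(shape, dtype=float)
    brain = labels != BACKGROUND
    signal[brain] = pd_map[brain] * forward_signal(
        t1_truth[brain], spec.params, spec.k_true
    )
    return Phantom(labels=labels, t1_truth=t1_truth, signal=signal, spec=spec)


def _place_lesions(labels: np.ndarray, spec: PhantomSpec,
                   rng: np.random.Generator, max_attempts: int = 2000) -> None:
    shape = labels.shape
    placed = 0
    attempts = 0
    lo, hi = spec.lesion_radius_range
    while placed < spec.lesion_count:
        if attempts >= max_attempts:
            raise LesionPlacementError(
                f"placed {placed}/{spec.lesion_count} lesions "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(lo, hi)
        center = [rng.uniform(0, n - 1) for n in shape]
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        ball = sum((g - c) ** 2 for g, c in zip(grids, center)) <= r**2
        # require the whole ball (plus nothing already a lesion) inside WM
        if not ball.any() or np.any(labels[ball] != WM):
            continue
        labels[ball] = LESION
        placed += 1


def add_noise(volume, snr: float, model: str = "rician",
              seed: int = 0, reference: float | None = None) -> np.ndarray:
    """Add measurement noise at a given SNR.

    SNR is defined on ``reference`` (default: mean of the positive
    voxels; for phantoms pass ``phantom.wm_reference_signal``), so the
    per-channel noise SD is ``reference / snr``.

    ``model="gaussian"`` adds real N(0, sigma). ``model="rician"`` takes
    the magnitude of (signal + N(0, sigma)) + i N(0, sigma) — the
    distribution of magnitude MRI in complex Gaussian noise, positively
    biased at low SNR (a zero-signal region acquires a positive floor).
    """
    if not (snr > 0):
        raise ValueError(f"snr must be > 0, got {snr}")
    vol = np.asarray(volume, dtype=float)
    if reference is None:
        pos = vol[vol > 0]
        if pos.size == 0:
            raise ValueError("cannot infer SNR reference from an all-zero volume")
        reference = float(pos.mean())
    sigma = reference / snr
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        return vol + rng.normal(0.0, sigma, vol.shape)
    if model == "rician":
        real = vol + rng.normal(0.0, sigma, vol.shape)
        imag = rng.normal(0.0, sigma, vol.shape)
        return np.hypot(real, imag)
    raise ValueError(f"unknown noise model {model!r}; use 'gaussian' or 'rician'")


# ---------------------------------------------------------------------------
# Longitudinal cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortEffects:
    """Configured ground truth of the simulated two-timepoint cohort.

    ``*_change_pct`` are the percent changes over the scan interval
    (negative = volume loss / T1 shortening). Defaults mirror a
    natalizumab-treated relapsing-remitting MS cohort followed ~36
    months: measurable gray-matter and thalamic atrophy, stable white
    matter and T2 lesion volume, and an age effect on whole-brain volume
    loss. ``age_effect_on_pbvc`` is the PBVC slope per year of age under
    the negative-=-loss convention (older subjects lose more volume).
    """

    gm_change_pct: float = -2.24
    wm_change_pct: float = -0.34
    thalamus_change_pct: float = -3.60
    corpus_callosum_change_pct: float = -5.26
    t2_lesion_change_pct: float = 0.0
    gm_t1_change_pct: float = 6.06     # 1240.46 -> ~1315.6 ms
    lesion_t1_change_pct: float = 2.64  # 1041.52 -> ~1069.0 ms
    age_effect_on_pbvc: float = -0.05   # % per year of age
    pbvc_intercept: float = 0.0         # PBVC at the mean age, %
    volume_noise_pct: float = 0.0       # follow-up measurement noise, % of baseline
    pbvc_noise_sd: float = 0.0          # residual PBVC SD, %


# Baseline population means / spreads (volumes mm^3, T1 ms, T2LV cm^3)
_BASELINE = {
    "gm_volume": (798024.63, 69695.0),
    "wm_volume": (643247.52, 58276.0),
    "thalamus_volume": (10670.98, 1618.9),
    "corpus_callosum_volume": (1751.24, 625.8),
    "gm_t1": (1240.46, 56.44),
    "lesion_t1": (1041.52, 125.82),
}
_RACES = ("caucasian", "african_american", "hispanic")
_RACE_P = (0.50, 0.45, 0.05)


def simulate_cohort(
    n_subjects: int = 20,
    effects: CohortEffects | None = None,
    interval_months: float = 36.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-timepoint cohort table, one row per subject.

    Columns: subject_id, age (years), race, disease_duration (years),
    treatment_duration (months), treatment_possession (%),
    t2_lesion_volume (cm^3), pbvc (%, negative = loss),
    ``<compartment>_baseline`` / ``<compartment>_followup`` volumes
    (mm^3) and ``gm_t1_*`` / ``lesion_t1_*`` (ms).

    Deterministic per seed. Follow-up values apply the configured
    percent change plus optional multiplicative measurement noise; PBVC
    is a linear function of age-centred-at-cohort-mean plus Gaussian
    residual.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    eff = effects if effects is not None else CohortEffects()
    rng = np.random.default_rng(seed)

    age = rng.normal(39.0, 8.0, n_subjects).clip(18, 70)
    disease_duration = rng.gamma(4.0, 2.75, n_subjects).clip(1, 35)
    treatment_duration = rng.uniform(24, 60, n_subjects)
    possession = treatment_duration / (disease_duration * 12.0) * 100.0
    t2lv = rng.lognormal(np.log(7.42), 0.9, n_subjects)
    race = rng.choice(_RACES, n_subjects, p=_RACE_P)

    rows: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i:03d}" for i in range(n_subjects)]),
        "age": age,
        "race": race,
        "disease_duration": disease_duration,
        "treatment_duration": treatment_duration,
        "treatment_possession": possession,
        "t2_lesion_volume": t2lv,
        "t2_lesion_volume_baseline": t2lv,
        "t2_lesion_volume_followup": t2lv * (1.0 + eff.t2_lesion_change_pct / 100.0),
        "interval_months": np.full(n_subjects, float(interval_months)),
    }

    change_of = {
        "gm_volume": eff.gm_change_pct,
        "wm_volume": eff.wm_change_pct,
        "thalamus_volume": eff.thalamus_change_pct,
        "corpus_callosum_volume": eff.corpus_callosum_change_pct,
        "gm_t1": eff.gm_t1_change_pct,
        "lesion_t1": eff.lesion_t1_change_pct,
    }
    for name, (mean, sd) in _BASELINE.items():
        base = rng.normal(mean, sd, n_subjects).clip(mean * 0.2, None)
        factor = 1.0 + change_of[name] / 100.0
        noise = (
            rng.normal(0.0, eff.volume_noise_pct / 100.0, n_subjects)
            if eff.volume_noise_pct > 0
            else np.zeros(n_subjects)
        )
        follow = base * factor * (1.0 + noise)
        rows[f"{name}_baseline"] = base
        rows[f"{name}_followup"] = follow

    pbvc = (
        eff.pbvc_intercept
        + eff.age_effect_on_pbvc * (age - age.mean())
        + (rng.normal(0.0, eff.pbvc_noise_sd, n_subjects)
           if eff.pbvc_noise_sd > 0 else 0.0)
    )
    rows["pbvc"] = pbvc
    return pd.DataFrame(rows)
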