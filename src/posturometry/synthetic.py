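"""Synthetic cohorts of posture/balance screening recordings.

Generates the three study designs the evaluation pipeline consumes —
test-retest reliability (two occasions, one device), construct validity
(one motion observed by a consumer depth-camera-like device and a
laboratory mocap/force-plate reference), and a clinical two-group
comparison — with fully known ground truth, so parameter recovery is
checkable.

Two granularities share one configuration:

* **endpoint-level** — each of the 18 endpoints is drawn directly from
  the variance-components model

      y(subject, occasion) = mean + b_subject + w_occasion + device term,
      b ~ N(0, sigma_between^2),  w ~ N(0, sigma_within^2),

  so the expected test-retest ICC equals
  sigma_between^2 / (sigma_between^2 + sigma_within^2) exactly;
* **trace-level** — full marker trajectories and CoP traces are built
  from a static anthropometric pose, planted posture/side-bend traits,
  and a per-axis stationary Ornstein-Uhlenbeck sway process, exercising
  the whole kinematic extraction stack.

Determinism: every draw is a pure function of ``master_seed`` and the
(subject, occasion, device, task, trial) coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .kinematics import (
    CoPTrace,
    InvalidConfigError,
    MARKER_NAMES,
    MarkerTrajectorySet,
    VariablePanel,
    extract_panel,
)
from .variables import VARIABLES, VARIABLE_NAMES, variable

__all__ = [
    "SubjectProfile",
    "SimulationConfig",
    "TrialRecording",
    "Session",
    "StudyData",
    "make_cohort",
    "simulate_trial",
    "simulate_session",
    "simulate_reliability_dataset",
    "simulate_validity_dataset",
    "simulate_clinical_dataset",
]

_DEVICES = ("kinect_like", "mocap_forceplate")
_TASKS = ("stand", "side_bend", "single_left", "single_right")


@dataclass
class SubjectProfile:
    """Latent per-subject ground truth: anthropometry and endpoint traits."""

    subject_id: str
    height: float  # cm
    weight: float  # kg
    group: str     # healthy | lbp
    trait_vector: dict[str, float]
    sway_scale: float
    seed: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.weight <= 0:
            raise InvalidConfigError("height and weight must be > 0")
        if self.group not in ("healthy", "lbp"):
            raise InvalidConfigError(f"unknown group {self.group!r}")
        for k, v in self.trait_vector.items():
            if not math.isfinite(v):
                raise InvalidConfigError(f"trait {k} is not finite")


@dataclass
class SimulationConfig:
    """Variance components, device model and sampling for one synthetic study.

    Per-variable parameters (``sigma_between``, ``sigma_within``,
    ``sigma_device``, ``device_bias``, ``group_effect``) accept a scalar
    (applied to every endpoint), a mapping by endpoint name (unlisted
    endpoints fall back to the registry default / zero), or ``None`` for
    the registry defaults.

    The low-fidelity device adds ``device_bias`` and N(0, sigma_device^2)
    per endpoint; the reference device reads ``ref_scale * latent +
    ref_offset`` (registry defaults: ~5x on maximal sway velocities,
    +6 %height on side-bend depth) unless ``use_reference_transform`` is
    off.  ``heavy_tailed_df`` switches the noise components to a scaled
    Student-t with that many degrees of freedom.
    """

    n_subjects: int = 37
    lbp_fraction: float = 0.0
    n_lbp: int = 20
    n_controls: int = 17
    sigma_between: float | Mapping[str, float] | None = None
    sigma_within: float | Mapping[str, float] | None = None
    sigma_device: float | Mapping[str, float] = 0.0
    device_bias: float | Mapping[str, float] = 0.0
    group_effect: float | Mapping[str, float] | None = None
    use_reference_transform: bool = True
    # trace-level sway model: stationary SD per axis (cm) and time constant (s)
    sway_sd_stand: tuple[float, float] = (0.30, 0.20)
    sway_sd_single: tuple[float, float] = (0.80, 0.70)
    sway_tau: float = 1.0
    marker_noise_sd: float = 0.0   # cm, isotropic per frame (low-fidelity device)
    cop_noise_sd: float = 0.0      # cm per axis (low-fidelity device)
    fs_kinect: float = 30.0
    fs_mocap: float = 100.0
    n_trials: int = 3
    granularity: Literal["endpoint", "trace"] = "endpoint"
    heavy_tailed_df: float | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not 0.0 <= self.lbp_fraction <= 1.0:
            raise InvalidConfigError("lbp_fraction must lie in [0, 1]")
        if self.fs_kinect <= 0 or self.fs_mocap <= 0:
            raise InvalidConfigError("sampling frequencies must be > 0")
        if self.n_trials < 1:
            raise InvalidConfigError("n_trials must be >= 1")
        if self.granularity not in ("endpoint", "trace"):
            raise InvalidConfigError(f"unknown granularity {self.granularity!r}")
        for name in ("sigma_between", "sigma_within", "sigma_device"):
            val = getattr(self, name)
            if isinstance(val, (int, float)) and val < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
            if isinstance(val, Mapping) and any(v < 0 for v in val.values()):
                raise InvalidConfigError(f"{name} entries must be >= 0")

    # -- per-variable parameter resolution ---------------------------------
    def _resolve(self, value, default_fn) -> dict[str, float]:
        if value is None:
            return {v.name: default_fn(v) for v in VARIABLES}
        if isinstance(value, Mapping):
            return {v.name: float(value.get(v.name, 0.0)) for v in VARIABLES}
        return {v.name: float(value) for v in VARIABLES}

    def sigma_between_map(self) -> dict[str, float]:
        return self._resolve(self.sigma_between, lambda v: v.sigma_between)

    def sigma_within_map(self) -> dict[str, float]:
        return self._resolve(self.sigma_within, lambda v: v.sigma_within)

    def sigma_device_map(self) -> dict[str, float]:
        return self._resolve(self.sigma_device, lambda v: 0.0)

    def device_bias_map(self) -> dict[str, float]:
        return self._resolve(self.device_bias, lambda v: 0.0)

    def group_effect_map(self) -> dict[str, float]:
        if self.group_effect is None:
            # chronic LBP reduces side-bend depth (higher %height endpoint);
            # clinical cohorts show ~2.7 %height on the left, ~1.4 on the right
            return {v.name: {"SB-LF": 2.7, "SB-RF": 1.4}.get(v.name, 0.0)
                    for v in VARIABLES}
        return self._resolve(self.group_effect, lambda v: 0.0)

    def expected_icc(self, name: str) -> float:
        b = self.sigma_between_map()[name]
        w = self.sigma_within_map()[name]
        if b == w == 0.0:
            return 1.0
        return b**2 / (b**2 + w**2)


@dataclass
class TrialRecording:
    """One recorded trial: markers, optional CoP trace, and provenance."""

    markers: MarkerTrajectorySet
    cop: CoPTrace | None
    task: str
    occasion: int
    device: str
    trial: int = 1
    subject: str = ""
    valid: bool = True

    def __post_init__(self) -> None:
        if self.task not in _TASKS:
            raise InvalidConfigError(f"unknown task {self.task!r}")
        if self.device not in _DEVICES:
            raise InvalidConfigError(f"unknown device {self.device!r}")
        missing = set(MARKER_NAMES) - set(self.markers.data)
        if missing:
            raise InvalidConfigError(f"trial lacks markers: {sorted(missing)}")

    @property
    def duration(self) -> float:
        return self.markers.n_frames / self.markers.rate


@dataclass
class Session:
    """All trials (or the directly generated panel) for one subject-occasion-device."""

    subject: str
    occasion: int
    device: str
    trials: list[TrialRecording] = field(default_factory=list)
    panel: VariablePanel | None = None


@dataclass
class StudyData:
    """A simulated study: cohort, sessions, and the config that made them."""

    config: SimulationConfig
    cohort: list[SubjectProfile]
    sessions: list[Session]

    def panel(self, subject: str, occasion: int, device: str) -> VariablePanel:
        for s in self.sessions:
            if (s.subject, s.occasion, s.device) == (subject, occasion, device):
                if s.panel is None:
                    raise ValueError("session has no extracted panel")
                return s.panel
        raise KeyError((subject, occasion, device))


# ---------------------------------------------------------------------------
# randomness plumbing


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(k)) % (2**31) for k in key])


def _noise(rng: np.random.Generator, sd: float, df: float | None,
           size=None) -> np.ndarray | float:
    """Gaussian noise, or variance-matched scaled Student-t when df is set."""
    if df is not None:
        if df <= 2:
            raise InvalidConfigError("heavy_tailed_df must be > 2 (finite variance)")
        return rng.standard_t(df, size=size) * sd * math.sqrt((df - 2) / df)
    return rng.normal(0.0, sd, size=size)


# ---------------------------------------------------------------------------
# cohort


def make_cohort(config: SimulationConfig, groups: Sequence[str] | None = None
                ) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles with between-subject trait variation.

    ``groups`` fixes each subject's group label; by default the first
    ``round(lbp_fraction * n)`` subjects are the patient group.  Traits
    are ``population mean + N(0, sigma_between^2)`` per endpoint, plus
    the group effect for patients.
    """
    master = _rng(config.master_seed)
    sb = config.sigma_between_map()
    ge = config.group_effect_map()
    df = config.heavy_tailed_df
    n = config.n_subjects
    if groups is None:
        n_lbp = round(config.lbp_fraction * n)
        groups = ["lbp"] * n_lbp + ["healthy"] * (n - n_lbp)
    if len(groups) != n:
        raise InvalidConfigError("groups length must equal n_subjects")
    seeds = master.integers(0, 2**31, size=n)
    cohort = []
    for i, (group, seed) in enumerate(zip(groups, seeds)):
        rng = _rng(seed, 0)
        if group == "lbp":
            height = rng.normal(180.0, 8.6)
            weight = max(45.0, rng.normal(82.0, 12.0))
        else:
            height = rng.normal(173.0, 7.0)
            weight = max(40.0, rng.normal(70.0, 17.0))
        height = max(140.0, height)
        traits = {}
        for v in VARIABLES:
            t = v.mean + float(_noise(rng, sb[v.name], df))
            if group == "lbp":
                t += ge[v.name]
            traits[v.name] = t
        cohort.append(SubjectProfile(
            subject_id=f"S{i + 1:03d}", height=height, weight=weight,
            group=group, trait_vector=traits,
            sway_scale=float(np.exp(rng.normal(0.0, 0.25))), seed=int(seed)))
    return cohort


def _occasion_traits(profile: SubjectProfile, occasion: int,
                     config: SimulationConfig) -> dict[str, float]:
    """Latent endpoint values for one occasion: trait + between-occasion shift.

    Both occasions carry an independent N(0, sigma_within^2) component, so
    the expected test-retest ICC is sigma_b^2 / (sigma_b^2 + sigma_w^2).
    """
    sw = config.sigma_within_map()
    rng = _rng(profile.seed, 1, occasion)
    return {name: profile.trait_vector[name] + float(_noise(rng, sw[name],
                                                            config.heavy_tailed_df))
            for name in VARIABLE_NAMES}


def _observe_endpoint(latent: float, name: str, device: str, rng,
                      config: SimulationConfig) -> float:
    """Apply the device measurement model to one latent endpoint value."""
    if device == "kinect_like":
        bias = config.device_bias_map()[name]
        sd = config.sigma_device_map()[name]
        return latent + bias + float(_noise(rng, sd, config.heavy_tailed_df))
    spec = variable(name)
    if config.use_reference_transform:
        return spec.ref_scale * latent + spec.ref_offset
    return latent


# ---------------------------------------------------------------------------
# trace-level simulation


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _static_pose(profile: SubjectProfile, traits: dict[str, float]
                 ) -> dict[str, np.ndarray]:
    """Static marker positions (cm) encoding the planted posture traits.

    Standard anthropometric proportions of standing height h place each
    marker; the posture endpoints then hold by construction: the head-top
    Z offset is the P-HL trait, the trochanter-midpoint Z offset P-PP,
    estimated minus reported height P-HS, and the shoulder X position is
    solved so the planted neck angle P-NA coexists with the planted head
    frontal offset P-HF.
    """
    h = profile.height
    y_sh, y_hip, y_ank = 0.818 * h, 0.530 * h, 0.039 * h
    z_sh, z_hip, z_ank = 0.115 * h, 0.095 * h, 0.050 * h
    head_y = h + traits["P-HS"]
    # neck/spine geometry: solve the shoulder anterior offset so that the
    # sagittal neck-vs-spine angle equals the planted P-NA
    l_neck, l_spine = head_y - y_sh, y_sh - y_hip
    a_neck = math.atan2(traits["P-HF"], l_neck)
    sh_x = l_spine * math.tan(a_neck - math.radians(traits["P-NA"]))
    pose = {
        "head_top": [sh_x + traits["P-HF"], head_y, traits["P-HL"]],
        "acromion_l": [sh_x, y_sh, z_sh],
        "acromion_r": [sh_x, y_sh, -z_sh],
        "c7": [sh_x - 0.02 * h, 0.835 * h, 0.0],
        "fingertip_l": [0.0, 0.470 * h, 0.130 * h],
        "fingertip_r": [0.0, 0.470 * h, -0.130 * h],
        "trochanter_l": [0.0, y_hip, z_hip + traits["P-PP"]],
        "trochanter_r": [0.0, y_hip, -z_hip + traits["P-PP"]],
        "mid_pelvic": [0.03 * h, 0.550 * h, traits["P-PP"]],
        "knee_lat_l": [0.0, 0.285 * h, z_ank + 0.030 * h],
        "knee_med_l": [0.0, 0.285 * h, z_ank - 0.030 * h],
        "knee_lat_r": [0.0, 0.285 * h, -z_ank - 0.030 * h],
        "knee_med_r": [0.0, 0.285 * h, -z_ank + 0.030 * h],
        "malleolus_l": [0.0, y_ank, z_ank],
        "malleolus_r": [0.0, y_ank, -z_ank],
    }
    return {k: np.asarray(v, dtype=float) for k, v in pose.items()}


def _ou(rng: np.random.Generator, n: int, sd: float, tau: float, dt: float
        ) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path, exact discretisation."""
    if sd == 0.0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    phi = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def simulate_trial(profile: SubjectProfile, task: str, occasion: int,
                   device: str, config: SimulationConfig, trial: int = 1
                   ) -> TrialRecording:
    """Synthesise one trial recording at full trace level.

    Stance tasks carry an OU CoP trace at the subject's sway scale;
    single-leg tasks plant the swinging-ankle A/P maximum at t* = 2 s
    (so the analysis window start is known by construction); side-bend
    trials move each fingertip down to the subject's true capacity
    (% height, with the low-fidelity device's bias folded into the
    executed depth).  Occasion and device effects follow the endpoint
    model; the low-fidelity device adds isotropic marker noise and CoP
    noise and samples at ``fs_kinect``.
    """
    if task not in _TASKS:
        raise InvalidConfigError(f"unknown task {task!r}")
    if device not in _DEVICES:
        raise InvalidConfigError(f"unknown device {device!r}")
    rate = config.fs_kinect if device == "kinect_like" else config.fs_mocap
    dt = 1.0 / rate
    traits = _occasion_traits(profile, occasion, config)
    bias = config.device_bias_map() if device == "kinect_like" else {
        n: 0.0 for n in VARIABLE_NAMES}
    rng = _rng(profile.seed, 2, occasion, _TASKS.index(task),
               _DEVICES.index(device), trial)

    duration = {"stand": 8.0, "single_left": 7.0, "single_right": 7.0,
                "side_bend": 10.0}[task]
    n = round(duration * rate)
    t = np.arange(n) * dt
    pose = _static_pose(profile, traits)
    markers = {k: np.tile(v, (n, 1)) for k, v in pose.items()}
    ank_mid_z = (pose["malleolus_l"][2] + pose["malleolus_r"][2]) / 2.0
    half_span = pose["malleolus_l"][2] - ank_mid_z

    sd_ap, sd_ml = (config.sway_sd_stand if task == "stand"
                    else config.sway_sd_single)
    scale = profile.sway_scale
    cop_ap = _ou(rng, n, sd_ap * scale, config.sway_tau, dt)
    cop_ml = _ou(rng, n, sd_ml * scale, config.sway_tau, dt)

    if task == "stand":
        pwb = traits["P-WB"] + bias["P-WB"]
        cop_ml = cop_ml + (pwb - 50.0) / 50.0 * half_span
    elif task in ("single_left", "single_right"):
        swing = "malleolus_r" if task == "single_left" else "malleolus_l"
        # anterior leg lift: rise to a unique max at t* = 2 s, slight
        # settle-back, then hold for the remainder
        t_star, lift = 2.0, 0.20 * profile.height
        x = lift * _smoothstep(t / t_star)
        settle = 0.97 + 0.03 * np.exp(-(np.maximum(t - t_star, 0.0)) / 0.4)
        x = np.where(t > t_star, lift * settle, x)
        markers[swing] = markers[swing].copy()
        markers[swing][:, 0] += x
        markers[swing][:, 1] += 0.15 * profile.height * _smoothstep(t / t_star)
        stance_z = pose["malleolus_l" if task == "single_left" else "malleolus_r"][2]
        cop_ml = cop_ml + stance_z
    elif task == "side_bend":
        for side, tip, t_mid in (("left", "fingertip_l", 2.5),
                                 ("right", "fingertip_r", 6.5)):
            name = "SB-LF" if side == "left" else "SB-RF"
            target = (traits[name] + bias[name]) / 100.0 * profile.height
            y0 = pose[tip][1]
            dip = (y0 - target) * _smoothstep(1.0 - np.abs(t - t_mid) / 1.5)
            markers[tip] = markers[tip].copy()
            markers[tip][:, 1] -= dip
        # weight shifts towards the bending side; leftward peak encodes SB-%BW
        ml_peak = (traits["SB-%BW"] + bias["SB-%BW"] - 50.0) / 50.0 * half_span
        cop_ml = cop_ml + ml_peak * _smoothstep(1.0 - np.abs(t - 2.5) / 1.5) \
            - ml_peak * _smoothstep(1.0 - np.abs(t - 6.5) / 1.5)

    if device == "kinect_like":
        if config.marker_noise_sd > 0:
            for k in markers:
                markers[k] = markers[k] + rng.normal(
                    0.0, config.marker_noise_sd, size=markers[k].shape)
        if config.cop_noise_sd > 0:
            cop_ap = cop_ap + rng.normal(0.0, config.cop_noise_sd, size=n)
            cop_ml = cop_ml + rng.normal(0.0, config.cop_noise_sd, size=n)

    return TrialRecording(
        markers=MarkerTrajectorySet(markers, rate),
        cop=CoPTrace(cop_ap, cop_ml, rate),
        task=task, occasion=occasion, device=device, trial=trial,
        subject=profile.subject_id)


def simulate_session(profile: SubjectProfile, occasion: int, device: str,
                     config: SimulationConfig) -> Session:
    """All tasks x trials for one subject-occasion-device, panel extracted."""
    session = Session(profile.subject_id, occasion, device)
    for task in _TASKS:
        for trial in range(1, config.n_trials + 1):
            session.trials.append(
                simulate_trial(profile, task, occasion, device, config, trial))
    session.panel = extract_panel(session.trials, profile.height)
    session.panel.subject = profile.subject_id
    session.panel.occasion = occasion
    session.panel.device = device
    return session


def _endpoint_session(profile: SubjectProfile, occasion: int, device: str,
                      config: SimulationConfig) -> Session:
    latent = _occasion_traits(profile, occasion, config)
    rng = _rng(profile.seed, 3, occasion, _DEVICES.index(device))
    panel = VariablePanel(subject=profile.subject_id, occasion=occasion,
                          device=device)
    for name in VARIABLE_NAMES:
        panel.set(name, _observe_endpoint(latent[name], name, device, rng, config))
    return Session(profile.subject_id, occasion, device, trials=[], panel=panel)


def _make_session(profile, occasion, device, config) -> Session:
    if config.granularity == "endpoint":
        return _endpoint_session(profile, occasion, device, config)
    return simulate_session(profile, occasion, device, config)


# ---------------------------------------------------------------------------
# study designs


def simulate_reliability_dataset(config: SimulationConfig) -> StudyData:
    """Two occasions per subject on the low-fidelity device (~1 week apart)."""
    cohort = make_cohort(config)
    sessions = [_make_session(p, occ, "kinect_like", config)
                for p in cohort for occ in (1, 2)]
    return StudyData(config, cohort, sessions)


def _degrade_to_kinect(trial: TrialRecording, profile: SubjectProfile,
                       config: SimulationConfig) -> TrialRecording:
    """Re-observe a reference recording through the low-fidelity device.

    Subsamples the shared motion to ``fs_kinect``, adds isotropic marker
    noise and CoP noise, and applies the additive device biases that are
    expressible at trace level (side-bend fingertip depth, CoP-derived
    weight-distribution offsets).
    """
    rate_out = config.fs_kinect
    n_out = int(trial.markers.n_frames * rate_out / trial.markers.rate)
    idx = np.minimum(np.round(np.arange(n_out) * trial.markers.rate / rate_out
                              ).astype(int), trial.markers.n_frames - 1)
    rng = _rng(profile.seed, 4, trial.occasion, _TASKS.index(trial.task),
               trial.trial)
    bias = config.device_bias_map()
    markers = {}
    for name, arr in trial.markers.data.items():
        out = arr[idx].copy()
        if config.marker_noise_sd > 0:
            out += rng.normal(0.0, config.marker_noise_sd, size=out.shape)
        markers[name] = out
    h = profile.height
    if trial.task == "side_bend":
        markers["fingertip_l"][:, 1] += bias["SB-LF"] / 100.0 * h
        markers["fingertip_r"][:, 1] += bias["SB-RF"] / 100.0 * h
    cop = None
    if trial.cop is not None:
        ap = trial.cop.ap[idx].copy()
        ml = trial.cop.ml[idx].copy()
        ank_mid = (trial.markers["malleolus_l"][:, 2].mean()
                   + trial.markers["malleolus_r"][:, 2].mean()) / 2.0
        half_span = trial.markers["malleolus_l"][:, 2].mean() - ank_mid
        if trial.task == "stand":
            ml += bias["P-WB"] / 50.0 * half_span
        elif trial.task == "side_bend":
            ml += bias["SB-%BW"] / 50.0 * half_span
        if config.cop_noise_sd > 0:
            ap += rng.normal(0.0, config.cop_noise_sd, size=n_out)
            ml += rng.normal(0.0, config.cop_noise_sd, size=n_out)
        cop = CoPTrace(ap, ml, rate_out)
    return TrialRecording(
        markers=MarkerTrajectorySet(markers, rate_out), cop=cop,
        task=trial.task, occasion=trial.occasion, device="kinect_like",
        trial=trial.trial, subject=trial.subject)


def simulate_validity_dataset(config: SimulationConfig) -> StudyData:
    """One occasion per subject, recorded simultaneously by both devices.

    Both devices observe the identical underlying latent motion (same
    occasion draw); only the measurement model — noise, bias, sampling
    rate, reference transform — differs between them.  At trace level the
    low-fidelity recording is the reference recording subsampled and
    degraded, so the shared motion is literal.
    """
    cohort = make_cohort(config)
    sessions: list[Session] = []
    for p in cohort:
        if config.granularity == "endpoint":
            sessions.append(_endpoint_session(p, 1, "kinect_like", config))
            sessions.append(_endpoint_session(p, 1, "mocap_forceplate", config))
            continue
        ref = simulate_session(p, 1, "mocap_forceplate", config)
        kin = Session(p.subject_id, 1, "kinect_like")
        kin.trials = [_degrade_to_kinect(t, p, config) for t in ref.trials]
        kin.panel = extract_panel(kin.trials, p.height)
        kin.panel.subject, kin.panel.occasion, kin.panel.device = (
            p.subject_id, 1, "kinect_like")
        sessions.extend([kin, ref])
    return StudyData(config, cohort, sessions)


def simulate_clinical_dataset(config: SimulationConfig) -> StudyData:
    """Patient vs control groups, one occasion, low-fidelity device only.

    Group sizes come from ``n_lbp`` / ``n_controls`` (defaults 20 / 17);
    patients' side-bend traits are shifted by the group effect.
    """
    n = config.n_lbp + config.n_controls
    cfg = replace(config, n_subjects=n)
    groups = ["lbp"] * config.n_lbp + ["healthy"] * config.n_controls
    cohort = make_cohort(cfg, groups=groups)
    sessions = [_make_session(p, 1, "kinect_like", cfg) for p in cohort]
    return StudyData(cfg, cohort, sessions)
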