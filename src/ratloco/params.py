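"""Model parameters: skeleton, ground contact, muscles, and motor control.

All defaults describe an adult (~125 g) rat.  Config files carry the raw
anatomical units (grams, millimetres, degrees); everything is converted to
SI (kg, m, rad) on load and used in SI internally.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import yaml

G_TO_KG = 1e-3
MM_TO_M = 1e-3
GMM2_TO_KGM2 = 1e-9

#: joint names in generalized-coordinate order (per limb)
FORE_JOINTS = ("shoulder", "elbow")
HIND_JOINTS = ("hip", "knee", "ankle")

#: neutral posture (deg) at which muscle lengths are calibrated
NEUTRAL_POSTURE_DEG = {
    "shoulder": 60.0,
    "elbow": 85.0,
    "hip": 70.0,
    "knee": 90.0,
    "ankle": 100.0,
}

#: reference (fully extended, limb perpendicular to trunk) joint angles (deg)
REFERENCE_POSTURE_DEG = {
    "shoulder": 120.0,
    "elbow": 180.0,
    "hip": 120.0,
    "knee": 180.0,
    "ankle": 180.0,
}


class ConfigurationError(ValueError):
    """Raised when a parameter set violates a model invariant."""


# ---------------------------------------------------------------------------
# Skeleton
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkParams:
    """One rigid link. ``com`` is the centre-of-mass offset from the proximal
    joint along the link axis (defaults to the midpoint)."""

    name: str
    mass: float          # kg
    length: float        # m
    inertia: float       # kg m^2, about the CoM
    com: float = None    # m from proximal end; None -> length / 2

    def __post_init__(self):
        if self.com is None:
            object.__setattr__(self, "com", self.length / 2.0)
        for attr in ("mass", "length", "inertia"):
            if not getattr(self, attr) > 0.0:
                raise ConfigurationError(
                    f"link {self.name!r}: {attr} must be strictly positive, "
                    f"got {getattr(self, attr)!r}"
                )
        if not 0.0 <= self.com <= self.length:
            raise ConfigurationError(
                f"link {self.name!r}: CoM offset {self.com} outside [0, length]"
            )


def _link(name, mass_g, length_mm, moi_e2_gmm2):
    return LinkParams(
        name=name,
        mass=mass_g * G_TO_KG,
        length=length_mm * MM_TO_M,
        inertia=moi_e2_gmm2 * 1e2 * GMM2_TO_KGM2,
    )


@dataclass(frozen=True)
class SkeletonParams:
    """Planar 11-link skeleton: trunk (head included) + 2 forelimb links and
    3 hindlimb links per side.  Left and right limbs are identical.

    13 generalized coordinates: trunk x, z, pitch + 10 joint angles
    (shoulder, elbow per forelimb; hip, knee, ankle per hindlimb).
    """

    trunk: LinkParams = field(default_factory=lambda: LinkParams(
        "trunk", mass=99.8 * G_TO_KG, length=93.0 * MM_TO_M,
        inertia=1410.0 * 1e2 * GMM2_TO_KGM2, com=0.4734 * 93.0 * MM_TO_M))
    brachium: LinkParams = field(default_factory=lambda: _link("brachium", 1.6, 16.1, 0.57))
    antebrachium: LinkParams = field(default_factory=lambda: _link("antebrachium", 1.6, 19.0, 0.53))
    thigh: LinkParams = field(default_factory=lambda: _link("thigh", 5.2, 18.5, 5.73))
    shank: LinkParams = field(default_factory=lambda: _link("shank", 2.8, 27.2, 2.62))
    foot: LinkParams = field(default_factory=lambda: _link("foot", 1.5, 17.7, 0.75))
    gravity: float = 9.81  # m/s^2
    #: passive viscous resistance at every joint (N m s/rad), standing in
    #: for the velocity-dependent passive muscle/tissue component
    joint_viscosity: float = 1e-4
    #: shoulder joint sits at the cranial trunk end, hip at the caudal end
    shoulder_offset: float = None  # m along trunk axis from trunk CoM
    hip_offset: float = None

    def __post_init__(self):
        if self.shoulder_offset is None:
            object.__setattr__(self, "shoulder_offset", self.trunk.length - self.trunk.com)
        if self.hip_offset is None:
            object.__setattr__(self, "hip_offset", -self.trunk.com)

    @property
    def links(self) -> Sequence[LinkParams]:
        return (self.trunk, self.brachium, self.antebrachium,
                self.thigh, self.shank, self.foot)

    @property
    def total_mass(self) -> float:
        """Whole-body mass: trunk once, each limb link twice (left + right)."""
        return self.trunk.mass + 2.0 * (
            self.brachium.mass + self.antebrachium.mass
            + self.thigh.mass + self.shank.mass + self.foot.mass
        )


@dataclass(frozen=True)
class JointLimitParams:
    """One-sided viscoelastic joint-limit torques at the anatomical bounds.

    The reference configuration defines full extension: the elbow, knee and
    ankle cannot pass 180 deg (bony/ligamentous stop).  Without these stops
    the near-straight stance limbs hyperextend, the limb strut folds
    backward, and the model collapses.  Torques are restoring-only
    (clamped toward the admissible range).
    """

    enabled: bool = True
    stiffness: float = 1.1     # N m / rad beyond the bound
    damping: float = 0.001     # N m s / rad while beyond the bound
    bounds_deg: dict = field(default_factory=lambda: {
        "shoulder": (58.9, 170.0),
        "elbow": (10.0, 180.0),
        "hip": (10.0, 170.0),
        "knee": (10.0, 180.0),
        "ankle": (10.0, 180.0),
    })

    def __post_init__(self):
        if self.stiffness < 0 or self.damping < 0:
            raise ConfigurationError("joint-limit stiffness/damping must be >= 0")
        for joint, (lo, hi) in self.bounds_deg.items():
            if lo >= hi:
                raise ConfigurationError(f"joint limit for {joint}: need lo < hi")


@dataclass(frozen=True)
class ContactParams:
    """Viscoelastic limb-tip/ground contact.

    Vertical: one-sided spring-damper, force clamped nonnegative; static
    penetration under body weight is a fraction of a millimetre.
    Horizontal: spring-damper to an anchor point planted at touchdown,
    capped by a Coulomb friction cone |Fx| <= mu * Fz (the anchor slips
    when the cone saturates).  Without the cone a grazing swing-paw touch
    would be rigidly tethered and trip the model.  The default horizontal
    pair is damper-dominated (a viscous skid): loaded paws may creep, which
    is what lets the short forelimbs keep up with the trunk (see
    docs/methods.md for the calibration).
    """

    vertical_stiffness: float = 3800.0    # N/m
    vertical_damping: float = 16.0        # N s/m
    horizontal_stiffness: float = 70.0    # N/m
    horizontal_damping: float = 25.0      # N s/m
    friction: float = 0.435               # Coulomb cap mu
    ground_height: float = 0.0            # m

    def __post_init__(self):
        for attr in ("vertical_stiffness", "vertical_damping",
                     "horizontal_stiffness", "horizontal_damping", "friction"):
            if getattr(self, attr) < 0.0:
                raise ConfigurationError(f"contact {attr} must be nonnegative")


# ---------------------------------------------------------------------------
# Muscles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MuscleJointAction:
    """How a muscle acts at one spanned joint.

    ``action`` is 'ext' or 'flex' with the extensor-positive joint-angle
    convention: an extensor shortens (and its tension produces positive
    torque) as the joint angle increases.

    ``deg_per_pct`` is the joint excursion (deg) per 1 % change of maximum
    muscle length (2 deg/1 % for most muscles).
    """

    joint: str
    action: str            # 'ext' | 'flex'
    moment_arm: float      # m, magnitude
    deg_per_pct: float = 2.0

    def __post_init__(self):
        if self.action not in ("ext", "flex"):
            raise ConfigurationError(f"action must be 'ext' or 'flex', got {self.action!r}")

    @property
    def torque_sign(self) -> float:
        return 1.0 if self.action == "ext" else -1.0

    @property
    def length_sign(self) -> float:
        """Sign of dl/dangle: flexors lengthen as the joint extends."""
        return -self.torque_sign


@dataclass(frozen=True)
class MuscleParams:
    name: str
    limb: str                      # 'fore' | 'hind'
    f_max: float                   # N
    joints: tuple                  # tuple[MuscleJointAction, ...]
    tau_act: float = 0.011         # s
    tau_deact: float = 0.018       # s

    def __post_init__(self):
        if not self.f_max > 0:
            raise ConfigurationError(f"muscle {self.name}: F_max must be > 0")
        if not (self.tau_act > 0 and self.tau_deact > 0):
            raise ConfigurationError(f"muscle {self.name}: time constants must be > 0")

    @property
    def biarticular(self) -> bool:
        return len(self.joints) == 2

    @property
    def neutral_norm_length(self) -> float:
        """Normalized length at the neutral posture: 0.85 uniarticular,
        0.75 biarticular."""
        return 0.75 if self.biarticular else 0.85


def _m(name, limb, f_max, *joints):
    return MuscleParams(name=name, limb=limb, f_max=f_max,
                        joints=tuple(MuscleJointAction(*j) for j in joints))


def default_muscles() -> tuple:
    """The 13 muscle types (instantiated per side by the model builder).

    Maximum tensions are PCSA-based; moment arms are constant (mm in the
    source table, SI here).
    """
    mm = MM_TO_M
    return (
        _m("SSP", "fore", 11.1, ("shoulder", "ext", 3.6 * mm)),
        _m("SPD", "fore", 9.8, ("shoulder", "flex", 5.3 * mm)),
        _m("BR", "fore", 5.1, ("elbow", "flex", 3.6 * mm)),
        _m("TRIL", "fore", 11.5, ("elbow", "ext", 5.9 * mm)),
        _m("BIC", "fore", 7.7, ("shoulder", "ext", 2.4 * mm, 4.5),
                                ("elbow", "flex", 4.0 * mm)),
        _m("TRI", "fore", 23.2, ("shoulder", "flex", 5.7 * mm),
                                 ("elbow", "ext", 5.9 * mm)),
        _m("IP", "hind", 15.7, ("hip", "flex", 4.5 * mm)),
        _m("GM", "hind", 23.3, ("hip", "ext", 2.3 * mm)),
        _m("VL", "hind", 24.0, ("knee", "ext", 3.2 * mm)),
        _m("TA", "hind", 4.1, ("ankle", "flex", 5.1 * mm)),
        _m("SO", "hind", 3.5, ("ankle", "ext", 6.0 * mm)),
        _m("BF", "hind", 3.1, ("hip", "ext", 2.5 * mm),
                               ("knee", "flex", 12.5 * mm)),
        _m("GA", "hind", 4.5, ("knee", "flex", 4.2 * mm, 4.5),
                               ("ankle", "ext", 6.0 * mm, 1.5)),
    )


MUSCLE_NAMES = tuple(m.name for m in default_muscles())

#: normalizing contraction speed: 1.8 maximum lengths per second
VELOCITY_NORM = 1.8


@dataclass(frozen=True)
class MuscleCurveParams:
    """Parameters of the default Hill-curve family.

    force-length   F^l(l) = exp(-((l-1)/fl_width)^2)
    force-velocity F^v(v) = (1-v)/(1+v/fv_shape) for 0<=v<1, 0 above;
                   eccentric branch min(fv_ecc_cap, 1.5-0.5*(1+v)/(1-fv_ecc_slope*v))
    passive        F^p(l) = fp_scale*(exp(fp_rate*(l-1))-1) for l>1, else 0

    Normalization invariants: F^l(1)=1, F^v(0)=1, F^p<=1 vanishes at/below
    the optimum length; all three are nonnegative.
    """

    fl_width: float = 0.564
    fv_shape: float = 0.3
    fv_ecc_slope: float = 7.56 / 3.75
    fv_ecc_cap: float = 1.5
    fp_scale: float = 0.2
    fp_rate: float = 12.0

    def __post_init__(self):
        if self.fl_width <= 0 or self.fv_shape <= 0:
            raise ConfigurationError("curve widths must be strictly positive")
        if self.fp_scale < 0 or self.fp_rate < 0 or self.fv_ecc_cap < 1.0:
            raise ConfigurationError("invalid passive/eccentric curve constants")


# ---------------------------------------------------------------------------
# Motor control: CPG schedule, synergy weights, regulators
# ---------------------------------------------------------------------------

PI = math.pi

#: nominal pulse onset phases (rad); pulses 1-2 drive extension, 3-4 flexion
PHI_HAT = (0.0, 0.40 * PI, 1.24 * PI, 1.42 * PI)
#: nominal pulse end phases (rad)
PSI_HAT = (0.33 * PI, 0.89 * PI, 1.42 * PI, 1.71 * PI)

#: nominal synergy weights w^hat_{m,i}; unlisted (muscle, pulse) pairs are 0
WEIGHTS_HAT = {
    "SSP": {1: 0.24, 4: 0.20},
    "SPD": {2: 0.27, 3: 0.08},
    "BR": {3: 0.09},
    "TRIL": {1: 0.47, 2: 0.57},
    "BIC": {3: 0.17, 4: 0.08},
    "TRI": {1: 0.27, 2: 0.56},
    "IP": {3: 0.32, 4: 0.32},
    "GM": {1: 0.61, 2: 0.25},
    "VL": {1: 0.19, 2: 0.22},
    "TA": {3: 0.45, 4: 0.06},
    "SO": {1: 0.58, 2: 0.14},
    "BF": {1: 0.22, 2: 0.12, 3: 0.09},
    "GA": {1: 0.47, 2: 0.10},
}


@dataclass(frozen=True)
class SynergySchedule:
    """Four rectangular pulses per limb cycle plus per-muscle weights."""

    onsets: tuple = PHI_HAT
    ends: tuple = PSI_HAT
    weights: dict = field(default_factory=lambda: {k: dict(v) for k, v in WEIGHTS_HAT.items()})

    def __post_init__(self):
        if abs(self.onsets[0]) > 1e-12:
            raise ConfigurationError("pulse 1 must start at phase 0")
        for i, (on, off) in enumerate(zip(self.onsets, self.ends), start=1):
            if not (0.0 <= on < off <= 2.0 * PI):
                raise ConfigurationError(f"pulse {i}: need 0 <= onset < end <= 2*pi")
        for name, wd in self.weights.items():
            for i, w in wd.items():
                if w < 0:
                    raise ConfigurationError(f"weight w[{name},{i}] must be >= 0")

    def weight_matrix(self, muscle_names=MUSCLE_NAMES):
        import numpy as np
        W = np.zeros((len(muscle_names), 4))
        for r, name in enumerate(muscle_names):
            for i, w in self.weights.get(name, {}).items():
                W[r, i - 1] = w
        return W


@dataclass(frozen=True)
class OscillatorParams:
    """Rhythm-generator network: four phase oscillators, one per limb.

    Contralateral coupling (gain K1) locks left/right in antiphase;
    ipsilateral coupling (gain K2) locks fore/hind at offset Delta
    (pi/2 walking, pi trotting).
    """

    k1: float = 20.0   # 1/s
    k2: float = 10.0   # 1/s


@dataclass(frozen=True)
class RegulatorParams:
    """Brainstem/cerebellar posture and speed feedback (stance limbs only),
    delivered with a fixed sensorimotor delay.

    Gains map height error (m) / speed error (m/s) to dimensionless motor
    commands; signs implement antagonist pairs.
    """

    h0_shoulder: float = 0.033   # m
    h0_hip: float = 0.054        # m
    v0: float = 0.4              # m/s
    k_height: dict = field(default_factory=lambda: {
        "BR": -2.07, "TRIL": 2.07, "VL": 12.4, "TA": -12.4, "SO": 12.4})
    d_height: dict = field(default_factory=lambda: {
        "BR": -0.001, "TRIL": 0.001, "VL": 0.006, "TA": -0.006, "SO": 0.006})
    k_speed: dict = field(default_factory=lambda: {
        "SSP": -0.007, "SPD": 0.007, "IP": -0.052, "GM": 0.052,
        "TA": -0.026, "SO": 0.026})
    delay: float = 0.015         # s

    def __post_init__(self):
        if self.delay < 0:
            raise ConfigurationError("regulator delay must be >= 0")


@dataclass(frozen=True)
class GaitParams:
    """Gait selection and speed modulation.

    The gait is set solely by the ipsilateral phase offset Delta; speed is
    modulated by the extension fraction beta at fixed flexion duration
    T_fl, which rescales the pulse schedule, the extension-pulse weights,
    and the regulator references.
    """

    gait: str = "walk"            # 'walk' | 'trot'
    beta: float = 0.62
    beta_hat: float = 0.62
    t_flex: float = 0.10          # s, flexion-phase duration (speed-invariant)
    alpha_shoulder: float = 0.01  # m, d h0_shoulder / d beta
    alpha_hip: float = 0.01       # m
    alpha_speed: float = -4.7     # m/s
    ramp_rate: float = 0.005      # max |d beta| per gait cycle
    beta_min: float = 0.56
    beta_max: float = 0.68

    def __post_init__(self):
        if self.gait not in ("walk", "trot"):
            raise ConfigurationError(f"gait must be 'walk' or 'trot', got {self.gait!r}")
        for b in (self.beta, self.beta_hat):
            if not 0.0 < b < 1.0:
                raise ConfigurationError("beta must lie in (0, 1)")

    @property
    def delta(self) -> float:
        """Ipsilateral fore-hind phase offset (rad)."""
        return PI / 2.0 if self.gait == "walk" else PI

    @property
    def cycle_duration(self) -> float:
        """T = T_fl / (1 - beta)."""
        return self.t_flex / (1.0 - self.beta)

    @property
    def extension_duration(self) -> float:
        return self.beta * self.cycle_duration


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Everything needed for one reproducible forward-dynamics run."""

    skeleton: SkeletonParams = field(default_factory=SkeletonParams)
    contact: ContactParams = field(default_factory=ContactParams)
    joint_limits: JointLimitParams = field(default_factory=JointLimitParams)
    curves: MuscleCurveParams = field(default_factory=MuscleCurveParams)
    schedule: SynergySchedule = field(default_factory=SynergySchedule)
    oscillator: OscillatorParams = field(default_factory=OscillatorParams)
    regulator: RegulatorParams = field(default_factory=RegulatorParams)
    gait: GaitParams = field(default_factory=GaitParams)
    dt: float = 2e-5              # s, RK4 time step
    duration: float = 5.5         # s
    record_stride: int = 50       # record every N steps (default 1 kHz)
    discard_cycles: int = 5
    measure_cycles: int = 10
    seed: int = 0
    random_phases: bool = False   # start oscillators at random instead of the fixed point
    #: initial forward speed (m/s).  The regulator target v0 = 0.4 m/s is not
    #: geometrically sustainable (the stance arc v*T_ex would exceed the
    #: forelimb length), so runs start at the model's own steady speed scale.
    start_speed: float = 0.15
    #: global oscillator phase at t = 0; the default places three limbs in
    #: stance and one forelimb in swing, closest to a static standing start
    start_phase: float = 1.0804 * math.pi
    passive: bool = False         # silence all muscles (skeleton-only run)
    fall_pitch: float = math.radians(60.0)
    fall_height_fraction: float = 0.30

    def __post_init__(self):
        if not self.dt > 0:
            raise ConfigurationError("dt must be > 0")
        if self.record_stride < 1:
            raise ConfigurationError("record_stride must be >= 1")

    @property
    def delay_steps(self) -> int:
        return int(round(self.regulator.delay / self.dt))


# ---------------------------------------------------------------------------
# Config file round-trip
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(config: SimConfig) -> dict:
    return _to_plain(config)


def _build(cls, data):
    kwargs = {}
    hints = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in hints:
            raise ConfigurationError(f"unknown {cls.__name__} field {key!r}")
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> SimConfig:
    data = dict(data)
    built = {}
    nested = {
        "skeleton": SkeletonParams, "contact": ContactParams,
        "joint_limits": JointLimitParams, "curves": MuscleCurveParams,
        "schedule": SynergySchedule, "oscillator": OscillatorParams,
        "regulator": RegulatorParams, "gait": GaitParams,
    }
    for key, cls in nested.items():
        if key in data:
            sub = dict(data.pop(key))
            if cls is SkeletonParams:
                for lname in ("trunk", "brachium", "antebrachium", "thigh", "shank", "foot"):
                    if lname in sub and isinstance(sub[lname], dict):
                        sub[lname] = LinkParams(**sub[lname])
            if cls is SynergySchedule:
                for tkey in ("onsets", "ends"):
                    if tkey in sub:
                        sub[tkey] = tuple(sub[tkey])
                if "weights" in sub:
                    sub["weights"] = {
                        name: {int(i): float(w) for i, w in wd.items()}
                        for name, wd in sub["weights"].items()
                    }
            built[key] = _build(cls, sub)
    for key, value in data.items():
        built[key] = value
    return _build(SimConfig, built)


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
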