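"""Run configuration: every tunable parameter of the model, with frozen defaults.

The configuration is a nested pydantic model.  Unknown keys are rejected,
round-trips through YAML are lossless, and a short hash of the canonical JSON
dump identifies a parameter set in trace headers and logs.

The six canonical threshold presets pair the two femur-tibia gating regimes
(``tonic``: gamma_thr = 83 deg, below the gamma oscillation floor; ``switch``:
gamma_thr = 145 deg, inside the oscillation band) with the three femur
elevation thresholds beta_thr = -4, 4, 16 deg.  Presets are data, not code.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class IntegrationConfig(_Section):
    """Fixed-step explicit 4th-order integration."""

    dt_ms: float = Field(0.1, gt=0.0, le=1.0)
    record_every_ms: float = Field(1.0, gt=0.0)


class CpgCellConfig(_Section):
    """Biophysics of one half-center cell.

    Each cell is a two-variable relaxation oscillator: a fast persistent
    inward (sodium-like) current with instantaneous activation ``m`` and a
    slow inactivation variable ``h``, plus leak and synaptic conductances.
    Voltages in mV, conductances in nS, capacitance in pF, times in ms
    (so the membrane time constant C/g comes out in ms).
    """

    c_m: float = Field(60.0, gt=0)
    g_leak: float = Field(2.8, ge=0)
    e_leak: float = -68.0
    g_nap: float = Field(10.0, ge=0)
    e_na: float = 50.0
    e_inh: float = -80.0
    e_exc: float = 0.0
    m_half: float = -37.0
    m_slope: float = Field(6.0, gt=0)
    h_half: float = -48.0
    h_slope: float = Field(6.0, gt=0)
    tau_h_max_ms: float = Field(2400.0, gt=0)
    #: slow-variable time constant of the flexor-side CPG cell C5 (sets the
    #: flexion-burst duration); None means same as the levator-depressor pair
    tau_h_max_ef_ms: Optional[float] = Field(550.0, gt=0)
    #: slow-variable time constant of the extensor-side cell C6 (sets how long
    #: its unaided reign lasts); None means same as C5
    tau_h_max_c6_ms: Optional[float] = Field(None, gt=0)
    #: de-inactivation (recovery) of the flexor-burst cell C5 is slowed by
    #: this factor relative to its inactivation, making the flexion burst a
    #: one-shot per release (no re-burst while the femur gate stays low)
    c5_h_recovery_scale: float = Field(2.5, ge=1.0)
    #: half-voltage / slope of the sigmoid mapping V to the cell's [0,1] output
    #: (also used as the presynaptic release variable of the mutual inhibition)
    out_half: float = -43.0
    out_slope: float = Field(2.0, gt=0)


class GradedUnitConfig(_Section):
    """First-order interneuron / motoneuron units with sigmoidal I/O."""

    tau_in_ms: float = Field(10.0, gt=0)
    tau_mn_ms: float = Field(5.0, gt=0)
    act_half: float = 0.55
    act_slope: float = Field(0.07, gt=0)


class CentralDrivesConfig(_Section):
    """Constant central inputs: CPG drives, premotor-IN inhibition, MN drive."""

    g_mn: float = Field(1.2, ge=0)
    g_app3: float = Field(0.0, ge=0)
    g_app4: float = Field(0.0, ge=0)
    g_app5: float = Field(0.30, ge=0)
    g_app6: float = Field(0.60, ge=0)
    g_d7: float = Field(0.0, ge=0)
    g_d8: float = Field(0.0, ge=0)
    g_d9: float = Field(0.0, ge=0)
    g_d10: float = Field(0.0, ge=0)
    g_d13: float = Field(0.0, ge=0)
    g_d14: float = Field(0.0, ge=0)
    g_d15: float = Field(0.0, ge=0)
    g_d16: float = Field(0.0, ge=0)


class SynapticWeightsConfig(_Section):
    """Maximal conductances / weights of the wired synapse classes."""

    cpg_mutual_ld: float = Field(6.0, ge=0)
    cpg_mutual_ef: float = Field(6.0, ge=0)
    cpg_to_in: float = Field(1.5, ge=0)
    in_to_mn: float = Field(1.5, ge=0)
    in12_to_cpg: float = Field(0.50, ge=0)
    in18_to_c6: float = Field(2.60, ge=0)
    in11_to_cpg: float = Field(0.30, ge=0)
    in17_to_cpg: float = Field(0.30, ge=0)


class ExtraSynapseConfig(_Section):
    """An additional synapse beyond the canonical wiring (labels validated
    against the known unit set when the network is built)."""

    source: str
    target: str
    sign: str = Field(pattern="^(excitatory|inhibitory)$")
    conductance: float = Field(ge=0)


class NetworkConfig(_Section):
    cell: CpgCellConfig = CpgCellConfig()
    unit: GradedUnitConfig = GradedUnitConfig()
    drives: CentralDrivesConfig = CentralDrivesConfig()
    weights: SynapticWeightsConfig = SynapticWeightsConfig()
    extra_synapses: list[ExtraSynapseConfig] = []
    #: mV offset added to the C3 initial voltage so the half-centers leave the
    #: symmetric state deterministically (no RNG anywhere in the core model)
    c3_init_offset_mv: float = 1.0
    v_init_mv: float = -60.0


class MuscleConfig(_Section):
    """One muscle group (pool of fibres driven by one MN or MN pool).

    ``gain_per_ms`` is the angular stiffness of the fully active muscle in
    the overdamped joint equation (deg/ms of drive per deg of displacement
    from ``rest_angle_deg``); ``passive_per_ms`` is the residual stiffness
    that holds posture when the MNs fall silent.
    """

    rest_angle_deg: float
    gain_per_ms: float = Field(ge=0)
    passive_per_ms: float = Field(5e-5, ge=0)
    tau_act_ms: float = Field(gt=0)
    n_units: int = Field(1, ge=1)


class MusculoskeletalConfig(_Section):
    femur_mm: float = Field(13.0, gt=0)
    tibia_mm: float = Field(12.0, gt=0)
    beta_init_deg: float = 10.0
    gamma_init_deg: float = 150.0
    #: recruit the fast levator/depressor pools in n_units discrete steps
    #: instead of a continuous ramp
    quantized_recruitment: bool = False
    levator_fast: MuscleConfig = MuscleConfig(
        rest_angle_deg=35.0, gain_per_ms=9e-3, tau_act_ms=40.0, n_units=5)
    levator_slow: MuscleConfig = MuscleConfig(
        rest_angle_deg=35.0, gain_per_ms=3e-3, tau_act_ms=100.0)
    depressor_fast: MuscleConfig = MuscleConfig(
        rest_angle_deg=-8.0, gain_per_ms=6.5e-3, tau_act_ms=40.0, n_units=5)
    depressor_slow: MuscleConfig = MuscleConfig(
        rest_angle_deg=-8.0, gain_per_ms=5e-4, tau_act_ms=100.0)
    extensor_fast: MuscleConfig = MuscleConfig(
        rest_angle_deg=176.0, gain_per_ms=1e-3, tau_act_ms=40.0)
    extensor_slow: MuscleConfig = MuscleConfig(
        rest_angle_deg=176.0, gain_per_ms=6e-3, tau_act_ms=250.0)
    flexor_fast: MuscleConfig = MuscleConfig(
        rest_angle_deg=82.0, gain_per_ms=7e-3, tau_act_ms=25.0)
    flexor_slow: MuscleConfig = MuscleConfig(
        rest_angle_deg=82.0, gain_per_ms=1e-3, tau_act_ms=100.0)

    @model_validator(mode="after")
    def _single_extensor_mn(self) -> "MusculoskeletalConfig":
        # there is a single slow and a single fast extensor (and flexor) MN,
        # so no recruitment is possible at the femur-tibia joint
        for name in ("extensor_fast", "extensor_slow",
                     "flexor_fast", "flexor_slow",
                     "levator_slow", "depressor_slow"):
            if getattr(self, name).n_units != 1:
                raise ValueError(f"{name} must have n_units = 1")
        return self

    def muscle(self, name: str) -> MuscleConfig:
        if name not in MUSCLE_ORDER:
            raise ConfigurationError(f"unknown muscle {name!r}")
        return getattr(self, name)


#: canonical muscle ordering used by the engine state vector; the first four
#: act on the CTr joint (beta), the last four on the FTi joint (gamma)
MUSCLE_ORDER = (
    "levator_fast", "levator_slow", "depressor_fast", "depressor_slow",
    "extensor_fast", "extensor_slow", "flexor_fast", "flexor_slow",
)


class GatingConfig(_Section):
    """Two-valued sensory coupling conductances and their angle thresholds."""

    beta_thr_deg: float = 16.0
    gamma_thr_deg: float = 145.0
    g_beta_high: float = Field(1.0, ge=0)
    g_beta_low: float = Field(0.05, ge=0)
    g_gamma_high: float = Field(1.0, ge=0)
    g_gamma_low: float = Field(0.05, ge=0)
    #: polarity: conductance takes its high value when the angle is at or
    #: above threshold.  The gamma polarity is fixed by the tonic regime of
    #: the model; whether beta uses the same polarity is an open point and
    #: therefore a switch.
    beta_high_above: bool = True
    gamma_high_above: bool = True
    #: optional first-order sensory filter; 0 disables (gate acts on the
    #: instantaneous angle every integration step)
    sensory_tau_ms: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _high_ge_low(self) -> "GatingConfig":
        if self.g_beta_high < self.g_beta_low:
            raise ValueError("g_beta_high must be >= g_beta_low")
        if self.g_gamma_high < self.g_gamma_low:
            raise ValueError("g_gamma_high must be >= g_gamma_low")
        return self


class RampConfig(_Section):
    """Endpoints of one linear obstacle-position -> recruitment-factor map.

    The two published interpolation-function sets are drawn as lines in a
    figure without printed endpoint values; these defaults are figure-derived
    placeholders (set A steeper than set B, depressor above levator) and are
    meant to be overridden when better estimates exist.
    """

    rf0: float = Field(ge=1.0)
    po0_deg: float
    rf1: float = Field(ge=1.0)
    po1_deg: float

    @model_validator(mode="after")
    def _distinct(self) -> "RampConfig":
        if self.po0_deg == self.po1_deg:
            raise ValueError("ramp endpoints must have distinct PO values")
        return self


class InterpolationSetConfig(_Section):
    levator: RampConfig
    depressor: RampConfig


class ProtocolConfig(_Section):
    contact_duration_ms: float = Field(100.0, gt=0, le=100.0)
    slow_ramp_ms: float = Field(200.0, gt=0, le=200.0)
    fast_ef_delay_ms: float = Field(0.0, ge=0)
    #: time to full fast levator/depressor recruitment at rf = 1
    base_duration_ms: float = Field(500.0, gt=0)
    #: contact detection is armed only after this much simulated time, so the
    #: pre-contact rhythm is established (>= 3 cycles at the default period)
    t_arm_ms: float = Field(5000.0, ge=0)
    #: maximum additional time allowed for the armed obstacle to be hit
    contact_wait_ms: float = Field(4000.0, gt=0)
    post_removal_ms: float = Field(6000.0, gt=0)
    set_a: InterpolationSetConfig = InterpolationSetConfig(
        levator=RampConfig(rf0=1.0, po0_deg=-40.0, rf1=2.5, po1_deg=25.0),
        depressor=RampConfig(rf0=1.2, po0_deg=-40.0, rf1=3.0, po1_deg=25.0),
    )
    set_b: InterpolationSetConfig = InterpolationSetConfig(
        levator=RampConfig(rf0=1.0, po0_deg=-40.0, rf1=1.5, po1_deg=25.0),
        depressor=RampConfig(rf0=1.0, po0_deg=-40.0, rf1=2.0, po1_deg=25.0),
    )
    #: beta_thr at or below this uses interpolation set A, above it set B
    #: (the published rule states A for beta_thr <= 6 deg and B for > 10 deg;
    #: the gap is closed at 10 deg)
    set_a_max_beta_thr_deg: float = 10.0


class AnalysisConfig(_Section):
    cessation_floor_deg: float = Field(2.0, gt=0)
    cessation_min_ms: float = Field(500.0, gt=0)
    cessation_window_ms: float = Field(800.0, gt=0)
    #: vertex-pruning tolerance as a fraction of the loop bounding-box diagonal
    rdp_tol_frac: float = Field(0.05, gt=0)
    #: smoothing window for peak detection, as a fraction of the cycle period
    smooth_frac: float = Field(0.05, ge=0)
    alternation_rel_diff: float = Field(0.10, gt=0)
    alternation_min_pairs: int = Field(4, ge=2)


#: the six canonical (gamma_thr, beta_thr) pairs used throughout
PRESETS: dict[str, tuple[float, float]] = {
    "tonic_bm4": (83.0, -4.0),
    "tonic_b4": (83.0, 4.0),
    "tonic_b16": (83.0, 16.0),
    "switch_bm4": (145.0, -4.0),
    "switch_b4": (145.0, 4.0),
    "switch_b16": (145.0, 16.0),
}


class RunConfig(_Section):
    """Top-level configuration; ``preset`` (if set) fixes the two thresholds."""

    preset: Optional[str] = None
    seed: Optional[int] = None  # only noisy synthetic fixtures consume this
    integration: IntegrationConfig = IntegrationConfig()
    network: NetworkConfig = NetworkConfig()
    musculoskeletal: MusculoskeletalConfig = MusculoskeletalConfig()
    gating: GatingConfig = GatingConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @model_validator(mode="after")
    def _apply_preset(self) -> "RunConfig":
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ValueError(
                    f"unknown preset {self.preset!r}; known: {sorted(PRESETS)}")
            gthr, bthr = PRESETS[self.preset]
            # bypass validate_assignment recursion via direct __dict__ write
            self.gating.__dict__["gamma_thr_deg"] = gthr
            self.gating.__dict__["beta_thr_deg"] = bthr
        return self

    def config_hash(self) -> str:
        """Short stable hash of the full parameter set."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def default_config(preset: Optional[str] = None) -> RunConfig:
    return RunConfig(preset=preset)


def load_config(path) -> RunConfig:
    """Read a YAML config file; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(str(exc)) from exc


def dump_config(config: RunConfig, path=None) -> str:
    """Serialize to YAML; round-trips losslessly through :func:`load_config`."""
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
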