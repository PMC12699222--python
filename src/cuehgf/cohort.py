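"""Synthetic cohort generator: two groups of simulated subjects with HGF-driven
behaviour, forward-modelled ERP epochs, and clinical scores.

Every subject performs the same canonical 284-trial cue-predictability
sequence.  Behaviour comes from the generative HGF response model
(:func:`cuehgf.hgf.simulate_agent`); the "TS-like" group defaults to
attenuated response-model slopes (smaller |zeta2|), which removes most of the
validity x predictability RT interaction while leaving the basic cue-validity
effect intact.

ERP epochs are produced by a deliberately minimal forward model — the study
this emulates reports effect directions, not a generative EEG model:

* P3a: Gaussian kernel peaking frontal-centrally (FCz) at 358 ms; its
  single-trial amplitude is linear in validity, predicted cue validity
  (belief) and their product.
* P3b: sigmoid-rise-then-decay kernel peaking centro-parietally (CPz); its
  amplitude is linear in the same regressors and its onset shifts with
  validity and validity x belief, so onset effects express in the 200-300 ms
  window and amplitude effects in the 400-600 ms window.
* Noise: white Gaussian per channel/sample (optional 1/f spectral shaping).

Group differences are injected at the coefficient level: control-like
subjects carry a negative P3b-amplitude belief coefficient (amplitude falls
as cue predictability rises), TS-like subjects carry zero.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design
from .hgf import (
    BeliefTrajectory,
    LapseConfig,
    PerceptualParams,
    ResponseParams,
    hgf_filter,
    simulate_agent,
)

__all__ = [
    "ComponentSpec",
    "ErpForwardModel",
    "EpochArray",
    "GroupSpec",
    "CohortConfig",
    "Subject",
    "generate_epochs",
    "generate_cohort",
    "default_cohort_config",
    "CHANNELS",
]

CHANNELS = ("Fz", "FCz", "Cz", "CPz", "Pz")

#: Clinical instruments simulated per subject.
CLINICAL_SCALES = ("ygtss_global", "ygtss_tic", "puts", "bdi_ii", "wurs_k", "oci_r")


@dataclass(frozen=True)
class EpochArray:
    """Target-locked epochs: trials x channels x time voltages in microvolt."""

    data: np.ndarray
    srate_hz: float = 500.0
    t0_ms: float = -200.0
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.t0_ms + 1000.0 * np.arange(n) / self.srate_hz

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name) if isinstance(
                self.channel_names, list) else list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None


def epoch_times(srate_hz: float, t0_ms: float = -200.0, t1_ms: float = 800.0) -> np.ndarray:
    """Sample times for a −200..800 ms target-locked epoch (endpoint included)."""
    n = int(round((t1_ms - t0_ms) / 1000.0 * srate_hz)) + 1
    return t0_ms + 1000.0 * np.arange(n) / srate_hz


@dataclass
class ComponentSpec:
    """One ERP component of the forward model.

    ``amp`` holds (intercept, validity, belief, interaction) coefficients in
    microvolt, applied with 0/1 validity coding; the regression stage's
    ±0.5 coding is an invertible linear reparameterization of the same model.
    """

    kind: str  # "gaussian" | "sigmoid_rise"
    latency_ms: float
    width_ms: float
    channel_weights: tuple[float, ...]
    amp: tuple[float, float, float, float]
    # sigmoid_rise only: latency shift (ms) per validity / validity*belief unit
    onset_shift: tuple[float, float] = (0.0, 0.0)
    # sigmoid_rise only: Gaussian decay envelope
    envelope_center_ms: float = 500.0
    envelope_width_ms: float = 180.0

    def kernel(self, times_ms: np.ndarray, validity: float, belief: float) -> np.ndarray:
        if self.width_ms <= 0:
            raise ValueError("component width must be positive")
        if self.kind == "gaussian":
            return np.exp(-0.5 * ((times_ms - self.latency_ms) / self.width_ms) ** 2)
        if self.kind == "sigmoid_rise":
            onset = (self.latency_ms
                     + self.onset_shift[0] * validity
                     + self.onset_shift[1] * validity * belief)
            rise = 1.0 / (1.0 + np.exp(-(times_ms - onset) / self.width_ms))
            envelope = np.exp(
                -0.5 * ((times_ms - self.envelope_center_ms) / self.envelope_width_ms) ** 2
            )
            return rise * envelope
        raise ValueError(f"unknown kernel kind {self.kind!r}")

    def amplitude(self, validity: float, belief: float) -> float:
        a0, a_v, a_p, a_int = self.amp
        return a0 + a_v * validity + a_p * belief + a_int * validity * belief


def _default_p3a(a_v: float = -1.5, a_p: float = 2.0) -> ComponentSpec:
    return ComponentSpec(
        kind="gaussian",
        latency_ms=358.0,
        width_ms=45.0,
        channel_weights=(0.6, 1.0, 0.7, 0.3, 0.1),  # peaks at FCz
        amp=(4.0, a_v, a_p, 0.0),
    )


def _default_p3b(a_p: float = -2.0) -> ComponentSpec:
    return ComponentSpec(
        kind="sigmoid_rise",
        latency_ms=270.0,
        width_ms=25.0,
        channel_weights=(0.1, 0.3, 0.7, 1.0, 0.8),  # peaks at CPz
        amp=(5.0, -2.0, a_p, 0.0),
        onset_shift=(-20.0, -30.0),  # valid earlier, more so when expected
    )


@dataclass
class ErpForwardModel:
    p3a: ComponentSpec = field(default_factory=_default_p3a)
    p3b: ComponentSpec = field(default_factory=_default_p3b)
    noise_sd: float = 15.0  # microvolt per channel/sample
    pink_noise: bool = False
    srate_hz: float = 500.0
    t0_ms: float = -200.0
    t1_ms: float = 800.0
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def components(self) -> tuple[ComponentSpec, ...]:
        return (self.p3a, self.p3b)


def _pink(shape: tuple[int, ...], rng: np.random.Generator, sd: float) -> np.ndarray:
    """Approximately 1/f-shaped Gaussian noise along the last axis, unit-free
    rescaled to the requested per-sample sd."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    f[0] = f[1] if len(f) > 1 else 1.0
    spec /= np.sqrt(f)
    shaped = np.fft.irfft(spec, n=shape[-1], axis=-1)
    shaped *= sd / shaped.std()
    return shaped


def generate_epochs(
    behavior: pd.DataFrame,
    traj: BeliefTrajectory,
    fwd: ErpForwardModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> EpochArray:
    """Forward-model single-trial epochs from behaviour and belief trajectory.

    epoch(t, c, tau) = sum over components of
    kernel(tau; latency(t)) * amplitude(t) * channel_weight(c) + noise.
    Deterministic per seed.
    """
    fwd = fwd or ErpForwardModel()
    if len(behavior) != len(traj):
        raise ValueError("behavior and trajectory lengths differ")
    validity = behavior["validity"].to_numpy(dtype=float)
    belief = np.asarray(traj.muhat1, dtype=float)
    times = epoch_times(fwd.srate_hz, fwd.t0_ms, fwd.t1_ms)
    n_trials, n_ch, n_t = len(validity), len(fwd.channel_names), len(times)

    rng = np.random.default_rng(seed)
    if fwd.pink_noise:
        data = _pink((n_trials, n_ch, n_t), rng, fwd.noise_sd)
    else:
        data = fwd.noise_sd * rng.standard_normal((n_trials, n_ch, n_t))

    for comp in fwd.components:
        weights = np.asarray(comp.channel_weights, dtype=float)
        if len(weights) != n_ch:
            raise ValueError("channel_weights do not match channel count")
        for t in range(n_trials):
            k = comp.kernel(times, validity[t], belief[t])
            a = comp.amplitude(validity[t], belief[t])
            data[t] += a * weights[:, None] * k[None, :]

    return EpochArray(data=data, srate_hz=fwd.srate_hz, t0_ms=fwd.t0_ms,
                      channel_names=tuple(fwd.channel_names))


# -- cohort -----------------------------------------------------------------

#: Table-style clinical score (mean, sd) defaults per group; scores are
#: truncated at 0 after the Gaussian draw.
_TS_SCORES = {
    "ygtss_global": (45.5, 20.0), "ygtss_tic": (22.3, 8.7), "puts": (37.8, 10.8),
    "bdi_ii": (13.3, 11.8), "wurs_k": (25.6, 14.5), "oci_r": (20.4, 15.2),
}
_CONTROL_SCORES = {
    "ygtss_global": (0.0, 1e-6), "ygtss_tic": (0.0, 1e-6), "puts": (0.0, 1e-6),
    "bdi_ii": (3.2, 3.2), "wurs_k": (12.2, 10.7), "oci_r": (9.6, 7.2),
}


@dataclass
class GroupSpec:
    """Sampling distributions (Gaussian mean/sd) for one group's parameters."""

    label: str
    # perceptual
    omega2: tuple[float, float] = (-3.0, 0.8)
    omega3: tuple[float, float] = (-6.0, 0.5)
    # response model (RS scale, 1/s)
    zeta1v: tuple[float, float] = (2.4, 0.2)
    zeta2v: tuple[float, float] = (1.0, 0.3)
    zeta1i: tuple[float, float] = (2.4, 0.2)
    zeta2i: tuple[float, float] = (0.8, 0.3)
    noise_sd: float = 0.35
    lapse: LapseConfig = field(default_factory=LapseConfig)
    erp: ErpForwardModel = field(default_factory=ErpForwardModel)
    clinical: dict[str, tuple[float, float]] = field(default_factory=dict)


def default_groups() -> tuple[GroupSpec, GroupSpec]:
    control = GroupSpec(label="control", clinical=dict(_CONTROL_SCORES))
    ts = GroupSpec(
        label="ts",
        zeta1v=(2.2, 0.2), zeta2v=(0.4, 0.3),
        zeta1i=(2.2, 0.2), zeta2i=(0.3, 0.3),
        erp=ErpForwardModel(p3a=_default_p3a(a_v=-0.3), p3b=_default_p3b(a_p=0.0)),
        clinical=dict(_TS_SCORES),
    )
    return control, ts


@dataclass
class CohortConfig:
    n_per_group: int = 30
    groups: tuple[GroupSpec, GroupSpec] = field(default_factory=default_groups)
    master_seed: int = 0
    sequence_seed: int = design.CANONICAL_SEED
    blocks: tuple = design.CANONICAL_BLOCKS

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for g in self.groups:
            for scale, (_, sd) in g.clinical.items():
                if sd <= 0:
                    raise ValueError(f"clinical sd must be > 0 ({g.label}/{scale})")


def default_cohort_config(n_per_group: int = 30, master_seed: int = 0) -> CohortConfig:
    return CohortConfig(n_per_group=n_per_group, master_seed=master_seed)


@dataclass
class Subject:
    subject_id: str
    group: str
    sequence: pd.DataFrame
    behavior: pd.DataFrame
    true_pparams: PerceptualParams
    true_rparams: ResponseParams
    trajectory: BeliefTrajectory
    clinical: dict[str, float]


def _draw_params(
    spec: GroupSpec, rng: np.random.Generator, u: np.ndarray | None = None
) -> tuple[PerceptualParams, ResponseParams]:
    """Draw one subject's parameters; draws whose filter diverges on the
    task sequence are rejected and redrawn (a simulated participant must
    hold finite beliefs throughout)."""

    def g(ms: tuple[float, float]) -> float:
        return float(rng.normal(*ms))

    from .hgf import ModelDivergence

    for _ in range(100):
        pp = PerceptualParams(omega2=g(spec.omega2), omega3=g(spec.omega3))
        if u is not None:
            try:
                hgf_filter(u, pp)
            except ModelDivergence:
                continue
        break
    else:
        raise RuntimeError("could not draw stable perceptual parameters")
    rp = ResponseParams(
        zeta1v=g(spec.zeta1v), zeta2v=g(spec.zeta2v),
        zeta1i=g(spec.zeta1i), zeta2i=g(spec.zeta2i),
        noise_var=spec.noise_sd ** 2,
    )
    return pp, rp


def generate_cohort(config: CohortConfig | None = None) -> list[Subject]:
    """Simulate the full two-group cohort (behaviour only; epochs are generated
    per subject on demand via :func:`generate_epochs`).

    All subjects share the canonical trial sequence.  Deterministic per
    ``config.master_seed``.
    """
    config = config or CohortConfig()
    sequence = design.assign_timing(
        design.generate_trial_sequence(config.blocks, seed=config.sequence_seed),
        seed=config.sequence_seed,
    )
    u = sequence["validity"].to_numpy()

    root = np.random.SeedSequence(config.master_seed)
    subjects: list[Subject] = []
    for gi, spec in enumerate(config.groups):
        group_ss = root.spawn(len(config.groups))[gi]
        children = group_ss.spawn(config.n_per_group)
        for si in range(config.n_per_group):
            param_ss, behav_ss = children[si].spawn(2)
            rng = np.random.default_rng(param_ss)
            pp, rp = _draw_params(spec, rng, u)
            behavior = simulate_agent(sequence, pp, rp, spec.lapse, seed=behav_ss)
            clinical = {
                scale: float(max(0.0, rng.normal(mean, sd)))
                for scale, (mean, sd) in spec.clinical.items()
            }
            subjects.append(
                Subject(
                    subject_id=f"{spec.label}_{si + 1:02d}",
                    group=spec.label,
                    sequence=sequence,
                    behavior=behavior,
                    true_pparams=pp,
                    true_rparams=rp,
                    trajectory=hgf_filter(u, pp),
                    clinical=clinical,
                )
            )
    return subjects


def epoch_seed_for(config: CohortConfig, subject_index: int) -> np.random.SeedSequence:
    """Reproducible epoch-noise seed for the subject at ``subject_index`` in
    the order returned by :func:`generate_cohort`."""
    return np.random.SeedSequence(config.master_seed, spawn_key=(999, subject_index))


def null_cohort_config(n_per_group: int = 30, master_seed: int = 0) -> CohortConfig:
    """Config with identical group distributions and all ERP effect
    coefficients zero — for type-I-error checks."""
    flat_erp = ErpForwardModel(
        p3a=ComponentSpec("gaussian", 358.0, 45.0, (0.6, 1.0, 0.7, 0.3, 0.1),
                          (0.0, 0.0, 0.0, 0.0)),
        p3b=ComponentSpec("sigmoid_rise", 270.0, 25.0, (0.1, 0.3, 0.7, 1.0, 0.8),
                          (0.0, 0.0, 0.0, 0.0), onset_shift=(0.0, 0.0)),
    )
    control = GroupSpec(label="control", erp=copy.deepcopy(flat_erp),
                        clinical=dict(_CONTROL_SCORES))
    other = GroupSpec(label="ts", erp=copy.deepcopy(flat_erp),
                      clinical=dict(_CONTROL_SCORES))
    return CohortConfig(n_per_group=n_per_group, groups=(control, other),
                        master_seed=master_seed)
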