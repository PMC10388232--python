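"""Synthetic vertical ground-reaction-force (GRF) generator.

During healthy stance the vertical GRF traces the characteristic
two-peak "M" curve: heel strike, a loading-response peak (~1.15 BW at
~25% of stance), a mid-stance valley (~0.75 BW at ~50%), a push-off peak
(~1.10 BW at ~75%) and toe-off.  Impaired gait attenuates the middle
three phases — loading response, mid-stance and push-off — while heel
strike and toe-off are usually preserved.

The generator produces such curves analytically (a superposition of
Gaussian bumps pinned to the three phase control points, with fast
smoothstep ramps at heel strike and toe-off), assembles multi-step
walking trials with baseline rest between contacts, and emulates the
acquisition chain of a typical laboratory force plate: additive Gaussian
sensor noise, quantization to the plate's 0.3 N resolution, and
saturation at 3500 N in compression / −900 N in tension.

This is a phenomenological stand-in for real recordings, not a
biomechanical model; it exists so the full pipeline can be exercised and
validated with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import ForceSignal

__all__ = [
    "GaitProfileParams",
    "ImpairmentProfile",
    "SyntheticTrial",
    "healthy_step",
    "impaired_step",
    "synth_trial",
    "synth_subject_pair",
]


@dataclass
class GaitProfileParams:
    """Shape, timing and acquisition parameters of a synthetic stance.

    Amplitudes are in units of body weight (BW); time fractions are
    fractions of the stance duration.  ``quantization_step`` and the two
    clip limits model the force plate (0.3 N resolution, 3500 N
    compression / 900 N tension saturation); setting
    ``quantization_step=0`` disables quantization.
    """

    body_weight: float = 700.0  # newtons
    stance_duration: float = 1.0  # seconds
    sample_rate: float = 100.0  # Hz
    peak1_amp: float = 1.15  # BW, loading-response peak
    valley_amp: float = 0.75  # BW, mid-stance valley
    peak2_amp: float = 1.10  # BW, push-off peak
    peak1_time_frac: float = 0.25
    valley_time_frac: float = 0.50
    peak2_time_frac: float = 0.75
    phase_width_frac: float = 0.12
    edge_ramp_frac: float = 0.03  # heel-strike / toe-off ramp width
    impaired_plateau_amp: float = 0.85  # BW, flat support level of a fully impaired phase
    # sensor noise on the order of the plate's 0.3 N resolution:
    # 0.002 BW is ~1.4 N for a 700 N subject
    noise_sd: float = 0.002  # BW
    quantization_step: float = 0.3  # newtons
    clip_compression: float = 3500.0  # newtons
    clip_tension: float = -900.0  # newtons
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.peak1_time_frac < self.valley_time_frac < self.peak2_time_frac < 1):
            raise ValueError("phase time fractions must be ordered in (0, 1)")
        for name in ("body_weight", "stance_duration", "sample_rate",
                     "peak1_amp", "valley_amp", "peak2_amp", "phase_width_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_stance_samples(self) -> int:
        return int(round(self.stance_duration * self.sample_rate))

    def replace(self, **kw) -> "GaitProfileParams":
        return replace(self, **kw)


@dataclass
class ImpairmentProfile:
    """Phase-localized attenuation of the stance curve.

    Each attenuation is in [0, 1]: 0 leaves the phase healthy, 1
    flattens it fully toward a featureless weight-support plateau (the
    foot still bears weight, but the phase's dynamics are gone).  The
    deficit is localized to loading response, mid-stance and push-off;
    heel strike and toe-off are untouched.
    """

    loading_response_atten: float = 0.0
    mid_stance_atten: float = 0.0
    push_off_atten: float = 0.0

    def __post_init__(self):
        for name in ("loading_response_atten", "mid_stance_atten", "push_off_atten"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_severity(cls, severity: float) -> "ImpairmentProfile":
        """Apply one severity scalar to all three phases."""
        return cls(severity, severity, severity)

    @property
    def severity(self) -> float:
        return max(self.loading_response_atten, self.mid_stance_atten, self.push_off_atten)


@dataclass
class SyntheticTrial:
    """A simulated walking trial with its ground truth."""

    signal: ForceSignal
    true_step_windows: list[tuple[int, int]]
    params: GaitProfileParams
    impairment: ImpairmentProfile = field(default_factory=ImpairmentProfile)

    def __post_init__(self):
        n = self.signal.n_samples
        prev_end = 0
        for start, end in self.true_step_windows:
            if not (prev_end <= start < end <= n):
                raise ValueError("step windows must be disjoint, ordered and inside the signal")
            prev_end = end

    def ground_truth(self) -> dict:
        imp = self.impairment
        return {
            "seed": self.params.seed,
            "true_step_windows": [list(w) for w in self.true_step_windows],
            "loading_response_atten": imp.loading_response_atten,
            "mid_stance_atten": imp.mid_stance_atten,
            "push_off_atten": imp.push_off_atten,
        }


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _edge_taper(x: np.ndarray, ramp: float) -> np.ndarray:
    """1 in the interior, smoothstep ramps to exactly 0 at x=0 and x=1."""
    return _smoothstep(x / ramp) * _smoothstep((1.0 - x) / ramp)


def _stance_grid(params: GaitProfileParams) -> np.ndarray:
    return np.linspace(0.0, 1.0, params.n_stance_samples)


def _bumps(x: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x[:, None] - centers[None, :]) / width) ** 2)


def _shape_bw(params: GaitProfileParams) -> np.ndarray:
    """Noiseless stance shape in BW units on the stance grid.

    Three Gaussian bumps whose coefficients are solved so the curve
    passes exactly through (peak1_time_frac, peak1_amp),
    (valley_time_frac, valley_amp) and (peak2_time_frac, peak2_amp);
    the edge taper pins heel strike and toe-off to exactly zero.
    """
    centers = np.array(
        [params.peak1_time_frac, params.valley_time_frac, params.peak2_time_frac]
    )
    targets = np.array([params.peak1_amp, params.valley_amp, params.peak2_amp])
    G = np.exp(-0.5 * ((centers[:, None] - centers[None, :]) / params.phase_width_frac) ** 2)
    coeffs = np.linalg.solve(G, targets)
    x = _stance_grid(params)
    curve = _bumps(x, centers, params.phase_width_frac) @ coeffs
    return curve * _edge_taper(x, params.edge_ramp_frac)


def healthy_step(params: GaitProfileParams) -> np.ndarray:
    """Noiseless healthy stance curve in newtons.

    Length is ``round(stance_duration * sample_rate)``; the first and
    last samples are exactly zero and every sample scales linearly with
    body weight.
    """
    return params.body_weight * _shape_bw(params)


def impaired_step(params: GaitProfileParams, impairment: ImpairmentProfile) -> np.ndarray:
    """Stance curve with phase-localized attenuation of the gait dynamics.

    Around each attenuated phase center the healthy curve is blended
    (with smooth Gaussian localization) toward a flat weight-support
    plateau of ``impaired_plateau_amp`` body weights: the defective limb
    still carries load, but the peaks and valley that characterize
    loading response, mid-stance and push-off are flattened away.  An
    all-zero impairment reproduces :func:`healthy_step` exactly.
    """
    x = _stance_grid(params)
    centers = np.array(
        [params.peak1_time_frac, params.valley_time_frac, params.peak2_time_frac]
    )
    attens = np.array(
        [
            impairment.loading_response_atten,
            impairment.mid_stance_atten,
            impairment.push_off_atten,
        ]
    )
    blend = np.clip(_bumps(x, centers, params.phase_width_frac) @ attens, 0.0, 1.0)
    plateau = (
        params.body_weight * params.impaired_plateau_amp * _edge_taper(x, params.edge_ramp_frac)
    )
    return healthy_step(params) * (1.0 - blend) + plateau * blend


def _quantize_clip(force: np.ndarray, params: GaitProfileParams) -> np.ndarray:
    if params.quantization_step > 0:
        force = np.round(force / params.quantization_step) * params.quantization_step
    return np.clip(force, params.clip_tension, params.clip_compression)


def synth_trial(
    params: GaitProfileParams,
    impairment: ImpairmentProfile | None = None,
    n_steps: int = 10,
    inter_step_gap: float = 1.0,
    foot_label: str = "unknown",
    subject_id: str = "",
) -> SyntheticTrial:
    """Simulate a walking trial of ``n_steps`` contacts on one plate.

    Stance curves are separated (and flanked) by ``inter_step_gap``
    seconds of zero-force baseline.  Gaussian noise of standard
    deviation ``noise_sd * body_weight`` is added from the trial's
    seeded generator, then the acquisition chain quantizes to the
    plate's resolution and clips to its saturation limits.  The true
    contact windows are recorded as ground truth.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    impairment = impairment or ImpairmentProfile()
    step = impaired_step(params, impairment)
    n_step = len(step)
    n_gap = int(round(inter_step_gap * params.sample_rate))

    chunks, windows = [], []
    pos = 0
    for i in range(n_steps):
        chunks.append(np.zeros(n_gap))
        pos += n_gap
        chunks.append(step)
        windows.append((pos, pos + n_step))
        pos += n_step
    chunks.append(np.zeros(n_gap))
    pos += n_gap
    force = np.concatenate(chunks)

    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        force = force + rng.normal(0.0, params.noise_sd * params.body_weight, size=pos)
    force = _quantize_clip(force, params)

    signal = ForceSignal(
        time=np.arange(pos) / params.sample_rate,
        force=force,
        gap_mask=np.zeros(pos, dtype=bool),
        sample_rate=params.sample_rate,
        foot_label=foot_label,
        subject_id=subject_id,
    )
    return SyntheticTrial(signal, windows, params, impairment)


def synth_subject_pair(
    params: GaitProfileParams,
    severity_before: float,
    severity_after: float,
    n_steps: int = 10,
    seed: int = 0,
) -> tuple[SyntheticTrial, SyntheticTrial]:
    """Before/after rehabilitation trials for one subject.

    Both trials share the gait parameters but draw independent noise
    streams deterministically derived from ``seed``; the true severities
    are retained in each trial for parameter-recovery tests.
    """
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(2)
    ]
    before = synth_trial(
        params.replace(seed=child_seeds[0]),
        ImpairmentProfile.from_severity(severity_before),
        n_steps=n_steps,
    )
    after = synth_trial(
        params.replace(seed=child_seeds[1]),
        ImpairmentProfile.from_severity(severity_after),
        n_steps=n_steps,
    )
    return before, after
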