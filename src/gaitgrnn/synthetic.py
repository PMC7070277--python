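"""Synthetic multi-source gait recordings.

Generates seeded, physiologically shaped level-walking signals — sagittal
hip/knee/ankle joint angles, three thigh sEMG channels (rectus femoris,
biceps femoris, semitendinosus) and three plantar-pressure channels (big
toe, forefoot, heel) — all driven by a single latent gait-phase variable so
that every channel is mutually consistent cycle by cycle.

The generator is the test bed for the whole prediction pipeline: sEMG
carriers are band-limited to the 20–500 Hz band on top of a low-frequency
drift and a white noise floor (so the band-pass stage has real work to do),
pressure bumps are confined to stance with optional sparse spikes (so the
wavelet denoiser has real work to do), and muscle activation envelopes can
lead joint motion by a configurable electromechanical delay.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import signal as _signal

__all__ = [
    "GaitParameters",
    "GaitRecording",
    "joint_trajectories",
    "semg_channels",
    "pressure_channels",
    "generate_recording",
]

SEMG_CHANNEL_NAMES = ("rf", "bf", "st")
ANGLE_CHANNEL_NAMES = ("hip", "knee", "ankle")
PRESSURE_CHANNEL_NAMES = ("toe", "fore", "heel")


@dataclass(frozen=True)
class GaitParameters:
    """Parameters of the synthetic level-walking generator.

    Parameters
    ----------
    n_cycles : int
        Number of gait cycles to generate (>= 1).
    cycle_duration : float
        Duration of one gait cycle in seconds. Cadence is not standardized
        across subjects; 1.0 s/cycle is a typical comfortable walking pace.
    semg_rate : float
        sEMG sampling rate in Hz. 2000 Hz matches common acquisition
        hardware and leaves the full 20–500 Hz sEMG band below Nyquist.
    angle_rate : float
        Raw angle-channel sampling rate in Hz. Defaults to the sEMG clock so
        that 20-sample windowing of every channel lands on a shared 100 Hz
        feature clock.
    stance_fraction : float
        Fraction of the cycle spent in stance, in (0, 1). ~0.6 for normal
        gait.
    angle_noise_sd : float
        Gaussian measurement noise on the angle channels, degrees.
    semg_noise_floor : float
        Standard deviation of the white noise floor added to each sEMG
        channel (unitless amplitude).
    semg_drift_amp : float
        Amplitude of the slow (0.3 Hz) baseline drift added to each sEMG
        channel, emulating electrode/temperature drift.
    semg_burst_amp : float
        Peak amplitude of the muscle activation envelopes. Set to 0 to turn
        all activations off (noise-only channels).
    semg_amp_cv : float
        Cycle-to-cycle coefficient of variation of the burst amplitudes,
        emulating the stride-to-stride sEMG amplitude variability of real
        recordings. 0 gives identical bursts every cycle.
    semg_lead_s : float
        Electromechanical delay: activation envelopes lead the joint motion
        by this many seconds (typical physiological range 0.04–0.1 s).
    pressure_spike_prob : float
        Per-sample probability of a sparse positive pressure spike
        (sensor artifact).
    pressure_spike_amp : float
        Scale of the spike magnitudes (exponentially distributed).
    seed : int
        Seed for all random draws; identical parameters (including seed)
        produce bit-identical recordings.
    """

    n_cycles: int = 30
    cycle_duration: float = 1.0
    semg_rate: float = 2000.0
    angle_rate: float = 2000.0
    stance_fraction: float = 0.6
    angle_noise_sd: float = 0.5
    semg_noise_floor: float = 0.02
    semg_drift_amp: float = 0.01
    semg_burst_amp: float = 1.0
    semg_amp_cv: float = 0.25
    semg_lead_s: float = 0.06
    pressure_spike_prob: float = 0.002
    pressure_spike_amp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.semg_rate <= 0 or self.angle_rate <= 0:
            raise ValueError("sampling rates must be > 0")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError(
                f"stance_fraction must lie in (0, 1), got {self.stance_fraction}"
            )
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be > 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "GaitParameters":
        kwargs = {}
        for f in fields(cls):
            if f.name in d:
                raw = d[f.name]
                kwargs[f.name] = int(raw) if f.type == "int" else float(raw)
        return cls(**kwargs)


@dataclass
class GaitRecording:
    """A synchronized raw multi-channel gait record.

    ``semg``, ``pressure`` and ``phase`` live on the sEMG clock
    (``time_semg``); ``angles`` lives on the angle clock (``time_angle``).
    ``phase`` is the ground-truth gait-phase fraction in [0, 1) and exists
    only for synthetic data.
    """

    time_semg: np.ndarray
    semg: dict[str, np.ndarray]
    time_angle: np.ndarray
    angles: dict[str, np.ndarray]
    pressure: dict[str, np.ndarray]
    phase: np.ndarray
    params: GaitParameters | None = None

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        for name, t in (("time_semg", self.time_semg), ("time_angle", self.time_angle)):
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        n = self.time_semg.size
        for group, clock_n in ((self.semg, n), (self.pressure, n)):
            for ch, x in group.items():
                if x.size != clock_n:
                    raise ValueError(f"channel {ch!r} length {x.size} != clock {clock_n}")
        for ch, x in self.angles.items():
            if x.size != self.time_angle.size:
                raise ValueError(f"angle channel {ch!r} does not match its clock")
        if self.phase.size != n:
            raise ValueError("phase must be on the sEMG clock")
        if np.any((self.phase < 0) | (self.phase >= 1)):
            raise ValueError("phase must lie in [0, 1)")
        for ch, x in self.pressure.items():
            if np.any(x < 0):
                raise ValueError(f"pressure channel {ch!r} has negative values")

    def cycle_index(self) -> np.ndarray:
        """Integer gait-cycle id per sEMG sample, from phase wrap-arounds."""
        wraps = np.diff(self.phase) < 0
        return np.concatenate([[0], np.cumsum(wraps)])


def _check_phase(phase: np.ndarray) -> np.ndarray:
    phase = np.asarray(phase, dtype=float)
    if phase.size and (phase.min() < 0.0 or phase.max() >= 1.0):
        raise ValueError("gait phase must lie in [0, 1)")
    return phase


def _bump(phase: np.ndarray, center: float, amp: float, conc: float) -> np.ndarray:
    """Periodic C-infinity bump (von Mises shape), peak ``amp`` at ``center``."""
    return amp * np.exp(conc * (np.cos(2 * np.pi * (phase - center)) - 1.0))


def _cos_bump(phase: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    """Periodic raised-cosine-squared bump with compact support ``width``.

    Wider-tailed than the von Mises shape; C1 at the support edges.
    """
    delta = np.mod(phase - center + 0.5, 1.0) - 0.5
    inside = np.abs(delta) < width / 2.0
    out = np.zeros_like(np.asarray(phase, dtype=float))
    out[inside] = amp * np.cos(np.pi * delta[inside] / width) ** 2
    return out


def joint_trajectories(
    phase: np.ndarray, params: GaitParameters, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Sagittal hip/knee/ankle angle trajectories (degrees) at given phases.

    All three trajectories are smooth periodic functions of gait phase:

    * hip — sinusoid spanning about [-10, +30] deg, peak flexion at heel
      strike (phase 0);
    * knee — two non-negative flexion bumps: ~15 deg stance flexion near
      phase 0.15 and a wide ~60 deg swing-flexion bump peaking near phase
      0.73 (flexion already substantial at toe-off, as in normal gait);
    * ankle — dorsiflexion bump (~+15 deg) in mid/late stance and a
      plantarflexion dip (~-20 deg) near toe-off.

    Gaussian noise with sd ``params.angle_noise_sd`` is added when an
    ``rng`` is supplied (pass ``None`` for the noiseless trajectories).
    """
    phase = _check_phase(phase)
    hip = 10.0 + 20.0 * np.cos(2 * np.pi * phase)
    # Swing flexion rises already in pre-swing (substantial knee flexion at
    # toe-off), hence the wide raised-cosine rather than a narrow peak.
    knee = _bump(phase, 0.15, 15.0, 40.0) + _cos_bump(phase, 0.73, 0.45, 60.0)
    ankle = _bump(phase, 0.45, 15.0, 30.0) - _bump(phase, 0.65, 20.0, 30.0)
    out = {"hip": hip, "knee": knee, "ankle": ankle}
    if rng is not None and params.angle_noise_sd > 0:
        for ch in out:
            out[ch] = out[ch] + rng.normal(0.0, params.angle_noise_sd, size=phase.size)
    return out


# Activation envelope centers (gait-phase fraction) and concentrations.
# RF fires around terminal swing / loading response and again in pre-swing
# (its biphasic pattern in normal gait); the hamstrings (BF, ST) around
# late swing / early stance.
_ENVELOPES = {
    "rf": ((0.92, 1.0, 60.0), (0.05, 0.6, 80.0), (0.60, 0.5, 80.0)),
    "bf": ((0.85, 1.0, 50.0), (0.02, 0.5, 80.0)),
    "st": ((0.80, 0.9, 50.0), (0.98, 0.5, 80.0)),
}


def activation_envelopes(phase: np.ndarray, params: GaitParameters) -> dict[str, np.ndarray]:
    """Smooth per-muscle activation envelopes (unitless, >= 0).

    Envelopes are evaluated at ``phase + lead`` so that muscle activity
    leads the joint motion by ``params.semg_lead_s`` seconds.
    """
    phase = _check_phase(phase)
    lead = params.semg_lead_s / params.cycle_duration
    ph = np.mod(phase + lead, 1.0)
    out = {}
    for ch, bumps in _ENVELOPES.items():
        env = np.zeros_like(ph)
        for center, amp, conc in bumps:
            env = env + _bump(ph, center, amp, conc)
        out[ch] = params.semg_burst_amp * env
    return out


def _bandlimited_carrier(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-RMS noise carrier with power concentrated in 20–450 Hz."""
    white = rng.standard_normal(n)
    lo, hi = 20.0, min(450.0, 0.45 * rate)
    sos = _signal.butter(4, [lo, hi], btype="bandpass", output="sos", fs=rate)
    carrier = _signal.sosfilt(sos, white)
    carrier -= carrier.mean()
    rms = np.sqrt(np.mean(carrier**2))
    return carrier / rms if rms > 0 else carrier


def semg_channels(
    phase: np.ndarray, params: GaitParameters, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Three sEMG channels on the sEMG clock.

    Each channel is (activation envelope) x (band-limited 20–450 Hz noise
    carrier) + 0.3 Hz baseline drift + white noise floor. Drift and floor
    are deliberately outside/below the useful sEMG band so the band-pass
    filter stage is non-trivially exercised.

    Burst amplitudes are jittered per gait cycle with coefficient of
    variation ``params.semg_amp_cv``, emulating stride-to-stride
    variability of muscle activity.
    """
    phase = _check_phase(phase)
    n = phase.size
    env = activation_envelopes(phase, params)
    cycle = np.concatenate([[0], np.cumsum(np.diff(phase) < 0)]) if n else np.empty(0, int)
    n_cycles = int(cycle[-1]) + 1 if n else 0
    t = np.arange(n) / params.semg_rate
    out = {}
    for i, ch in enumerate(SEMG_CHANNEL_NAMES):
        carrier = _bandlimited_carrier(n, params.semg_rate, rng)
        amps = np.maximum(rng.normal(1.0, params.semg_amp_cv, size=n_cycles), 0.1)
        drift = params.semg_drift_amp * np.sin(2 * np.pi * 0.3 * t + i * 2.0)
        floor = rng.normal(0.0, params.semg_noise_floor, size=n)
        out[ch] = env[ch] * amps[cycle] * carrier + drift + floor
    return out


# Pressure bump supports as fractions of the stance interval [0, stance).
_PRESSURE_WINDOWS = {
    "heel": (0.00, 0.55, 1.0),
    "fore": (0.15, 0.90, 0.8),
    "toe": (0.45, 1.00, 0.9),
}


def pressure_channels(
    phase: np.ndarray, params: GaitParameters, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Three plantar-pressure channels (unitless force, >= 0).

    Smooth raised-cosine bumps with compact support inside stance (heel
    early, forefoot mid, big toe near toe-off); identically zero in swing.
    Sparse positive sensor spikes are injected with probability
    ``params.pressure_spike_prob`` per sample when an ``rng`` is given.
    """
    phase = _check_phase(phase)
    sf = params.stance_fraction
    u = phase / sf  # stance-relative position; >= 1 during swing
    out = {}
    spike_u = spike_mag = None
    if rng is not None:
        # Draw spike placement and magnitudes for all samples up front so
        # that spike_prob only gates which sites fire, never shifts the
        # stream consumed by other draws.
        spike_u = rng.uniform(size=phase.size)
        spike_mag = rng.exponential(params.pressure_spike_amp, size=phase.size)
    for ch, (lo, hi, amp) in _PRESSURE_WINDOWS.items():
        w = (u - lo) / (hi - lo)
        bump = np.where((w > 0) & (w < 1), np.sin(np.pi * np.clip(w, 0, 1)) ** 2, 0.0)
        x = amp * bump
        if rng is not None and params.pressure_spike_prob > 0:
            mask = spike_u < params.pressure_spike_prob
            x = x + mask * spike_mag
        out[ch] = x
    return out


def generate_recording(params: GaitParameters) -> GaitRecording:
    """Generate a full synthetic recording from one shared phase trajectory.

    All channels are deterministic functions of the common latent gait
    phase plus seeded noise, so angle extrema, sEMG bursts and pressure
    bumps keep a fixed relative phase across cycles.
    """
    duration = params.n_cycles * params.cycle_duration
    n_semg = int(round(duration * params.semg_rate))
    n_angle = int(round(duration * params.angle_rate))
    t_semg = np.arange(n_semg) / params.semg_rate
    t_angle = np.arange(n_angle) / params.angle_rate
    phase_semg = np.mod(t_semg / params.cycle_duration, 1.0)
    phase_angle = np.mod(t_angle / params.cycle_duration, 1.0)

    seq = np.random.SeedSequence(params.seed)
    rng_angle, rng_semg, rng_press = (np.random.default_rng(s) for s in seq.spawn(3))

    angles = joint_trajectories(phase_angle, params, rng=rng_angle)
    semg = semg_channels(phase_semg, params, rng_semg)
    pressure = pressure_channels(phase_semg, params, rng=rng_press)

    rec = GaitRecording(
        time_semg=t_semg,
        semg=semg,
        time_angle=t_angle,
        angles=angles,
        pressure=pressure,
        phase=phase_semg,
        params=params,
    )
    rec.validate()
    return rec
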