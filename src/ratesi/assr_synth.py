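"""Synthetic multi-subject ASSR (auditory steady-state response) datasets.

Each subject is a continuous 12-channel recording containing 120
click-train trials (1 s trains, inter-stimulus intervals drawn uniformly
from 2-4 s) built from three event-locked source components projected
through the lead field:

* an early thalamic component — a high-frequency (100-400 Hz) burst from
  a deep diencephalic dipole in the 5-9 ms window,
* a late slow wave — frontal dipoles with a Gaussian time course peaking
  near 350 ms,
* 43-Hz entrainment — bilateral temporal ("auditory") dipoles oscillating
  at the stimulus frequency from 400 ms to train end, with a 50 ms ramp,

plus per-channel 1/f + white background noise, lognormal between-subject
amplitude variability, and optionally injected broadband artifacts with a
ground-truth mask.  Everything is deterministic under the protocol seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import LeadField
from .recording import SensorRecording

__all__ = [
    "ComponentSpec",
    "ArtifactSpec",
    "AssrProtocol",
    "GroundTruth",
    "generate_assr_subject",
    "generate_assr_dataset",
    "inject_artifacts",
    "default_components",
]


@dataclass
class ComponentSpec:
    """One event-locked source component.

    ``seed_position`` (mm) is mapped to the nearest source-grid dipoles;
    ``amplitude`` is the dipole moment in A*m.
    """

    name: str
    seed_positions: list            # list of (x, y, z) mm
    amplitude: float                # A*m peak moment
    orientation: tuple = (0.0, 0.0, 1.0)
    #: SD (radians) of the independent per-trial, per-dipole phase jitter
    #: applied to oscillatory components.  Perfectly coherent bilateral
    #: sources are a degenerate beamformer case; real interhemispheric
    #: ASSR coherence is partial, emulated here by sigma = 1 rad
    #: (coherence ~ exp(-sigma^2) ~ 0.37).
    phase_jitter: float = 0.0


@dataclass
class ArtifactSpec:
    """Injected broadband artifact bursts (what the detector must catch)."""

    rate_per_min: float = 2.0
    duration: float = 0.4           # s
    amplitude_factor: float = 20.0  # burst RMS relative to background RMS
    band: tuple = (105.0, 135.0)    # Hz, covers the 110-130 Hz detector band


def default_components() -> list[ComponentSpec]:
    """Thalamic burst, frontal late wave, bilateral auditory entrainment.

    Amplitudes are set so the noiseless evoked deflections at the best
    electrode reach typical rat cortical-EEG scales: ~180 uV for the late
    slow wave, ~50 uV for the 43-Hz entrainment, ~30 uV for the early
    thalamic far-field component.
    """
    return [
        ComponentSpec("thalamic", [(0.0, -4.0, -3.5)], amplitude=1.5e-8),
        ComponentSpec("late", [(-1.5, 4.0, -2.0), (1.5, 4.0, -2.0)],
                      amplitude=6.0e-9),
        ComponentSpec("entrainment", [(-5.0, -3.0, -2.0), (5.0, -3.0, -2.0)],
                      amplitude=4.0e-9, phase_jitter=1.0),
    ]


@dataclass
class AssrProtocol:
    """ASSR experiment protocol (43-Hz click-train condition)."""

    n_subjects: int = 20
    n_trials: int = 120
    train_duration: float = 1.0     # s
    isi_range: tuple = (2.0, 4.0)   # s between trains
    stim_freq: float = 43.0         # Hz
    fs: float = 1000.0              # Hz
    components: list = field(default_factory=default_components)
    entrainment_onset: float = 0.400    # s after train start
    entrainment_ramp: float = 0.050     # s
    thalamic_window: tuple = (0.005, 0.009)     # s
    thalamic_freq: float = 250.0    # Hz centre of the 100-400 Hz burst
    late_peak: float = 0.350        # s
    late_width: float = 0.060       # s (Gaussian sigma)
    noise_white: float = 10e-6      # V RMS per channel
    noise_pink: float = 20e-6       # V RMS per channel, 1/f spectral slope
    amplitude_cv: float = 0.3       # between-subject lognormal CV
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.stim_freq, self.thalamic_freq):
            if f >= self.fs / 2:
                raise ValueError(f"component frequency {f} Hz >= Nyquist")


@dataclass
class GroundTruth:
    """Planted structure of one synthetic subject."""

    component_dipoles: dict         # name -> dipole index array
    component_templates: dict       # name -> per-trial time course (T,)
    events: np.ndarray              # (n_trials,) onset samples
    amplitude_scale: float          # subject's lognormal amplitude factor
    artifact_mask: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64))


def _component_templates(proto: AssrProtocol) -> dict:
    """Per-trial source time courses (train_duration long, at fs)."""
    T = int(round(proto.train_duration * proto.fs))
    t = np.arange(T) / proto.fs
    out = {}
    # Thalamic: Gabor burst centred in the 5-9 ms window.
    c = 0.5 * (proto.thalamic_window[0] + proto.thalamic_window[1])
    sig = (proto.thalamic_window[1] - proto.thalamic_window[0]) / 4
    out["thalamic"] = (np.exp(-0.5 * ((t - c) / sig) ** 2)
                       * np.sin(2 * np.pi * proto.thalamic_freq * (t - c)))
    # Late slow wave: Gaussian peak.
    out["late"] = np.exp(-0.5 * ((t - proto.late_peak) / proto.late_width) ** 2)
    # Entrainment: 43-Hz sinusoid from onset to train end with a ramp.
    env = np.clip((t - proto.entrainment_onset) / proto.entrainment_ramp, 0, 1)
    out["entrainment"] = env * np.sin(2 * np.pi * proto.stim_freq
                                      * (t - proto.entrainment_onset))
    return out


def _pink_noise(shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with 1/f power spectrum (slope -1) per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** -0.5
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _nearest_dipoles(lf: LeadField, positions: list) -> np.ndarray:
    g = lf.grid.positions
    return np.array([int(np.argmin(np.linalg.norm(g - np.asarray(p), axis=1)))
                     for p in positions])


def generate_assr_subject(lf: LeadField, proto: AssrProtocol,
                          subject: int) -> tuple[SensorRecording, GroundTruth]:
    """One subject's continuous recording with ground truth.

    Deterministic per (protocol seed, subject index).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(proto.seed, spawn_key=(int(subject),)))
    fs = proto.fs
    T_train = int(round(proto.train_duration * fs))
    pre = int(round(1.5 * fs))      # head room for the prestimulus epoch
    isis = rng.uniform(*proto.isi_range, size=proto.n_trials)
    onsets = np.empty(proto.n_trials, dtype=np.int64)
    s = pre
    for i in range(proto.n_trials):
        onsets[i] = s
        s += T_train + int(round(isis[i] * fs))
    n_samples = s + pre

    scale = float(rng.lognormal(mean=-0.5 * np.log(1 + proto.amplitude_cv ** 2),
                                sigma=np.sqrt(np.log(1 + proto.amplitude_cv ** 2))))
    templates = _component_templates(proto)
    N = lf.n_channels
    X = (proto.noise_white * rng.standard_normal((N, n_samples))
         + proto.noise_pink * _pink_noise((N, n_samples), rng))

    t_train = np.arange(T_train) / fs
    env = np.clip((t_train - proto.entrainment_onset)
                  / proto.entrainment_ramp, 0, 1)
    comp_dipoles = {}
    for comp in proto.components:
        dip = _nearest_dipoles(lf, comp.seed_positions)
        comp_dipoles[comp.name] = dip
        moment = np.asarray(comp.orientation, dtype=float)
        moment /= np.linalg.norm(moment)
        topos = lf.K[:, dip, :] @ moment            # (N, n_dip) footprints
        if comp.name == "entrainment" and comp.phase_jitter > 0:
            # Partially coherent oscillators: independent per-trial,
            # per-dipole phase jitter around the stimulus-locked phase.
            for i, on in enumerate(onsets):
                phases = comp.phase_jitter * rng.standard_normal(len(dip))
                for j in range(len(dip)):
                    wave = comp.amplitude * scale * env * np.sin(
                        2 * np.pi * proto.stim_freq
                        * (t_train - proto.entrainment_onset) + phases[j])
                    X[:, on:on + T_train] += np.outer(topos[:, j], wave)
        else:
            wave = comp.amplitude * scale * templates[comp.name]
            topo = topos.sum(axis=1)
            for on in onsets:
                X[:, on:on + T_train] += np.outer(topo, wave)

    events = np.column_stack([onsets, np.full(proto.n_trials, 43, dtype=np.int64)])
    rec = SensorRecording(data=X, fs=fs,
                          labels=[lf.montage.labels[i] for i in lf.montage.active],
                          events=events)
    gt = GroundTruth(component_dipoles=comp_dipoles,
                     component_templates=templates,
                     events=onsets, amplitude_scale=scale)
    return rec, gt


def generate_assr_dataset(lf: LeadField, proto: AssrProtocol | None = None
                          ) -> list[tuple[SensorRecording, GroundTruth]]:
    """All subjects' recordings (see :func:`generate_assr_subject` for a
    streaming alternative when memory matters)."""
    proto = proto or AssrProtocol()
    return [generate_assr_subject(lf, proto, s)
            for s in range(proto.n_subjects)]


def inject_artifacts(rec: SensorRecording, spec: ArtifactSpec,
                     rng: np.random.Generator | int | None = None
                     ) -> tuple[SensorRecording, np.ndarray]:
    """Add broadband high-amplitude bursts at known times.

    Returns the contaminated recording and the ground-truth mask as an
    (n_artifacts, 2) array of [start, end) sample intervals.
    """
    rng = np.random.default_rng(rng)
    out = rec.copy()
    n_art = int(round(spec.rate_per_min * rec.duration / 60.0))
    if n_art == 0:
        return out, np.empty((0, 2), dtype=np.int64)
    dur = int(round(spec.duration * rec.fs))
    background = rec.data.std()
    starts = np.sort(rng.integers(0, rec.n_samples - dur, size=n_art))
    lo, hi = spec.band
    t = np.arange(dur) / rec.fs
    win = np.hanning(dur)
    mask = []
    for s0 in starts:
        # Narrowband noise burst inside the detector band.
        carrier = np.zeros(dur)
        for f in np.linspace(lo, hi, 7):
            carrier += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        carrier *= win / carrier.std()
        burst = (spec.amplitude_factor * background
                 * np.outer(rng.uniform(0.5, 1.0, rec.n_channels), carrier))
        out.data[:, s0:s0 + dur] += burst
        mask.append((int(s0), int(s0 + dur)))
    return out, np.asarray(mask, dtype=np.int64)
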