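"""Seedable synthetic cohort generator for rPPG-vs-contact-PPG evaluation.

Real studies of camera-based pulse extraction record short face videos per
subject and activity together with a fingertip pulse oximeter as ground
truth. This module emulates that data structure without any video: a blood
volume pulse (BVP) waveform drives both a 60 Hz contact trace and the
pulsatile component of the three camera color channels, with per-channel
gains encoding the hemoglobin absorptivity premise (green strongest, then
blue, then red), plus illumination drift, sensor noise, and activity-
dependent motion-artifact bursts that are common-mode across channels.

Every output is a pure function of its parameters and seed, so cohorts are
byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigError, DataError
from .traces import CHANNELS, ContactTrace, RGBTrace

#: Activities emulated by the generator (mirrors the recording protocols of
#: public rPPG benchmarks: still sitting, talking, head rotation, head
#: translation, cycling on an ergometer).
ACTIVITIES = ("Resting", "Talking", "Rotation", "Translation", "Gym")

#: Motion-artifact burst rate per second, by activity. Resting is nearly
#: artifact-free; rotation and exercise are the most disturbed.
ACTIVITY_ARTIFACT_RATE = {
    "Resting": 0.02,
    "Talking": 0.10,
    "Translation": 0.15,
    "Rotation": 0.30,
    "Gym": 0.30,
}

#: Burst amplitude (intensity units, relative to a unit pulsatile gain),
#: scaled with the same activity ordering as the rates.
ACTIVITY_ARTIFACT_AMP = {
    "Resting": 0.5,
    "Talking": 1.5,
    "Translation": 2.0,
    "Rotation": 3.0,
    "Gym": 3.0,
}

#: Default pulsatile gains G : B : R = 1 : 0.6 : 0.35 — green carries the
#: strongest cardiac component, then blue, then red.
DEFAULT_GAINS = (0.35, 1.0, 0.6)  # (red, green, blue)

VALID_CAMERA_FPS = (25.0, 30.0)

HR_BPM_RANGE = (39.0, 240.0)


@dataclass
class BVPParams:
    """Parameters of the simulated blood volume pulse waveform.

    The waveform is a sum of a fundamental at the heart rate and two
    overtones, amplitude-modulated at a respiratory frequency. ``hr_bpm``
    is either a constant or a piecewise-linear profile given as
    ``(times_s, values_bpm)``.
    """

    hr_bpm: float | tuple = 72.0
    harmonic_amps: tuple = (1.0, 0.4, 0.2)
    resp_mod_depth: float = 0.1
    resp_freq_hz: float = 0.25
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if any(a < 0 for a in self.harmonic_amps):
            raise ConfigError("harmonic amplitudes must be non-negative")
        if not 0 <= self.resp_mod_depth <= 1:
            raise ConfigError("resp_mod_depth must be in [0, 1]")
        hr = self.hr_values()
        if hr.size == 0:
            raise ConfigError("empty heart-rate profile")
        if np.any(hr <= HR_BPM_RANGE[0]) or np.any(hr >= HR_BPM_RANGE[1]):
            raise ConfigError(
                f"hr_bpm must lie within {HR_BPM_RANGE} BPM, got {hr.min()}-{hr.max()}")

    def hr_values(self) -> np.ndarray:
        if np.isscalar(self.hr_bpm):
            return np.array([float(self.hr_bpm)])
        times, values = self.hr_bpm
        return np.asarray(values, dtype=float)

    def hr_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous heart rate (BPM) at times ``t`` (piecewise linear)."""
        if np.isscalar(self.hr_bpm):
            return np.full_like(t, float(self.hr_bpm))
        times, values = self.hr_bpm
        return np.interp(t, np.asarray(times, float), np.asarray(values, float))


@dataclass
class ChannelModel:
    """Additive model of one scene's camera color channels.

    Each channel is ``baseline + pulsatile_gain * bvp + drift + noise +
    artifacts``; the artifact bursts (timing and shape) are shared across
    channels because face motion displaces all channels together.
    """

    pulsatile_gain: tuple = DEFAULT_GAINS           # (red, green, blue)
    baseline: tuple = (120.0, 110.0, 100.0)
    drift_amp: float = 2.0
    drift_period_s: float = 30.0
    noise_sd: float = 0.2
    artifact_rate: float = ACTIVITY_ARTIFACT_RATE["Resting"]
    artifact_amp: float = ACTIVITY_ARTIFACT_AMP["Resting"]

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.pulsatile_gain):
            raise ConfigError("pulsatile gains must be non-negative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.artifact_rate < 0 or self.artifact_amp < 0:
            raise ConfigError("artifact rate/amplitude must be non-negative")

    @classmethod
    def for_activity(cls, activity: str, **overrides) -> "ChannelModel":
        """Default channel model with artifact statistics set by activity."""
        if activity not in ACTIVITIES:
            raise ConfigError(f"unknown activity {activity!r}; expected one of {ACTIVITIES}")
        kwargs = dict(artifact_rate=ACTIVITY_ARTIFACT_RATE[activity],
                      artifact_amp=ACTIVITY_ARTIFACT_AMP[activity])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class SceneSpec:
    """Identity and sampling setup of one simulated video."""

    subject_id: str
    activity: str = "Resting"
    camera_fps: float = 30.0
    cppg_fs: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ConfigError(f"unknown activity {self.activity!r}")
        if float(self.camera_fps) not in VALID_CAMERA_FPS:
            raise ConfigError(
                f"camera_fps must be one of {VALID_CAMERA_FPS}, got {self.camera_fps}")
        if self.cppg_fs <= 0:
            raise ConfigError("cppg_fs must be positive")


@dataclass
class Scene:
    """One simulated subject-activity recording with its ground truth."""

    spec: SceneSpec
    rgb: RGBTrace
    cppg: ContactTrace
    true_hr_bpm: float          # mean heart rate over the scene
    hr_profile: BVPParams = None


def generate_bvp(params: BVPParams, fs: float) -> np.ndarray:
    """Sample the BVP waveform at rate ``fs``.

    The instantaneous phase is the integral of the heart-rate profile, so
    the dominant spectral frequency tracks ``hr_bpm / 60`` by construction.
    Deterministic: no randomness enters the waveform itself.
    """
    if fs <= 0:
        raise ConfigError("fs must be positive")
    hr_max = params.hr_values().max()
    if fs <= 2 * hr_max / 60.0:
        raise ConfigError(f"fs={fs} violates Nyquist for HR {hr_max} BPM")
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    f_inst = params.hr_at(t) / 60.0
    phase = 2 * np.pi * cumulative_trapezoid(f_inst, t, initial=0.0)
    resp = 1.0 + params.resp_mod_depth * np.sin(2 * np.pi * params.resp_freq_hz * t)
    bvp = np.zeros(n)
    for h, amp in enumerate(params.harmonic_amps, start=1):
        bvp += amp * np.sin(h * phase)
    return resp * bvp


def generate_cppg(bvp: np.ndarray, fs: float = 60.0, noise_sd: float = 0.0,
                  seed: int | np.random.Generator = 0) -> ContactTrace:
    """Contact-PPG trace: the BVP waveform plus white sensor noise."""
    bvp = np.asarray(bvp, dtype=float)
    if bvp.size == 0:
        raise DataError("empty BVP waveform")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    samples = bvp + rng.normal(0.0, noise_sd, size=bvp.shape) if noise_sd > 0 else bvp.copy()
    return ContactTrace(samples=samples, fs=fs)


def draw_artifact_bursts(rng: np.random.Generator, rate_per_s: float,
                         duration_s: float) -> np.ndarray:
    """Poisson-timed motion-artifact onset times within [0, duration)."""
    count = rng.poisson(rate_per_s * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=count))


def _artifact_waveform(t: np.ndarray, onsets: np.ndarray, amps: np.ndarray,
                       tau_s: float = 0.5) -> np.ndarray:
    """Sum of exponentially decaying steps: step at onset, decay constant tau."""
    wave = np.zeros_like(t)
    for t0, a in zip(onsets, amps):
        mask = t >= t0
        wave[mask] += a * np.exp(-(t[mask] - t0) / tau_s)
    return wave


def generate_rgb_trace(bvp: np.ndarray, model: ChannelModel,
                       spec: SceneSpec) -> RGBTrace:
    """Camera color-channel traces for one scene.

    ``bvp`` must already be sampled at ``spec.camera_fps``. Drift and
    artifact bursts are common-mode (identical across channels); white
    noise is drawn independently per channel.
    """
    bvp = np.asarray(bvp, dtype=float)
    n = bvp.size
    t = np.arange(n) / spec.camera_fps
    rng = np.random.default_rng(spec.seed)
    drift_phase = rng.uniform(0, 2 * np.pi)
    drift = model.drift_amp * np.sin(2 * np.pi * t / model.drift_period_s + drift_phase)
    onsets = draw_artifact_bursts(rng, model.artifact_rate, n / spec.camera_fps)
    amps = model.artifact_amp * rng.uniform(0.5, 1.5, size=onsets.size) \
        * rng.choice([-1.0, 1.0], size=onsets.size)
    artifacts = _artifact_waveform(t, onsets, amps)
    channels = {}
    for i, name in enumerate(CHANNELS):
        noise = rng.normal(0.0, model.noise_sd, size=n) if model.noise_sd > 0 else 0.0
        channels[name] = (model.baseline[i] + model.pulsatile_gain[i] * bvp
                          + drift + artifacts + noise)
    return RGBTrace(red=channels["red"], green=channels["green"],
                    blue=channels["blue"], fs=spec.camera_fps,
                    meta={"artifact_onsets_s": onsets.tolist(),
                          "n_artifacts": int(onsets.size)})


def generate_frames(rgb_trace: RGBTrace, roi_mask: np.ndarray,
                    frame_shape: tuple[int, int], pixel_noise_sd: float = 0.0,
                    background: float = -1.0,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Render a trace into a synthetic frame stack for ROI-averaging tests.

    Pixels inside ``roi_mask`` carry the channel trace value (plus optional
    pixel noise); pixels outside carry a distinct constant background, so a
    correct ROI mean recovers the trace exactly when pixel noise is zero.

    Returns an array of shape ``(n_frames, H, W, 3)``.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != tuple(frame_shape):
        raise DataError("ROI mask shape does not match frame shape")
    m = int(roi_mask.sum())
    if m == 0:
        raise DataError("empty ROI: mask covers no pixels")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = rgb_trace.n
    frames = np.full((n, *frame_shape, 3), background, dtype=float)
    for c, name in enumerate(CHANNELS):
        vals = rgb_trace.channel(name)
        plane = np.broadcast_to(vals[:, None], (n, m)).copy()
        if pixel_noise_sd > 0:
            plane += rng.normal(0.0, pixel_noise_sd, size=plane.shape)
        frames[:, roi_mask, c] = plane
    return frames


def _subject_hr(rng: np.random.Generator, activity: str) -> float:
    """Scene mean heart rate: resting baseline plus an activity elevation."""
    base = rng.uniform(60.0, 90.0)
    elevation = {"Resting": 0.0, "Talking": 5.0, "Rotation": 5.0,
                 "Translation": 8.0, "Gym": 25.0}[activity]
    return base + elevation


def generate_scene(spec: SceneSpec, model: ChannelModel | None = None,
                   params: BVPParams | None = None,
                   cppg_noise_sd: float = 0.05) -> Scene:
    """Generate one (RGB trace, contact trace) pair from a scene spec."""
    rng = np.random.default_rng(spec.seed)
    if params is None:
        params = BVPParams(hr_bpm=_subject_hr(rng, spec.activity))
    if model is None:
        model = ChannelModel.for_activity(spec.activity)
    bvp_cam = generate_bvp(params, spec.camera_fps)
    bvp_cppg = generate_bvp(params, spec.cppg_fs)
    rgb = generate_rgb_trace(bvp_cam, model, spec)
    # offset the cPPG sensor-noise stream from the scene stream
    cppg = generate_cppg(bvp_cppg, spec.cppg_fs, cppg_noise_sd,
                         seed=np.random.default_rng(spec.seed + 1_000_003))
    true_hr = float(np.mean(params.hr_at(np.arange(0, params.duration_s, 0.1))))
    return Scene(spec=spec, rgb=rgb, cppg=cppg, true_hr_bpm=true_hr,
                 hr_profile=params)


def generate_cohort(n_subjects: int = 6,
                    activities: tuple = ("Resting", "Talking", "Rotation", "Gym"),
                    channel_models: dict | None = None,
                    master_seed: int = 0,
                    duration_s: float = 60.0,
                    camera_fps: float = 30.0,
                    cppg_noise_sd: float = 0.05) -> list[Scene]:
    """Simulate a cohort: one 60-s scene per subject per activity.

    Per-scene seeds are derived deterministically from ``master_seed`` via
    ``numpy.random.SeedSequence``, so the same master seed reproduces the
    cohort byte-for-byte. ``channel_models`` optionally maps activity name
    to a :class:`ChannelModel`, overriding the activity defaults.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be at least 1")
    for act in activities:
        if act not in ACTIVITIES:
            raise ConfigError(f"unknown activity {act!r}")
    ss = np.random.SeedSequence(master_seed)
    child_seeds = ss.generate_state(n_subjects * len(activities)) % (2**31)
    scenes = []
    idx = 0
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        for act in activities:
            spec = SceneSpec(subject_id=subject, activity=act,
                             camera_fps=camera_fps, seed=int(child_seeds[idx]))
            model = None if channel_models is None else channel_models.get(act)
            rng = np.random.default_rng(spec.seed)
            params = BVPParams(hr_bpm=_subject_hr(rng, act), duration_s=duration_s)
            scenes.append(generate_scene(spec, model=model, params=params,
                                         cppg_noise_sd=cppg_noise_sd))
            idx += 1
    return scenes


# ---------------------------------------------------------------------------
# Cohort CSV export / import

def scene_basename(scene: Scene) -> str:
    return f"{scene.spec.subject_id}_{scene.spec.activity}"


def export_cohort(scenes: list[Scene], outdir: str | Path) -> Path:
    """Write one CSV file pair per scene plus a JSON manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for scene in scenes:
        base = scene_basename(scene)
        scene.rgb.to_csv(outdir / f"{base}_rppg.csv")
        scene.cppg.to_csv(outdir / f"{base}_cppg.csv")
        entries.append({
            "subject": scene.spec.subject_id,
            "activity": scene.spec.activity,
            "camera_fps": scene.spec.camera_fps,
            "cppg_fs": scene.spec.cppg_fs,
            "seed": scene.spec.seed,
            "true_hr_bpm": round(scene.true_hr_bpm, 6),
            "rppg_file": f"{base}_rppg.csv",
            "cppg_file": f"{base}_cppg.csv",
        })
    manifest_path = outdir / "scenes.json"
    manifest_path.write_text(json.dumps(entries, indent=2) + "\n")
    return manifest_path


def load_cohort(indir: str | Path) -> list[Scene]:
    """Load a cohort exported by :func:`export_cohort` (or hand-prepared
    trace files following the same layout)."""
    indir = Path(indir)
    manifest_path = indir / "scenes.json"
    if not manifest_path.exists():
        raise DataError(f"no scene manifest found at {manifest_path}")
    entries = json.loads(manifest_path.read_text())
    scenes = []
    for e in entries:
        rppg_path = indir / e["rppg_file"]
        cppg_path = indir / e["cppg_file"]
        if not cppg_path.exists():
            raise DataError(f"missing cPPG partner file: {cppg_path}")
        rgb = RGBTrace.from_csv(rppg_path)
        cppg = ContactTrace.from_csv(cppg_path)
        spec = SceneSpec(subject_id=e["subject"], activity=e["activity"],
                         camera_fps=e.get("camera_fps", rgb.fs),
                         cppg_fs=e.get("cppg_fs", cppg.fs),
                         seed=e.get("seed", 0))
        scenes.append(Scene(spec=spec, rgb=rgb, cppg=cppg,
                            true_hr_bpm=e.get("true_hr_bpm", float("nan"))))
    return scenes
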