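"""Synthetic multimode-fiber specklegram recordings.

A multimode fiber carrying coherent light produces a far-field speckle
pattern: the interference of many guided modes with quasi-random relative
phases.  A specklegram sensor infers perturbations of the fiber (vibration,
evanescent-field interaction with adjacent tissue) from the temporal
dynamics of that pattern.

This module generates labeled speckle image stacks with the statistical
structure a glucose-sensing specklegram analysis assumes:

* modes are random transverse plane waves; their superposition yields
  fully developed speckle (contrast -> 1 as the mode count grows);
* an AC magnetic drive at ``drive_freq_hz`` agitates the guided phases.
  For an *uncovered* fiber (cladding stripped over the sensing region,
  evanescent light leaking into tissue) the agitation strength depends on
  the glucose concentration through ``modulation_depth``; higher glucose
  gives a weaker modulation.  For a *covered* fiber the drive only couples
  through glucose-independent skin vibration;
* physiological interference (heartbeat, respiration), slow phase drift
  and sensor shot/read noise are superimposed.

The magneto-optic coupling is phenomenological: a drive-synchronous,
amplitude-modulated per-mode phase jitter whose envelope oscillates at the
drive frequency.  The frame-to-frame decorrelation it causes therefore
oscillates at the drive frequency as well, so the correlation-peak-height
trace extracted downstream carries a spectral line at ``drive_freq_hz``
whose amplitude grows monotonically with ``modulation_depth``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Iterator, Sequence

import numpy as np
import tifffile

from .exceptions import ConfigurationError, DomainError, ValidationError

__all__ = [
    "GLUCOSE_LEVELS_MG_DL",
    "FiberSpec",
    "ModeSet",
    "AcquisitionConfig",
    "GlucoseSample",
    "SpeckleRecording",
    "SpeckleDataset",
    "penetration_depth",
    "transmitted_power",
    "default_modulation_depth",
    "sample_mode_set",
    "render_frame",
    "render_stack",
    "simulate_recording",
    "generate_dataset",
    "write_recording_tiff",
    "read_recording_tiff",
]

#: Reference finger-prick glucose levels (mg/dl) used as the fixed class
#: vocabulary throughout the package.
GLUCOSE_LEVELS_MG_DL: tuple[int, ...] = (
    86, 93, 97, 103, 105, 110, 111, 115, 119, 126, 132, 147, 153, 170,
)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberSpec:
    """Optical and geometric parameters of the sensing fiber.

    Lengths are in the units their names state.  ``gamma_eff`` is the
    dimensionless evanescent-wave absorption coefficient of the stripped
    sensing region (reflection-normalized form); ``covered`` flags whether
    the cladding/jacket is intact (no evanescent leakage, vibration-only
    sensitivity).
    """

    core_diameter_um: float = 400.0
    cladding_diameter_um: float = 425.0
    coating_diameter_um: float = 730.0
    wavelength_nm: float = 532.0
    n_eff: float = 1.46
    n_s: float = 1.33
    active_length_mm: float = 10.0
    gamma_eff: float = 0.1
    covered: bool = False

    def __post_init__(self) -> None:
        for name in ("core_diameter_um", "cladding_diameter_um",
                     "coating_diameter_um", "wavelength_nm",
                     "active_length_mm"):
            if getattr(self, name) <= 0 and name != "active_length_mm":
                raise ValidationError(f"{name} must be > 0")
        if self.active_length_mm < 0:
            raise ValidationError("active_length_mm must be >= 0")
        if not (self.core_diameter_um < self.cladding_diameter_um
                < self.coating_diameter_um):
            raise ValidationError(
                "expected core < cladding < coating diameter")


@dataclass(frozen=True)
class ModeSet:
    """A sampled set of transverse plane-wave modes.

    ``wavevectors`` has shape (M, 2) holding (kx, ky) in cycles/pixel with
    x = column, y = row; ``amplitudes`` and ``phases`` have shape (M,).
    """

    wavevectors: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        k = np.asarray(self.wavevectors, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        p = np.asarray(self.phases, dtype=float)
        if k.ndim != 2 or k.shape[1] != 2 or k.shape[0] < 1:
            raise ValidationError("wavevectors must have shape (M, 2), M >= 1")
        if a.shape != (k.shape[0],) or p.shape != (k.shape[0],):
            raise ValidationError("amplitudes/phases must have shape (M,)")
        if np.any(a < 0):
            raise ValidationError("amplitudes must be >= 0")
        if np.any(np.hypot(k[:, 0], k[:, 1]) > 0.5 + 1e-12):
            raise ValidationError("|k| must not exceed Nyquist (0.5 cyc/px)")
        object.__setattr__(self, "wavevectors", k)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "phases", p)

    @property
    def n_modes(self) -> int:
        return self.wavevectors.shape[0]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera timing, drive settings and interference/noise amplitudes.

    Phase-perturbation amplitudes are in radians.  ``noise_sigma`` is the
    additive white intensity-noise standard deviation as a fraction of the
    mean frame intensity.  Drift is a per-mode random walk whose RMS
    excursion over ``drift_timescale_s`` equals ``drift_amplitude_rad``.
    """

    frame_rate_hz: float = 1000.0
    duration_s: float = 5.0
    frame_shape: tuple[int, int] = (128, 128)
    drive_freq_hz: float = 140.0
    field_on: bool = True
    field_strength_gauss: float = 150.0
    noise_sigma: float = 0.005
    drift_amplitude_rad: float = 0.1
    drift_timescale_s: float = 1.0
    heartbeat_amplitude_rad: float = 0.05
    heartbeat_freq_hz: float = 1.17
    respiration_amplitude_rad: float = 0.03
    respiration_freq_hz: float = 0.25
    hum_amplitude_rad: float = 0.25
    hum_freq_hz: float = 50.0
    vibration_amplitude_rad: float = 0.05

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise ValidationError("frame_rate_hz and duration_s must be > 0")
        if self.n_frames < 2:
            raise ValidationError("duration x frame_rate must give >= 2 frames")
        rows, cols = self.frame_shape
        if rows < 2 or cols < 2:
            raise ValidationError("frame_shape must be at least 2x2")
        if self.field_on and self.frame_rate_hz <= 2.0 * self.drive_freq_hz:
            raise ConfigurationError(
                f"frame_rate_hz={self.frame_rate_hz} must exceed twice the "
                f"drive frequency ({self.drive_freq_hz} Hz) when the field "
                "is on (Nyquist)")
        for name in ("noise_sigma", "drift_amplitude_rad",
                     "heartbeat_amplitude_rad", "respiration_amplitude_rad",
                     "hum_amplitude_rad", "vibration_amplitude_rad"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate_hz * self.duration_s))

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def default_modulation_depth(glucose_mg_dl: float) -> float:
    """Map a glucose level to the drive-frequency phase-modulation depth.

    Linear and strictly decreasing over the reference range 86-170 mg/dl
    (0.3 rad at 86, 0.05 rad at 170): higher glucose damps the
    magneto-optically driven speckle variation.
    """
    g_lo, g_hi = GLUCOSE_LEVELS_MG_DL[0], GLUCOSE_LEVELS_MG_DL[-1]
    d_max, d_min = 0.3, 0.05
    return d_max - (d_max - d_min) * (glucose_mg_dl - g_lo) / (g_hi - g_lo)


@dataclass(frozen=True)
class GlucoseSample:
    """Ground-truth glucose label and its drive-modulation depth."""

    glucose_mg_dl: float
    modulation_depth: float | None = None

    def __post_init__(self) -> None:
        if self.glucose_mg_dl <= 0:
            raise ValidationError("glucose_mg_dl must be > 0")
        if self.modulation_depth is None:
            object.__setattr__(
                self, "modulation_depth",
                default_modulation_depth(self.glucose_mg_dl))
        if self.modulation_depth < 0:
            raise ValidationError("modulation_depth must be >= 0")


@dataclass
class SpeckleRecording:
    """A timed stack of nonnegative speckle intensity frames."""

    frames: np.ndarray            # (T, rows, cols), float, >= 0
    acquisition: AcquisitionConfig
    fiber: FiberSpec
    label: GlucoseSample
    recording_id: str = "rec0"

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValidationError("frames must be a (T, rows, cols) stack")
        if f.shape[0] != self.acquisition.n_frames:
            raise ValidationError(
                f"frame count {f.shape[0]} != round(frame_rate x duration) "
                f"= {self.acquisition.n_frames}")
        if f.shape[1:] != tuple(self.acquisition.frame_shape):
            raise ValidationError("frames do not match acquisition frame_shape")
        if f.size and float(f.min()) < 0:
            raise ValidationError("intensities must be >= 0")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# --------------------------------------------------------------------------
# fiber optics scalars
# --------------------------------------------------------------------------

def penetration_depth(fiber: FiberSpec) -> float:
    """Evanescent-field penetration depth, in nm.

    d_p = lambda / (2 pi sqrt(n_eff^2 - n_s^2)); the 1/e decay length of
    the evanescent wave outside the core, which sets the light-tissue
    interaction range of an uncovered fiber.
    """
    if fiber.wavelength_nm <= 0:
        raise ValidationError("wavelength_nm must be > 0")
    delta = fiber.n_eff ** 2 - fiber.n_s ** 2
    if delta <= 0:
        raise DomainError(
            "n_eff must exceed n_s for a guided evanescent field "
            f"(got n_eff={fiber.n_eff}, n_s={fiber.n_s})")
    return fiber.wavelength_nm / (2.0 * np.pi * np.sqrt(delta))


def transmitted_power(fiber: FiberSpec, p0: float) -> float:
    """Power leaving the stripped sensing region.

    P = P0 exp(-gamma_eff L / D) with the active length L and core
    diameter D in a common unit.
    """
    if p0 < 0:
        raise ValidationError("p0 must be >= 0")
    if fiber.gamma_eff < 0:
        raise ValidationError("gamma_eff must be >= 0")
    ratio = (fiber.active_length_mm * 1000.0) / fiber.core_diameter_um
    return p0 * float(np.exp(-fiber.gamma_eff * ratio))


# --------------------------------------------------------------------------
# mode sampling and frame rendering
# --------------------------------------------------------------------------

def sample_mode_set(
    fiber: FiberSpec,
    frame_shape: tuple[int, int],
    n_modes: int,
    seed: int | None = None,
) -> ModeSet:
    """Draw a random set of transverse plane-wave modes.

    Wavevectors are uniform over the Nyquist disc (|k| <= 0.5 cycles/px),
    static phases uniform on [0, 2 pi), amplitudes uniform on [0.5, 1.5].
    Deterministic for a fixed seed.
    """
    if n_modes < 1:
        raise ValidationError("n_modes must be >= 1")
    rng = np.random.default_rng(seed)
    radius = 0.5 * np.sqrt(rng.uniform(size=n_modes))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
    k = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    amplitudes = rng.uniform(0.5, 1.5, size=n_modes)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
    return ModeSet(wavevectors=k, amplitudes=amplitudes, phases=phases,
                   seed=seed)


def _mode_fields(modes: ModeSet, frame_shape: tuple[int, int]) -> np.ndarray:
    """Static complex field of each mode, shape (M, rows*cols)."""
    rows, cols = frame_shape
    y, x = np.mgrid[0:rows, 0:cols].astype(np.float64)
    kx = modes.wavevectors[:, 0][:, None]
    ky = modes.wavevectors[:, 1][:, None]
    r = (x.ravel()[None, :], y.ravel()[None, :])
    phase = 2.0 * np.pi * (kx * r[0] + ky * r[1]) + modes.phases[:, None]
    return (modes.amplitudes[:, None] * np.exp(1j * phase)).astype(np.complex128)


def render_frame(
    modes: ModeSet,
    frame_shape: tuple[int, int],
    phase_perturbation: np.ndarray | None = None,
) -> np.ndarray:
    """Far-field intensity of the mode superposition.

    Each mode contributes a_m exp(i(2 pi k_m . r + phi_m + dphi_m)); the
    intensity is the squared modulus of the summed field, so it is
    nonnegative and invariant under a global phase shift.
    """
    if phase_perturbation is None:
        phase_perturbation = np.zeros(modes.n_modes)
    dphi = np.asarray(phase_perturbation, dtype=float)
    if dphi.shape != (modes.n_modes,):
        raise ValidationError(
            f"phase_perturbation must have shape ({modes.n_modes},)")
    return render_stack(modes, frame_shape, dphi[None, :])[0]


def render_stack(
    modes: ModeSet,
    frame_shape: tuple[int, int],
    phase_table: np.ndarray,
) -> np.ndarray:
    """Render a (T, rows, cols) stack from per-frame per-mode phases.

    Vectorized over frames: with E the (M, pixels) static mode fields and
    c[t, m] = exp(i dphi[t, m]), the stack is |c @ E|^2.
    """
    phase_table = np.asarray(phase_table, dtype=float)
    if phase_table.ndim != 2 or phase_table.shape[1] != modes.n_modes:
        raise ValidationError("phase_table must have shape (T, n_modes)")
    fields = _mode_fields(modes, frame_shape).astype(np.complex64)
    coeff = np.exp(1j * phase_table).astype(np.complex64)
    stack = np.abs(coeff @ fields).astype(np.float64) ** 2
    return stack.reshape(phase_table.shape[0], *frame_shape)


# --------------------------------------------------------------------------
# recording simulation
# --------------------------------------------------------------------------

def _child_seed(master: int | None, *key: int) -> int:
    """Derived integer seed (< 2^31) for a keyed sub-stream.

    The (master, key...) tuple feeds a SeedSequence so every recording
    and noise channel is reproducible in isolation from the stored
    integer.
    """
    entropy = (0 if master is None else int(master),) + tuple(int(k) for k in key)
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] & 0x7FFFFFFF)


def _modulated_jitter(
    rng: np.random.Generator,
    depth: float,
    freq_hz: float,
    times_s: np.ndarray,
    n_modes: int,
    envelope_phase: float = 0.0,
) -> np.ndarray:
    """Decorrelation-strength modulation at ``freq_hz``, shape (T, M).

    Per-mode white phase jitter whose standard deviation is amplitude-
    modulated: depth * (1 + sin(2 pi f t + phase)) / 2.  The induced
    frame-to-frame speckle decorrelation oscillates at f, which puts a
    spectral line at f into the correlation-peak-height trace.  Used for
    the drive-locked channels (phase 0, locked to the field generator)
    and for pulsatile physiological coupling (random phase per
    recording).
    """
    envelope = 0.5 * (1.0 + np.sin(
        2.0 * np.pi * freq_hz * times_s + envelope_phase))
    jitter = rng.standard_normal((times_s.size, n_modes))
    return depth * envelope[:, None] * jitter


def simulate_recording(
    fiber: FiberSpec,
    acquisition: AcquisitionConfig,
    glucose: GlucoseSample,
    seed: int | None = None,
    n_modes: int = 100,
    recording_id: str = "rec0",
    mode_seed: int | None = None,
) -> SpeckleRecording:
    """Simulate one speckle recording.

    Per-frame per-mode phase perturbations compose four channels:

    a. glucose channel — drive-locked jitter scaled by the sample's
       ``modulation_depth``; active only for an *uncovered* fiber with the
       field on (magneto-optic interaction needs leaked light);
    b. vibration channel — the same drive-locked form at a fixed,
       glucose-independent amplitude whenever the field is on (skin /
       fiber vibration at the drive frequency);
    c. interference — pulsatile modulation of the tissue coupling at the
       heartbeat and respiration frequencies (envelope-modulated jitter
       with a random envelope phase per recording, the mechanism laser
       speckle flowmetry exploits) plus mains-frequency mechanical hum of
       the drive rig, same form;
    d. slow drift — a per-mode Gaussian random walk.

    Additive white noise is applied to the intensities (clipped at zero).
    Each channel draws from its own seeded sub-stream, so e.g. toggling
    the glucose channel does not perturb the others; with a covered fiber
    two recordings sharing a seed are identical regardless of the label.

    ``mode_seed`` fixes the static mode structure independently of the
    per-recording channels: recordings taken with the same instrument
    share one fiber speckle realization while their perturbations differ
    (what repeated recordings on one setup look like).  By default the
    mode set derives from ``seed`` like every other channel.
    """
    if acquisition.field_on and \
            acquisition.frame_rate_hz <= 2.0 * acquisition.drive_freq_hz:
        raise ConfigurationError("drive frequency at or above Nyquist")

    t = acquisition.times_s
    n_frames = acquisition.n_frames
    modes = sample_mode_set(
        fiber, acquisition.frame_shape, n_modes,
        seed=_child_seed(seed, 0) if mode_seed is None else mode_seed)
    phases = np.zeros((n_frames, n_modes))

    if acquisition.field_on and not fiber.covered:
        rng_g = np.random.default_rng(_child_seed(seed, 1))
        phases += _modulated_jitter(rng_g, glucose.modulation_depth,
                                    acquisition.drive_freq_hz, t, n_modes)
    if acquisition.field_on:
        rng_v = np.random.default_rng(_child_seed(seed, 2))
        phases += _modulated_jitter(rng_v,
                                    acquisition.vibration_amplitude_rad,
                                    acquisition.drive_freq_hz, t, n_modes)

    # physiological coupling and mains-frequency rig hum: pulsatile
    # decorrelation with a random envelope phase per recording
    rng_p = np.random.default_rng(_child_seed(seed, 3))
    for amp, freq in ((acquisition.heartbeat_amplitude_rad,
                       acquisition.heartbeat_freq_hz),
                      (acquisition.respiration_amplitude_rad,
                       acquisition.respiration_freq_hz),
                      (acquisition.hum_amplitude_rad,
                       acquisition.hum_freq_hz)):
        phases += _modulated_jitter(
            rng_p, amp, freq, t, n_modes,
            envelope_phase=rng_p.uniform(0.0, 2.0 * np.pi))

    if acquisition.drift_amplitude_rad > 0:
        rng_d = np.random.default_rng(_child_seed(seed, 4))
        step_sigma = acquisition.drift_amplitude_rad / np.sqrt(
            acquisition.drift_timescale_s * acquisition.frame_rate_hz)
        phases += np.cumsum(
            rng_d.standard_normal((n_frames, n_modes)) * step_sigma, axis=0)

    frames = render_stack(modes, acquisition.frame_shape, phases)

    if acquisition.noise_sigma > 0:
        rng_n = np.random.default_rng(_child_seed(seed, 5))
        sigma = acquisition.noise_sigma * float(frames.mean())
        frames = frames + rng_n.standard_normal(frames.shape) * sigma
        np.clip(frames, 0.0, None, out=frames)

    return SpeckleRecording(frames=frames.astype(np.float32),
                            acquisition=acquisition, fiber=fiber,
                            label=glucose, recording_id=recording_id)


# --------------------------------------------------------------------------
# dataset generation
# --------------------------------------------------------------------------

def _config_hash(fiber: FiberSpec, acquisition: AcquisitionConfig) -> str:
    blob = json.dumps({"fiber": asdict(fiber),
                       "acquisition": asdict(acquisition)},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SpeckleDataset:
    """A labeled set of recordings described by a deterministic manifest.

    Recordings are materialized lazily (``iter_recordings``) so datasets
    larger than memory can be streamed through the tracking stage.
    """

    manifest: list[dict]
    fiber: FiberSpec
    acquisition: AcquisitionConfig
    n_modes: int
    master_seed: int | None
    mode_seed: int | None = None

    def __len__(self) -> int:
        return len(self.manifest)

    def iter_recordings(self) -> Iterator[SpeckleRecording]:
        for entry in self.manifest:
            yield simulate_recording(
                self.fiber, self.acquisition,
                GlucoseSample(entry["glucose_mg_dl"],
                              entry["modulation_depth"]),
                seed=entry["seed"], n_modes=self.n_modes,
                recording_id=entry["recording_id"],
                mode_seed=entry.get("mode_seed"))

    def manifest_json(self) -> str:
        return json.dumps(
            {"config_hash": _config_hash(self.fiber, self.acquisition),
             "master_seed": self.master_seed,
             "n_modes": self.n_modes,
             "recordings": self.manifest},
            sort_keys=True, indent=2)

    def write(self, out_dir) -> None:
        """Write one multi-page TIFF per recording plus manifest.json."""
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for entry, rec in zip(self.manifest, self.iter_recordings()):
            write_recording_tiff(rec, out / f"{entry['recording_id']}.tiff")
        (out / "manifest.json").write_text(self.manifest_json())


def generate_dataset(
    levels: Sequence[float] = GLUCOSE_LEVELS_MG_DL,
    recordings_per_level: int = 5,
    fiber: FiberSpec | None = None,
    acquisition: AcquisitionConfig | None = None,
    n_modes: int = 100,
    seed: int | None = None,
) -> SpeckleDataset:
    """Build the manifest for a labeled recording set.

    Defaults emulate the study conditions: the 14 reference glucose levels
    with 5 consecutive recordings each (70 recordings).  Each recording
    gets a child seed derived from (seed, index) so any single recording
    is reproducible in isolation; the manifest is byte-identical for a
    fixed seed.  All recordings of a dataset share one fiber speckle
    realization (a dataset-level mode seed): they model repeated
    acquisitions on a single instrument, where only the perturbation
    channels change between recordings.
    """
    if len(levels) == 0:
        raise ValidationError("levels must be nonempty")
    if len(set(levels)) != len(levels):
        raise ValidationError("duplicate glucose levels in dataset definition")
    if recordings_per_level < 1:
        raise ValidationError("recordings_per_level must be >= 1")
    fiber = fiber if fiber is not None else FiberSpec()
    acquisition = acquisition if acquisition is not None else AcquisitionConfig()

    mode_seed = _child_seed(seed, 999)
    manifest = []
    index = 0
    for level in levels:
        sample = GlucoseSample(float(level))
        for rep in range(recordings_per_level):
            manifest.append({
                "recording_id": f"g{int(round(level)):03d}_r{rep}",
                "glucose_mg_dl": float(level),
                "modulation_depth": float(sample.modulation_depth),
                "repeat": rep,
                "seed": _child_seed(seed, 100, index),
                "mode_seed": mode_seed,
                "file": f"g{int(round(level)):03d}_r{rep}.tiff",
            })
            index += 1
    return SpeckleDataset(manifest=manifest, fiber=fiber,
                          acquisition=acquisition, n_modes=n_modes,
                          master_seed=seed, mode_seed=mode_seed)


# --------------------------------------------------------------------------
# TIFF I/O
# --------------------------------------------------------------------------

def write_recording_tiff(recording: SpeckleRecording, path) -> None:
    """Store a recording as 16-bit grayscale multi-page TIFF.

    Intensities are scaled to [0, 65535] per recording; the scale factor
    and acquisition metadata travel in the ImageDescription tag so the
    float stack can be recovered on read.
    """
    frames = recording.frames
    peak = float(frames.max()) if frames.size else 1.0
    scale = 65535.0 / peak if peak > 0 else 1.0
    data = np.round(frames * scale).astype(np.uint16)
    meta = {
        "scale": scale,
        "recording_id": recording.recording_id,
        "glucose_mg_dl": recording.label.glucose_mg_dl,
        "modulation_depth": recording.label.modulation_depth,
        "frame_rate_hz": recording.acquisition.frame_rate_hz,
        "drive_freq_hz": recording.acquisition.drive_freq_hz,
    }
    tifffile.imwrite(path, data, metadata=meta)


def read_recording_tiff(path) -> tuple[np.ndarray, dict]:
    """Read a stack written by :func:`write_recording_tiff`.

    Returns the float intensity stack (descaled) and the stored metadata.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    scale = float(meta.get("scale", 1.0))
    return data.astype(np.float64) / scale, dict(meta)
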