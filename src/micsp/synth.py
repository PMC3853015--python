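"""Synthetic 7-class motor-imagery EEG with known ground truth.

The generator plants band-limited stochastic oscillators (mu ~10 Hz and
beta ~20 Hz sources) at hand/foot sensorimotor locations of a 64-channel
10/20-style montage and mixes them onto the scalp with Gaussian spatial
spreads. Each of the seven classes attenuates a class-specific subset of
sources during the imagery window (event-related desynchronization);
compound-limb classes attenuate strictly more sources over broader bands
than their simple counterparts. Background noise is per-channel 1/f plus
spatially correlated white noise. Everything is deterministic per seed.

Class coding: 1=LH (left hand), 2=RH, 3=F (feet), 4=BH (both hands),
5=LH&RF (left hand + right foot), 6=RH&LF, 7=R (rest).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from micsp.io_preprocess import ChannelLayout, Epochs, ValidationError

CLASS_NAMES: dict[int, str] = {1: "LH", 2: "RH", 3: "F", 4: "BH", 5: "LH&RF", 6: "RH&LF", 7: "R"}
NAME_TO_CLASS: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}

#: electrodes excluded from topographies (EOG and cerebellar leads)
NON_SCALP_CHANNELS: tuple[str, ...] = ("HEO", "VEO", "CB1", "CB2")

_MONTAGE_ROWS: list[tuple[float, list[str]]] = [
    (0.85, ["FP1", "FPZ", "FP2"]),
    (0.70, ["AF3", "AF4"]),
    (0.55, ["F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8"]),
    (0.30, ["FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8"]),
    (0.00, ["T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8"]),
    (-0.30, ["TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8"]),
    (-0.55, ["P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8"]),
    (-0.70, ["PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8"]),
    (-0.82, ["O1", "OZ", "O2"]),
]
_EXTRA_POSITIONS: dict[str, tuple[float, float]] = {
    "CB1": (-0.50, -0.82),
    "CB2": (0.50, -0.82),
    "HEO": (0.93, 0.30),
    "VEO": (0.00, 0.95),
}


def standard_layout_64() -> ChannelLayout:
    """64-channel 10/20-style layout (60 scalp + HEO/VEO/CB1/CB2)."""
    positions: dict[str, tuple[float, float]] = {}
    for y, names in _MONTAGE_ROWS:
        n = len(names)
        half_width = 0.80 * np.sqrt(max(1.0 - y * y, 0.05))
        for i, name in enumerate(names):
            lat = 0.0 if n == 1 else -1.0 + 2.0 * i / (n - 1)
            positions[name] = (lat * half_width, y)
    positions.update(_EXTRA_POSITIONS)
    return ChannelLayout(positions)


def standard_channels_64() -> list[str]:
    """Channel order of the default montage (64 names)."""
    names = [n for _, row in _MONTAGE_ROWS for n in row]
    return names + list(_EXTRA_POSITIONS)


@dataclass(frozen=True)
class SourceSpec:
    """A band-limited stochastic oscillator planted at one electrode."""

    name: str
    electrode: str
    center_hz: float
    bandwidth_hz: float
    amplitude: float  # baseline RMS amplitude, microvolts


def default_sources(mu_amp: float = 2.0, beta_amp: float = 1.0) -> tuple[SourceSpec, ...]:
    """Mu and beta sources at the left-hand (C4), right-hand (C3) and
    midcentral foot (CZ) sensorimotor areas."""
    out = []
    for loc in ("C3", "CZ", "C4"):
        out.append(SourceSpec(f"{loc}-mu", loc, 10.0, 4.0, mu_amp))
        out.append(SourceSpec(f"{loc}-beta", loc, 20.0, 8.0, beta_amp))
    return tuple(out)


def default_class_map(attenuation: float = 0.5, asymmetry: float = 0.0) -> dict[int, dict[str, float]]:
    """Per class: which sources attenuate (amplitude factor) during imagery.

    Hand imagery attenuates the contralateral hand-area mu source; feet
    imagery the midcentral mu source; both-hands imagery both hand-area mu
    sources (optionally weaker on the right hemisphere via `asymmetry`);
    hand + contralateral foot attenuates the hand *and* midcentral sources
    in both the mu and beta bands (broader bands, more locations). Rest
    attenuates nothing.
    """
    if not 0.0 <= attenuation <= 1.0:
        raise ValidationError("attenuation must lie in [0, 1]")
    a = attenuation
    a_right = min(1.0, a * (1.0 + asymmetry))
    return {
        1: {"C4-mu": a},
        2: {"C3-mu": a},
        3: {"CZ-mu": a},
        4: {"C3-mu": a, "C4-mu": a_right},
        5: {"C4-mu": a, "C4-beta": a, "CZ-mu": a, "CZ-beta": a},
        6: {"C3-mu": a, "C3-beta": a, "CZ-mu": a, "CZ-beta": a},
        7: {},
    }


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults emulate the recording geometry of the
    target paradigm (64 channels, 1000 Hz, 8 s trials, cue at 3 s, 7 x 80
    trials)."""

    channels: tuple[str, ...] = tuple(standard_channels_64())
    fs: float = 1000.0
    trial_s: float = 8.0
    cue_s: float = 3.0
    imagery: tuple[float, float] = (0.5, 3.5)  # relative to cue
    ramp_s: float = 0.25
    n_trials_per_class: int = 80
    classes: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    sources: tuple[SourceSpec, ...] = field(default_factory=default_sources)
    class_map: dict[int, dict[str, float]] = field(default_factory=default_class_map)
    spread: float = 0.15  # Gaussian mixing spread on the unit disc
    noise_level: float = 1.0  # microvolts RMS of the background noise
    pink_fraction: float = 0.5  # share of noise power in the 1/f component
    spatial_scale: float = 0.3  # spatial correlation length of the white noise
    drift: float = 0.0  # per-trial nonstationarity strength (artifacts + source gains)
    gain_drift_fraction: float = 0.3  # share of `drift` applied to source gains
    artifact_amp: float = 6.0  # RMS amplitude of drift artifacts at unit drift
    artifact_prob: float = 0.2  # per-trial probability of each drift artifact
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.classes) <= set(range(1, 8)):
            raise ValidationError("classes must be a subset of {1..7}")
        missing = [c for c in self.classes if c not in self.class_map]
        if missing:
            raise ValidationError(f"classes without an ERD map entry: {missing}")
        for cls, effects in self.class_map.items():
            for src, a in effects.items():
                if not 0.0 <= a <= 1.0:
                    raise ValidationError(f"attenuation {a} for {src} in class {cls} outside [0, 1]")
                if src not in {s.name for s in self.sources}:
                    raise ValidationError(f"class {cls} references unknown source {src!r}")
        for s in self.sources:
            if s.center_hz + s.bandwidth_hz / 2 >= self.fs / 2:
                raise ValidationError(f"source {s.name} exceeds Nyquist")
            if s.electrode not in self.channels:
                raise ValidationError(f"source electrode {s.electrode} not in channel set")
        if self.drift < 0:
            raise ValidationError("drift must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows: mixing, schedule, labels."""

    mixing: np.ndarray  # (n_channels, n_sources)
    source_names: list[str]
    labels: np.ndarray
    attenuations: np.ndarray  # (n_trials, n_sources), imagery-window amplitude factors
    gains: np.ndarray  # (n_trials, n_sources), whole-trial nonstationary gains
    layout: ChannelLayout

    def mixing_column(self, source_name: str) -> np.ndarray:
        return self.mixing[:, self.source_names.index(source_name)]


def _mixing_matrix(cfg: SynthConfig, layout: ChannelLayout) -> np.ndarray:
    pos = layout.coords(list(cfg.channels))
    cols = []
    for s in cfg.sources:
        center = np.array(layout[s.electrode])
        d2 = ((pos - center) ** 2).sum(axis=1)
        col = np.exp(-d2 / (2.0 * cfg.spread**2))
        cols.append(col / col.max())
    return np.column_stack(cols)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, fs: float) -> np.ndarray:
    """Per-channel 1/f noise with unit RMS, via spectral shaping."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_channels, len(freqs))) + 1j * rng.standard_normal((n_channels, len(freqs)))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    return x / np.maximum(rms, np.finfo(float).tiny)


#: scalp locations of the drift-artifact generators (frontal blink-like,
#: left/right temporal muscle-like); broadband so they survive band-passing
_ARTIFACT_CENTERS: tuple[tuple[float, float], ...] = ((0.0, 0.88), (-0.92, 0.0), (0.92, 0.0))
_ARTIFACT_BAND: tuple[float, float] = (5.0, 35.0)


def _envelope(cfg: SynthConfig, n_samples: int, attenuation: float) -> np.ndarray:
    """Amplitude envelope: 1 outside imagery, `attenuation` inside, with
    cosine ramps of `ramp_s` seconds at onset and offset."""
    t = np.arange(n_samples) / cfg.fs
    on = cfg.cue_s + cfg.imagery[0]
    off = cfg.cue_s + cfg.imagery[1]
    env = np.ones(n_samples)
    depth = 1.0 - attenuation
    ramp = cfg.ramp_s
    inside = (t >= on) & (t < off)
    env[inside] = attenuation
    if ramp > 0:
        rising = (t >= on) & (t < on + ramp)
        env[rising] = 1.0 - depth * 0.5 * (1 - np.cos(np.pi * (t[rising] - on) / ramp))
        falling = (t >= off - ramp) & (t < off)
        env[falling] = attenuation + depth * 0.5 * (1 - np.cos(np.pi * (t[falling] - (off - ramp)) / ramp))
    return env


def generate(cfg: SynthConfig, seed: int | None = None) -> tuple[Epochs, GroundTruth]:
    """Generate one synthetic session: ``X(t) = A S(t) + noise`` per trial.

    Deterministic given the configuration (and optional `seed` override).
    Trials are generated in a seed-shuffled class order with exactly
    `n_trials_per_class` trials per class.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    layout = standard_layout_64()
    A = _mixing_matrix(cfg, layout)
    n_ch = len(cfg.channels)
    n_samples = int(round(cfg.trial_s * cfg.fs))
    src_names = [s.name for s in cfg.sources]
    n_src = len(cfg.sources)

    labels = np.repeat(list(cfg.classes), cfg.n_trials_per_class)
    labels = rng.permutation(labels)
    n_trials = len(labels)

    sos = {
        s.name: signal.butter(
            4,
            [max(s.center_hz - s.bandwidth_hz / 2, 0.1), s.center_hz + s.bandwidth_hz / 2],
            btype="bandpass",
            fs=cfg.fs,
            output="sos",
        )
        for s in cfg.sources
    }
    # spatially correlated white-noise mixer (exponential kernel on the layout)
    pos = layout.coords(list(cfg.channels))
    dist = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    K = np.exp(-dist / cfg.spatial_scale) + 1e-9 * np.eye(n_ch)
    L = linalg.cholesky(K, lower=True)
    L /= np.sqrt(np.diag(K)).mean()
    # nonstationarity artifacts: fixed spatial columns, random per-trial amplitude
    art_cols = np.column_stack(
        [np.exp(-((pos - np.array(c)) ** 2).sum(axis=1) / (2 * 0.3**2)) for c in _ARTIFACT_CENTERS]
    )
    art_cols /= art_cols.max(axis=0)
    sos_art = signal.butter(4, _ARTIFACT_BAND, btype="bandpass", fs=cfg.fs, output="sos")
    n_art = art_cols.shape[1]

    data = np.empty((n_trials, n_ch, n_samples), dtype=np.float32)
    attenuations = np.ones((n_trials, n_src))
    gains = np.ones((n_trials, n_src))
    amp_white = np.sqrt(1.0 - cfg.pink_fraction)
    amp_pink = np.sqrt(cfg.pink_fraction)
    for t_idx in range(n_trials):
        effects = cfg.class_map[int(labels[t_idx])]
        # random draws below happen unconditionally so that drift=0 leaves the
        # stream (and hence the dataset) identical to the stationary base config
        zeta = rng.standard_normal(n_src)
        gains[t_idx] = np.clip(1.0 + cfg.drift * cfg.gain_drift_fraction * zeta, 0.05, None)
        art_hits = rng.random(n_art) < cfg.artifact_prob
        art_amps = cfg.drift * cfg.artifact_amp * np.abs(rng.standard_normal(n_art)) * art_hits
        art_sig = rng.standard_normal((n_art, n_samples))
        S = np.empty((n_src, n_samples))
        for j, s in enumerate(cfg.sources):
            x = signal.sosfiltfilt(sos[s.name], rng.standard_normal(n_samples))
            x /= max(x.std(), np.finfo(float).tiny)
            a = effects.get(s.name, 1.0)
            attenuations[t_idx, j] = a
            S[j] = s.amplitude * gains[t_idx, j] * x * _envelope(cfg, n_samples, a)
        noise = amp_white * (L @ rng.standard_normal((n_ch, n_samples)))
        noise += amp_pink * _pink_noise(rng, n_ch, n_samples, cfg.fs)
        trial = A @ S + cfg.noise_level * noise
        if cfg.drift > 0:
            art = signal.sosfiltfilt(sos_art, art_sig, axis=-1)
            art /= np.maximum(art.std(axis=-1, keepdims=True), np.finfo(float).tiny)
            trial += art_cols @ (art_amps[:, None] * art)
        data[t_idx] = trial.astype(np.float32)

    epochs = Epochs(data=data, labels=labels, fs=cfg.fs, channels=list(cfg.channels), t0=0.0)
    gt = GroundTruth(
        mixing=A, source_names=src_names, labels=labels.copy(),
        attenuations=attenuations, gains=gains, layout=layout,
    )
    return epochs, gt


def nonstationary_variant(cfg: SynthConfig, drift: float) -> SynthConfig:
    """Copy of `cfg` with per-trial source-gain drift; drift=0 reproduces
    the base configuration exactly (the random stream is unchanged)."""
    if drift < 0:
        raise ValidationError("drift must be non-negative")
    return dataclasses.replace(cfg, drift=float(drift))


def zero_contrast_variant(cfg: SynthConfig) -> SynthConfig:
    """Copy of `cfg` in which no class attenuates any source (chance-level
    dataset: classes are statistically indistinguishable)."""
    empty_map = {c: {} for c in cfg.class_map}
    return dataclasses.replace(cfg, class_map=empty_map)
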