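"""Time-frequency and spectral descriptors of event-related desynchronization.

Implements:

* short-time-Fourier power per trial/channel (:func:`tf_power`),
* trial-averaged event-related spectral perturbation maps expressed in
  decibels relative to a pre-cue baseline (:func:`ersp`),
* per-frequency band-power curves over the imagery window with paired
  t-tests across subjects (:func:`band_power_curve`,
  :func:`paired_freq_ttest`),
* power spectral entropy of the normalized spectrum (:func:`pse`,
  :func:`pse_per_class`),
* the spatial distribution coefficient: an entropy over channels of the
  relative task-vs-rest alpha-power change (:func:`sdc`), and
* per-electrode topography values (:func:`topography`).

All dB/entropy quantities are relative measures: scaling every trial by a
constant leaves them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from micsp.io_preprocess import Epochs, ValidationError


@dataclass(frozen=True)
class STFTConfig:
    """Short-time Fourier transform settings for time-frequency maps.

    Defaults: 0.5 s Hann window, 90% overlap, 0.5 Hz frequency grid
    restricted to 1-35 Hz.
    """

    window_s: float = 0.5
    overlap: float = 0.9
    freq_res: float = 0.5
    fmin: float = 1.0
    fmax: float = 35.0


@dataclass
class TFPower:
    """Non-negative spectral power on a frequency x time grid (one signal)."""

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray  # (n_freqs, n_times)

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise ValidationError("power grid does not match freqs/times")
        if np.any(self.power < 0):
            raise ValidationError("power must be non-negative")


@dataclass
class ERSPMap:
    """Baseline-normalized spectral power change in dB (one class/channel)."""

    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray  # (n_freqs, n_times), dB
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("ERSP values must be finite")


@dataclass
class PowerCurve:
    """Mean power change per frequency (dB), one subject/condition."""

    freqs: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.freqs.shape:
            raise ValidationError("one value per frequency bin required")


@dataclass
class SpectrumPD:
    """Normalized spectral mass per frequency bin (sums to 1)."""

    freqs: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0):
            raise ValidationError("spectral probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-10:
            raise ValidationError("spectral probabilities must sum to 1")


@dataclass
class SDCInput:
    """Per-channel alpha-band mean PSD for task (m) and rest (r)."""

    task: np.ndarray
    rest: np.ndarray

    def __post_init__(self) -> None:
        self.task = np.asarray(self.task, dtype=float)
        self.rest = np.asarray(self.rest, dtype=float)
        if self.task.shape != self.rest.shape:
            raise ValidationError("task and rest must have one value per channel each")
        if np.any(self.rest <= 0):
            raise ValidationError("rest-state PSD must be strictly positive")


@dataclass
class SigMask:
    """Per-frequency paired-test outcome."""

    freqs: np.ndarray
    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    alpha: float = 0.05

    def __post_init__(self) -> None:
        finite = self.p[~np.isnan(self.p)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValidationError("p-values must lie in [0, 1]")


# -- short-time Fourier power ------------------------------------------------


def _make_stft(fs: float, cfg: STFTConfig) -> signal.ShortTimeFFT:
    nwin = int(round(cfg.window_s * fs))
    hop = max(1, int(round(nwin * (1.0 - cfg.overlap))))
    mfft = max(nwin, int(round(fs / cfg.freq_res)))
    win = signal.windows.hann(nwin, sym=False)
    return signal.ShortTimeFFT(win, hop=hop, fs=fs, mfft=mfft, scale_to="magnitude")


def tf_power(x: np.ndarray, fs: float, cfg: STFTConfig = STFTConfig(), t0: float = 0.0) -> TFPower:
    """Squared-magnitude STFT of a single 1-D signal on the configured grid."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("tf_power expects a 1-D signal")
    sft = _make_stft(fs, cfg)
    if len(x) < len(sft.win):
        raise ValidationError(f"signal length {len(x)} shorter than STFT window {len(sft.win)}")
    spec = sft.stft(x)
    power = np.abs(spec) ** 2
    times = sft.t(len(x)) + t0
    # keep only frames whose window lies fully inside the signal (border
    # frames overlap the zero padding and carry spurious power drops)
    lo = sft.lower_border_end[1] - sft.p_min
    hi = sft.upper_border_begin(len(x))[1] - sft.p_min
    band = (sft.f >= cfg.fmin) & (sft.f <= cfg.fmax)
    return TFPower(freqs=sft.f[band], times=times[lo:hi], power=power[band][:, lo:hi])


def _class_mean_power(
    epochs: Epochs, class_id: int, channel: str, cfg: STFTConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Mean over class trials of |F_k(f, t)|^2 at one channel."""
    ci = epochs.channel_index(channel)
    trials = epochs.class_trials(class_id)[:, ci, :]
    acc = None
    freqs = times = None
    for x in trials:
        tf = tf_power(x, epochs.fs, cfg, t0=epochs.t0)
        freqs, times = tf.freqs, tf.times
        acc = tf.power if acc is None else acc + tf.power
    return freqs, times, acc / len(trials), len(trials)


def ersp(
    epochs: Epochs,
    class_id: int,
    channel: str,
    baseline: tuple[float, float] = (0.0, 3.0),
    cfg: STFTConfig = STFTConfig(),
) -> ERSPMap:
    """Trial-averaged spectral power in dB relative to the baseline window.

    The trial-mean power ``mean_k |F_k(f, t)|^2`` is divided per frequency
    by its mean over the baseline interval and expressed as
    ``10 log10``. Negative values indicate event-related
    desynchronization, positive values synchronization.
    """
    freqs, times, mean_power, n = _class_mean_power(epochs, class_id, channel, cfg)
    in_base = (times >= baseline[0]) & (times <= baseline[1])
    if not in_base.any():
        raise ValidationError(f"baseline {baseline} contains no STFT frames")
    base = mean_power[:, in_base].mean(axis=1, keepdims=True)
    if np.any(base <= 0):
        raise ValidationError("baseline power is zero at some frequency; cannot normalize")
    values = 10.0 * np.log10(mean_power / base + np.finfo(float).tiny)
    return ERSPMap(freqs=freqs, times=times, values=values, n_trials=n)


# -- band-power curves and group statistics ----------------------------------


def imagery_power_curve(m: ERSPMap, imagery: tuple[float, float] = (3.5, 6.5)) -> PowerCurve:
    """Average an ERSP map over the imagery time window (one subject)."""
    sel = (m.times >= imagery[0]) & (m.times <= imagery[1])
    if not sel.any():
        raise ValidationError(f"imagery window {imagery} contains no STFT frames")
    return PowerCurve(freqs=m.freqs, values=m.values[:, sel].mean(axis=1))


def band_power_curve(maps: list[ERSPMap], imagery: tuple[float, float] = (3.5, 6.5)) -> PowerCurve:
    """Group-mean power-change curve: per-frequency mean over the imagery
    window within each subject's map, then the mean over subjects."""
    if not maps:
        raise ValidationError("need at least one ERSP map")
    curves = [imagery_power_curve(m, imagery) for m in maps]
    f0 = curves[0].freqs
    for c in curves[1:]:
        if c.freqs.shape != f0.shape or not np.allclose(c.freqs, f0):
            raise ValidationError("frequency grids differ between subjects")
    return PowerCurve(freqs=f0, values=np.mean([c.values for c in curves], axis=0))


def paired_freq_ttest(a: list[PowerCurve], b: list[PowerCurve], alpha: float = 0.05) -> SigMask:
    """Per-frequency paired t-test between two conditions across subjects.

    Two-sided, uncorrected for multiple comparisons. Frequencies where the
    paired differences are identically zero get ``t = 0`` and ``p = 1``.
    """
    if len(a) != len(b):
        raise ValidationError("conditions must have the same subjects")
    if len(a) < 2:
        raise ValidationError("paired t-test needs >= 2 subjects")
    f0 = a[0].freqs
    for c in list(a) + list(b):
        if c.freqs.shape != f0.shape or not np.allclose(c.freqs, f0):
            raise ValidationError("frequency grids differ")
    d = np.stack([ca.values - cb.values for ca, cb in zip(a, b)])  # (subjects, freqs)
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    # degenerate bins (zero spread of the paired differences) carry no
    # evidence either way: identical conditions get t=0/p=1, a constant
    # nonzero shift cannot be assessed and is marked not significant
    degenerate = sd == 0
    t[degenerate & (mean == 0)] = 0.0
    p[degenerate & (mean == 0)] = 1.0
    shifted = degenerate & (mean != 0)
    t[shifted] = np.sign(mean[shifted]) * np.inf
    p[shifted] = np.nan
    mask = np.where(np.isnan(p), False, p < alpha)
    return SigMask(freqs=f0, t=t, p=p, mask=mask, alpha=alpha)


# -- power spectral entropy --------------------------------------------------


def pse(spectrum: SpectrumPD) -> float:
    """Shannon entropy ``-sum p ln p`` of a normalized spectrum, in nats.

    Bounded by ``0 <= H <= ln(n_bins)``; ``0 ln 0`` is taken as 0.
    """
    p = spectrum.p[spectrum.p > 0]
    return float(-(p * np.log(p)).sum())


def trial_spectrum(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (5.0, 35.0),
    segment_s: float = 1.0,
) -> SpectrumPD:
    """Welch PSD of one signal, restricted to `band` and normalized to sum 1.

    Welch settings: Hann segments of `segment_s` seconds, 50% overlap.
    """
    x = np.asarray(x, dtype=float)
    nper = min(int(round(segment_s * fs)), len(x))
    freqs, psd = signal.welch(x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValidationError(f"band {band} contains no Welch frequency bins")
    mass = psd[sel]
    total = mass.sum()
    if total <= 0:
        raise ValidationError("zero spectral mass in the analysis band")
    return SpectrumPD(freqs=freqs[sel], p=mass / total)


def pse_per_class(
    epochs: Epochs,
    channel: str,
    band: tuple[float, float] = (5.0, 35.0),
    segment_s: float = 1.0,
) -> dict[int, float]:
    """Mean power spectral entropy per class at one channel.

    Per trial: Welch PSD -> normalize over `band` -> entropy; then averaged
    over the trials of each class.
    """
    if band[1] >= epochs.fs / 2:
        raise ValidationError(f"band {band} exceeds Nyquist {epochs.fs / 2} Hz")
    ci = epochs.channel_index(channel)
    out: dict[int, float] = {}
    for label in sorted(np.unique(epochs.labels).tolist()):
        trials = epochs.class_trials(label)[:, ci, :]
        values = [pse(trial_spectrum(x, epochs.fs, band, segment_s)) for x in trials]
        out[label] = float(np.mean(values))
    return out


# -- spatial distribution coefficient ----------------------------------------


def sdc(inp: SDCInput) -> float:
    """Entropy over channels of the relative task-vs-rest power change.

    Per channel ``q_i = (m_i - r_i) / r_i``; the entropy is computed on the
    normalized magnitudes ``|q_i| / sum_j |q_j|`` so that it is well defined
    when power decreases (q < 0). Bounded by ``0 <= H <= ln(n_channels)``:
    ln(m) when the change is spread uniformly over all m channels, 0 when it
    is confined to a single channel.
    """
    q = (inp.task - inp.rest) / inp.rest
    total = np.abs(q).sum()
    if total == 0:
        raise ValidationError("all channel changes are zero; SDC undefined")
    q_norm = np.abs(q) / total
    nz = q_norm[q_norm > 0]
    return float(-(nz * np.log(nz)).sum())


def alpha_band_psd(
    epochs: Epochs,
    class_id: int,
    band: tuple[float, float] = (8.0, 13.0),
    interval: tuple[float, float] | None = None,
    segment_s: float = 1.0,
) -> np.ndarray:
    """Per-channel mean band PSD for one class (trial-averaged)."""
    e = epochs
    if interval is not None:
        from micsp.io_preprocess import crop_interval

        e = crop_interval(e, interval[0], interval[1])
    trials = e.class_trials(class_id)  # (n, channels, samples)
    nper = min(int(round(segment_s * e.fs)), trials.shape[-1])
    freqs, psd = signal.welch(trials, fs=e.fs, window="hann", nperseg=nper, noverlap=nper // 2, axis=-1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValidationError(f"band {band} contains no Welch frequency bins")
    return psd[..., sel].mean(axis=(0, 2))


def sdc_task_vs_rest(
    epochs: Epochs,
    task_class: int,
    rest_class: int = 7,
    band: tuple[float, float] = (8.0, 13.0),
    interval: tuple[float, float] = (3.5, 6.5),
    channels: list[str] | None = None,
) -> float:
    """Spatial distribution coefficient of `task_class` against the rest class."""
    if channels is not None:
        idx = [epochs.channel_index(c) for c in channels]
    else:
        idx = list(range(epochs.n_channels))
    task = alpha_band_psd(epochs, task_class, band, interval)[idx]
    rest = alpha_band_psd(epochs, rest_class, band, interval)[idx]
    return sdc(SDCInput(task=task, rest=rest))


# -- topography --------------------------------------------------------------


def topography(
    epochs: Epochs,
    class_id: int,
    band: tuple[float, float] = (8.0, 13.0),
    interval: tuple[float, float] = (3.5, 6.5),
    electrodes: list[str] | None = None,
    baseline: tuple[float, float] = (0.0, 3.0),
    cfg: STFTConfig = STFTConfig(),
) -> dict[str, float]:
    """Mean ERSP value in `band` x `interval` per electrode.

    Returns one scalar (dB) per requested electrode, usable as a scalp map
    or as the task input of the spatial distribution coefficient.
    """
    electrodes = list(epochs.channels) if electrodes is None else list(electrodes)
    unknown = [c for c in electrodes if c not in epochs.channels]
    if unknown:
        raise ValidationError(f"unknown electrodes: {unknown}")
    out: dict[str, float] = {}
    for name in electrodes:
        m = ersp(epochs, class_id, name, baseline=baseline, cfg=cfg)
        fsel = (m.freqs >= band[0]) & (m.freqs <= band[1])
        tsel = (m.times >= interval[0]) & (m.times <= interval[1])
        if not fsel.any() or not tsel.any():
            raise ValidationError("band/interval selects no ERSP cells")
        out[name] = float(m.values[np.ix_(fsel, tsel)].mean())
    return out
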