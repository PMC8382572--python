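"""Raw EEG -> N100/P300/N400 amplitudes and latencies.

Processing chain, in order: zero-phase 0.5–20 Hz band-pass, adaptive (NLMS)
ocular correction against the EOG channel, stimulus-locked epoching with
baseline correction, per-epoch wavelet shrinkage, +/-75 uV artifact rejection,
participant-level quality control (excluded when more than 25% of epochs are
rejected), condition averaging, and peak measurement as the most extreme local
extremum inside a component-specific search window.

Conventions: N100 and P300 are measured on the deviant-tone average (the
oddball response); N400 on the incongruent-minus-congruent difference wave.
Amplitudes are reported as magnitudes (uV); latencies in ms at the peak
sample, so at 500 Hz they are multiples of 2 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .measures import COMPONENTS, POLARITY
from .recording import EOG_CHANNEL, RawRecording

# QC status values
QC_INCLUDED = "included"
QC_EXCLUDED_QUALITY = "excluded_quality"
QC_N400_MISSING_LANGUAGE = "n400_missing_language"


@dataclass
class PipelineConfig:
    """All tunable parameters of the extraction pipeline."""

    band_hz: tuple[float, float] = (0.5, 20.0)
    filter_order: int = 4
    epoch_window_ms: tuple[float, float] = (-100.0, 900.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    reject_threshold_uv: float = 75.0
    qc_max_rejection: float = 0.25  # strict ">" comparison
    #: component -> (low, high) peak-search window in ms post-stimulus
    windows_ms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"n100": (70.0, 150.0), "p300": (160.0, 450.0), "n400": (280.0, 610.0)}
    )
    #: component -> measurement electrode
    electrodes: dict[str, str] = field(
        default_factory=lambda: {"n100": "Cz", "p300": "Pz", "n400": "Cz"}
    )
    #: "difference" (incongruent - congruent) or "incongruent_only"
    n400_mode: str = "difference"
    nlms_order: int = 3
    nlms_step: float = 0.002
    wavelet: str = "sym4"
    wavelet_mode: str = "soft"
    #: only detail levels finer than this timescale are thresholded, so the
    #: shrinkage removes fast noise without attenuating ERP-band coefficients
    wavelet_max_scale_ms: float = 16.0
    #: detect peak latencies on a smoothed copy of the average (amplitude is
    #: still read from the unsmoothed average at the detected sample); kernel
    #: SD in ms, scaled to each component's typical timescale
    detection_smooth_ms: dict[str, float] = field(
        default_factory=lambda: {"n100": 8.0, "p300": 20.0, "n400": 25.0}
    )


@dataclass
class Epoch:
    """One stimulus-locked segment (channels x samples, uV)."""

    condition: str
    window_ms: tuple[float, float]
    sample_rate: float
    channels: list[str]
    data: np.ndarray
    rejected: bool = False
    rejection_reason: str | None = None

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[1]
        return self.window_ms[0] + 1000.0 * np.arange(n) / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channels.index(label)]


@dataclass
class AverageWaveform:
    """Condition-mean ERP at one electrode."""

    condition: str
    electrode: str
    times_ms: np.ndarray
    samples: np.ndarray  # uV
    n_epochs_included: int


@dataclass
class ErpMeasurementSet:
    """The six brain vital signs for one participant-session, plus QC."""

    participant_id: str
    session: int
    n100_amplitude: float | None = None
    n100_latency: float | None = None
    p300_amplitude: float | None = None
    p300_latency: float | None = None
    n400_amplitude: float | None = None
    n400_latency: float | None = None
    qc: str = QC_INCLUDED
    rejection_fraction: float = 0.0
    #: component -> True when the peak fell back to a window edge
    edge_fallback: dict[str, bool] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "n100_amplitude": self.n100_amplitude,
            "n100_latency": self.n100_latency,
            "p300_amplitude": self.p300_amplitude,
            "p300_latency": self.p300_latency,
            "n400_amplitude": self.n400_amplitude,
            "n400_latency": self.n400_latency,
        }


# ---------------------------------------------------------------------------
# Filtering


def bandpass_filter(recording: RawRecording, low: float = 0.5, high: float = 20.0,
                    order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass applied to every channel (EOG included)."""
    nyq = recording.sample_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"invalid band edges ({low}, {high}) for rate {recording.sample_rate} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=recording.sample_rate, output="sos")
    out = signal.sosfiltfilt(sos, recording.data, axis=1)
    return recording.with_data(out)


def remove_ocular_artifacts(recording: RawRecording, order: int = 3,
                            step: float = 0.002, eps: float = 1e-12) -> RawRecording:
    """Subtract the EOG-correlated component from each scalp channel.

    A normalized least-mean-squares (NLMS) adaptive filter predicts each scalp
    channel from the last ``order`` EOG samples; the prediction error — the
    ocular-cleaned signal — replaces the scalp channel. The EOG channel itself
    passes through unchanged.
    """
    if EOG_CHANNEL not in recording.channels:
        raise ValueError("recording has no EOG channel; ocular correction needs one")
    eog = recording.channel(EOG_CHANNEL)
    n = len(eog)
    # Tap matrix: row t holds [eog[t], eog[t-1], ..., eog[t-order+1]]
    taps = np.zeros((n, order))
    for j in range(order):
        taps[j:, j] = eog[: n - j]
    norms = np.einsum("ij,ij->i", taps, taps) + eps

    out = recording.data.copy()
    for ci in recording.scalp_indices():
        d = recording.data[ci]
        w = np.zeros(order)
        e = np.empty(n)
        for t in range(n):
            x = taps[t]
            y = w @ x
            e[t] = d[t] - y
            w += (step / norms[t]) * e[t] * x
        out[ci] = e
    return recording.with_data(out)


# ---------------------------------------------------------------------------
# Epoching


def segment_epochs(recording: RawRecording,
                   window_ms: tuple[float, float] = (-100.0, 900.0),
                   baseline_ms: tuple[float, float] = (-100.0, 0.0),
                   ) -> tuple[list[Epoch], int]:
    """Cut one baseline-corrected epoch per analyzable marker.

    Analyzable conditions are standard/deviant tones and congruent/incongruent
    word targets (word primes carry condition ``none`` and are skipped).
    Epochs that would overlap a recording edge are dropped; the second return
    value counts them.
    """
    pre, post = window_ms
    b0, b1 = baseline_ms
    if not (pre < 0 < post):
        raise ValueError("epoch window must span the stimulus onset (pre < 0 < post)")
    if b0 < pre or b1 > post or b0 >= b1:
        raise ValueError("baseline interval must lie inside the epoch window")
    rate = recording.sample_rate
    i_pre = int(round(pre * rate / 1000.0))
    i_post = int(round(post * rate / 1000.0))
    n_ep = i_post - i_pre + 1
    times = pre + 1000.0 * np.arange(n_ep) / rate
    bmask = (times >= b0) & (times <= b1)

    epochs: list[Epoch] = []
    n_dropped = 0
    onsets = recording.marker_samples()
    for onset, cond in zip(onsets, recording.markers.conditions):
        if cond not in ("standard", "deviant", "congruent", "incongruent"):
            continue
        lo, hi = onset + i_pre, onset + i_post
        if lo < 0 or hi >= recording.n_samples:
            n_dropped += 1
            continue
        seg = recording.data[:, lo : hi + 1].copy()
        seg -= seg[:, bmask].mean(axis=1, keepdims=True)
        epochs.append(Epoch(cond, (pre, post), rate, list(recording.channels), seg))
    return epochs, n_dropped


def _baseline_correct(epoch: Epoch, baseline_ms: tuple[float, float]) -> None:
    t = epoch.times_ms
    bmask = (t >= baseline_ms[0]) & (t <= baseline_ms[1])
    epoch.data -= epoch.data[:, bmask].mean(axis=1, keepdims=True)


def denoise_epoch(epoch: Epoch, wavelet: str = "sym4", mode: str = "soft",
                  max_scale_ms: float = 16.0) -> Epoch:
    """Per-channel wavelet shrinkage with the universal threshold.

    The noise scale is estimated per channel from the median absolute
    deviation of the finest detail coefficients; detail coefficients are then
    soft-thresholded at sigma*sqrt(2 log N). Only detail levels with a
    timescale below ``max_scale_ms`` are thresholded — coarser levels carry
    the ERP morphology itself, and shrinking them would bias peak amplitudes
    downward in proportion to the noise. Epochs shorter than one
    decomposition length pass through unchanged.
    """
    n = epoch.data.shape[1]
    wav = pywt.Wavelet(wavelet)
    level = pywt.dwt_max_level(n, wav.dec_len)
    if level < 1:
        return epoch  # too short to decompose; pass through
    level = min(level, 5)
    # detail level j (1 = coarsest in wavedec order) spans ~2^j samples
    dt_ms = 1000.0 / epoch.sample_rate
    out = np.empty_like(epoch.data)
    for ci in range(epoch.data.shape[0]):
        coeffs = pywt.wavedec(epoch.data[ci], wav, level=level, mode="symmetric")
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if len(coeffs[-1]) else 0.0
        thr = sigma * math.sqrt(2.0 * math.log(max(n, 2)))
        den = [coeffs[0]]
        for k, c in enumerate(coeffs[1:], start=1):
            scale_ms = dt_ms * 2 ** (level - k + 1)
            if scale_ms <= max_scale_ms:
                with np.errstate(invalid="ignore", divide="ignore"):
                    c = pywt.threshold(c, thr, mode=mode)
            den.append(c)
        out[ci] = pywt.waverec(den, wav, mode="symmetric")[:n]
    return replace(epoch, data=out)


def reject_epochs(epochs: list[Epoch], threshold: float = 75.0) -> list[Epoch]:
    """Flag epochs whose scalp channels exceed +/-threshold uV anywhere.

    Epochs are flagged in place and all are kept in the list so that the
    rejection fraction can be computed for quality control.
    """
    if threshold <= 0:
        raise ValueError("rejection threshold must be positive")
    for ep in epochs:
        scalp = [i for i, c in enumerate(ep.channels) if c != EOG_CHANNEL]
        if np.max(np.abs(ep.data[scalp])) > threshold:
            ep.rejected = True
            ep.rejection_reason = f"amplitude above +/-{threshold:g} uV"
    return epochs


def qc_participant(epochs: list[Epoch], max_rejection: float = 0.25) -> tuple[str, float]:
    """Quality status from the epoch rejection fraction (strictly > 25% excludes)."""
    if not epochs:
        raise ValueError("quality control needs at least one epoch")
    frac = sum(ep.rejected for ep in epochs) / len(epochs)
    status = QC_EXCLUDED_QUALITY if frac > max_rejection else QC_INCLUDED
    return status, frac


# ---------------------------------------------------------------------------
# Averaging and peak measurement


def average_condition(epochs: list[Epoch], condition: str, electrode: str) -> AverageWaveform:
    """Pointwise mean over non-rejected epochs of one condition at one electrode."""
    keep = [ep for ep in epochs if ep.condition == condition and not ep.rejected]
    if not keep:
        raise ValueError(f"no usable epochs for condition {condition!r}")
    stack = np.stack([ep.channel(electrode) for ep in keep])
    return AverageWaveform(condition, electrode, keep[0].times_ms.copy(), stack.mean(axis=0), len(keep))


def find_peak(times_ms: np.ndarray, samples: np.ndarray, window_ms: tuple[float, float],
              polarity: int) -> tuple[float, float, bool]:
    """Most extreme interior local extremum of the given polarity in a window.

    Returns ``(amplitude_magnitude, latency_ms, edge_fallback)``. Candidates
    are samples inside the window that are local minima (polarity -1) or
    maxima (+1) of the full waveform; the most extreme wins, earliest latency
    breaking ties. With no interior extremum the window-edge extremum is
    returned and flagged.
    """
    s = polarity * np.asarray(samples, dtype=float)  # peak is now a maximum
    inside = np.flatnonzero((times_ms >= window_ms[0]) & (times_ms <= window_ms[1]))
    if inside.size == 0:
        raise ValueError("peak-search window contains no samples")
    cand = [i for i in inside
            if 0 < i < len(s) - 1 and s[i] >= s[i - 1] and s[i] >= s[i + 1]
            and (s[i] > s[i - 1] or s[i] > s[i + 1])]
    if cand:
        vals = s[cand]
        best = cand[int(np.argmax(vals))]  # argmax returns first = earliest on ties
        return abs(samples[best]), float(times_ms[best]), False
    best = inside[int(np.argmax(s[inside]))]
    return abs(samples[best]), float(times_ms[best]), True


def measure_peaks(waveforms: dict[str, AverageWaveform], config: PipelineConfig | None = None,
                  *, participant_id: str = "", session: int = 1,
                  fluent: bool = True) -> ErpMeasurementSet:
    """Measure the six brain vital signs from condition-average waveforms.

    ``waveforms`` maps keys ``"deviant@<electrode>"``, ``"congruent@<electrode>"``,
    ``"incongruent@<electrode>"`` to averages; the config's electrode map
    selects which are consulted per component. Missing inputs leave the
    corresponding measures as ``None``.
    """
    cfg = config or PipelineConfig()
    result = ErpMeasurementSet(participant_id=participant_id, session=session)

    for comp in COMPONENTS:
        el = cfg.electrodes[comp]
        if comp in ("n100", "p300"):
            wf = waveforms.get(f"deviant@{el}")
            if wf is None:
                continue
            times, samples = wf.times_ms, wf.samples
        else:
            if not fluent:
                result.qc = QC_N400_MISSING_LANGUAGE
                continue
            inc = waveforms.get(f"incongruent@{el}")
            if inc is None:
                continue
            if cfg.n400_mode == "difference":
                con = waveforms.get(f"congruent@{el}")
                if con is None:
                    continue
                times, samples = inc.times_ms, inc.samples - con.samples
            else:
                times, samples = inc.times_ms, inc.samples
        smooth_ms = cfg.detection_smooth_ms.get(comp, 0.0)
        if smooth_ms > 0:
            dt_ms = float(times[1] - times[0])
            detect_on = gaussian_filter1d(samples, smooth_ms / dt_ms, mode="nearest")
        else:
            detect_on = samples
        _, lat, fallback = find_peak(times, detect_on, cfg.windows_ms[comp], POLARITY[comp])
        amp = float(abs(samples[int(np.argmin(np.abs(times - lat)))]))
        setattr(result, f"{comp}_amplitude", amp)
        setattr(result, f"{comp}_latency", lat)
        result.edge_fallback[comp] = fallback
    return result


# ---------------------------------------------------------------------------
# End-to-end


def process_recording(recording: RawRecording, *, participant_id: str = "", session: int = 1,
                      fluent: bool = True, config: PipelineConfig | None = None,
                      ) -> ErpMeasurementSet:
    """Run the full extraction chain on one recording."""
    cfg = config or PipelineConfig()
    rec = bandpass_filter(recording, *cfg.band_hz, order=cfg.filter_order)
    if EOG_CHANNEL in rec.channels:
        rec = remove_ocular_artifacts(rec, order=cfg.nlms_order, step=cfg.nlms_step)
    epochs, _ = segment_epochs(rec, cfg.epoch_window_ms, cfg.baseline_ms)
    if not epochs:
        raise ValueError("recording contains no analyzable markers")
    epochs = [denoise_epoch(ep, cfg.wavelet, cfg.wavelet_mode, cfg.wavelet_max_scale_ms)
              for ep in epochs]
    for ep in epochs:
        _baseline_correct(ep, cfg.baseline_ms)
    reject_epochs(epochs, cfg.reject_threshold_uv)
    qc, frac = qc_participant(epochs, cfg.qc_max_rejection)

    waveforms: dict[str, AverageWaveform] = {}
    for cond in ("deviant", "congruent", "incongruent"):
        for el in set(cfg.electrodes.values()):
            try:
                waveforms[f"{cond}@{el}"] = average_condition(epochs, cond, el)
            except ValueError:
                pass
    result = measure_peaks(waveforms, cfg, participant_id=participant_id,
                           session=session, fluent=fluent)
    result.rejection_fraction = frac
    if qc == QC_EXCLUDED_QUALITY:
        result.qc = qc
    return result
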