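"""Band-pass filtering, segmentation, sub-band decomposition and timestep
splitting.

The analysis path is common to every dialect: a zero-phase Butterworth
band-pass (0.5–80 Hz by default), resampling to a 160 Hz analysis rate,
and a 4-level ``db4`` discrete wavelet transform whose dyadic bands then
fall exactly on the nominal table A4: 0.5–5, D4: 5–10, D3: 10–20,
D2: 20–40, D1: 40–80 Hz. For dual-channel segments the wavelet
coefficients of the two channels are averaged level by level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal as sps

from .types import Recording, Segment

__all__ = [
    "PreprocessConfig",
    "SubbandSet",
    "bandpass",
    "resample_to",
    "preprocess_signal",
    "segment_recording",
    "decompose_subbands",
    "split_timesteps",
    "NOMINAL_BANDS",
]

#: nominal band edges (Hz) of the public-data decomposition scheme
NOMINAL_BANDS: dict[str, tuple[float, float]] = {
    "A4": (0.5, 5.0),
    "D4": (5.0, 10.0),
    "D3": (10.0, 20.0),
    "D2": (20.0, 40.0),
    "D1": (40.0, 80.0),
}

SUBBAND_ORDER = ("A4", "D4", "D3", "D2", "D1")


@dataclass
class PreprocessConfig:
    """Analysis-path parameters.

    ``bandpass`` is the Butterworth pass band applied before the DWT
    (0.5–80 Hz for public-style data; clinical wide-band uses 0.5–256 Hz
    upstream while the common analysis path below 80 Hz is unchanged).
    ``analysis_fs`` is the rate everything is resampled to before the
    wavelet decomposition so that the dyadic bands match the nominal
    table; 160 Hz puts the Nyquist at the 80 Hz band top.
    """

    bandpass: tuple[float, float] = (0.5, 80.0)
    filter_order: int = 6
    window_seconds: float = 20.0
    n_timesteps: int = 4
    wavelet_name: str = "db4"
    analysis_fs: float = 160.0


@dataclass
class SubbandSet:
    """DWT coefficient arrays A4, D4, D3, D2, D1 with nominal band edges."""

    coeffs: dict[str, np.ndarray]
    band_edges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(NOMINAL_BANDS)
    )
    source_fs: float = 160.0

    def __post_init__(self) -> None:
        if set(self.coeffs) != set(SUBBAND_ORDER):
            raise ValueError(f"expected exactly the bands {SUBBAND_ORDER}")

    def energy(self) -> float:
        return float(sum(np.sum(c**2) for c in self.coeffs.values()))


def bandpass(segment: Segment, low: float, high: float, order: int = 6) -> Segment:
    """Zero-phase Butterworth band-pass, applied per channel."""
    nyq = segment.fs / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(
            f"band top {high} Hz violates the Nyquist limit {nyq} Hz at fs={segment.fs}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=segment.fs, output="sos")
    filtered = np.vstack([sps.sosfiltfilt(sos, ch) for ch in segment.samples])
    return Segment(
        samples=filtered,
        fs=segment.fs,
        label=segment.label,
        patient_id=segment.patient_id,
        lead_id=segment.lead_id,
        t_start=segment.t_start,
    )


def resample_to(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Polyphase resampling of a 1-D signal to ``target_fs``."""
    if abs(fs - target_fs) < 1e-9:
        return np.asarray(x, dtype=float)
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


def preprocess_signal(segment: Segment, cfg: PreprocessConfig) -> np.ndarray:
    """Channel-averaged, band-passed, resampled 1-D analysis signal."""
    bp = bandpass(segment, *cfg.bandpass, order=cfg.filter_order)
    return resample_to(bp.channel_mean(), segment.fs, cfg.analysis_fs)


def segment_recording(
    rec: Recording, window: float, stride: float | None = None
) -> list[Segment]:
    """Cut each lead into fixed-length windows.

    With ``stride == window`` (the default) the count per lead is
    ``floor(dur / window)``; with an overlapping stride it is
    ``fix((dur - window) / stride)``, matching the sliding-window count
    convention of the balance stage. Partial trailing windows are
    dropped; a window longer than the recording yields an empty list
    with a warning.
    """
    stride = window if stride is None else stride
    if stride <= 0:
        raise ValueError("stride must be positive")
    dur = rec.duration
    if window > dur:
        warnings.warn(
            f"window {window}s exceeds recording duration {dur:.1f}s", stacklevel=2
        )
        return []
    n_pts = int(round(window * rec.fs))
    if abs(stride - window) < 1e-12:
        n_win = int(np.floor(dur / window + 1e-9))
    else:
        n_win = int((dur - window) / stride + 1e-9)  # fix() toward zero
    from .types import Label, LeadClass

    segments: list[Segment] = []
    for ci, (lid, cls) in enumerate(zip(rec.lead_ids, rec.lead_class)):
        label = (
            Label.ES
            if cls is LeadClass.EPILEPTOGENIC
            else Label.NES
            if cls is LeadClass.NON_EPILEPTOGENIC
            else Label.UNKNOWN
        )
        for w in range(n_win):
            start = int(round(w * stride * rec.fs))
            if start + n_pts > rec.n_points:
                break
            segments.append(
                Segment(
                    samples=rec.samples[ci : ci + 1, start : start + n_pts],
                    fs=rec.fs,
                    label=label,
                    patient_id=rec.patient_id,
                    lead_id=lid,
                    t_start=start / rec.fs,
                )
            )
    return segments


def decompose_subbands(segment: Segment, cfg: PreprocessConfig | None = None) -> SubbandSet:
    """Resample to the analysis rate and apply a 4-level DWT.

    Uses periodized boundary handling so that, with an orthogonal
    wavelet, the summed squared coefficients equal the squared norm of
    the resampled signal (Parseval). Dual-channel segments are
    decomposed per channel and the coefficients averaged level-wise.
    """
    cfg = cfg or PreprocessConfig()
    min_len = 2**4 * pywt.Wavelet(cfg.wavelet_name).dec_len
    per_channel = []
    for ch in segment.samples:
        y = resample_to(ch, segment.fs, cfg.analysis_fs)
        if y.size < min_len:
            raise ValueError(
                f"segment too short for a 4-level {cfg.wavelet_name} decomposition"
            )
        per_channel.append(pywt.wavedec(y, cfg.wavelet_name, level=4, mode="periodization"))
    averaged = [
        np.mean([coeffs[i] for coeffs in per_channel], axis=0)
        for i in range(5)
    ]
    coeffs = dict(zip(SUBBAND_ORDER, averaged))  # wavedec order: cA4, cD4..cD1
    return SubbandSet(coeffs=coeffs, source_fs=cfg.analysis_fs)


def split_timesteps(segment: Segment, n: int) -> list[Segment]:
    """Partition a segment into ``n`` contiguous, non-overlapping timesteps."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if segment.n_points % n != 0:
        raise ValueError(f"{segment.n_points} points not divisible into {n} timesteps")
    step = segment.n_points // n
    return [
        Segment(
            samples=segment.samples[:, i * step : (i + 1) * step],
            fs=segment.fs,
            label=segment.label,
            patient_id=segment.patient_id,
            lead_id=segment.lead_id,
            t_start=segment.t_start + i * step / segment.fs,
        )
        for i in range(n)
    ]
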