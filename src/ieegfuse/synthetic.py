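"""Synthetic two-class iEEG-like signals and multi-lead SEEG-like sessions.

The generator produces a 1/f^beta Gaussian background for both classes.
Epileptogenic (ES) signals additionally carry interictal spike-wave
transients (Ricker pulses with jittered inter-event intervals) and
band-limited high-frequency-oscillation bursts (Gaussian-windowed
sinusoids), the two signal patterns most often cited as discriminative
of the seizure-onset zone. Non-epileptogenic (NES) signals are the
background alone. All randomness flows from one seeded generator per
call, so identical configurations give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import Label, LeadClass, Recording, Segment

__all__ = ["SynthConfig", "SynthSession", "generate_segment", "generate_session"]


@dataclass
class SynthConfig:
    """Parameters of a single synthetic segment.

    Defaults follow the dual-channel public-database dialect: 20 s at
    512 Hz (10,240 points). Contrast parameters (spike rate/amplitude,
    HFO band and burst rate) control how separable the two classes are.
    """

    sampling_rate: float = 512.0
    duration: float = 20.0
    class_label: Label = Label.NES
    background_exponent: float = 1.0
    spike_rate: float = 1.5  # events/s in ES signals
    spike_amplitude: float = 5.0  # multiples of background SD
    hfo_band: tuple[float, float] = (80.0, 150.0)
    hfo_burst_rate: float = 1.0  # bursts/s in ES signals
    hfo_amplitude: float = 1.5  # multiples of background SD
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.class_label, Label):
            self.class_label = Label(self.class_label)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.spike_rate < 0 or self.hfo_burst_rate < 0:
            raise ValueError("event rates must be non-negative")
        low, high = self.hfo_band
        if not (0 < low < high):
            raise ValueError("hfo_band must satisfy 0 < low < high")
        if self.sampling_rate <= 2 * high:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} must exceed twice the HFO "
                f"band upper edge {high} (Nyquist)"
            )


@dataclass
class SynthSession:
    """A multi-lead synthetic SEEG session with a minority of ES leads."""

    recording: Recording
    leads: list[str] = field(default_factory=list)
    epileptogenic_leads: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.leads:
            self.leads = list(self.recording.lead_ids)
        if len(self.epileptogenic_leads) >= len(self.leads):
            raise ValueError("epileptogenic leads must be a strict minority")


def _powerlaw_background(n: int, fs: float, beta: float, sd: float,
                         rng: np.random.Generator) -> np.ndarray:
    """1/f^beta Gaussian noise synthesized in the frequency domain."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def _ricker(width_samples: float, half_len: int) -> np.ndarray:
    """Mexican-hat pulse used as a spike-wave transient template."""
    t = np.arange(-half_len, half_len + 1, dtype=float)
    a = width_samples
    return (1 - (t / a) ** 2) * np.exp(-0.5 * (t / a) ** 2)


def _add_events(x: np.ndarray, fs: float, rate: float, template_fn, rng) -> None:
    """Superimpose templates at jittered inter-event intervals, in place."""
    n = x.size
    if rate <= 0:
        return
    mean_iei = fs / rate  # samples between events
    pos = mean_iei * rng.uniform(0.2, 1.0)
    while pos < n:
        tpl = template_fn()
        half = tpl.size // 2
        lo = int(pos) - half
        hi = lo + tpl.size
        a, b = max(lo, 0), min(hi, n)
        x[a:b] += tpl[a - lo : tpl.size - (hi - b)]
        pos += mean_iei * rng.uniform(0.5, 1.5)


def _one_channel(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(round(cfg.duration * cfg.sampling_rate))
    fs = cfg.sampling_rate
    x = _powerlaw_background(n, fs, cfg.background_exponent, cfg.noise_sd, rng)
    if cfg.class_label is Label.ES:
        bg_sd = x.std()

        def spike() -> np.ndarray:
            # ~70 ms spike followed by an implicit slow wave from the Ricker lobes
            width = 0.02 * fs * rng.uniform(0.8, 1.3)
            amp = cfg.spike_amplitude * bg_sd * rng.uniform(0.7, 1.3)
            sign = rng.choice([-1.0, 1.0])
            return sign * amp * _ricker(width, int(6 * width))

        def hfo() -> np.ndarray:
            f0 = rng.uniform(*cfg.hfo_band)
            n_cyc = rng.integers(6, 12)
            dur = n_cyc / f0
            m = int(dur * fs)
            t = np.arange(m) / fs
            env = np.exp(-0.5 * ((t - dur / 2) / (dur / 6)) ** 2)
            amp = cfg.hfo_amplitude * bg_sd * rng.uniform(0.7, 1.3)
            return amp * env * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))

        _add_events(x, fs, cfg.spike_rate, spike, rng)
        _add_events(x, fs, cfg.hfo_burst_rate, hfo, rng)
    return x


def generate_segment(cfg: SynthConfig, n_channels: int = 1) -> Segment:
    """Generate one synthetic segment (1 or 2 channels) from ``cfg``.

    Two channels share the event process statistics but are independent
    realizations, mimicking the paired focal/non-focal channel dialect.
    """
    rng = np.random.default_rng(cfg.seed)
    chans = [_one_channel(cfg, rng) for _ in range(n_channels)]
    return Segment(
        samples=np.vstack(chans),
        fs=cfg.sampling_rate,
        label=cfg.class_label,
    )


def generate_session(
    n_leads: int,
    n_epi: int,
    dur: float = 120.0,
    fs: float = 512.0,
    seed: int = 0,
    base_cfg: SynthConfig | None = None,
) -> SynthSession:
    """Generate a continuous multi-lead session.

    The first ``n_epi`` leads draw from the ES generator, the remaining
    majority from the NES generator, reproducing the lead imbalance of
    clinical SEEG (minority epileptogenic).
    """
    if n_epi >= n_leads:
        raise ValueError("n_epi must be strictly less than n_leads")
    if n_epi < 0:
        raise ValueError("n_epi must be non-negative")
    if base_cfg is None:
        # keep the default HFO band below Nyquist at low sampling rates
        lo, hi = 80.0, 150.0
        base = SynthConfig(
            sampling_rate=fs,
            duration=dur,
            hfo_band=(min(lo, 0.31 * fs), min(hi, 0.45 * fs)),
        )
    else:
        base = base_cfg
    root = np.random.default_rng(seed)
    lead_seeds = root.integers(0, 2**31 - 1, size=n_leads)
    samples = []
    lead_ids = []
    lead_cls = []
    for i in range(n_leads):
        is_epi = i < n_epi
        cfg = replace(
            base,
            sampling_rate=fs,
            duration=dur,
            class_label=Label.ES if is_epi else Label.NES,
            seed=int(lead_seeds[i]),
        )
        rng = np.random.default_rng(cfg.seed)
        samples.append(_one_channel(cfg, rng))
        lead_ids.append(f"L{i:03d}")
        lead_cls.append(
            LeadClass.EPILEPTOGENIC if is_epi else LeadClass.NON_EPILEPTOGENIC
        )
    rec = Recording(
        samples=np.vstack(samples),
        fs=fs,
        patient_id=f"synth{seed}",
        lead_ids=lead_ids,
        lead_class=lead_cls,
    )
    return SynthSession(
        recording=rec,
        leads=lead_ids,
        epileptogenic_leads=lead_ids[:n_epi],
    )
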