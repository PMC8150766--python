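"""Core in-memory containers: recordings, segments and lead classes."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Label(str, Enum):
    """Binary segment class: epileptogenic (ES) or non-epileptogenic (NES)."""

    ES = "ES"
    NES = "NES"
    UNKNOWN = "unknown"


class LeadClass(str, Enum):
    """Clinician-assigned class of a recording lead."""

    EPILEPTOGENIC = "epileptogenic"
    NON_EPILEPTOGENIC = "non-epileptogenic"
    EXCLUDED = "excluded"


@dataclass
class Segment:
    """A fixed-length window of one or two iEEG channels.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_points)
        Signal samples; one row per channel (two for the dual-channel
        focal/non-focal dialect).
    fs : float
        Sampling rate in Hz.
    label : Label
        ES, NES or unknown.
    patient_id, lead_id : str
        Provenance metadata (may be empty).
    t_start : float
        Offset in seconds of the window within its source recording.
    """

    samples: np.ndarray
    fs: float
    label: Label = Label.UNKNOWN
    patient_id: str = ""
    lead_id: str = ""
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[0] not in (1, 2):
            raise ValueError("Segment expects 1 or 2 channels")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not isinstance(self.label, Label):
            self.label = Label(self.label)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_points(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_points / self.fs

    def channel_mean(self) -> np.ndarray:
        """Average across channels (identity for single-channel segments)."""
        return self.samples.mean(axis=0)


@dataclass
class Recording:
    """A continuous multi-channel recording with per-lead class labels."""

    samples: np.ndarray  # (n_channels, n_points)
    fs: float
    patient_id: str = ""
    lead_ids: list[str] = field(default_factory=list)
    lead_class: list[LeadClass] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.samples.shape[0]
        if not self.lead_ids:
            self.lead_ids = [f"ch{i}" for i in range(n)]
        if len(self.lead_ids) != n:
            raise ValueError("lead_ids length must match channel count")
        if len(set(self.lead_ids)) != n:
            raise ValueError("lead_ids must be unique")
        if not self.lead_class:
            self.lead_class = [LeadClass.NON_EPILEPTOGENIC] * n
        self.lead_class = [LeadClass(c) for c in self.lead_class]
        if len(self.lead_class) != n:
            raise ValueError("lead_class length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_points(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_points / self.fs

    def drop_excluded(self) -> "Recording":
        """Return a copy without leads marked excluded (bad / functional-area)."""
        keep = [i for i, c in enumerate(self.lead_class) if c is not LeadClass.EXCLUDED]
        return Recording(
            samples=self.samples[keep],
            fs=self.fs,
            patient_id=self.patient_id,
            lead_ids=[self.lead_ids[i] for i in keep],
            lead_class=[self.lead_class[i] for i in keep],
        )
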