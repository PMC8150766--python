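"""Lead-imbalance resampling.

Clinical SEEG sessions have many more non-epileptogenic (majority,
``M``) leads than epileptogenic (minority, ``N``) leads. The minority
leads are re-segmented with an overlapping sliding window whose stride
is ``S * N / M`` rounded to the nearest multiple of 0.5 s (clamped to
[0.5, S]), while majority leads keep non-overlapping ``S``-second
windows, so the pooled two-class segment counts come out near-equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .preprocess import segment_recording
from .types import LeadClass, Recording, Segment

__all__ = ["BalancePlan", "compute_slidsize", "count_segments", "balance_dataset"]

log = logging.getLogger(__name__)


@dataclass
class BalancePlan:
    """Bookkeeping of one balancing run."""

    M: int  # majority (non-epileptogenic) lead count
    N: int  # minority (epileptogenic) lead count
    S: float  # segment seconds
    slidsize: float  # minority stride, seconds
    dur: float  # per-lead duration, seconds
    n_nonoverlap: int  # segments per majority lead
    m_sliding: int  # segments per minority lead


def compute_slidsize(M: int, N: int, S: float) -> float:
    """Sliding-window stride ``S*N/M`` snapped to the 0.5 s grid.

    The snap keeps every window start on a whole- or half-second
    boundary; the result is clamped to [0.5, S].
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if M <= N:
        raise ValueError("resampling applies only when M > N")
    if S <= 0:
        raise ValueError("S must be positive")
    raw = S * N / M
    snapped = round(raw / 0.5) * 0.5
    return float(min(max(snapped, 0.5), S))


def count_segments(dur: float, S: float, slidsize: float) -> tuple[int, int]:
    """Per-lead segment counts.

    Returns ``(n_nonoverlap, m_sliding)`` where ``n = floor(dur/S)`` is
    the non-overlapping count and ``m = fix((dur - S)/slidsize)`` the
    sliding-window count (``fix`` truncates toward zero).
    """
    if dur < S:
        return (0, 0)
    n = int(dur / S + 1e-9)
    m = int((dur - S) / slidsize + 1e-9)
    return (n, m)


def balance_dataset(
    rec: Recording, S: float
) -> tuple[list[Segment], BalancePlan]:
    """Segment a labelled session so ES and NES counts are near-equal.

    Majority (non-epileptogenic) leads are segmented with non-overlapping
    ``S``-second windows; minority (epileptogenic) leads with an
    overlapping window of stride :func:`compute_slidsize`. Leads shorter
    than ``S`` contribute nothing (logged). When ``M == N`` no resampling
    is needed and both classes are segmented non-overlapping.
    """
    rec = rec.drop_excluded()
    epi = [i for i, c in enumerate(rec.lead_class) if c is LeadClass.EPILEPTOGENIC]
    non = [i for i, c in enumerate(rec.lead_class) if c is LeadClass.NON_EPILEPTOGENIC]
    if not epi:
        raise ValueError("no epileptogenic lead present; nothing to balance")
    M, N = len(non), len(epi)
    dur = rec.duration
    slidsize = compute_slidsize(M, N, S) if M > N else S
    n_no, m_sl = count_segments(dur, S, slidsize)
    if dur < S:
        log.warning("per-lead duration %.1fs below segment size %.1fs", dur, S)

    def sub(indices: list[int]) -> Recording:
        return Recording(
            samples=rec.samples[indices],
            fs=rec.fs,
            patient_id=rec.patient_id,
            lead_ids=[rec.lead_ids[i] for i in indices],
            lead_class=[rec.lead_class[i] for i in indices],
        )

    segments: list[Segment] = []
    if non:
        segments.extend(segment_recording(sub(non), window=S, stride=S))
    minority_stride = slidsize if M > N else S
    segments.extend(segment_recording(sub(epi), window=S, stride=minority_stride))
    plan = BalancePlan(
        M=M, N=N, S=S, slidsize=slidsize, dur=dur,
        n_nonoverlap=n_no, m_sliding=m_sl if M > N else n_no,
    )
    return segments, plan
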