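"""Readers and writers for the three data dialects.

Supported formats:

* dual-channel comma-separated ASCII (the public focal/non-focal
  database dialect; 512 Hz, 10,240 rows per 20 s segment),
* single-column ASCII (the single-channel public dialect; 173.61 Hz),
* EDF for continuous multi-channel clinical sessions, with a two-column
  ``lead_id,class`` CSV assigning each lead to epileptogenic /
  non-epileptogenic / excluded.

EDF is read through :mod:`mne`; writing uses a minimal in-package
16-bit EDF encoder so synthetic sessions can be round-tripped without
any additional dependency.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import Label, LeadClass, Recording, Segment

__all__ = [
    "read_bern_barcelona",
    "write_bern_barcelona",
    "read_bonn",
    "write_bonn",
    "read_edf",
    "write_edf",
    "read_lead_table",
    "write_lead_table",
    "LeadReconciliation",
]

BONN_FS = 173.61
BB_FS = 512.0

#: default filename rule: a standalone F token means ES (focal), N means NES
DEFAULT_LABEL_PATTERN = r"(?:^|[_\-.])([FN])"


def _label_from_name(name: str, pattern: str) -> Label:
    m = re.search(pattern, Path(name).stem, flags=re.IGNORECASE)
    if not m:
        return Label.UNKNOWN
    return Label.ES if m.group(1).upper() == "F" else Label.NES


def _read_ascii_matrix(path: str | Path, n_cols: int) -> np.ndarray:
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter="," if n_cols == 2 else None, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric token in {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty segment file: {path}")
    if data.shape[1] != n_cols:
        raise ValueError(
            f"{path}: expected {n_cols} column(s), found {data.shape[1]}"
        )
    return data


def read_bern_barcelona(
    path: str | Path,
    fs: float = BB_FS,
    expected_points: int | None = 10240,
    label_pattern: str = DEFAULT_LABEL_PATTERN,
) -> Segment:
    """Read a dual-channel comma-separated ASCII segment.

    The class label is taken from the filename via ``label_pattern``
    (default: a standalone ``F`` token means ES, ``N`` means NES). A row
    count different from ``expected_points`` raises a warning but the
    segment is still returned with its actual length — the reader never
    truncates.
    """
    data = _read_ascii_matrix(path, 2)
    if expected_points is not None and data.shape[0] != expected_points:
        warnings.warn(
            f"{path}: {data.shape[0]} rows, expected {expected_points}",
            stacklevel=2,
        )
    return Segment(samples=data.T, fs=fs, label=_label_from_name(str(path), label_pattern))


def write_bern_barcelona(segment: Segment, path: str | Path, fmt: str = "%.6f") -> None:
    """Write a dual-channel segment as two comma-separated ASCII columns."""
    if segment.n_channels != 2:
        raise ValueError("dual-channel dialect requires exactly 2 channels")
    np.savetxt(path, segment.samples.T, fmt=fmt, delimiter=",")


def read_bonn(
    path: str | Path,
    fs: float = BONN_FS,
    label_pattern: str = DEFAULT_LABEL_PATTERN,
) -> Segment:
    """Read a single-column ASCII segment (subset F -> ES, subset N -> NES)."""
    data = _read_ascii_matrix(path, 1)
    return Segment(samples=data.T, fs=fs, label=_label_from_name(str(path), label_pattern))


def write_bonn(segment: Segment, path: str | Path, fmt: str = "%.6f") -> None:
    if segment.n_channels != 1:
        raise ValueError("single-channel dialect requires exactly 1 channel")
    np.savetxt(path, segment.samples.T, fmt=fmt)


# ---------------------------------------------------------------------------
# EDF


def _fit8(value: float) -> str:
    """Render a float into at most 8 ASCII chars, parseable back."""
    for spec in (".6g", ".5g", ".4g", ".3g", ".2g"):
        s = format(value, spec)
        if len(s) <= 8:
            return s
    return format(value, ".1g")[:8]


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    The sampling rate must be an integer and the recording an integer
    number of seconds long (true for all synthetic sessions). Physical
    units are microvolts; per-channel physical min/max are derived from
    the data, so round-trip error is bounded by the 16-bit quantization
    step ``(max - min) / 65535``.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_pts = rec.samples.shape
    if n_pts % fs != 0:
        raise ValueError("EDF writer requires an integer number of seconds")
    n_rec = n_pts // fs

    phys_min_s, phys_max_s, scaled = [], [], []
    for ch in rec.samples:
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            hi = lo + 1.0
        lo_s, hi_s = _fit8(lo), _fit8(hi)
        lo_v, hi_v = float(lo_s), float(hi_s)
        if hi_v <= lo_v:
            hi_v = lo_v + 1.0
            hi_s = _fit8(hi_v)
        gain = 65535.0 / (hi_v - lo_v)
        dig = np.clip(np.round((ch - lo_v) * gain) - 32768, -32768, 32767)
        phys_min_s.append(lo_s)
        phys_max_s.append(hi_s)
        scaled.append(dig.astype("<i2"))

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad(rec.patient_id or "X", 80),
            pad("Startdate 01-JAN-2020", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        ("label", 16, [f"EEG {lid}"[:16] for lid in rec.lead_ids]),
        ("transducer", 80, [""] * n_ch),
        ("dim", 8, ["uV"] * n_ch),
        ("pmin", 8, phys_min_s),
        ("pmax", 8, phys_max_s),
        ("dmin", 8, ["-32768"] * n_ch),
        ("dmax", 8, ["32767"] * n_ch),
        ("prefilter", 80, [""] * n_ch),
        ("spr", 8, [str(fs)] * n_ch),
        ("reserved", 32, [""] * n_ch),
    ]
    sig_header = b"".join(
        pad(v, width) for _, width, values in fields for v in values
    )

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            for ch in scaled:
                fh.write(ch[r * fs : (r + 1) * fs].tobytes())


@dataclass
class LeadReconciliation:
    """Differences between the lead table and the channels found in an EDF."""

    missing_in_edf: list[str] = field(default_factory=list)
    unlisted_in_table: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def read_lead_table(path: str | Path) -> dict[str, LeadClass]:
    """Read a two-column ``lead_id,class`` CSV (header optional)."""
    table: dict[str, LeadClass] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("lead_id", "lead", ""):
                continue
            table[row[0].strip()] = LeadClass(row[1].strip())
    return table


def write_lead_table(table: dict[str, LeadClass], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lead_id", "class"])
        for lid, cls in table.items():
            w.writerow([lid, cls.value])


def _strip_prefix(name: str) -> str:
    return re.sub(r"^EEG\s+", "", name).strip()


def read_edf(
    edf_path: str | Path,
    lead_table: str | Path | dict[str, LeadClass] | None = None,
    patient_id: str = "",
) -> tuple[Recording, LeadReconciliation]:
    """Read an EDF session and attach per-lead classes.

    Leads marked ``excluded`` in the table (bad leads, functional-area
    electrodes) are dropped from the returned recording. Table entries
    with no matching EDF channel are reported in the reconciliation
    object, not raised.
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne yields volts; files are written in uV
    lead_ids = [_strip_prefix(n) for n in raw.ch_names]
    table: dict[str, LeadClass]
    if lead_table is None:
        table = {}
    elif isinstance(lead_table, dict):
        table = dict(lead_table)
    else:
        table = read_lead_table(lead_table)

    report = LeadReconciliation(
        missing_in_edf=[lid for lid in table if lid not in lead_ids],
        unlisted_in_table=[lid for lid in lead_ids if table and lid not in table],
    )
    classes = [table.get(lid, LeadClass.NON_EPILEPTOGENIC) for lid in lead_ids]
    rec = Recording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        patient_id=patient_id,
        lead_ids=lead_ids,
        lead_class=classes,
    )
    report.excluded = [
        lid for lid, c in zip(lead_ids, classes) if c is LeadClass.EXCLUDED
    ]
    return rec.drop_excluded(), report
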