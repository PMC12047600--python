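"""Reading and writing RR-interval (RRI) series and cohort manifests.

An RRI series is the universal input of the package: the sequence of
interbeat intervals of one subject, in milliseconds, together with the
cumulative beat times in seconds and the subject's clinical metadata
(group label, optional NYHA class, optional sinus-rhythm fraction).

Two on-disk formats are supported natively:

``plain_ms`` (``.rri``)
    One interval per line in milliseconds, ASCII.  Metadata travels in
    ``# key: value`` comment lines at the top of the file.

``csv``
    Two columns ``t_s`` (cumulative time, seconds) and ``rri_ms``
    (interval, milliseconds), plus the same comment header.

A third format, ``wfdb_ann`` (PhysioNet WFDB beat annotations), is an
optional adapter that requires the ``wfdb`` package.
"""
from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "NYHA_CLASSES",
    "RRISeries",
    "ManifestEntry",
    "CohortManifest",
    "read_rri",
    "write_rri",
    "read_manifest",
    "write_manifest",
    "RRIParseError",
    "RRIValidationError",
]

#: Tolerance (seconds) for consistency between stored cumulative times and
#: the re-accumulated intervals; absorbs decimal rounding in text files.
TIME_CONSISTENCY_TOL_S = 1e-3

NYHA_CLASSES = ("I", "II", "III", "IV")


class RRIParseError(ValueError):
    """A file could not be parsed as an RRI series or manifest."""


class RRIValidationError(ValueError):
    """Parsed data violates the RRI series / manifest invariants."""


class Group(str, enum.Enum):
    """Subject group label."""

    HEALTHY = "healthy"
    CHF = "chf"
    AF = "af"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "Group":
        normalized = str(text).strip().lower()
        try:
            return cls(normalized)
        except ValueError:
            raise RRIValidationError(
                f"unknown group label {text!r}; expected one of "
                f"{[g.value for g in cls]}"
            ) from None


@dataclass(frozen=True)
class RRISeries:
    """One subject's interbeat-interval sequence with metadata.

    Parameters
    ----------
    subject_id
        Identifier, unique within a cohort.
    intervals
        Positive RR intervals in milliseconds, length >= 2.
    times
        Cumulative beat times in seconds; ``times[k] == sum(intervals[:k+1]) / 1000``.
    group
        Clinical group label.
    nyha
        Optional NYHA functional class ("I".."IV"), CHF subjects only.
    sr_fraction
        Optional fraction of the recording spent in sinus rhythm, in [0, 1].
    """

    subject_id: str
    intervals: np.ndarray
    times: np.ndarray
    group: Group = Group.UNKNOWN
    nyha: Optional[str] = None
    sr_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        object.__setattr__(self, "times", times)
        if intervals.ndim != 1 or times.ndim != 1:
            raise RRIValidationError("intervals and times must be 1-D")
        if intervals.size < 2:
            raise RRIValidationError("an RRI series needs at least 2 beats")
        if intervals.size != times.size:
            raise RRIValidationError("intervals and times differ in length")
        if not np.all(np.isfinite(intervals)) or not np.all(intervals > 0):
            raise RRIValidationError("all intervals must be positive and finite")
        if np.any(np.diff(times) <= 0):
            raise RRIValidationError("times must be strictly increasing")
        expected = np.cumsum(intervals) / 1000.0
        expected += times[0] - expected[0]
        if np.max(np.abs(times - expected)) > TIME_CONSISTENCY_TOL_S:
            raise RRIValidationError(
                "times are inconsistent with the cumulative sum of intervals"
            )
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group.parse(self.group))
        if self.nyha is not None and self.nyha not in NYHA_CLASSES:
            raise RRIValidationError(f"invalid NYHA class {self.nyha!r}")
        if self.sr_fraction is not None and not (0.0 <= self.sr_fraction <= 1.0):
            raise RRIValidationError("sr_fraction must lie in [0, 1]")

    @classmethod
    def from_intervals(
        cls,
        subject_id: str,
        intervals: Sequence[float],
        group: Group | str = Group.UNKNOWN,
        nyha: Optional[str] = None,
        sr_fraction: Optional[float] = None,
    ) -> "RRISeries":
        """Build a series from intervals alone, reconstructing cumulative times."""
        intervals = np.asarray(intervals, dtype=float)
        times = np.cumsum(intervals) / 1000.0
        return cls(
            subject_id=subject_id,
            intervals=intervals,
            times=times,
            group=group if isinstance(group, Group) else Group.parse(group),
            nyha=nyha,
            sr_fraction=sr_fraction,
        )

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0] + self.intervals[0] / 1000.0)

    def with_metadata(self, **kwargs) -> "RRISeries":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    subject_id: str
    group: Group
    nyha: Optional[str] = None
    sr_fraction: Optional[float] = None


@dataclass
class CohortManifest:
    """Listing of the subjects in a cohort and where their series live."""

    entries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.subject_id for e in self.entries]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise RRIValidationError(f"duplicate subject_id(s) in manifest: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def subjects(self, group: Optional[Group] = None) -> list:
        if group is None:
            return list(self.entries)
        return [e for e in self.entries if e.group == group]


# ---------------------------------------------------------------------------
# series I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("subject_id", "group", "nyha", "sr_fraction")


def _format_from_path(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".rri", ".txt"):
        return "plain_ms"
    if ext == ".csv":
        return "csv"
    raise RRIParseError(f"cannot infer RRI format from extension of {path!r}")


def _parse_header(lines: list) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" not in body:
            continue
        key, _, value = body.partition(":")
        key, value = key.strip(), value.strip()
        if key in _META_KEYS and value not in ("", "None"):
            meta[key] = value
    if "sr_fraction" in meta:
        meta["sr_fraction"] = float(meta["sr_fraction"])
    if "group" in meta:
        meta["group"] = Group.parse(meta["group"])
    return meta


def read_rri(path: str, format: Optional[str] = None) -> RRISeries:
    """Read one subject's RRI series from disk.

    Parameters
    ----------
    path
        File to read.
    format
        One of ``plain_ms``, ``csv``, ``wfdb_ann``; inferred from the file
        extension when omitted.

    Returns
    -------
    RRISeries
        With cumulative times reconstructed from the intervals when the
        format does not store them.
    """
    if format is None:
        format = _format_from_path(path)
    if format == "plain_ms":
        return _read_plain(path)
    if format == "csv":
        return _read_csv(path)
    if format == "wfdb_ann":
        return _read_wfdb(path)
    raise RRIParseError(f"unsupported RRI format {format!r}")


def _read_plain(path: str) -> RRISeries:
    header, values = [], []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header.append(line)
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise RRIParseError(
                    f"{path}: malformed line {lineno}: {line!r}"
                ) from None
    if not values:
        raise RRIParseError(f"{path}: no intervals")
    meta = _parse_header(header)
    meta.setdefault("subject_id", os.path.splitext(os.path.basename(path))[0])
    intervals = np.asarray(values, dtype=float)
    if np.any(intervals <= 0):
        bad = int(np.flatnonzero(intervals <= 0)[0])
        raise RRIValidationError(f"{path}: non-positive interval at beat {bad}")
    return RRISeries.from_intervals(intervals=intervals, **meta)


def _read_csv(path: str) -> RRISeries:
    header = []
    with open(path, "r") as fh:
        for line in fh:
            if line.startswith("#"):
                header.append(line)
            else:
                break
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RRIParseError(f"{path}: not parseable as CSV ({exc})") from exc
    for col in ("t_s", "rri_ms"):
        if col not in frame.columns:
            raise RRIParseError(f"{path}: missing required column {col!r}")
    if len(frame) == 0:
        raise RRIParseError(f"{path}: no intervals")
    meta = _parse_header(header)
    meta.setdefault("subject_id", os.path.splitext(os.path.basename(path))[0])
    intervals = frame["rri_ms"].to_numpy(dtype=float)
    times = frame["t_s"].to_numpy(dtype=float)
    if np.any(intervals <= 0):
        bad = int(np.flatnonzero(intervals <= 0)[0])
        raise RRIValidationError(f"{path}: non-positive interval at beat {bad}")
    return RRISeries(intervals=intervals, times=times, **meta)


def _read_wfdb(path: str) -> RRISeries:
    try:
        import wfdb  # type: ignore
    except ImportError:
        raise ImportError(
            "reading WFDB annotations requires the optional 'wfdb' package "
            "(pip install ddfa-hrv[wfdb])"
        ) from None
    record, _, ext = path.rpartition(".")
    ann = wfdb.rdann(record, ext)
    samples = np.asarray(ann.sample, dtype=float)
    if samples.size < 3:
        raise RRIParseError(f"{path}: too few annotations")
    intervals = np.diff(samples) / float(ann.fs) * 1000.0
    if np.any(intervals <= 0):
        raise RRIValidationError(f"{path}: non-positive interval from annotations")
    return RRISeries.from_intervals(os.path.basename(record), intervals)


def _header_lines(series: RRISeries) -> list:
    lines = [
        f"# subject_id: {series.subject_id}",
        f"# group: {series.group.value}",
    ]
    if series.nyha is not None:
        lines.append(f"# nyha: {series.nyha}")
    if series.sr_fraction is not None:
        lines.append(f"# sr_fraction: {series.sr_fraction!r}")
    return lines


def write_rri(series: RRISeries, path: str, format: Optional[str] = None) -> None:
    """Write a series to disk; round-trips intervals to better than 1e-6 ms."""
    if format is None:
        format = _format_from_path(path)
    if format == "plain_ms":
        with open(path, "w") as fh:
            fh.write("\n".join(_header_lines(series)) + "\n")
            np.savetxt(fh, series.intervals, fmt="%.9f")
    elif format == "csv":
        with open(path, "w") as fh:
            fh.write("\n".join(_header_lines(series)) + "\n")
            fh.write("t_s,rri_ms\n")
            for t, x in zip(series.times, series.intervals):
                fh.write(f"{t:.9f},{x:.9f}\n")
    else:
        raise RRIParseError(f"unsupported write format {format!r}")


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def read_manifest(path: str) -> CohortManifest:
    """Read a cohort manifest CSV (columns: path, subject_id, group, nyha, sr_fraction)."""
    frame = pd.read_csv(path, comment="#")
    for col in ("path", "subject_id", "group"):
        if col not in frame.columns:
            raise RRIParseError(f"{path}: manifest missing column {col!r}")
    entries = []
    for _, row in frame.iterrows():
        nyha = row.get("nyha")
        if pd.isna(nyha) or nyha is None:
            nyha = None
        else:
            nyha = str(nyha).strip().upper()
            if nyha not in NYHA_CLASSES:
                raise RRIValidationError(f"{path}: invalid NYHA class {nyha!r}")
        sr = row.get("sr_fraction")
        sr = None if (sr is None or pd.isna(sr)) else float(sr)
        entries.append(
            ManifestEntry(
                path=str(row["path"]),
                subject_id=str(row["subject_id"]).strip(),
                group=Group.parse(row["group"]),
                nyha=nyha,
                sr_fraction=sr,
            )
        )
    return CohortManifest(entries=entries)


def write_manifest(manifest: CohortManifest, path: str) -> None:
    rows = [
        {
            "path": e.path,
            "subject_id": e.subject_id,
            "group": e.group.value,
            "nyha": e.nyha,
            "sr_fraction": e.sr_fraction,
        }
        for e in manifest.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
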