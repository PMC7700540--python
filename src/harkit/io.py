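"""Readers and writers for raw-signal text formats and feature tables.

The raw accelerometer dialect is the WISDM-style line format
``user,activity,timestamp,x,y,z;`` — comma separated, optional trailing
semicolon, known to contain blank and corrupt lines which are skipped
and counted rather than failing the parse.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import RawRecord, SignalStream, FeatureVector, RunConfig

log = logging.getLogger(__name__)

#: streams are split where the timestamp gap exceeds this multiple of the median gap
GAP_SPLIT_FACTOR = 10.0


def parse_wisdm_line(line: str) -> RawRecord | None:
    """Parse one raw text line; return None for blank or corrupt lines."""
    line = line.strip().rstrip(";").rstrip(",").strip()
    if not line:
        return None
    parts = [p.strip() for p in line.split(",")]
    if len(parts) != 6:
        return None
    try:
        ts = int(float(parts[2]))
        x, y, z = float(parts[3]), float(parts[4]), float(parts[5])
    except ValueError:
        return None
    if ts < 0 or not all(np.isfinite(v) for v in (x, y, z)):
        return None
    if not parts[0] or not parts[1]:
        return None
    return RawRecord(parts[0], parts[1], ts, x, y, z)


def _infer_rate(timestamps: np.ndarray, fallback: float) -> float:
    """Median-gap sampling rate; fall back when timestamps are degenerate.

    Timestamps are interpreted as nanoseconds when the median gap is
    large enough to be a nanosecond period (> 1e4), else device ticks at
    the fallback rate.
    """
    if len(timestamps) < 2:
        return fallback
    gaps = np.diff(timestamps.astype(float))
    gaps = gaps[gaps > 0]
    if len(gaps) == 0:
        return fallback
    med = float(np.median(gaps))
    if med > 1e4:  # nanosecond timestamps
        return 1e9 / med
    return fallback


def _records_to_streams(
    records: Sequence[RawRecord], fallback_rate: float
) -> list[SignalStream]:
    """Group records into streams at subject/label changes and large time gaps."""
    streams: list[SignalStream] = []
    if not records:
        return streams

    # median gap over the whole file, used for the split threshold
    all_ts = np.array([r.timestamp for r in records], dtype=float)
    gaps = np.diff(all_ts)
    gaps = gaps[gaps > 0]
    med_gap = float(np.median(gaps)) if len(gaps) else 0.0

    def flush(group: list[RawRecord]) -> None:
        ts = np.array([r.timestamp for r in group])
        rate = _infer_rate(ts, fallback_rate)
        streams.append(
            SignalStream(
                samples=np.array([[r.x, r.y, r.z] for r in group]),
                sampling_rate=rate,
                subject_id=group[0].subject_id,
                activity_label=group[0].activity_label,
            )
        )

    group = [records[0]]
    for rec in records[1:]:
        prev = group[-1]
        gap = rec.timestamp - prev.timestamp
        boundary = (
            rec.subject_id != prev.subject_id
            or rec.activity_label != prev.activity_label
            or (med_gap > 0 and gap > GAP_SPLIT_FACTOR * med_gap)
        )
        if boundary:
            flush(group)
            group = [rec]
        else:
            group.append(rec)
    flush(group)
    return streams


def read_wisdm_raw(
    path: str | Path, config: RunConfig | None = None
) -> list[SignalStream]:
    """Read a raw WISDM-style text file into labeled signal streams.

    Returns one stream per contiguous same-subject, same-label run;
    runs are additionally split where the timestamp gap exceeds 10x the
    file's median gap. Corrupt lines are skipped and counted in a log
    message. Raises ``ValueError`` when no line parses.
    """
    config = config or RunConfig()
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise OSError(f"cannot read raw signal file {path}: {exc}") from exc

    records: list[RawRecord] = []
    n_bad = 0
    for line in lines:
        rec = parse_wisdm_line(line)
        if rec is None:
            if line.strip():
                n_bad += 1
            continue
        records.append(rec)
    if n_bad:
        log.warning("skipped %d corrupt lines in %s", n_bad, path)
    if not records:
        raise ValueError(f"no parseable records in {path}")
    return _records_to_streams(records, config.sampling_rate)


def write_wisdm_raw(streams: Sequence[SignalStream], path: str | Path) -> None:
    """Serialize streams back to the raw text dialect (one line per sample)."""
    path = Path(path)
    lines = []
    t = 0
    for s in streams:
        period_ns = int(round(1e9 / s.sampling_rate))
        for x, y, z in s.samples:
            lines.append(
                f"{s.subject_id or '0'},{s.activity_label or 'Unknown'},"
                f"{t},{float(x)!r},{float(y)!r},{float(z)!r};"
            )
            t += period_ns
    path.write_text("\n".join(lines) + "\n")


def read_csv_imu(path: str | Path, config: RunConfig | None = None) -> list[SignalStream]:
    """Read a generic IMU CSV with header ``t,x,y,z[,sensor,placement,label]``.

    Consecutive rows sharing the same label (and sensor/placement where
    present) form one stream; metadata columns are optional and default
    to the config values.
    """
    config = config or RunConfig()
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    missing = [ax for ax in ("x", "y", "z") if ax not in cols]
    if missing:
        raise ValueError(
            f"CSV {path} is missing required columns {missing}; found {list(df.columns)}"
        )

    meta_cols = [c for c in ("label", "sensor", "placement", "subject") if c in cols]
    if meta_cols:
        key = df[[cols[c] for c in meta_cols]].astype(str).agg("|".join, axis=1)
        block = (key != key.shift()).cumsum()
    else:
        block = pd.Series(1, index=df.index)

    streams = []
    for _, sub in df.groupby(block, sort=False):
        first = sub.iloc[0]
        streams.append(
            SignalStream(
                samples=sub[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float),
                sampling_rate=config.sampling_rate,
                sensor_kind=str(first[cols["sensor"]]) if "sensor" in cols else "accelerometer",
                placement=str(first[cols["placement"]]) if "placement" in cols else "unspecified",
                subject_id=str(first[cols["subject"]]) if "subject" in cols else "",
                activity_label=str(first[cols["label"]]) if "label" in cols else None,
            )
        )
    return streams


def write_csv_imu(streams: Sequence[SignalStream], path: str | Path) -> None:
    """Write streams as a ``t,x,y,z,label`` CSV."""
    rows = []
    for s in streams:
        t = np.arange(len(s)) / s.sampling_rate
        for i in range(len(s)):
            rows.append(
                {
                    "t": t[i],
                    "x": s.samples[i, 0],
                    "y": s.samples[i, 1],
                    "z": s.samples[i, 2],
                    "label": s.activity_label or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_feature_table(vectors: Sequence[FeatureVector], path: str | Path) -> None:
    """Write feature vectors as CSV: one header row of names plus ``label``."""
    if not vectors:
        raise ValueError("no feature vectors to write")
    names = vectors[0].names
    for v in vectors:
        if v.names != names:
            raise ValueError("feature vectors have inconsistent feature names")
    df = pd.DataFrame([v.values for v in vectors], columns=names)
    df["label"] = [v.label if v.label is not None else "" for v in vectors]
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> list[FeatureVector]:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, keep_default_na=False)
    if "label" not in df.columns:
        raise ValueError(f"feature table {path} lacks a 'label' column")
    names = [c for c in df.columns if c != "label"]
    return [
        FeatureVector(
            names=list(names),
            values=row[names].to_numpy(dtype=float),
            label=str(row["label"]) if row["label"] != "" else None,
        )
        for _, row in df.iterrows()
    ]


def table_to_arrays(vectors: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack feature vectors into (X, y, names) for the learning stages."""
    if not vectors:
        raise ValueError("empty feature table")
    names = vectors[0].names
    X = np.vstack([v.values for v in vectors])
    y = np.array([v.label if v.label is not None else "" for v in vectors])
    return X, y, list(names)
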