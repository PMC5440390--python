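"""CSV readers/writers for epoch counts, diaries, and result tables.

Two epoch dialects are supported:

* ``tidy`` — columns ``participant_id, timestamp, vm_counts`` (ISO 8601
  timestamps at minute resolution), any number of participants per file;
* ``actigraph_export`` — a single-participant vendor-style export: a free-form
  preamble followed by a column header containing either a ``Vector Magnitude``
  column or ``Axis1/Axis2/Axis3`` columns (collapsed to vector magnitude on
  read).  The reader keys on column names, not on a fixed preamble length;
  when rows carry no timestamp the preamble must state ``Start Date`` and
  ``Start Time``.

Timestamps are naive local times.  Within a participant they must increase
strictly; a spacing other than one epoch starts a new contiguous segment, so
zero runs can never span recording gaps.

Diaries use one row per record: ``participant_id, record_type`` (``phase`` or
``nwt``), ``kind`` (``waking``/``sleeping`` for phases), ``start``, ``end``,
``reason`` (non-wear rows only).

Result writers round sensitivity/specificity to 2 decimals and percentages to
1 decimal.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .detection import EpochSeries, NwtPeriod, Source, vector_magnitude
from .diary import DiaryRecord, assessment_window
from .synthetic import GeneratorConfig, SyntheticParticipant
from .timeline import MINUTE, Interval, Phase, PhaseKind

logger = logging.getLogger(__name__)

__all__ = [
    "read_epochs",
    "write_epochs",
    "read_diary",
    "write_diary",
    "write_cohort",
    "write_table",
    "read_generator_config",
    "write_generator_config",
]


def _split_segments(
    pid: str,
    times: pd.Series,
    counts: np.ndarray,
    epoch_length: int,
    placement: Optional[str],
) -> list[EpochSeries]:
    diffs = times.diff().dropna()
    if (diffs <= pd.Timedelta(0)).any():
        row = int(np.argmax(diffs.to_numpy() <= np.timedelta64(0))) + 1
        raise ValueError(
            f"non-monotone timestamps for participant {pid!r} at row {row}"
        )
    step = pd.Timedelta(seconds=epoch_length)
    breaks = np.flatnonzero((diffs != step).to_numpy()) + 1
    segments = []
    for lo, hi in zip(
        np.concatenate(([0], breaks)), np.concatenate((breaks, [len(counts)]))
    ):
        segments.append(
            EpochSeries(
                participant_id=pid,
                epoch_start=times.iloc[lo],
                counts=counts[lo:hi],
                epoch_length=epoch_length,
                placement=placement,
            )
        )
    if len(segments) > 1:
        logger.info(
            "participant %s: %d recording gaps split the series into %d segments",
            pid,
            len(segments) - 1,
            len(segments),
        )
    return segments


def _read_tidy(path: Path, epoch_length: int) -> list[EpochSeries]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "timestamp", "vm_counts"}
    if not required.issubset(df.columns):
        raise ValueError(f"tidy epoch file must have columns {sorted(required)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.floor("min")
    series: list[EpochSeries] = []
    for pid, grp in df.groupby("participant_id", sort=True):
        placement = None
        if "placement" in grp.columns and grp["placement"].notna().any():
            placement = str(grp["placement"].dropna().iloc[0])
        series.extend(
            _split_segments(
                str(pid),
                grp["timestamp"].reset_index(drop=True),
                grp["vm_counts"].to_numpy(),
                epoch_length,
                placement,
            )
        )
    return series


def _read_actigraph(path: Path, epoch_length: int) -> list[EpochSeries]:
    lines = Path(path).read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        low = line.lower()
        if "vector magnitude" in low or "axis1" in low:
            header_idx = i
            break
    if header_idx is None:
        raise ValueError("no recognizable column header (Axis1/Vector Magnitude)")
    preamble = "\n".join(lines[:header_idx])
    df = pd.read_csv(path, skiprows=header_idx)
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]

    if "vector_magnitude" in df.columns:
        vm = np.round(df["vector_magnitude"].to_numpy()).astype(np.int64)
    elif {"axis1", "axis2", "axis3"}.issubset(df.columns):
        vm = np.array(
            [
                vector_magnitude(int(x), int(y), int(z))
                for x, y, z in zip(df["axis1"], df["axis2"], df["axis3"])
            ],
            dtype=np.int64,
        )
    else:
        raise ValueError("need a Vector Magnitude column or all of Axis1/2/3")

    if {"date", "time"}.issubset(df.columns):
        times = pd.to_datetime(
            df["date"].astype(str) + " " + df["time"].astype(str)
        ).dt.floor("min")
    elif "timestamp" in df.columns:
        times = pd.to_datetime(df["timestamp"]).dt.floor("min")
    else:
        m_date = re.search(r"Start Date[,\s]+([0-9/.-]+)", preamble)
        m_time = re.search(r"Start Time[,\s]+([0-9:]+)", preamble)
        if not (m_date and m_time):
            raise ValueError(
                "rows carry no timestamps and the preamble states no "
                "Start Date/Start Time"
            )
        start = pd.Timestamp(f"{m_date.group(1)} {m_time.group(1)}").floor("min")
        times = pd.Series(
            start + pd.to_timedelta(np.arange(len(vm)) * epoch_length, unit="s")
        )
    m_id = re.search(r"Serial Number[,:\s]+(\S+)", preamble)
    pid = m_id.group(1) if m_id else Path(path).stem
    return _split_segments(pid, times.reset_index(drop=True), vm, epoch_length, None)


def read_epochs(
    path, dialect: str = "tidy", epoch_length: int = 60
) -> list[EpochSeries]:
    """Read an epoch-count CSV into validated, gap-split series segments."""
    path = Path(path)
    if dialect == "tidy":
        return _read_tidy(path, epoch_length)
    if dialect == "actigraph_export":
        return _read_actigraph(path, epoch_length)
    raise ValueError(f"unknown epoch dialect: {dialect!r}")


def write_epochs(series: Sequence[EpochSeries], path) -> None:
    """Write series segments as one tidy CSV (sorted by participant, time)."""
    frames = []
    for s in sorted(series, key=lambda s: (s.participant_id, s.epoch_start)):
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "timestamp": s.epoch_start
                    + pd.to_timedelta(np.arange(len(s)) * s.epoch_length, unit="s"),
                    "vm_counts": s.counts,
                    "placement": s.placement or "",
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, date_format="%Y-%m-%dT%H:%M"
    )


def read_diary(path) -> list[DiaryRecord]:
    """Read a diary CSV into per-participant records.

    Non-wear entries reaching outside the phase-derived assessment window are
    clipped with a warning; rows that would become zero-length are rejected.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "record_type", "kind", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"diary file must have columns {sorted(required)}")
    df["start"] = pd.to_datetime(df["start"]).dt.floor("min")
    df["end"] = pd.to_datetime(df["end"]).dt.floor("min")
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0]
        raise ValueError(f"zero- or negative-length diary row at index {bad}")

    records: list[DiaryRecord] = []
    for pid, grp in df.groupby("participant_id", sort=True):
        phases = [
            Phase(Interval(r.start, r.end), PhaseKind(r.kind))
            for r in grp[grp["record_type"] == "phase"].itertuples()
        ]
        entries = []
        nwt_rows = grp[grp["record_type"] == "nwt"]
        if phases:
            win_lo = min(p.interval.start for p in phases)
            win_hi = max(p.interval.end for p in phases)
        else:
            win_lo, win_hi = None, None
        for r in nwt_rows.itertuples():
            start, end = r.start, r.end
            if win_lo is not None and (start < win_lo or end > win_hi):
                start, end = max(start, win_lo), min(end, win_hi)
                logger.warning(
                    "participant %s: non-wear entry clipped to assessment window",
                    pid,
                )
                if end <= start:
                    logger.warning(
                        "participant %s: entry entirely outside window dropped", pid
                    )
                    continue
            reason = getattr(r, "reason", None)
            if pd.isna(reason):
                reason = None
            entries.append(
                NwtPeriod(Interval(start, end), Source.DIARY, reason=reason)
            )
        records.append(DiaryRecord(str(pid), phases, entries))
    return records


def write_diary(records: Sequence[DiaryRecord], path) -> None:
    rows = []
    for d in sorted(records, key=lambda d: d.participant_id):
        for p in d.phases:
            rows.append(
                {
                    "participant_id": d.participant_id,
                    "record_type": "phase",
                    "kind": p.kind.value,
                    "start": p.interval.start,
                    "end": p.interval.end,
                    "reason": "",
                }
            )
        for e in d.nwt_entries:
            rows.append(
                {
                    "participant_id": d.participant_id,
                    "record_type": "nwt",
                    "kind": "",
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "reason": e.reason or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M")


def write_cohort(participants: Sequence[SyntheticParticipant], out_dir) -> None:
    """Write a synthetic cohort: epochs.csv, diary_reported.csv, diary_truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_epochs([p.series for p in participants], out / "epochs.csv")
    write_diary([p.reported for p in participants], out / "diary_reported.csv")
    write_diary([p.truth for p in participants], out / "diary_truth.csv")


_ROUND_2DP = ("sensitivity", "specificity")
_ROUND_1DP = ("pct_both", "pct_diary_only", "pct_accel_only")


def write_table(df: pd.DataFrame, path, fmt: Optional[str] = None) -> None:
    """Write a result table as TSV or JSON (chosen by suffix unless given)."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "tsv")
    out = df.copy()
    for col in out.columns:
        if col in _ROUND_2DP:
            out[col] = out[col].round(2)
        elif col in _ROUND_1DP:
            out[col] = out[col].round(1)
    if fmt == "tsv":
        out.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        out.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown table format: {fmt!r}")


def read_generator_config(path) -> GeneratorConfig:
    """Read a generator configuration from a YAML key-value file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in (
        "removal_duration_lognorm",
        "sleep_motionless_lognorm",
        "waking_zero_lognorm",
        "counts_lognorm",
        "removal_reasons",
    ):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return GeneratorConfig(**data)


def write_generator_config(cfg: GeneratorConfig, path) -> None:
    from dataclasses import asdict

    data = asdict(cfg)
    for k, v in data.items():
        if isinstance(v, tuple):
            data[k] = list(v)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
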