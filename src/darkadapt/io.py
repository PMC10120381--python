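"""CSV/JSON file formats for trial logs, cohort tables and results.

Trial logs are RFC-4180 CSV with the exact header
``participant_id,channel,time_s,intensity_log_cdm2,detected`` (one row per
staircase presentation, ``detected`` strictly 0/1).  Cohort tables are CSV
with one row per participant.  Lines starting with ``#`` are provenance
comments (config hash + master seed) and are skipped on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .fitting import ResponseSequence
from .model import DEFAULT_TEST_DURATION_S

__all__ = [
    "TRIAL_LOG_HEADER",
    "write_trial_logs",
    "read_trial_logs",
    "write_cohort",
    "read_cohort",
    "write_json",
    "TrialLogFormatError",
]

TRIAL_LOG_HEADER = ["participant_id", "channel", "time_s", "intensity_log_cdm2", "detected"]
CHANNELS = ("red625", "green527")


class TrialLogFormatError(ValueError):
    """A trial-log file violates the declared CSV dialect."""


def _provenance_line(provenance: Optional[Mapping]) -> str:
    if not provenance:
        return ""
    items = " ".join(f"{k}={v}" for k, v in provenance.items())
    return f"# {items}\n"


def write_trial_logs(sequences: Mapping[str, Tuple[ResponseSequence, ResponseSequence]],
                     path, provenance: Optional[Mapping] = None) -> None:
    """Write a mapping ``id -> (red, green)`` as one flat trial-log CSV."""
    frames = []
    for pid, pair in sequences.items():
        for seq in pair:
            if seq is None:
                continue
            frames.append(pd.DataFrame({
                "participant_id": pid,
                "channel": seq.channel,
                "time_s": seq.times,
                "intensity_log_cdm2": seq.intensities,
                "detected": seq.detected.astype(int),
            }))
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w", newline="") as fh:
        fh.write(_provenance_line(provenance))
        df.to_csv(fh, index=False)


def read_trial_logs(path, test_duration: float = DEFAULT_TEST_DURATION_S,
                    ) -> Dict[str, Tuple[Optional[ResponseSequence],
                                         Optional[ResponseSequence]]]:
    """Read a trial-log CSV into ``id -> (red, green)`` response sequences.

    Participants missing a channel get ``None`` in that slot (callers must
    treat them as flagged, never silently dropped).  Malformed rows raise
    :class:`TrialLogFormatError` with the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    if list(df.columns) != TRIAL_LOG_HEADER:
        raise TrialLogFormatError(
            f"{path.name}: header must be exactly {','.join(TRIAL_LOG_HEADER)}")
    # first file line is the header; +2 maps frame index -> 1-based file line
    offset = 2 + sum(1 for line in open(path) if line.startswith("#"))

    bad_channel = ~df["channel"].isin(CHANNELS)
    if bad_channel.any():
        i = int(np.argmax(bad_channel.to_numpy()))
        raise TrialLogFormatError(
            f"{path.name}:{i + offset}: unknown channel {df['channel'].iloc[i]!r}")
    if not df["detected"].isin(["0", "1"]).all():
        bad = ~df["detected"].isin(["0", "1"])
        i = int(np.argmax(bad.to_numpy()))
        raise TrialLogFormatError(
            f"{path.name}:{i + offset}: detected must be 0 or 1, "
            f"got {df['detected'].iloc[i]!r}")
    for col in ("time_s", "intensity_log_cdm2"):
        try:
            df[col] = df[col].astype(float)
        except ValueError as err:
            raise TrialLogFormatError(f"{path.name}: non-numeric {col}: {err}") from None
    if (df["time_s"] < 0).any():
        i = int(np.argmax((df["time_s"] < 0).to_numpy()))
        raise TrialLogFormatError(f"{path.name}:{i + offset}: negative time_s")
    df["detected"] = df["detected"].astype(int).astype(bool)

    out: Dict[str, Tuple[Optional[ResponseSequence], Optional[ResponseSequence]]] = {}
    for pid, sub in df.groupby("participant_id", sort=False):
        seqs = {}
        for channel, chunk in sub.groupby("channel", sort=False):
            chunk = chunk.sort_values("time_s")
            seqs[channel] = ResponseSequence(
                channel=channel,
                times=chunk["time_s"].to_numpy(),
                intensities=chunk["intensity_log_cdm2"].to_numpy(),
                detected=chunk["detected"].to_numpy(),
                test_duration=test_duration,
            )
        out[str(pid)] = (seqs.get("red625"), seqs.get("green527"))
    return out


def write_cohort(cohort: pd.DataFrame, path, provenance: Optional[Mapping] = None) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_provenance_line(provenance))
        cohort.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort covariate table; ids must be unique, groups known."""
    df = pd.read_csv(path, comment="#")
    if "id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{Path(path).name}: cohort file needs 'id' and 'group' columns")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{Path(path).name}: duplicate participant id {dup!r}")
    bad = ~df["group"].isin(["aniridia", "control"])
    if bad.any():
        raise ValueError(f"{Path(path).name}: unknown group "
                         f"{df.loc[bad, 'group'].iloc[0]!r}")
    df["id"] = df["id"].astype(str)
    return df


def write_json(obj, path, provenance: Optional[Mapping] = None) -> None:
    doc = {"provenance": dict(provenance)} if provenance else {}
    doc.update(obj if isinstance(obj, dict) else {"result": obj})

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        return str(o)

    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=default, allow_nan=True)
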