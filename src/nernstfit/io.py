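"""Reading and writing time-activity curves (TACs).

The on-disk format is a plain CSV with a required header: columns ``time_s``
and ``activity``, plus an optional ``duration_s`` column for frame-mode
acquisitions (sample-mode TACs omit it).  Metadata — count scale, whether the
curve is peak-normalized, simulation ground truth, seeds — travels in a JSON
sidecar next to the CSV (``<name>.meta.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TimeActivityCurve", "read_tac", "write_tac", "normalize_tac"]


@dataclass
class TimeActivityCurve:
    """A sampled radioactivity-versus-time curve.

    ``times`` are sample times (sample mode) or frame start times (frame
    mode, when ``durations`` is present), in seconds.  ``activity`` is in
    counts per second or normalized units; the ``metadata`` dict records
    which (key ``"normalized"``) and the count scale needed to reconstruct
    integer counts (key ``"count_scale"``).
    """

    times: np.ndarray
    activity: np.ndarray
    durations: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.durations is not None:
            self.durations = np.asarray(self.durations, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if self.activity.shape != self.times.shape:
            raise ValueError("activity must match times in shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.activity < 0):
            raise ValueError("activities must be >= 0")
        if self.durations is not None:
            if self.durations.shape != self.times.shape:
                raise ValueError("durations must match times in shape")
            if np.any(self.durations <= 0):
                raise ValueError("durations must be > 0")
            ends = self.times[:-1] + self.durations[:-1]
            if np.any(ends > self.times[1:] + 1e-9):
                raise ValueError("frames must not overlap")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def eval_times(self) -> np.ndarray:
        """Times at which the model is evaluated: frame midpoints if frames."""
        if self.durations is not None:
            return self.times + self.durations / 2.0
        return self.times

    @property
    def is_normalized(self) -> bool:
        return bool(self.metadata.get("normalized", False))


def normalize_tac(tac: TimeActivityCurve) -> TimeActivityCurve:
    """Return a copy scaled to unit peak activity.

    The original peak is stored in ``metadata["count_scale"]`` so integer
    counts can be reconstructed (Poisson likelihood), and
    ``metadata["normalized"]`` is set.  A no-op if already normalized.
    """
    if tac.is_normalized:
        return tac
    peak = float(tac.activity.max())
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero TAC")
    meta = dict(tac.metadata)
    meta["count_scale"] = peak
    meta["normalized"] = True
    return TimeActivityCurve(
        times=tac.times.copy(),
        activity=tac.activity / peak,
        durations=None if tac.durations is None else tac.durations.copy(),
        metadata=meta,
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def read_tac(path, normalize: bool = False) -> TimeActivityCurve:
    """Read a TAC from CSV (+ optional JSON sidecar).

    Validation errors report the offending CSV line (1-based, counting the
    header as line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in ("time_s", "activity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    times = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(dtype=float)
    activity = pd.to_numeric(df["activity"], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(times)) or np.any(~np.isfinite(activity)):
        bad = int(np.argmax(~(np.isfinite(times) & np.isfinite(activity)))) + 2
        raise ValueError(f"{path}: malformed row at line {bad}")
    bad_time = np.where(np.diff(times) <= 0)[0]
    if len(bad_time):
        raise ValueError(
            f"{path}: times not strictly increasing at line {int(bad_time[0]) + 3}"
        )
    bad_act = np.where(activity < 0)[0]
    if len(bad_act):
        raise ValueError(f"{path}: negative activity at line {int(bad_act[0]) + 2}")
    durations = None
    if "duration_s" in df.columns:
        durations = df["duration_s"].to_numpy(dtype=float)

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    tac = TimeActivityCurve(times, activity, durations, meta)
    return normalize_tac(tac) if normalize else tac


def write_tac(tac: TimeActivityCurve, path) -> Path:
    """Write a TAC as CSV with a JSON metadata sidecar.

    Floats are written with repr precision so write/read round-trips are
    exact and the byte output is deterministic for a fixed input.
    """
    path = Path(path)
    cols = {"time_s": tac.times}
    if tac.durations is not None:
        cols["duration_s"] = tac.durations
    cols["activity"] = tac.activity
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, lineterminator="\n")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(tac.metadata, indent=1, sort_keys=True) + "\n")
    return path
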