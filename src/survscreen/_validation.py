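"""Shared input validation for survival data."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["check_time_event", "check_survival_y"]


def check_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Coerce time/event pairs to clean float / 0-1 int arrays.

    Raises ``ValueError`` on negative times, events outside {0, 1},
    mismatched lengths or non-finite times.
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel()
    if time.shape[0] != event.shape[0]:
        raise ValueError(
            f"time and event lengths differ: {time.shape[0]} vs {event.shape[0]}"
        )
    if time.shape[0] == 0:
        raise ValueError("empty survival data")
    if not np.all(np.isfinite(time)):
        raise ValueError("non-finite survival times")
    if np.any(time < 0):
        raise ValueError("negative survival times")
    ev = event.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        bad = sorted(set(ev[~np.isin(ev, (0.0, 1.0))]))
        raise ValueError(f"event indicator must be 0/1, found {bad}")
    return time, ev.astype(int)


def check_survival_y(y) -> tuple[np.ndarray, np.ndarray]:
    """Accept survival outcomes in the common container conventions.

    Supported: ``(time, event)`` tuple/list, an ``(n, 2)`` array with columns
    (time, event), a DataFrame with ``time``/``event`` columns, or a structured
    array with an event (bool) and a time field in either order (the
    scikit-survival convention).
    """
    if isinstance(y, pd.DataFrame):
        if not {"time", "event"} <= set(y.columns):
            raise ValueError("survival DataFrame needs 'time' and 'event' columns")
        return check_time_event(y["time"].to_numpy(), y["event"].to_numpy())
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return check_time_event(y[0], y[1])
    arr = np.asarray(y)
    if arr.dtype.names:
        names = arr.dtype.names
        bool_fields = [n for n in names if arr.dtype[n].kind == "b"]
        if len(bool_fields) != 1 or len(names) != 2:
            raise ValueError("structured survival array needs one bool and one time field")
        ev = bool_fields[0]
        tm = next(n for n in names if n != ev)
        return check_time_event(arr[tm], arr[ev])
    if arr.ndim == 2 and arr.shape[1] == 2:
        return check_time_event(arr[:, 0], arr[:, 1])
    raise ValueError("cannot interpret survival outcome container")
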