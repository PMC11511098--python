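"""Amplitude and waveform feature extraction.

Amplitude features (per task, per sensor, per normalization method): the
median and the range (max - min) of the normalized 1000-frame envelope.

Waveform features (per task, per sensor), computed on the band-passed raw
signal of length L:

* NZC — count of strict sign changes between consecutive samples,
  ``x_i > 0 and x_{i+1} < 0`` or vice versa (a sample exactly at zero breaks
  the change), scaled by 1000/L to a per-second rate.
* EWL — enhanced wavelength ``sum_{i=2..L} |x_i - x_{i-1}|^p`` with exponent
  p = 0.75 when the 1-based index i lies in [0.2 L, 0.8 L] and p = 0.5
  outside, scaled by 1000/L.

Both rates are then min-max rescaled to [0, 1] per participant x sensor over
that participant's functional tasks, and finally averaged across tasks into
one participant-level summary per sensor.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MissingDataError, SignalLengthError

__all__ = [
    "amplitude_params",
    "compute_nzc",
    "compute_ewl",
    "rescale_minmax",
    "average_over_tasks",
    "summarize_participants",
]

logger = logging.getLogger(__name__)

EXPECTED_FRAMES = 1000


def amplitude_params(envelope: np.ndarray, n_frames: int = EXPECTED_FRAMES) -> tuple[float, float]:
    """Median and range of a normalized fixed-length envelope.

    The median of the even-length frame vector is the mean of the two middle
    order statistics (numpy's convention).
    """
    x = np.asarray(envelope, dtype=float)
    if len(x) != n_frames:
        raise SignalLengthError(f"expected a {n_frames}-frame envelope, got length {len(x)}")
    return float(np.median(x)), float(np.max(x) - np.min(x))


def compute_nzc(samples: np.ndarray) -> float:
    """Zero-crossing rate: strict sign changes per 1000 frames."""
    x = np.asarray(samples, dtype=float)
    L = len(x)
    if L < 2:
        raise SignalLengthError(f"NZC needs at least 2 samples, got {L}")
    a, b = x[:-1], x[1:]
    crossings = np.count_nonzero(((a > 0) & (b < 0)) | ((a < 0) & (b > 0)))
    return crossings * 1000.0 / L


def compute_ewl(samples: np.ndarray) -> float:
    """Enhanced wavelength per 1000 frames.

    The exponent window [0.2 L, 0.8 L] is compared against the 1-based sample
    index i of the difference term |x_i - x_{i-1}| without rounding.
    """
    x = np.asarray(samples, dtype=float)
    L = len(x)
    if L < 2:
        raise SignalLengthError(f"EWL needs at least 2 samples, got {L}")
    diffs = np.abs(x[1:] - x[:-1])
    i = np.arange(2, L + 1, dtype=float)
    p = np.where((i >= 0.2 * L) & (i <= 0.8 * L), 0.75, 0.5)
    return float(np.sum(diffs**p) * 1000.0 / L)


def rescale_minmax(values: Sequence[float], context: str = "") -> np.ndarray:
    """Min-max rescale a participant x sensor's per-task rates to [0, 1].

    Degenerate input (max == min) maps every task to 0 and logs a warning; it
    cannot occur with continuous data but keeps downstream averaging defined.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise MissingDataError(
            f"min-max rescaling needs >= 2 task values{', ' + context if context else ''}"
        )
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        logger.warning(
            "degenerate min-max rescale (all task values equal)%s; returning zeros",
            f" for {context}" if context else "",
        )
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def average_over_tasks(
    table: pd.DataFrame,
    value_columns: Sequence[str],
    expected_tasks: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Arithmetic mean of per-task feature rows per participant x sensor.

    ``table`` must carry ``participant_id``, ``group``, ``sensor``, ``task_id``
    and the listed value columns (plus an optional ``method`` column, kept as a
    grouping key).  Missing tasks raise rather than silently imputing.
    """
    keys = ["participant_id", "group", "sensor"]
    if "method" in table.columns:
        keys.append("method")
    if expected_tasks is not None:
        expected = set(int(t) for t in expected_tasks)
        for key_vals, sub in table.groupby(keys, sort=False):
            missing = expected - set(sub["task_id"].astype(int))
            if missing:
                raise MissingDataError(
                    f"missing task(s) {sorted(missing)} for {dict(zip(keys, key_vals))}"
                )
    out = table.groupby(keys, as_index=False, sort=True)[list(value_columns)].mean()
    return out


def summarize_participants(
    amplitude_table: pd.DataFrame | None,
    waveform_table: pd.DataFrame | None,
    expected_tasks: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Wide participant-level summary with classifier-style column names.

    Columns: ``M_<method><sensor>`` and ``R_<method><sensor>`` for the
    task-averaged median/range under each normalization method, and
    ``NZC<sensor>`` / ``EWL<sensor>`` for the task-averaged rescaled waveform
    parameters.  One row per participant, plus a ``group`` column.
    """
    pieces = []
    if amplitude_table is not None and len(amplitude_table):
        avg = average_over_tasks(
            amplitude_table, ["median", "range"], expected_tasks=expected_tasks
        )
        wide = avg.pivot_table(
            index=["participant_id", "group"],
            columns=["method", "sensor"],
            values=["median", "range"],
        )
        wide.columns = [
            f"{'M' if stat == 'median' else 'R'}_{method}{sensor}"
            for stat, method, sensor in wide.columns
        ]
        pieces.append(wide)
    if waveform_table is not None and len(waveform_table):
        avg = average_over_tasks(
            waveform_table,
            ["nzc_rescaled", "ewl_rescaled"],
            expected_tasks=expected_tasks,
        )
        wide = avg.pivot_table(
            index=["participant_id", "group"],
            columns="sensor",
            values=["nzc_rescaled", "ewl_rescaled"],
        )
        wide.columns = [
            f"{'NZC' if stat == 'nzc_rescaled' else 'EWL'}{sensor}"
            for stat, sensor in wide.columns
        ]
        pieces.append(wide)
    if not pieces:
        raise MissingDataError("no feature tables supplied")
    out = pd.concat(pieces, axis=1).reset_index()
    return out.sort_values("participant_id").reset_index(drop=True)
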