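"""Per-participant, per-sensor amplitude normalization values (MAX/MVC/GRASP).

MAX: maximum envelope value over all functional (SHFT) task recordings.
MVC: maximum over the targeted maximal-voluntary-contraction movements.
GRASP: maximum over the maximal-effort grasp recordings.

Maxima are taken on the filtered, rectified and smoothed envelope *before*
frame resampling (resampling can clip the true peak); the division is applied
to whichever envelope the caller provides.  MVC or GRASP denominators may be
smaller than a functional-task peak, so normalized values above 1 are valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingDataError, NormalizationError
from .preprocessing import ProcessedSignal

__all__ = [
    "NormalizationSet",
    "compute_normalization_values",
    "normalize_envelope",
    "normalization_table",
]

METHODS = ("MAX", "MVC", "GRASP")
_FAMILY_OF = {"MAX": "shft", "MVC": "mvc", "GRASP": "grasp"}


@dataclass(frozen=True)
class NormalizationSet:
    participant_id: str
    sensor: int
    max_value: float
    mvc_value: float
    grasp_value: float

    def denominator(self, method: str) -> float:
        return {"MAX": self.max_value, "MVC": self.mvc_value, "GRASP": self.grasp_value}[method]


def compute_normalization_values(
    envelopes: Iterable[ProcessedSignal],
    participant_id: str,
    sensor: int,
) -> NormalizationSet:
    """Extract the three denominators from one participant x sensor's envelopes.

    ``envelopes`` must contain amplitude-path signals (pre-resampling) from all
    three task families for the given participant and sensor.
    """
    peaks: dict[str, float] = {}
    for env in envelopes:
        rec = env.source
        if rec.participant_id != participant_id or rec.sensor != sensor:
            continue
        fam = rec.task_family
        peak = float(np.max(env.samples)) if len(env.samples) else 0.0
        peaks[fam] = max(peaks.get(fam, -np.inf), peak)
    missing = [fam for fam in ("shft", "mvc", "grasp") if fam not in peaks]
    if missing:
        raise MissingDataError(
            f"participant {participant_id!r} sensor {sensor}: missing task "
            f"famil{'ies' if len(missing) > 1 else 'y'} {missing}"
        )
    return NormalizationSet(
        participant_id=participant_id,
        sensor=sensor,
        max_value=peaks["shft"],
        mvc_value=peaks["mvc"],
        grasp_value=peaks["grasp"],
    )


def normalize_envelope(envelope: np.ndarray, denom: float, context: str = "") -> np.ndarray:
    """Divide an envelope by a normalization value (must be positive)."""
    if not denom > 0:
        where = f" ({context})" if context else ""
        raise NormalizationError(f"non-positive normalization denominator {denom!r}{where}")
    return np.asarray(envelope, dtype=float) / denom


def normalization_table(norm_sets: Sequence[NormalizationSet]) -> pd.DataFrame:
    """Tidy CSV-ready table of normalization values in mV."""
    return pd.DataFrame(
        [
            {
                "participant_id": ns.participant_id,
                "sensor": ns.sensor,
                "max_mV": ns.max_value,
                "mvc_mV": ns.mvc_value,
                "grasp_mV": ns.grasp_value,
            }
            for ns in norm_sets
        ]
    )
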