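"""Standardized 0-100 brain vital sign scores against a reference cohort.

A measurement x is placed on its reference distribution (mean mu, SD sigma)
and mapped linearly across the +/-3 sigma band:

    amplitude score = 100 * clip((x - (mu - 3 sigma)) / (6 sigma), 0, 1)
    latency   score = 100 * clip(((mu + 3 sigma) - x) / (6 sigma), 0, 1)

so larger amplitudes and faster (smaller) latencies score higher, the
reference mean scores 50, and anything beyond +/-3 sigma saturates at 0 or
100. All six measures thus share one scale and can be overlaid on a single
radar profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .measures import MEASURES, UNITS, measure_kind
from .pipeline import ErpMeasurementSet


@dataclass
class ReferenceDistribution:
    """Per-measure normative mean/SD (with n) from a reference cohort."""

    stats: dict[str, tuple[float, float, int]] = field(default_factory=dict)  # measure -> (mu, sd, n)

    def mean(self, measure: str) -> float:
        return self.stats[measure][0]

    def sd(self, measure: str) -> float:
        return self.stats[measure][1]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(measure=m, mean=mu, sd=sd, n=n, unit=UNITS[m])
                for m, (mu, sd, n) in self.stats.items()]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {m: {"mean": mu, "sd": sd, "n": n, "unit": UNITS[m]}
                   for m, (mu, sd, n) in self.stats.items()}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceDistribution":
        payload = json.loads(Path(path).read_text())
        return cls({m: (d["mean"], d["sd"], d["n"]) for m, d in payload.items()})


@dataclass
class StandardizedProfile:
    """Six 0-100 scores (and underlying z-values) for one participant-session."""

    scores: dict[str, float | None]
    z_values: dict[str, float | None]


def build_reference(measurements: pd.DataFrame) -> ReferenceDistribution:
    """Sample mean and SD (denominator n-1) per measure from a long-format table.

    Rows with missing values are ignored; a measure with fewer than two
    values raises, since no spread can be estimated from one observation.
    """
    ref = ReferenceDistribution()
    for m in MEASURES:
        vals = measurements.loc[measurements["measure"] == m, "value"].dropna().to_numpy(float)
        if len(vals) < 2:
            raise ValueError(f"reference for {m} needs >= 2 values, got {len(vals)}")
        ref.stats[m] = (float(vals.mean()), float(vals.std(ddof=1)), int(len(vals)))
    return ref


def standardize(x: float, kind: str, mu: float, sigma: float) -> float:
    """Map one measurement to its 0-100 standardized score."""
    if sigma <= 0:
        raise ValueError("reference SD must be positive")
    if kind == "amplitude":
        frac = (x - (mu - 3.0 * sigma)) / (6.0 * sigma)
    elif kind == "latency":
        frac = ((mu + 3.0 * sigma) - x) / (6.0 * sigma)
    else:
        raise ValueError(f"kind must be 'amplitude' or 'latency', got {kind!r}")
    return 100.0 * float(np.clip(frac, 0.0, 1.0))


def radar_profile(measures: ErpMeasurementSet | dict[str, float | None],
                  ref: ReferenceDistribution) -> StandardizedProfile:
    """Standardize all six measures of one participant-session.

    Missing measures propagate as ``None`` (rendered as gaps on the radar).
    """
    values = measures.as_dict() if isinstance(measures, ErpMeasurementSet) else measures
    missing = [m for m in MEASURES if m not in ref.stats]
    if missing:
        raise ValueError(f"reference does not cover: {missing}")
    scores: dict[str, float | None] = {}
    zs: dict[str, float | None] = {}
    for m in MEASURES:
        x = values.get(m)
        if x is None or (isinstance(x, float) and np.isnan(x)):
            scores[m] = zs[m] = None
            continue
        mu, sd, _ = ref.stats[m]
        scores[m] = standardize(float(x), measure_kind(m), mu, sd)
        zs[m] = (float(x) - mu) / sd
    return StandardizedProfile(scores, zs)
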