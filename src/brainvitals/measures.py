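"""Canonical names and units for the six brain vital sign measures.

Every module exchanges participant-level results as long-format tables with
one row per (participant, session, measure); these constants pin down the
measure vocabulary so the pipeline, scoring and statistics stages agree.
"""

from __future__ import annotations

#: The six outcome measures, in the fixed radar-axis order.
MEASURES: tuple[str, ...] = (
    "n100_amplitude",
    "n100_latency",
    "p300_amplitude",
    "p300_latency",
    "n400_amplitude",
    "n400_latency",
)

#: ERP components and their deflection polarity (sign of the peak searched for).
COMPONENTS: tuple[str, ...] = ("n100", "p300", "n400")
POLARITY: dict[str, int] = {"n100": -1, "p300": +1, "n400": -1}

AMPLITUDE_MEASURES = tuple(m for m in MEASURES if m.endswith("amplitude"))
LATENCY_MEASURES = tuple(m for m in MEASURES if m.endswith("latency"))

UNITS: dict[str, str] = {m: ("uV" if m.endswith("amplitude") else "ms") for m in MEASURES}

#: Column order of the long-format measurement / truth CSV dialect.
LONG_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "group",
    "age",
    "sex",
    "session",
    "measure",
    "value",
    "unit",
)


def measure_kind(measure: str) -> str:
    """Return ``"amplitude"`` or ``"latency"`` for a measure name."""
    if measure in AMPLITUDE_MEASURES:
        return "amplitude"
    if measure in LATENCY_MEASURES:
        return "latency"
    raise ValueError(f"unknown measure: {measure!r}")


def component_of(measure: str) -> str:
    """Return the ERP component (``n100``/``p300``/``n400``) a measure belongs to."""
    comp = measure.split("_", 1)[0]
    if comp not in COMPONENTS:
        raise ValueError(f"unknown measure: {measure!r}")
    return comp
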