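"""The six-class ingestive-behavior ethogram shared by every module.

Behaviors are mutually exclusive instantaneous states of a grazing animal:
``grazing`` (searching for / apprehending forage), ``ruminating`` (chewing a
ruminal bolus), ``lying_standing`` (resting, lying or standing without
locomotion), ``drinking``, ``eating`` (ingesting dietary supplement at the
trough) and ``other`` (everything else).  The tuple order below is the fixed
class order used by confusion matrices and reports.
"""

from __future__ import annotations

BEHAVIORS: tuple[str, ...] = (
    "grazing",
    "ruminating",
    "lying_standing",
    "drinking",
    "eating",
    "other",
)

#: behaviors counted as food intake in ethogram summaries (grazing + eating)
INTAKE_BEHAVIORS: frozenset[str] = frozenset({"grazing", "eating"})

GENETIC_GROUPS: tuple[str, ...] = ("nellore_dry", "nellore_wet", "crossbred_wet")

#: reference level for dummy-coding the genetic group in regression and PCA
GENETIC_GROUP_REFERENCE = "nellore_dry"


def validate_behavior(label: str) -> str:
    """Return *label* if it is one of the six ethogram classes, else raise."""
    if label not in BEHAVIORS:
        raise ValueError(
            f"unknown behavior {label!r}; expected one of {', '.join(BEHAVIORS)}"
        )
    return label
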