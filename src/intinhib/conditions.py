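"""Shared vocabulary for the modified Go/NoGo ("intentional inhibition") task.

The task presents three cue types: green Go cues instructing a button press,
red NoGo cues instructing the press be withheld, and yellow Choose cues on
which the participant decides to press or withhold.  Combined with the
participant's response, each trial resolves into an outcome condition.  The
four correct outcomes (Go, NoGo-correct, Choose-Go, Choose-NoGo) are the
conditions entered to pattern-similarity analysis; omissions and commission
errors are modelled as nuisance conditions.
"""

from __future__ import annotations

#: Cue types as presented, in canonical order.
TRIAL_TYPES: tuple[str, ...] = ("Go", "NoGo", "Choose")

#: The four analysed outcome conditions, in the fixed order used by every
#: pattern matrix and similarity matrix in this package.
CONDITIONS: tuple[str, ...] = ("Go", "NoGo", "ChooseGo", "ChooseNoGo")

#: All outcome conditions a trial can resolve to (analysed + nuisance).
OUTCOME_CONDITIONS: tuple[str, ...] = (
    "Go",
    "NoGoCorrect",
    "ChooseGo",
    "ChooseNoGo",
    "GoOmission",
    "NoGoError",
)

#: Maps an analysed outcome condition to the label used in similarity
#: matrices (NoGo-correct trials are labelled "NoGo" there).
OUTCOME_TO_CONDITION: dict[str, str] = {
    "Go": "Go",
    "NoGoCorrect": "NoGo",
    "ChooseGo": "ChooseGo",
    "ChooseNoGo": "ChooseNoGo",
}

#: Valid (trial_type, response) -> outcome_condition resolutions.
RESOLUTION: dict[tuple[str, str], str] = {
    ("Go", "press"): "Go",
    ("Go", "withhold"): "GoOmission",
    ("NoGo", "withhold"): "NoGoCorrect",
    ("NoGo", "press"): "NoGoError",
    ("Choose", "press"): "ChooseGo",
    ("Choose", "withhold"): "ChooseNoGo",
}


class InvalidConfigError(ValueError):
    """Raised when a configuration violates a documented invariant."""
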