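"""Mitotic phase vocabulary used throughout the package.

The six labels follow the standard morphological staging of mitosis as seen
in a chromatin channel: interphase (decondensed nucleus), prophase
(condensing), prometaphase (condensed, post nuclear-envelope breakdown),
metaphase (aligned plate), anaphase (segregating sisters) and telophase
(decondensing daughters, nuclear envelope reassembling).
"""

PHASES: tuple[str, ...] = (
    "interphase",
    "prophase",
    "prometaphase",
    "metaphase",
    "anaphase",
    "telophase",
)

MITOTIC_PHASES = frozenset(PHASES[1:])


def validate_phase(phase: str) -> str:
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    return phase
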