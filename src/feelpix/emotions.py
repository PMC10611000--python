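"""Emotion vocabulary shared across the pipeline.

The seven emotion categories follow Ekman's discrete theory: the six basic
emotions plus a neutral state. ``EMOTIONS`` fixes the canonical
(alphabetical) order used for label vectors, reports, and CSV columns
everywhere in the package.
"""

from __future__ import annotations

#: Canonical label-vector order for the seven recognized emotional states.
EMOTIONS: tuple[str, ...] = (
    "anger",
    "disgust",
    "fear",
    "happy",
    "neutral",
    "sad",
    "surprise",
)

#: Ekman's six basic emotions (the seven states minus neutrality).
BASIC_EMOTIONS: tuple[str, ...] = (
    "anger",
    "disgust",
    "fear",
    "happy",
    "sad",
    "surprise",
)

#: Index of each emotion within ``EMOTIONS``.
EMOTION_INDEX: dict[str, int] = {name: i for i, name in enumerate(EMOTIONS)}


def validate_emotions(names, allow_neutral: bool = True) -> None:
    """Raise ``ValueError`` if any name is not a recognized emotion."""
    valid = set(EMOTIONS) if allow_neutral else set(BASIC_EMOTIONS)
    unknown = sorted(set(names) - valid)
    if unknown:
        raise ValueError(f"unknown emotion name(s): {', '.join(unknown)}")
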