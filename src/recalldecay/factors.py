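"""Categorical risk factors shared across the package.

Each factor maps to an ordered tuple of levels; the first level is the
reference category used in dummy coding. The middle socioeconomic tertile
is the reference because relative rates between tertiles are conventionally
reported against it.
"""

from __future__ import annotations

FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "age_group": ("16-44", "0-15", "45+"),
    "education": ("none", "khalwa_primary", "secondary", "diploma_plus"),
    "location": ("urban", "rural"),
    "ses_tertile": ("middle", "lower", "upper"),
}

FACTORS: tuple[str, ...] = tuple(FACTOR_LEVELS)

INJURY_CAUSES: tuple[str, ...] = (
    "fall",
    "mechanical",
    "road_traffic",
    "burn",
    "other",
)


def check_level(factor: str, level: str) -> str:
    """Validate that *level* belongs to *factor*; returns the level."""
    if factor not in FACTOR_LEVELS:
        raise ValueError(f"unknown factor {factor!r}")
    if level not in FACTOR_LEVELS[factor]:
        raise ValueError(
            f"unknown level {level!r} for factor {factor!r}; "
            f"expected one of {FACTOR_LEVELS[factor]}"
        )
    return level


def ordered_levels(factor: str, reference: str | None = None) -> tuple[str, ...]:
    """Levels of *factor* with *reference* (default: built-in) first."""
    levels = FACTOR_LEVELS[factor]
    if reference is None or reference == levels[0]:
        return levels
    check_level(factor, reference)
    return (reference,) + tuple(l for l in levels if l != reference)
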