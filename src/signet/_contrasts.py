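"""Registry of the study's named contrasts.

A contrast is an ordered pair of condition-by-age groups, written
``test_vs_reference`` (or ``test:reference`` on the command line).
Conditions come from the inducible alpha-synuclein mouse design:
``synON`` (lifelong transgene expression), ``synlateON`` (expression
induced late in life) and ``synOFF`` (no expression), each sampled at
6, 16 and 24 months of age.
"""

from __future__ import annotations

CONDITIONS = ("synON", "synlateON", "synOFF")
AGES = ("6M", "16M", "24M")

#: Groups are condition+age composites, e.g. "synON24M".
GROUPS = tuple(f"{c}{a}" for c in CONDITIONS for a in AGES)

# The five disease-related contrasts (transgene arms vs non-expressing
# littermates at matched ages) and the three aging contrasts within the
# non-expressing arm.
PD_CONTRASTS = (
    "synON16M_vs_synOFF16M",
    "synlateON16M_vs_synOFF16M",
    "synON24M_vs_synOFF24M",
    "synlateON24M_vs_synOFF24M",
    "synON6M_vs_synOFF6M",
)
AGING_CONTRASTS = (
    "synOFF24M_vs_synOFF6M",
    "synOFF16M_vs_synOFF6M",
    "synOFF24M_vs_synOFF16M",
)
NAMED_CONTRASTS = PD_CONTRASTS + AGING_CONTRASTS


class UnknownContrastError(ValueError):
    """Raised when a contrast label is not one of the named contrasts."""


def parse_contrast(label: str) -> tuple[str, str]:
    """Split a contrast label into (test_group, reference_group).

    Accepts both ``A_vs_B`` and ``A:B`` spellings.
    """
    if ":" in label:
        parts = label.split(":")
    else:
        parts = label.split("_vs_")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"cannot parse contrast label {label!r}")
    test, ref = parts
    for g in (test, ref):
        if g not in GROUPS:
            raise ValueError(
                f"unknown group {g!r} in contrast {label!r}; "
                f"expected one of {GROUPS}"
            )
    return test, ref


def canonical_label(label: str) -> str:
    test, ref = parse_contrast(label)
    return f"{test}_vs_{ref}"


def require_named(label: str) -> str:
    """Canonicalize *label* and require it to be a named study contrast."""
    canon = canonical_label(label)
    if canon not in NAMED_CONTRASTS:
        raise UnknownContrastError(
            f"{label!r} is not one of the study's named contrasts: "
            f"{NAMED_CONTRASTS}"
        )
    return canon
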