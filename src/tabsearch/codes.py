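"""Tableau orientation codes, the double-quadrant angle encoding, SSE type
classes, and the pairwise code scoring function ζ.

A tableau code is a two-character string describing the relative orientation
of two secondary structure elements (SSEs).  The first character classifies
the signed interaxial angle ω into four 90°-wide sectors centred on 0°, ±90°
and 180°:

    P  parallel        ω ∈ [−45°,  45°)
    R  crossing-right  ω ∈ [ 45°, 135°)
    O  anti-parallel   ω ∈ [135°, 180°] ∪ (−180°, −135°)
    L  crossing-left   ω ∈ [−135°, −45°)

The second character uses the same four-sector scheme rotated by 45°:

    E  ω ∈ [   0°,  90°)
    T  ω ∈ [  90°, 180°]
    D  ω ∈ [ −90°,   0°)
    S  ω ∈ (−180°, −90°)

Because the two classifications are offset by 45°, a perturbation of less
than 45° can change at most one of the two characters, so near-identical
orientations always score at least 1 under ζ.  An anti-parallel pair at,
say, 143° encodes as "OT"; at −143° it encodes as "OS".

SSE types are stored on the tableau diagonal as lowercase codes: ``e`` for
β-strands and ``xa``/``xi``/``xg`` for α-, π- and 3₁₀-helices.  For matching
purposes the three helix types form a single class: a 3₁₀-helix may be
matched with an α-helix, but never with a strand.
"""

from __future__ import annotations

import math

__all__ = [
    "FIRST_CHARS",
    "SECOND_CHARS",
    "SSE_TYPES",
    "ALL_CODES",
    "encode_angle",
    "zeta",
    "same_type_class",
    "sse_class",
    "validate_code",
    "validate_sse_type",
]

from .errors import InvalidAngleError, ValidationError

FIRST_CHARS = "PORL"
SECOND_CHARS = "EDST"

#: Valid SSE type codes and their matching class.
SSE_TYPES = {"e": "strand", "xa": "helix", "xi": "helix", "xg": "helix"}

#: All 16 valid tableau codes.
ALL_CODES = tuple(a + b for a in FIRST_CHARS for b in SECOND_CHARS)

_CODE_SET = frozenset(ALL_CODES)


def validate_code(code: str) -> str:
    """Return *code* if it is a valid two-character tableau code, else raise."""
    if not isinstance(code, str) or code not in _CODE_SET:
        raise ValidationError(
            f"invalid tableau code {code!r}: expected one of "
            f"{{P,O,L,R}}×{{E,D,S,T}}"
        )
    return code


def validate_sse_type(code: str) -> str:
    """Return *code* if it is a valid SSE type code (e, xa, xi, xg)."""
    if not isinstance(code, str) or code not in SSE_TYPES:
        raise ValidationError(
            f"invalid SSE type code {code!r}: expected one of e, xa, xi, xg"
        )
    return code


def encode_angle(omega: float) -> str:
    """Encode a signed interaxial angle (degrees) as a two-character code.

    The angle must be finite; values are normalized into (−180, 180] before
    classification, so e.g. encode_angle(270) == encode_angle(-90).

    >>> encode_angle(143.0)
    'OT'
    >>> encode_angle(-170.0)
    'OS'
    """
    try:
        omega = float(omega)
    except (TypeError, ValueError) as exc:
        raise InvalidAngleError(f"angle must be a real number, got {omega!r}") from exc
    if not math.isfinite(omega):
        raise InvalidAngleError(f"angle must be finite, got {omega!r}")
    # normalize into (-180, 180]
    omega = omega - 360.0 * math.floor((omega + 180.0) / 360.0)
    if omega <= -180.0:
        omega += 360.0

    if -45.0 <= omega < 45.0:
        first = "P"
    elif 45.0 <= omega < 135.0:
        first = "R"
    elif -135.0 <= omega < -45.0:
        first = "L"
    else:  # [135, 180] ∪ (−180, −135)
        first = "O"

    if 0.0 <= omega < 90.0:
        second = "E"
    elif 90.0 <= omega <= 180.0:
        second = "T"
    elif -90.0 <= omega < 0.0:
        second = "D"
    else:  # (−180, −90)
        second = "S"

    return first + second


def zeta(a: str, b: str) -> int:
    """Pairwise similarity of two tableau codes: 2, 1 or −2.

    Identical codes score 2; codes agreeing in exactly one of the two
    quadrant characters score 1; codes differing in both score −2.
    ζ is symmetric and ζ(a, a) = 2 for every valid code.
    """
    validate_code(a)
    validate_code(b)
    if a == b:
        return 2
    if a[0] == b[0] or a[1] == b[1]:
        return 1
    return -2


def sse_class(t: str) -> str:
    """Matching class ('helix' or 'strand') of an SSE type code."""
    validate_sse_type(t)
    return SSE_TYPES[t]


def same_type_class(a: str, b: str) -> bool:
    """True iff two SSE type codes belong to the same matching class.

    All helix variants (xa, xi, xg) are mutually compatible; a helix is
    never compatible with a strand (e).
    """
    return sse_class(a) == sse_class(b)
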