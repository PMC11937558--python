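"""Small shared helpers (reporting-layer rounding, dyad keys)."""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of the published tables).

    Python's built-in round() is banker's rounding; published behavioural
    tables round 0.005 up, so this is applied at the reporting layer only.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ndigits decimals (space-per-animal convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_DOWN))


def dyad_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered dyad identifier."""
    if a == b:
        raise ValueError(f"a dyad needs two distinct animals, got {a!r} twice")
    return (a, b) if a <= b else (b, a)
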