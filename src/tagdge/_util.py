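"""Small shared helpers: strand arithmetic and report rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(value: float, digits: int = 2) -> float:
    """Round with ties away from zero (half-up), as in printed report tables."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct_half_up(numerator: float, denominator: float, digits: int = 2) -> float:
    """numerator/denominator as a percentage, half-up rounded; 0 when denominator is 0."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-digits)
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))
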