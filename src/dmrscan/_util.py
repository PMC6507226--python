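"""Small shared helpers: exact decimal percentages and sequence ops."""

from __future__ import annotations

from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def percent(numerator: int | float, denominator: int | float,
            ndigits: int = 2, mode: str = "half_up") -> float:
    """100 * numerator / denominator at fixed decimal precision.

    Computed in exact decimal arithmetic so that printed-table percentages
    are reproduced bit-for-bit.  ``mode`` is ``half_up`` (conventional
    rounding) or ``truncate`` (floor at the displayed precision, the rule
    some published percentages follow).
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator is undefined")
    rounding = ROUND_HALF_UP if mode == "half_up" else ROUND_DOWN
    quant = Decimal(1).scaleb(-ndigits)
    value = Decimal(str(numerator)) / Decimal(str(denominator)) * 100
    return float(value.quantize(quant, rounding=rounding))
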