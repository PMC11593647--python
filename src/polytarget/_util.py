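"""Small shared helpers: sequence complementing and display rounding."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def round_half_away(value, ndigits: int = 0):
    """Round with ties going away from zero, at the printed precision.

    Python's builtin round() is banker's rounding; reported percentages here
    follow the convention that e.g. 87.5 -> 88 at whole-percent precision.
    Accepts exact Fractions so that display rounding is the only inexact step.
    """
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    out = dec.quantize(quantum, rounding=ROUND_HALF_UP)
    return int(out) if ndigits == 0 else float(out)
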