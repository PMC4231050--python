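"""Small shared helpers: alphabet, reverse complement, half-up rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_acgt(seq: str) -> bool:
    return bool(seq) and all(c in "ACGT" for c in seq)


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), not banker's rounding.

    Summary tables print one decimal and screening rates print integers; both
    use conventional half-up rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(part: float, whole: float, ndigits: int = 1) -> float:
    """100*part/whole rounded half-up to ``ndigits`` decimals."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    return round_half_up(100.0 * part / whole, ndigits)
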