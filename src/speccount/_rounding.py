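"""Half-up decimal rounding used for all reported percentages and cutoffs.

Python's builtin ``round`` is banker's rounding; reported values here follow
the half-up convention instead (0.005 -> 0.01, -0.005 -> -0.01).
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
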