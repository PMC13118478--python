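"""Decimal half-up rounding for display values.

Binary floats round-half-even at exactly-representable halves and
unpredictably otherwise; published tables use conventional half-up
rounding, so display formatting goes through :mod:`decimal`.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round *x* to *ndigits* decimals with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
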