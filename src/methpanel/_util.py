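"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float | int:
    """Round to *ndigits* decimals with ties going away from zero.

    Clinical frequency tables conventionally round 88.5 % up to 89 %,
    which differs from banker's rounding used by :func:`round`.  The value
    is routed through its shortest decimal representation so that inputs
    entered as e.g. 0.205 land on 0.21 rather than on the binary artefact
    0.20499999999999996.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d) if ndigits > 0 else int(d)
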