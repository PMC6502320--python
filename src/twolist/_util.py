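"""Small shared helpers: half-up rounding and seed derivation."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero at the last kept digit.

    Banker's rounding (Python's built-in) would turn 0.5 into 0; surveillance
    reports conventionally round half up, and every printed figure this
    package reproduces follows that convention.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d) if ndigits > 0 else float(int(d))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits``."""
    return round_half_up(100.0 * numerator / denominator, ndigits)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent, reproducible generators from one seed.

    Uses numpy's SeedSequence spawning so streams are statistically
    independent yet fully determined by ``seed``.
    """
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]
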