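"""Small shared helpers: star-allele label parsing and percentage rounding."""
from __future__ import annotations

import math
import re
from decimal import ROUND_HALF_UP, Decimal

_XN_RE = re.compile(r"^(?P<base>.+?)x(?P<mult>\d+)$")


def parse_multiplier(label: str) -> tuple[str, int]:
    """Split a star-allele label into (base, copy multiplier).

    ``*1x2`` -> (``*1``, 2); plain labels have multiplier 1.
    """
    m = _XN_RE.match(label)
    if m:
        return m.group("base"), int(m.group("mult"))
    return label, 1


def star_sort_key(label: str) -> tuple[float, str]:
    """Canonical ordering for star-allele labels: numerically lower allele
    first (*2 < *10), non-numeric labels (e.g. *DEL) last, name as tiebreak."""
    base, _ = parse_multiplier(label)
    m = re.match(r"^\*(\d+)", base)
    num = int(m.group(1)) if m else math.inf
    return (num, label)


def canonical_pair(allele1: str, allele2: str) -> tuple[str, str]:
    a, b = sorted((allele1, allele2), key=star_sort_key)
    return a, b


def diplotype_string(allele1: str, allele2: str) -> str:
    return "/".join(canonical_pair(allele1, allele2))


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, decimal-exact (53.25 -> 53.3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, denom: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up, matching printed-report style."""
    if denom == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_up(100.0 * count / denom, ndigits)
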