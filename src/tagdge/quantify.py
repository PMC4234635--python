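"""RPKM quantification and the log2 expression ratio.

RPKM (reads per kilobase of transcript model per million mapped reads) is
``10^9 * C / (N * L)`` for a gene with ``C`` tags and length ``L`` bp in a
library of ``N`` total tags.  The expression ratio reported throughout is
``log2(RPKM_B / RPKM_A)``; with a zero denominator and no pseudocount it
degenerates to a signed-infinity sentinel rather than a guessed floor.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def rpkm(count: int, length_bp: int, library_total: int) -> float:
    """Reads per kilobase per million mapped reads for one gene.

    Parameters
    ----------
    count : tag count of the gene in the library (>= 0)
    length_bp : gene length in base pairs (>= 1)
    library_total : total tag count of the library (>= 1)
    """
    if length_bp < 1:
        raise ValueError(f"length_bp must be >= 1, got {length_bp}")
    if library_total < 1:
        raise ValueError(f"library_total must be >= 1, got {library_total}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return 1e9 * count / (library_total * length_bp)


def log2_ratio(rpkm_a: float, rpkm_b: float, pseudo: float = 0.0) -> float:
    """log2((rpkm_b + pseudo) / (rpkm_a + pseudo)).

    With ``pseudo == 0`` and one side zero the result is the signed
    infinity sentinel (+inf when only B is expressed, -inf when only A is);
    both sides zero gives NaN, which callers treat as untestable.
    Antisymmetric under swapping the two libraries.
    """
    if rpkm_a < 0 or rpkm_b < 0 or pseudo < 0:
        raise ValueError("rpkm values and pseudo must be non-negative")
    a = rpkm_a + pseudo
    b = rpkm_b + pseudo
    if a == 0.0 and b == 0.0:
        return math.nan
    if b == 0.0:
        return -math.inf
    if a == 0.0:
        return math.inf
    return math.log2(b / a)


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of the report tables.

    Python's and numpy's default round-half-to-even would turn e.g. 2.25
    into 2.2; report columns use the convention where 2.25 becomes 2.3 and
    -2.25 becomes -2.3.  Infinities and NaN pass through unchanged.
    """
    if math.isinf(value) or math.isnan(value):
        return value
    quantum = Decimal(1).scaleb(-decimals)
    magnitude = Decimal(str(abs(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(magnitude) if value >= 0 else -float(magnitude)
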