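"""Binomial recessive-disease risk for couples sharing heterozygous variants.

When both partners carry the same heterozygous autosomal-recessive variant,
each pregnancy has a 1/4 chance of an affected child for that condition.
With k shared variants in distinct genes, treated as independent, the
number of conditions affecting the offspring is Binomial(k, 1/4); the
headline quantity is the probability of at least one affected condition,
1 - (3/4)^k.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from math import comb

__all__ = ["RiskResult", "shared_variant_risk"]


@dataclasses.dataclass(frozen=True)
class RiskResult:
    k: int
    p_per_variant: float
    p_any: float                       # probability of >= 1 affected condition
    pmf: tuple[float, ...]             # P(exactly j conditions), j = 0..k
    pmf_exact: tuple[Fraction, ...]    # same, in exact rational arithmetic

    def __post_init__(self) -> None:
        assert abs(sum(self.pmf) - 1.0) <= 1e-12
        assert sum(self.pmf_exact) == 1


def shared_variant_risk(
    k: int, p_per_variant: Fraction | float = Fraction(1, 4)
) -> RiskResult:
    """Binomial risk profile for ``k`` shared heterozygous recessive variants.

    ``p_per_variant`` is the per-condition risk to each offspring (1/4 for a
    couple who are both carriers). Computed in exact rational arithmetic;
    ``p_any = 1 - (1 - p)^k``.
    """
    if not isinstance(k, (int,)) or isinstance(k, bool):
        raise ValueError("k must be an integer")
    if k < 0:
        raise ValueError("k must be non-negative")
    p = Fraction(p_per_variant).limit_denominator(10**12) if not isinstance(
        p_per_variant, Fraction
    ) else p_per_variant
    if not (0 <= p <= 1):
        raise ValueError("p_per_variant must lie in [0, 1]")
    q = 1 - p
    pmf_exact = tuple(comb(k, j) * p**j * q ** (k - j) for j in range(k + 1))
    p_any = 1 - q**k
    return RiskResult(
        k=k,
        p_per_variant=float(p),
        p_any=float(p_any),
        pmf=tuple(float(x) for x in pmf_exact),
        pmf_exact=pmf_exact,
    )
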