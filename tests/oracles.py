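"""Independent reference computations used to check the package's results.

These deliberately take different routes than the implementation: exact
integer arithmetic for the Hardy-Weinberg test, and a step-by-step scalar
evaluation of the Weir-Cockerham intermediates.
"""

from fractions import Fraction
from functools import lru_cache
from math import comb


@lru_cache(maxsize=None)
def _hwe_weights(n: int, rare: int) -> tuple[int, ...]:
    """Exact integer weights of P(het = h | n, rare) for h = parity, parity+2, ...

    w(h) = multinomial(n; hom_rare, h, hom_common) * 2^h, an integer, so the
    tail comparison against the observed weight is exact.
    """
    weights = []
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        if hom_common < 0:
            weights.append(0)
            continue
        w = comb(n, h) * comb(n - h, hom_rare) * 2 ** h
        weights.append(w)
    return tuple(weights)


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Full-enumeration two-sided HWE exact p-value in exact rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0
    weights = _hwe_weights(n, rare)
    w_obs = weights[(n_Aa - rare % 2) // 2]
    p = Fraction(sum(w for w in weights if w <= w_obs), sum(weights))
    return float(p)


def wc_components_scalar(n_list, p_list, h_list):
    """Plain-Python evaluation of the Weir-Cockerham intermediates and a, b, c."""
    r = len(n_list)
    n_bar = sum(n_list) / r
    n_c = (r * n_bar - sum(ni ** 2 for ni in n_list) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n_list, p_list)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n_list, p_list)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n_list, h_list)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, b, c
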