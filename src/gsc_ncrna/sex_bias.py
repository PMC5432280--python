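"""Autosome-vs-X enrichment of sex-biased transcripts.

The 2x2 table is (biased/non-biased) x (autosomal/X-linked); the odds ratio
(a/b)/(c/d) is > 1 when the biased set is enriched on autosomes and < 1 when
it is enriched on X.  Significance comes from a two-sided Fisher exact test
computed by direct hypergeometric enumeration with exact integer arithmetic
(every table with a point probability no larger than the observed one is
summed).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Optional, Set

from .errors import ConfigError
from .io_formats import AUTOSOME, X_CHROM


@dataclass
class ChromContingency:
    a: int  # biased, autosomal
    b: int  # biased, X-linked
    c: int  # non-biased, autosomal
    d: int  # non-biased, X-linked
    odds_ratio: Optional[float]
    fisher_p: float


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The conditional distribution of ``a`` given all margins is hypergeometric.
    Point probabilities are compared as exact integer table counts, so ties
    are handled without floating-point tolerance; the final p is the summed
    count ratio.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ConfigError("contingency cells must be non-negative")
    m = a + b  # biased row total
    n2 = c + d
    k = a + c  # autosomal column total
    n = m + n2
    if n == 0:
        return 1.0
    lo, hi = max(0, k - n2), min(k, m)
    obs = comb(m, a) * comb(n2, c)
    selected = 0
    for x in range(lo, hi + 1):
        count = comb(m, x) * comb(n2, k - x)
        if count <= obs:
            selected += count
    return selected / comb(n, k)


def odds_ratio(a: int, b: int, c: int, d: int) -> Optional[float]:
    """(a/b)/(c/d); None when b or d is zero (undefined, no correction)."""
    if b == 0 or d == 0:
        return None
    if c == 0:
        return float("inf")
    return (a / b) / (c / d)


def chromosome_odds_ratio(
    biased_ids: Iterable[str],
    universe_ids: Iterable[str],
    chrom_class_map: Mapping[str, str],
) -> ChromContingency:
    """Tally the biased-vs-universe autosome/X table and test it.

    ``biased_ids`` must be a subset of ``universe_ids`` and every id needs a
    chromosome class (``autosome`` or ``X``).
    """
    universe: Set[str] = set(universe_ids)
    biased: Set[str] = set(biased_ids)
    if not universe:
        raise ConfigError("empty universe")
    if not biased <= universe:
        raise ConfigError("biased ids must be a subset of the universe")
    missing = [i for i in universe if i not in chrom_class_map]
    if missing:
        raise ConfigError(f"ids without chrom class: {sorted(missing)[:5]}")
    bad = [
        i for i in universe if chrom_class_map[i] not in (AUTOSOME, X_CHROM)
    ]
    if bad:
        raise ConfigError(f"unknown chrom class for ids: {sorted(bad)[:5]}")

    a = sum(1 for i in biased if chrom_class_map[i] == AUTOSOME)
    b = len(biased) - a
    non_biased = universe - biased
    c = sum(1 for i in non_biased if chrom_class_map[i] == AUTOSOME)
    d = len(non_biased) - c
    return ChromContingency(
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=odds_ratio(a, b, c, d),
        fisher_p=fisher_exact_two_sided(a, b, c, d),
    )
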