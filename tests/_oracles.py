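"""Independent oracles used by unit and acceptance tests.

Each oracle re-derives an expected result through a different route from the
implementation it checks (direct rule enumeration, exact rational arithmetic,
brute-force scans), and stays import-independent from the package internals
beyond plain data types.
"""

from fractions import Fraction
from math import comb
from typing import Dict, List, Tuple

MAX_SPAN = 100_000


def brute_force_candidates(alignments) -> Dict[Tuple[str, str, int, int], int]:
    """Re-apply the reversed-dual-segment rule per read, condition by
    condition, tallying raw junctions; independent of detect_candidates."""
    tally: Dict[Tuple[str, str, int, int], int] = {}
    for a in alignments:
        same_chrom = a.chrom1 == a.chrom2
        seg1_start, seg1_end = a.seg1
        seg2_start, seg2_end = a.seg2
        reversed_order = seg2_end <= seg1_start
        within_span = (seg1_end - seg2_start) <= MAX_SPAN
        if same_chrom and reversed_order and within_span:
            key = (a.chrom1, a.strand, seg2_start, seg1_end)
            tally[key] = tally.get(key, 0) + 1
    return tally


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    m, n2, k = a + b, c + d, a + c
    n = m + n2
    if n == 0:
        return 1.0
    denom = comb(n, k)
    obs = comb(m, a) * comb(n2, c)
    total = Fraction(0)
    for x in range(max(0, k - n2), min(k, m) + 1):
        cnt = comb(m, x) * comb(n2, k - x)
        if cnt <= obs:
            total += Fraction(cnt, denom)
    return float(total)


def pearson_oracle(x, y) -> float:
    """PCC from the raw covariance formula with Fraction-free plain floats."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def max_orf_oracle(seq: str) -> int:
    """Longest ATG..stop ORF (bp, stop included) via explicit window scan."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    n = len(seq)
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= n:
            if seq[j : j + 3] in stops:
                best = max(best, j + 3 - i)
                break
            j += 3
    return best


def seed_sites_oracle(target: str, mirna_seq_rna: str, circular: bool = False) -> List[Tuple[int, str]]:
    """Brute-force window scan for canonical seed sites.

    Returns (position, site_type) tuples, mirroring the documented site
    definitions from first principles (explicit reverse complement, explicit
    window comparisons).
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    seed = mirna_seq_rna.replace("U", "T")[1:8]
    rc7 = "".join(comp[b] for b in reversed(seed))
    core6, m8_base = rc7[1:], rc7[0]
    n = len(target)
    out: List[Tuple[int, str]] = []
    idx = range(n) if circular else range(n - 5)

    def at(i: int) -> str:
        return target[i % n] if circular else (target[i] if 0 <= i < n else "")

    for q in idx:
        window = "".join(at(q + k) for k in range(6))
        if window != core6:
            continue
        m8 = at(q - 1) == m8_base if (circular or q > 0) else False
        a1 = at(q + 6) == "A"
        if m8 and a1:
            out.append(((q - 1) % n if circular else q - 1, "8mer"))
        elif m8:
            out.append(((q - 1) % n if circular else q - 1, "7mer_m8"))
        elif a1:
            out.append((q % n, "7mer_A1"))
    return out
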