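"""Independent brute-force oracle for the exchange band tables.

Builds an explicit interval list per macronutrient (printed bands plus
their periodic extension) and answers lookups by linear scan.  Kept
deliberately separate from the closed-form arithmetic in the package so
the two can be compared on a dense grid.
"""

from typing import List, Tuple

# (lo, lo_closed, hi, hi_closed, exchanges)
Interval = Tuple[float, bool, float, bool, float]

MAX_G = 220.0


def starch_intervals() -> List[Interval]:
    out: List[Interval] = [(0.0, True, 5.5, False, 0.0), (5.5, True, 10.5, False, 0.5)]
    k = 1
    while 15 * k - 4.5 <= MAX_G:
        out.append((15 * k - 4.5, True, 15 * k + 5.5, False, float(k)))
        out.append((15 * k + 5.5, True, 15 * k + 10.5, False, k + 0.5))
        k += 1
    return out


def fat_intervals() -> List[Interval]:
    out: List[Interval] = [(0.0, True, 2.0, False, 0.0), (2.0, True, 4.0, False, 0.5)]
    k = 1
    while 5 * k - 1 <= MAX_G:
        out.append((5 * k - 1.0, True, 5 * k + 2.0, True, float(k)))
        out.append((5 * k + 2.0, False, 5 * k + 4.0, False, k + 0.5))
        k += 1
    return out


def lean_meat_intervals() -> List[Interval]:
    out: List[Interval] = [(0.0, True, 4.0, False, 0.0), (4.0, True, 14.0, False, 1.0)]
    k = 2
    while 7 * k <= MAX_G:
        out.append((7.0 * k, True, 7.0 * (k + 1), False, float(k)))
        k += 1
    return out


def scan(intervals: List[Interval], grams: float) -> float:
    hits = [
        v
        for lo, lo_c, hi, hi_c, v in intervals
        if (grams > lo or (lo_c and grams == lo))
        and (grams < hi or (hi_c and grams == hi))
    ]
    assert len(hits) == 1, f"bands must cover {grams} exactly once, got {hits}"
    return hits[0]
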