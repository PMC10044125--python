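"""Independent brute-force oracles for the sequence scanners.

Deliberately naive (position-by-position scans, quadratic smallest-period
checks) so they share no code path with the package implementations.
"""

from __future__ import annotations

from mitochar.control_region import SequenceHit


def motif_oracle(seq: str, motif: str) -> list[tuple[int, int]]:
    s, m = seq.upper(), motif.upper()
    out = []
    for i in range(len(s) - len(m) + 1):
        ok = True
        for j in range(len(m)):
            if m[j] != "N" and s[i + j] != m[j]:
                ok = False
                break
        if ok:
            out.append((i + 1, i + len(m)))
    return out


def homopolymer_oracle(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    s, b = seq.upper(), base.upper()
    out = []
    run = 0
    for i, ch in enumerate(s + "$"):
        if ch == b:
            run += 1
        else:
            if run >= min_len:
                out.append((i - run + 1, i))
            run = 0
    return out


def microsat_oracle(seq: str, unit: str, min_copies: int) -> list[tuple[int, int, int]]:
    """Maximal exact arrays of *unit*: (start, end incl. trailing partial,
    whole copies)."""
    s, u = seq.upper(), unit.upper()
    n, ul = len(s), len(u)
    out = []
    for i in range(n - ul + 1):
        if s[i : i + ul] != u:
            continue
        if i >= ul and s[i - ul : i] == u:
            continue  # not left-maximal
        k = 0
        while s[i + k * ul : i + (k + 1) * ul] == u:
            k += 1
        if k < min_copies:
            continue
        end = i + k * ul
        while end < n and s[end] == u[(end - i) % ul]:
            end += 1
        out.append((i + 1, end, k))
    return out


def _smallest_period_naive(s: str) -> int:
    for p in range(1, len(s) + 1):
        if all(s[i] == s[i + p] for i in range(len(s) - p)):
            return p
    return len(s)


def tandem_oracle(
    seq: str, min_unit: int, min_copies: int, max_unit: int
) -> list[tuple[int, int, str, int]]:
    """Maximal periodicity runs reported once at their smallest period:
    (start, end, unit, copies)."""
    s = seq.upper()
    n = len(s)
    out = []
    for p in range(min_unit, max_unit + 1):
        i = 0
        while i < n - p:
            if s[i] != s[i + p]:
                i += 1
                continue
            if i > 0 and s[i - 1] == s[i - 1 + p]:
                i += 1
                continue  # not left-maximal
            j = i
            while j < n - p and s[j] == s[j + p]:
                j += 1
            run = s[i : j + p]
            if len(run) // p >= min_copies and _smallest_period_naive(run) == p:
                out.append((i + 1, j + p, run[:p], len(run) // p))
            i = j + 1
    out.sort(key=lambda t: (t[0], len(t[2])))
    return out


def as_tuples(hits: list[SequenceHit], with_unit: bool = False):
    if with_unit:
        return [(h.start, h.end, h.unit, int(h.copies)) for h in hits]
    return [(h.start, h.end) for h in hits]
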