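"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values from first principles
(definition-level enumeration) rather than sharing code paths with the
package implementation.
"""

from __future__ import annotations

from typing import List, Set, Tuple

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_runs(s: str, min_tract: int = 2) -> List[Tuple[int, int, int]]:
    """All maximal repetitions by O(n^3+) enumeration of (start, end) pairs.

    For every substring the minimal period is found by direct testing of
    each candidate period; the substring is kept iff it holds at least two
    full periods, contains no N, and cannot be extended one position in
    either direction under the same period.
    """
    n = len(s)
    out = []
    for start in range(n):
        for end in range(start + 2, n + 1):
            sub = s[start:end]
            if "N" in sub:
                continue
            length = end - start
            p = next(
                d
                for d in range(1, length + 1)
                if all(sub[k] == sub[k - d] for k in range(d, length))
            )
            if length < 2 * p or length < min_tract:
                continue
            if start > 0 and s[start - 1] not in "N" and s[start - 1] == s[start - 1 + p]:
                continue  # extensible left
            if end < n and s[end] not in "N" and s[end] == s[end - p]:
                continue  # extensible right
            out.append((start, end, p))
    return sorted(out)


def fast_runs_oracle(s: str, min_tract: int = 2) -> List[Tuple[int, int, int]]:
    """Same enumeration, with minimal periods from per-start failure functions.

    Still checks every (start, end) pair against the run definition, but
    obtains each substring's minimal period incrementally, so random
    strings of length ~40 are cheap.  Agreement with :func:`naive_runs` is
    itself asserted in the suite on small strings.
    """
    n = len(s)
    out = []
    for start in range(n):
        sub = s[start:]
        m = len(sub)
        fail = [0] * m
        k = 0
        first_n = sub.find("N")
        limit = m if first_n == -1 else first_n
        for idx in range(1, limit):
            c = sub[idx]
            while k and c != sub[k]:
                k = fail[k - 1]
            if c == sub[k]:
                k += 1
            fail[idx] = k
            length = idx + 1
            p = length - k
            end = start + length
            if length < 2 * p or length < min_tract:
                continue
            if start > 0 and s[start - 1] != "N" and s[start - 1] == s[start - 1 + p]:
                continue
            if end < n and s[end] != "N" and s[end] == s[end - p]:
                continue
            out.append((start, end, p))
    return sorted(out)


def motif_class_count(k: int) -> int:
    """Number of canonical motif classes of length k by explicit orbit closure.

    Enumerates all 4^k strings, discards non-primitive ones, and unions
    rotation/reverse-complement orbits computed by breadth-first closure.
    """
    from itertools import product

    def revcomp(m: str) -> str:
        return "".join(_COMP[c] for c in reversed(m))

    def primitive(m: str) -> bool:
        for d in range(1, len(m)):
            if len(m) % d == 0 and m == m[:d] * (len(m) // d):
                return False
        return True

    seen: Set[str] = set()
    count = 0
    for tup in product("ACGT", repeat=k):
        m = "".join(tup)
        if m in seen or not primitive(m):
            continue
        count += 1
        frontier = {m}
        orbit: Set[str] = set()
        while frontier:
            x = frontier.pop()
            if x in orbit:
                continue
            orbit.add(x)
            frontier.add(x[1:] + x[0])
            frontier.add(revcomp(x))
        seen |= orbit
    return count


def bh_stepup(p_values) -> List[float]:
    """Benjamini-Hochberg adjusted values straight from the step-up definition:
    p_adj for the i-th smallest p is min_{k >= i} (m * p_(k) / k), capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p_values[i] / rank_from_top)
        adjusted[i] = running
    return adjusted


def exact_mw_p(case, control) -> Tuple[float, float]:
    """One-sided exact Mann-Whitney p by exhaustive labelling enumeration,
    with U computed by direct pairwise win counting (ties count 1/2)."""
    from itertools import combinations

    def u_stat(a, b):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
        )

    pooled = list(case) + list(control)
    n1 = len(case)
    u_obs = u_stat(case, control)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        if u_stat(chosen, rest) >= u_obs - 1e-9:
            count += 1
        total += 1
    return u_obs, count / total
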