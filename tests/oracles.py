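"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the implementation: the trimming
oracle is a plain dynamic-programming semi-global aligner, and the mapping
oracle scans every position of every oriented reference copy with numpy.
"""

from __future__ import annotations

import numpy as np


def semiglobal_best(pattern: str, text: str, budget: int):
    """Best semi-global occurrence of ``pattern`` inside ``text``.

    The whole pattern is aligned (unit-cost substitutions/indels); the match
    may start and end anywhere in ``text``.  Returns ``(end_offset, errors)``
    minimizing (errors, end_offset), or ``None`` if no occurrence fits the
    error budget.
    """
    m, n = len(pattern), len(text)
    prev = [0] * (n + 1)  # free start anywhere in text
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        pc = pattern[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j - 1] + (pc != text[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    best = None
    for j in range(n + 1):  # smallest end offset wins ties
        if prev[j] <= budget and (best is None or prev[j] < best[1]):
            best = (j, prev[j])
    return best


_ENC = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii").translate(_ENC), dtype=np.uint8)


def exhaustive_map(read: str, entries: list[tuple[str, str]], budget: int):
    """Exhaustively place a read over every position of every oriented entry.

    Mirrors the mapper's decision rule: report the placement with the fewest
    mismatches iff it is within ``budget`` and strictly better than every
    other placement; otherwise ``None``.
    """
    r = _encode(read)
    L = len(r)
    hits = []  # (nm, entry_idx, start0)
    for idx, (_, seq) in enumerate(entries):
        if len(seq) < L:
            continue
        g = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(g, L)
        nm = (windows != r).sum(axis=1)
        # two best placements per entry are enough to detect global ties
        order = np.argsort(nm, kind="stable")[:2]
        for start0 in order:
            hits.append((int(nm[start0]), idx, int(start0)))
    if not hits:
        return None
    hits.sort()
    best_nm, entry_idx, start0 = hits[0]
    if best_nm > budget:
        return None
    if len(hits) > 1 and hits[1][0] == best_nm:
        return None
    return (entries[entry_idx][0], start0 + 1, best_nm)
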