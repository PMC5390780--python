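"""Independent oracles used by the test suite.

These deliberately do NOT share code with the package: the alignment
oracle is a plain-Python Gotoh dynamic program, and the suffix-category
reference is a regex formulation of the classification rules.
"""

from __future__ import annotations

import re


def gotoh_local_score(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -3,
    gap_open: int = 2,
    gap_extend: int = 1,
) -> int:
    """Optimal local alignment score; a gap of length k costs open + k*extend."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    open_cost = gap_open + gap_extend
    H_prev = [0] * (m + 1)
    F_prev = [NEG] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        H_cur = [0] * (m + 1)
        F_cur = [NEG] * (m + 1)
        E = NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            E = max(H_cur[j - 1] - open_cost, E - gap_extend)
            F_cur[j] = max(H_prev[j] - open_cost, F_prev[j] - gap_extend)
            s = match if ai == b[j - 1] else mismatch
            h = max(0, H_prev[j - 1] + s, E, F_cur[j])
            H_cur[j] = h
            if h > best:
                best = h
        H_prev, F_prev = H_cur, F_cur
    return best


_OLIGO_RE = re.compile(r"(C|CC|CCA)?(A+)")


def reference_classify(end_offset: int, suffix: str) -> str:
    """Regex-based reference for the 3'-end category rules."""
    if set(suffix) - set("ACGT"):
        return "OTHER"
    if end_offset == 0 and suffix == "CCA":
        return "PLUS_CCA"
    m = _OLIGO_RE.fullmatch(suffix)
    if m and (m.group(1) is None or end_offset == 0):
        return "OLIGO_A"
    if end_offset == 0 and suffix == "CC":
        return "PLUS_CC"
    if end_offset == 0 and suffix == "C":
        return "PLUS_C"
    if suffix == "":
        if end_offset == 0:
            return "PROCESSED_EXACT"
        return "TRAILER" if end_offset > 0 else "TRIMMED"
    return "OTHER"


def all_suffixes(max_len: int) -> list[str]:
    """All ACGT strings of length 0..max_len (341 for max_len=4)."""
    out = [""]
    frontier = [""]
    for _ in range(max_len):
        frontier = [s + b for s in frontier for b in "ACGT"]
        out.extend(frontier)
    return out
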