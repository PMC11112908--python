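"""Independent brute-force oracles for the folding engines.

These enumerate nested structures explicitly (no interval dynamic program),
so they share no code path with the engines they check.
"""

from __future__ import annotations

from functools import lru_cache

from spscreen.rnastruct import is_canonical


def enumerate_structures(
    seq: str, min_hairpin: int = 3, allow_gu: bool = True
) -> list[tuple[tuple[int, int], ...]]:
    """All nested canonical pair sets over ``seq``, each exactly once."""

    @lru_cache(maxsize=None)
    def sub(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        # all structures of seq[i..j]
        if j - i < min_hairpin + 1:
            return ((),)
        out = list(sub(i + 1, j))  # i unpaired
        for k in range(i + min_hairpin + 1, j + 1):
            if is_canonical(seq[i], seq[k], allow_gu):
                inner = sub(i + 1, k - 1) if k - 1 >= i + 1 else ((),)
                rest = sub(k + 1, j) if k + 1 <= j else ((),)
                for a in inner:
                    for b in rest:
                        out.append(((i, k),) + a + b)
        return tuple(out)

    if len(seq) == 0:
        return [()]
    return [tuple(sorted(s)) for s in sub(0, len(seq) - 1)]


def max_pairs_by_enumeration(seq: str, min_hairpin: int = 3) -> int:
    return max(len(s) for s in enumerate_structures(seq, min_hairpin))
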