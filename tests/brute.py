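"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: runs are found by testing
every (start, period) pair with plain string slicing, primitivity by checking
every divisor prefix, and the heterogeneity statistic by a literal
transcription of the goodness-of-fit formula.
"""

from __future__ import annotations

ACGT = set("ACGT")


def brute_smallest_period(s: str) -> int:
    for p in range(1, len(s) + 1):
        if len(s) % p == 0 and s[:p] * (len(s) // p) == s:
            return p
    raise AssertionError("unreachable")


def brute_is_primitive(motif: str) -> bool:
    return brute_smallest_period(motif) == len(motif)


def brute_force_runs(seq: str, k_max: int = 10):
    """Every maximal perfect run of a primitive motif with >= 2 whole units.

    A run starts where the pattern cannot be continued one character to the
    left, counts whole units only, and never touches a non-ACGT character.
    """
    out = []
    n = len(seq)
    for k in range(1, k_max + 1):
        for i in range(0, n - 2 * k + 1):
            motif = seq[i : i + k]
            if set(motif) - ACGT:
                continue
            if not brute_is_primitive(motif):
                continue
            # left maximality at character level
            if i > 0 and seq[i - 1] in ACGT and seq[i - 1] == seq[i - 1 + k]:
                continue
            j = i + k
            while j + k <= n and seq[j : j + k] == motif:
                j += k
            units = (j - i) // k
            if units >= 2:
                out.append((i, k, units, motif))
    out.sort()
    return out
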