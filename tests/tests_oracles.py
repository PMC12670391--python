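"""Shared brute-force oracles kept independent of the library's
implementation paths."""

import numpy as np


def brute_pairs(coords, set_a, set_b, cutoff):
    n = 0
    for i in set_a:
        for j in set_b:
            if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                n += 1
    return n


def brute_elastic_pairs(coords, chains, resnums, cutoff):
    """All-pairs rule: same chain, non-adjacent residues, distance
    strictly below the cutoff."""
    out = set()
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            if chains[i] != chains[j]:
                continue
            if abs(int(resnums[i]) - int(resnums[j])) <= 1:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                out.add((i, j))
    return out
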