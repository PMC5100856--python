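"""Independent brute-force four-gamete oracle used by the test suite.

Deliberately coded without reusing any of the library's pair-test or
partition internals: gametes are enumerated with a Counter and the greedy
maximal-extension rule is re-applied from its definition.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from consomix import hapblocks as hb


def oracle_pair_recombinant(matrix, i, j, freq=0.01, min_count=1) -> bool:
    gametes = Counter()
    for row in matrix.alleles:
        if row[i] != hb.MISSING and row[j] != hb.MISSING:
            gametes[(int(row[i]), int(row[j]))] += 1
    n = sum(gametes.values())
    if len(gametes) < 4:
        return False
    return all(c >= min_count and c / n >= freq for c in gametes.values())


def oracle_partition(matrix, freq=0.01, min_count=1) -> list[tuple[int, int]]:
    """Greedy maximal extension with independently recomputed pair tests."""
    m = matrix.n_snps
    if m == 0:
        return []
    blocks, start = [], 0
    for j in range(1, m):
        if any(oracle_pair_recombinant(matrix, i, j, freq, min_count)
               for i in range(start, j)):
            blocks.append((start, j - 1))
            start = j
    blocks.append((start, m - 1))
    return blocks


def polymorphic_columns(alleles: np.ndarray) -> np.ndarray:
    keep = []
    for k in range(alleles.shape[1]):
        col = alleles[:, k][alleles[:, k] != hb.MISSING]
        keep.append(len(col) > 0 and not np.all(col == col[0]))
    return np.array(keep, dtype=bool)


def random_matrix(rng, n_lines, n_snps, missing_p=0.1) -> hb.HaplotypeMatrix:
    """Random matrix whose columns are all polymorphic among non-missing."""
    while True:
        alleles = rng.integers(0, 2, size=(n_lines, n_snps)).astype(np.int8)
        mask = rng.random((n_lines, n_snps)) < missing_p
        alleles[mask] = hb.MISSING
        if polymorphic_columns(alleles).all():
            return hb.HaplotypeMatrix(
                "chr1", np.arange(1, n_snps + 1) * 50,
                [f"l{i}" for i in range(n_lines)], alleles,
            )
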