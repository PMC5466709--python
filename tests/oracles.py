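"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package kernels: the aligner is
a memoized recursion over suffixes (vs the package's iterative matrix with
end-cell search), the bimera oracle enumerates orderings × breakpoints with
explicit counting loops, and the rarefaction oracle is plain Monte-Carlo
subsampling.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

import numpy as np

MATCH, MISMATCH, GAP = 1, -1, -2


def brute_semiglobal_score(a: str, b: str) -> int:
    """Optimal semi-global score (free terminal gaps, N never matches) by
    memoized recursion; independent of the package's DP."""

    @lru_cache(maxsize=None)
    def suffix(i: int, j: int) -> int:
        if i == len(a) or j == len(b):
            return 0  # trailing terminal gaps are free
        s = MATCH if (a[i] == b[j] and a[i] in "ACGT" and b[j] in "ACGT") else MISMATCH
        return max(
            suffix(i + 1, j + 1) + s,
            suffix(i + 1, j) + GAP,
            suffix(i, j + 1) + GAP,
        )

    best = max(
        max(suffix(i, 0) for i in range(len(a) + 1)),
        max(suffix(0, j) for j in range(len(b) + 1)),
    )
    suffix.cache_clear()
    return best


def hamming_profile(query: str, parent: str) -> List[bool]:
    """Per-position match profile for equal-length sequences (no alignment)."""
    assert len(query) == len(parent)
    return [
        q == p and q in "ACGT" and p in "ACGT" for q, p in zip(query, parent)
    ]


def brute_bimera(
    prof_a: Sequence[bool], prof_b: Sequence[bool]
) -> Tuple[int, int]:
    """(min two-parent mismatches over all orderings and breakpoints,
    best single-parent mismatches), by explicit enumeration."""
    L = len(prof_a)
    best_model = None
    for left, right in ((prof_a, prof_b), (prof_b, prof_a)):
        for x in range(L + 1):
            m = sum(1 for i in range(x) if not left[i])
            m += sum(1 for i in range(x, L) if not right[i])
            if best_model is None or m < best_model:
                best_model = m
    single = min(
        sum(1 for v in prof_a if not v), sum(1 for v in prof_b if not v)
    )
    return best_model, single


def naive_edit_distance(a: str, b: str) -> int:
    """Full-matrix unit-cost edit distance; N never matches."""
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1), dtype=int)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else 1
            D[i, j] = min(D[i - 1, j - 1] + cost, D[i - 1, j] + 1, D[i, j - 1] + 1)
    return int(D[n, m])


def monte_carlo_richness(
    otu_sizes: Sequence[int], depth: int, n_rep: int, rng: np.random.Generator
) -> Tuple[float, float]:
    """Mean and standard error of observed OTU counts over random
    subsamples without replacement."""
    labels = np.repeat(np.arange(len(otu_sizes)), otu_sizes)
    observed = np.empty(n_rep)
    for r in range(n_rep):
        pick = rng.choice(labels, size=depth, replace=False)
        observed[r] = len(np.unique(pick))
    return float(observed.mean()), float(observed.std(ddof=1) / np.sqrt(n_rep))


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
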