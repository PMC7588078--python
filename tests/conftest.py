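import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from sortscreen import CountMatrix, LibraryDesign


@pytest.fixture
def tiny_library() -> LibraryDesign:
    """Two genes x two guides plus two NTCs, 6-mer spacers."""
    rows = [
        ("gA_sg1", "GENEA", "GENEA_TSS1", "AAAAAA", "L1"),
        ("gA_sg2", "GENEA", "GENEA_TSS1", "CCCCCC", "L1"),
        ("gB_sg1", "GENEB", "GENEB_TSS1", "GGGGGG", "L1"),
        ("gB_sg2", "GENEB", "GENEB_TSS1", "TTTTTT", "L1"),
        ("ntc_1", "NTC", "", "ACGTAC", "L1"),
        ("ntc_2", "NTC", "", "TGCATG", "L1"),
    ]
    return LibraryDesign(
        pd.DataFrame(
            rows, columns=["sgrna_id", "target", "tss_id", "spacer", "library_id"]
        )
    )


@pytest.fixture
def tiny_counts(tiny_library) -> CountMatrix:
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.integers(5, 200, size=(len(tiny_library), 3)),
        index=tiny_library.sgrna_ids,
        columns=["low", "medium", "high"],
    )
    return CountMatrix(counts, library_id="L1")


def exhaustive_mannwhitney_p(x, y) -> float:
    """Independent two-sided Mann-Whitney oracle by full enumeration.

    Enumerates every assignment of the pooled ranks to the smaller sample,
    builds the exact null distribution of U, and doubles the smaller
    inclusive tail.  Assumes no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    pooled = n + m
    u_values = []
    for positions in itertools.combinations(range(pooled), n):
        # ranks occupied by the x-sample; U = sum(rank_i) - n(n+1)/2
        u_values.append(sum(positions) - n * (n - 1) // 2)
    u_values = np.array(u_values)
    total = len(u_values)
    lower = Fraction(int((u_values <= u_obs).sum()), total)
    upper = Fraction(int((u_values >= u_obs).sum()), total)
    p = 2 * min(lower, upper)
    return float(min(p, Fraction(1)))


def brute_force_epsilon(values, ids, k=3) -> float:
    """Independent epsilon oracle: exhaustively search all size-k subsets
    for maximal total |L2FC|, breaking ties by the smallest sorted id tuple,
    then average the signed members."""
    values = np.asarray(values, dtype=float)
    k = min(k, len(values))
    best_key = None
    best_mean = None
    for subset in itertools.combinations(range(len(values)), k):
        # exact rational total so tied subsets are true ties
        total = -sum(abs(Fraction(float(values[i]))) for i in subset)
        key = (total, tuple(sorted(str(ids[i]) for i in subset)))
        if best_key is None or key < best_key:
            best_key = key
            best_mean = float(values[list(subset)].mean())
    return best_mean
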