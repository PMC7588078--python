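"""Empirical FDR via negative-control quasi-genes, and hit calling.

Quasi-genes are pseudo-genes assembled by drawing 5 NTC guides with
replacement; scored exactly like real genes, their hit-strength distribution
is an empirical null.  The FDR at a |hit strength| cutoff t is the ratio of
the quasi and real exceedance fractions, and the reported threshold is the
smallest attained real value whose FDR - and that of every attained value
above it - stays below the target (default 0.10).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .errors import ConfigurationError, NoPassingGenesError
from .library_io import CountMatrix, LibraryDesign
from .phenotype import (
    ComparisonSpec,
    compute_centered_lfcs,
    gene_epsilon,
    gene_pvalue,
    hit_strength,
)

logger = logging.getLogger(__name__)

#: fraction names in increasing fluorescence order
FRACTION_ORDER = {"low": 0, "medium": 1, "high": 2}


@dataclass(frozen=True)
class QuasiGeneSet:
    """Groups of NTC guide ids (size 5 by default, repeats allowed)."""

    groups: tuple[tuple[str, tuple[str, ...]], ...]
    seed: int

    def __len__(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class ThresholdResult:
    """The chosen |hit strength| cutoff and the FDR estimate it achieves."""

    threshold: float
    achieved_fdr: float
    target_fdr: float
    n_hits: int


def make_quasi_genes(
    library: LibraryDesign,
    n_quasi: int | None = None,
    group_size: int = 5,
    seed: int = 0,
) -> QuasiGeneSet:
    """Draw ``n_quasi`` quasi-genes, each ``group_size`` NTC ids sampled
    uniformly with replacement.  ``n_quasi`` defaults to the number of real
    targets so the FDR ratio is on the unit scale."""
    ntc_ids = library.ntc_ids
    if not ntc_ids:
        raise ConfigurationError("library has no NTCs to build quasi-genes from")
    if group_size < 1:
        raise ConfigurationError("quasi-gene group size must be >= 1")
    if n_quasi is None:
        n_quasi = len(library.targets())
    if n_quasi < 0:
        raise ConfigurationError("n_quasi must be >= 0")
    rng = np.random.default_rng(seed)
    width = len(str(max(n_quasi, 1)))
    groups = tuple(
        (
            f"quasi_{i + 1:0{width}d}",
            tuple(rng.choice(ntc_ids, size=group_size, replace=True)),
        )
        for i in range(n_quasi)
    )
    return QuasiGeneSet(groups=groups, seed=seed)


def score_quasi_genes(
    matrix: CountMatrix,
    library: LibraryDesign,
    quasi: QuasiGeneSet,
    comparison: ComparisonSpec,
    pseudocount: float = 1.0,
    k: int = 3,
    center: bool = True,
) -> pd.DataFrame:
    """Score each quasi-gene exactly as a real gene: epsilon over its member
    L2FCs, Mann-Whitney against all NTC L2FCs, hit strength."""
    centered = compute_centered_lfcs(matrix, library, comparison, pseudocount, center)
    ntc_values = centered.loc[
        [i for i in library.ntc_ids if i in centered.index]
    ].to_numpy()
    records = []
    for quasi_id, members in quasi.groups:
        lfcs = centered.loc[list(members)]
        eps = gene_epsilon(lfcs.to_numpy(), k=k, ids=list(members))
        p = gene_pvalue(lfcs.to_numpy(), ntc_values)
        records.append((quasi_id, eps, p, hit_strength(eps, p), len(members)))
    return pd.DataFrame(
        records, columns=["target", "epsilon", "p_value", "hit_strength", "n_sgrnas"]
    )


def _abs_hit_strengths(scores) -> np.ndarray:
    if isinstance(scores, pd.DataFrame):
        values = scores["hit_strength"].to_numpy()
    else:
        values = np.asarray(scores, dtype=float)
    return np.abs(values)


def empirical_fdr(real_scores, quasi_scores, threshold: float) -> float:
    """FDR(t) = [Q(t)/N_Q] / [R(t)/N_R] with Q, R the numbers of quasi and
    real entries whose |hit strength| >= t.

    Zero when no quasi-gene passes; raises NoPassingGenesError when no real
    gene does (the caller should move the threshold).
    """
    real = _abs_hit_strengths(real_scores)
    quasi = _abs_hit_strengths(quasi_scores)
    if len(real) == 0 or len(quasi) == 0:
        raise ConfigurationError("empirical_fdr needs non-empty score sets")
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    n_real_pass = int((real >= threshold).sum())
    n_quasi_pass = int((quasi >= threshold).sum())
    if n_real_pass == 0:
        raise NoPassingGenesError(f"no real gene attains |hit strength| >= {threshold}")
    if n_quasi_pass == 0:
        return 0.0
    return (n_quasi_pass / len(quasi)) / (n_real_pass / len(real))


def find_threshold(
    real_scores, quasi_scores, target_fdr: float = 0.10
) -> ThresholdResult:
    """Choose the hit-calling cutoff: the smallest attained real
    |hit strength| t such that the empirical FDR stays below ``target_fdr``
    at t and at every attained value above it.

    If even the most extreme real gene fails, the threshold is +inf and no
    hits are called (a valid outcome, not an error).
    """
    real = _abs_hit_strengths(real_scores)
    quasi = _abs_hit_strengths(quasi_scores)
    if len(real) == 0 or len(quasi) == 0:
        raise ConfigurationError("find_threshold needs non-empty score sets")
    candidates = np.unique(real)[::-1]  # attained values, descending
    best = math.inf
    for t in candidates:
        if empirical_fdr(real, quasi, float(t)) < target_fdr:
            best = float(t)
        else:
            break
    if math.isinf(best):
        return ThresholdResult(math.inf, math.nan, target_fdr, 0)
    achieved = empirical_fdr(real, quasi, best)
    n_hits = int((real >= best).sum())
    return ThresholdResult(best, achieved, target_fdr, n_hits)


def regulator_sign(epsilon: float, comparison: ComparisonSpec) -> str:
    """Map an epsilon sign to a regulator class for a given comparison.

    Positive regulators enrich in the lower-fluorescence fraction of the
    pair when silenced; negative regulators in the higher one.  The mapping
    therefore flips when the comparison's numerator is the higher fraction.
    """
    for sample in (comparison.numerator, comparison.denominator):
        if sample not in FRACTION_ORDER:
            raise ConfigurationError(
                f"unknown fraction {sample!r}; expected one of {list(FRACTION_ORDER)}"
            )
    numerator_is_lower = (
        FRACTION_ORDER[comparison.numerator] < FRACTION_ORDER[comparison.denominator]
    )
    if epsilon == 0:
        return "none"
    if epsilon > 0:
        return "positive" if numerator_is_lower else "negative"
    return "negative" if numerator_is_lower else "positive"


def call_hits(
    real_scores: pd.DataFrame,
    threshold_result: ThresholdResult,
    comparison: ComparisonSpec,
) -> pd.DataFrame:
    """Return the rows of ``real_scores`` passing the threshold, annotated
    with regulator sign and the comparison name."""
    if threshold_result.threshold == 0:
        logger.warning("threshold is 0: every gene, including epsilon=0, passes")
    mask = real_scores["hit_strength"].abs() >= threshold_result.threshold
    hits = real_scores.loc[mask].copy()
    hits["regulator_sign"] = [
        regulator_sign(e, comparison) for e in hits["epsilon"]
    ]
    hits["comparison"] = comparison.name
    return hits.reset_index(drop=True)
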