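"""Per-sgRNA and per-gene scoring for one pairwise fraction comparison.

The scoring chain is: pseudocounted frequency normalization per sample,
log2 fold change (L2FC) per guide between the two samples, centering to the
library's non-targeting-control (NTC) median, a gene phenotype score epsilon
(mean signed L2FC of the gene's 3 most extreme guides), a two-sided
Mann-Whitney U p-value of the gene's guide L2FCs against all NTC L2FCs, and
hit strength = epsilon x -log10(p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ConfigurationError, ValidationError
from .library_io import CountMatrix, LibraryDesign, NTC_TARGET

_TINY = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class ComparisonSpec:
    """One pairwise fraction comparison, numerator over denominator."""

    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ConfigurationError("comparison samples must be distinct")

    @property
    def name(self) -> str:
        return f"{self.numerator}_vs_{self.denominator}"

    def reversed(self) -> "ComparisonSpec":
        return ComparisonSpec(self.denominator, self.numerator)


def normalize_counts(
    matrix: CountMatrix,
    library: LibraryDesign | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pseudocounted per-sample frequencies:
    ``freq(i, s) = (count(i, s) + pc) / sum_j (count(j, s) + pc)``.

    Each column sums to 1.  The default pseudocount of one read per guide per
    sample guarantees finite log fold changes with minimal influence on
    well-covered guides.
    """
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    counts = matrix.counts
    if library is not None:
        counts = matrix.align_to_library(library).counts
    shifted = counts.astype(float) + pseudocount
    totals = shifted.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ZeroDivisionError(
            f"columns {bad} sum to zero; use a positive pseudocount"
        )
    return shifted / totals


def sgrna_log2fc(freqs: pd.DataFrame, comparison: ComparisonSpec) -> pd.Series:
    """Per-guide log2 fold change of normalized frequency between the two
    samples of ``comparison`` (numerator over denominator)."""
    for sample in (comparison.numerator, comparison.denominator):
        if sample not in freqs.columns:
            raise ConfigurationError(f"sample {sample!r} missing from frequencies")
    lfc = np.log2(freqs[comparison.numerator] / freqs[comparison.denominator])
    return lfc.rename("lfc")


def center_to_ntc(lfc: pd.Series, library: LibraryDesign) -> pd.Series:
    """Subtract the median NTC L2FC so the NTC median of the output is 0."""
    ntc_ids = [i for i in library.ntc_ids if i in lfc.index]
    if not ntc_ids:
        raise ConfigurationError("library has no NTCs present in the L2FC table")
    return (lfc - float(lfc.loc[ntc_ids].median())).rename("lfc")


def gene_epsilon(
    lfcs: Sequence[float] | pd.Series,
    k: int = 3,
    ids: Sequence[str] | None = None,
) -> float:
    """Gene phenotype score: mean signed L2FC of the ``min(k, n)`` guides
    with the largest absolute (centered) L2FC.

    Ties in absolute value are broken by ascending guide id (or input
    position when no ids are given) for determinism.
    """
    if isinstance(lfcs, pd.Series):
        if ids is None:
            ids = list(lfcs.index)
        lfcs = lfcs.to_numpy()
    values = np.asarray(lfcs, dtype=float)
    n = len(values)
    if n == 0:
        raise ValidationError("gene_epsilon needs at least one guide")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    keys = list(ids) if ids is not None else list(range(n))
    order = sorted(range(n), key=lambda i: (-abs(values[i]), keys[i]))
    chosen = sorted(order[: min(k, n)])  # input order for stable summation
    return float(values[chosen].mean())


def gene_pvalue(
    gene_lfcs: Sequence[float], ntc_lfcs: Sequence[float]
) -> float:
    """Two-sided Mann-Whitney U p-value of a gene's guide L2FCs against the
    NTC L2FCs.

    Uses the exact null distribution when ``min(n, m) <= 8`` and there are no
    ties, otherwise the normal approximation with tie correction.  The result
    is clamped into (0, 1].
    """
    x = np.asarray(gene_lfcs, dtype=float)
    y = np.asarray(ntc_lfcs, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("Mann-Whitney requires two non-empty samples")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    p = float(
        mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )
    return min(max(p, _TINY), 1.0)


def hit_strength(epsilon: float, p: float) -> float:
    """Signed hit strength ``epsilon x -log10(p)``; zero when p = 1."""
    return epsilon * -np.log10(p)


def score_genes(
    matrix: CountMatrix,
    library: LibraryDesign,
    comparison: ComparisonSpec,
    pseudocount: float = 1.0,
    k: int = 3,
    center: bool = True,
) -> pd.DataFrame:
    """Score every gene-targeting TSS of one library for one comparison.

    Returns a DataFrame with columns ``target, tss_id, epsilon, p_value,
    hit_strength, n_sgrnas``, one row per (target, tss_id), sorted.  NTC
    guides provide the centering reference and the Mann-Whitney null but are
    not themselves scored.
    """
    if len(library.library_ids) > 1:
        raise ConfigurationError(
            "score_genes expects a single library; use run_all_comparisons "
            "for multi-library screens"
        )
    centered = compute_centered_lfcs(matrix, library, comparison, pseudocount, center)
    ntc_values = centered.loc[[i for i in library.ntc_ids if i in centered.index]]

    entries = library.entries
    gene_rows = entries[entries["target"] != NTC_TARGET]
    records = []
    for (target, tss_id), group in gene_rows.groupby(["target", "tss_id"], sort=True):
        lfcs = centered.loc[group["sgrna_id"]]
        eps = gene_epsilon(lfcs, k=k)
        p = gene_pvalue(lfcs.to_numpy(), ntc_values.to_numpy())
        records.append(
            (target, tss_id, eps, p, hit_strength(eps, p), len(group))
        )
    return pd.DataFrame(
        records,
        columns=["target", "tss_id", "epsilon", "p_value", "hit_strength", "n_sgrnas"],
    )


def compute_centered_lfcs(
    matrix: CountMatrix,
    library: LibraryDesign,
    comparison: ComparisonSpec,
    pseudocount: float = 1.0,
    center: bool = True,
) -> pd.Series:
    """Normalize, take L2FC for ``comparison``, and (by default) center to
    the NTC median.  Shared by real-gene and quasi-gene scoring."""
    freqs = normalize_counts(matrix, library, pseudocount)
    lfc = sgrna_log2fc(freqs, comparison)
    return center_to_ntc(lfc, library) if center else lfc
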