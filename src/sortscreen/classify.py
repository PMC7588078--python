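"""Three-comparison orchestration, confidence classes, and report tables.

Hits from the "low" vs "high" comparison are high-confidence; hits appearing
only in a comparison involving the "medium" fraction are putative.  TSS-level
scores collapse to genes by keeping the most extreme hit strength, and the
overlap between hit sets is tested with the hypergeometric (one-sided
Fisher's exact) tail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigurationError, ValidationError
from .fdr import (
    ThresholdResult,
    call_hits,
    find_threshold,
    make_quasi_genes,
    score_quasi_genes,
)
from .library_io import CountMatrix, LibraryDesign
from .phenotype import ComparisonSpec, score_genes

#: the three pairwise comparisons of the sorted fractions, numerator first
DEFAULT_COMPARISONS = (
    ComparisonSpec("low", "high"),
    ComparisonSpec("medium", "high"),
    ComparisonSpec("medium", "low"),
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for the full screen analysis."""

    pseudocount: float = 1.0
    k: int = 3  # guides averaged into epsilon
    target_fdr: float = 0.10
    n_quasi: int | None = None  # default: one quasi-gene per real target
    quasi_group_size: int = 5
    center: bool = True
    seed: int = 0


@dataclass(frozen=True)
class ComparisonResult:
    comparison: ComparisonSpec
    scores: pd.DataFrame
    quasi_scores: pd.DataFrame
    threshold: ThresholdResult
    hits: pd.DataFrame


def run_all_comparisons(
    matrix: CountMatrix,
    library: LibraryDesign,
    config: AnalysisConfig = AnalysisConfig(),
) -> dict[str, ComparisonResult]:
    """Score all three pairwise fraction comparisons and call hits in each.

    Scoring is per library (each library's own NTCs normalize and calibrate
    it); score tables from multiple libraries are concatenated before one
    threshold per comparison is chosen.  Quasi-gene seeds derive from
    ``config.seed`` deterministically, one offset per (library, comparison).
    """
    for sample in ("low", "medium", "high"):
        if sample not in matrix.counts.columns:
            raise ConfigurationError(f"count matrix lacks a {sample!r} column")

    results: dict[str, ComparisonResult] = {}
    library_ids = library.library_ids
    for c_index, comparison in enumerate(DEFAULT_COMPARISONS):
        score_tables = []
        quasi_tables = []
        for l_index, lib_id in enumerate(library_ids):
            sub_library = library.subset(lib_id)
            sub_matrix = matrix.restrict(library, lib_id)
            scores = score_genes(
                sub_matrix,
                sub_library,
                comparison,
                pseudocount=config.pseudocount,
                k=config.k,
                center=config.center,
            )
            quasi = make_quasi_genes(
                sub_library,
                n_quasi=config.n_quasi,
                group_size=config.quasi_group_size,
                seed=(config.seed + 1000 * c_index + l_index) % 2**31,
            )
            quasi_scores = score_quasi_genes(
                sub_matrix,
                sub_library,
                quasi,
                comparison,
                pseudocount=config.pseudocount,
                k=config.k,
                center=config.center,
            )
            scores.insert(0, "library_id", lib_id)
            quasi_scores.insert(0, "library_id", lib_id)
            score_tables.append(scores)
            quasi_tables.append(quasi_scores)
        all_scores = pd.concat(score_tables, ignore_index=True)
        all_quasi = pd.concat(quasi_tables, ignore_index=True)
        threshold = find_threshold(all_scores, all_quasi, config.target_fdr)
        hits = call_hits(all_scores, threshold, comparison)
        results[comparison.name] = ComparisonResult(
            comparison, all_scores, all_quasi, threshold, hits
        )
    return results


@dataclass(frozen=True)
class HitClassification:
    """Hit table with confidence classes plus the headline counts."""

    table: pd.DataFrame
    n_high_confidence: int
    n_putative: int
    n_shared: int


def _gene_set(hits) -> set[str]:
    if isinstance(hits, pd.DataFrame):
        return set(hits["target"])
    return set(hits)


def classify_hits(
    hits_low_high,
    hits_medium_low,
    hits_medium_high,
) -> HitClassification:
    """Assign confidence classes across the three comparisons.

    Genes hit in (low, high) are high-confidence; genes hit in either
    medium comparison but not in (low, high) are putative (high-confidence
    takes precedence, so the classes partition the hit genes).  Inputs may
    be hit DataFrames (with a ``target`` column) or bare gene collections.

    Each classified gene contributes one row: its (low, high) row for
    high-confidence genes, or its most extreme medium-comparison row for
    putative genes (when score columns are available).
    """
    strong = _gene_set(hits_low_high)
    medium_union = _gene_set(hits_medium_low) | _gene_set(hits_medium_high)
    shared = strong & medium_union
    putative = medium_union - strong

    rows = []
    if isinstance(hits_low_high, pd.DataFrame) and len(hits_low_high):
        strong_rows = hits_low_high.copy()
    else:
        strong_rows = pd.DataFrame({"target": sorted(strong)})
    strong_rows["confidence_class"] = "high_confidence"
    rows.append(strong_rows)

    medium_frames = [
        h for h in (hits_medium_low, hits_medium_high) if isinstance(h, pd.DataFrame)
    ]
    if medium_frames and any(len(f) for f in medium_frames):
        combined = pd.concat(medium_frames, ignore_index=True)
        combined = combined[combined["target"].isin(putative)]
        if "hit_strength" in combined.columns:
            combined = combined.reindex(
                combined["hit_strength"].abs().sort_values(ascending=False).index
            )
        putative_rows = combined.drop_duplicates("target", keep="first")
    else:
        putative_rows = pd.DataFrame({"target": sorted(putative)})
    putative_rows = putative_rows.copy()
    putative_rows["confidence_class"] = "putative"
    rows.append(putative_rows)

    table = pd.concat(rows, ignore_index=True).sort_values(
        ["confidence_class", "target"], ignore_index=True
    )
    return HitClassification(
        table=table,
        n_high_confidence=len(strong),
        n_putative=len(putative),
        n_shared=len(shared),
    )


def collapse_tss_to_gene(scores: pd.DataFrame) -> pd.DataFrame:
    """Collapse TSS-level score rows to one row per gene, keeping the row
    with the largest |hit strength| (ties: smallest tss_id)."""
    for col in ("target", "tss_id", "hit_strength"):
        if col not in scores.columns:
            raise ConfigurationError(f"scores table lacks a {col!r} column")
    ordered = scores.assign(_abs_hs=scores["hit_strength"].abs()).sort_values(
        ["target", "_abs_hs", "tss_id"], ascending=[True, False, True]
    )
    collapsed = ordered.drop_duplicates("target", keep="first").drop(columns="_abs_hs")
    return collapsed.reset_index(drop=True)


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> tuple[int, float]:
    """Hypergeometric upper-tail (one-sided Fisher's exact) test for the
    overlap of two gene sets in a universe of ``universe_size`` genes.

    Returns ``(overlap, P(X >= overlap))`` with the tail computed in log
    space for numerical range.
    """
    a, b = set(set_a), set(set_b)
    if max(len(a), len(b)) > universe_size:
        raise ValidationError("set sizes exceed the universe size")
    overlap = len(a & b)
    if overlap == 0:
        return 0, 1.0
    log_p = hypergeom.logsf(overlap - 1, universe_size, len(a), len(b))
    return overlap, float(np.exp(log_p))


def write_volcano_table(
    scores: pd.DataFrame,
    threshold: ThresholdResult,
    comparison: ComparisonSpec,
    path: Union[str, Path, None] = None,
) -> pd.DataFrame:
    """Volcano-plot table: epsilon vs -log10 p with hit flag and regulator
    sign, sorted by gene; optionally written as TSV (12 significant digits,
    enough to round-trip)."""
    from .fdr import regulator_sign

    out = scores[["target"]].copy()
    if "tss_id" in scores.columns:
        out["tss_id"] = scores["tss_id"]
    out["epsilon"] = scores["epsilon"]
    out["neg_log10_p"] = -np.log10(scores["p_value"])
    out["hit_strength"] = scores["hit_strength"]
    out["hit"] = scores["hit_strength"].abs() >= threshold.threshold
    out["regulator_sign"] = [
        regulator_sign(e, comparison) for e in scores["epsilon"]
    ]
    out = out.sort_values("target", ignore_index=True)
    if path is not None:
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return out


def summarize(
    results: Mapping[str, ComparisonResult],
    classification: HitClassification,
    overlap: tuple[int, float] | None = None,
) -> dict:
    """JSON-ready summary: per-comparison thresholds, achieved FDRs and hit
    counts, plus the confidence-class accounting."""
    summary = {
        "comparisons": {
            name: {
                "threshold": res.threshold.threshold,
                "achieved_fdr": res.threshold.achieved_fdr,
                "target_fdr": res.threshold.target_fdr,
                "n_hits": res.threshold.n_hits,
            }
            for name, res in results.items()
        },
        "n_high_confidence": classification.n_high_confidence,
        "n_putative": classification.n_putative,
        "n_shared": classification.n_shared,
    }
    if overlap is not None:
        summary["overlap"] = {"count": overlap[0], "p_value": overlap[1]}
    return summary


def write_summary(summary: dict, path: Union[str, Path]) -> None:
    def _default(x):
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        raise TypeError(type(x))

    with open(path, "w") as handle:
        json.dump(summary, handle, indent=2, default=_default)
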