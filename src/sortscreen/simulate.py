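"""Synthetic three-fraction reporter-sorting screens with known ground truth.

The generative model follows the screen design: cells are infected at MOI < 1
(exactly one sgRNA each), induced-reporter fluorescence is a two-component
lognormal mixture (a large right-shifted responding peak plus a small
left-shifted non-responding peak), silencing a regulator shifts a responding
cell's log10 fluorescence by the gene effect scaled by per-guide knockdown
activity, cells are sorted at the valley between the two peaks with the
responding population split into two equal halves ("medium"/"high"), and each
sorted fraction is sequenced as a multinomial draw over its per-guide cell
tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .errors import ConfigurationError
from .library_io import CountMatrix, LibraryDesign, NTC_TARGET

logger = logging.getLogger(__name__)

_FRACTIONS = ("low", "medium", "high")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions for one simulated screen.

    Fluorescence is modelled in log10 arbitrary units.  Defaults give a
    ~30-fold dynamic range between the non-responding and fully induced
    peaks, a within-peak spread typical of a clonal reporter line, and a
    small (10%) left-shifted non-responder population.
    """

    n_genes: int
    sgrnas_per_gene: int = 5
    n_ntc: int = 250
    coverage: int = 100  # sorted cells per library element, per fraction
    depth: int = 2_000_000  # sequencing reads per sorted fraction
    mu_induced: float = 3.0  # mean log10 fluorescence, responding cells
    mu_off: float = 1.5  # mean log10 fluorescence, non-responding peak
    sigma: float = 0.25  # within-peak log10 SD
    pi_off: float = 0.10  # baseline non-responder fraction
    spacer_length: int = 20
    library_id: str = "SIM1"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.sgrnas_per_gene, self.coverage, self.depth) <= 0:
            raise ConfigurationError("counts and depth must be positive")
        if self.n_ntc < 0:
            raise ConfigurationError("n_ntc must be >= 0")
        if not self.mu_off < self.mu_induced:
            raise ConfigurationError("mu_off must be below mu_induced")
        if not 0 <= self.pi_off < 0.5:
            raise ConfigurationError("pi_off must lie in [0, 0.5)")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")

    @property
    def n_sgrnas(self) -> int:
        return self.n_genes * self.sgrnas_per_gene + self.n_ntc


@dataclass(frozen=True)
class EffectSpec:
    """Which genes are regulators and how strong their effects are.

    ``fraction_positive`` genes become positive regulators (silencing lowers
    reporter output, i.e. beta < 0); ``fraction_negative`` become negative
    regulators (beta > 0).  ``beta_magnitude`` is either a point-mass |beta|
    in log10 units or a callable ``(rng, size) -> array`` of magnitudes.
    Guide activities default to Beta(5, 1): most guides silence well, a
    minority are weak.
    """

    fraction_positive: float = 0.0
    fraction_negative: float = 0.0
    beta_magnitude: Union[float, Callable] = 0.6
    activity_sampler: Optional[Callable] = None

    def __post_init__(self) -> None:
        if self.fraction_positive < 0 or self.fraction_negative < 0:
            raise ConfigurationError("regulator fractions must be >= 0")
        if self.fraction_positive + self.fraction_negative > 1:
            raise ConfigurationError("regulator fractions must sum to <= 1")

    def sample_magnitudes(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if callable(self.beta_magnitude):
            return np.asarray(self.beta_magnitude(rng, size), dtype=float)
        return np.full(size, float(self.beta_magnitude))

    def sample_activities(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.activity_sampler is not None:
            out = np.asarray(self.activity_sampler(rng, size), dtype=float)
        else:
            out = rng.beta(5.0, 1.0, size=size)
        if out.size and (out.min() < 0 or out.max() > 1):
            raise ConfigurationError("guide activities must lie in [0, 1]")
        return out


@dataclass(frozen=True)
class GeneEffectMap:
    """Ground truth: per-gene log10 reporter shift and per-guide activity."""

    beta: pd.Series  # index: gene name, value: log10 shift when silenced
    activity: pd.Series  # index: sgrna_id (gene-targeting only), value in [0, 1]

    def positive_regulators(self) -> list[str]:
        return self.beta.index[self.beta < 0].tolist()

    def negative_regulators(self) -> list[str]:
        return self.beta.index[self.beta > 0].tolist()

    def regulators(self) -> list[str]:
        return self.beta.index[self.beta != 0].tolist()


@dataclass(frozen=True)
class CellPopulation:
    """Per-cell records; exactly one sgRNA per cell (MOI < 1)."""

    sgrna_index: np.ndarray  # int index into sgrna_ids
    fluorescence: np.ndarray  # linear fluorescence, > 0
    sgrna_ids: np.ndarray  # id per library position

    def __len__(self) -> int:
        return len(self.sgrna_index)


@dataclass(frozen=True)
class SortedFractions:
    """Index sets of the three gates; medium/high sizes differ by <= 1."""

    low: np.ndarray
    medium: np.ndarray
    high: np.ndarray
    valley: float  # linear-fluorescence gate boundary
    used_fallback: bool = False

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"low": self.low, "medium": self.medium, "high": self.high}


def _random_distinct_spacers(
    rng: np.random.Generator, n: int, length: int
) -> list[str]:
    if 4**length < n:
        raise ConfigurationError(
            f"cannot draw {n} distinct spacers of length {length}"
        )
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            sp = "".join(bases[row])
            if sp not in seen:
                seen.add(sp)
                out.append(sp)
    return out


def build_library(
    n_genes: int,
    sgrnas_per_gene: int = 5,
    n_ntc: int = 250,
    seed: int = 0,
    spacer_length: int = 20,
    library_id: str = "SIM1",
) -> LibraryDesign:
    """Synthesize a library: ``n_genes`` x ``sgrnas_per_gene`` gene-targeting
    guides plus ``n_ntc`` non-targeting controls, with random distinct
    spacers."""
    if n_genes <= 0 or sgrnas_per_gene <= 0 or n_ntc < 0:
        raise ConfigurationError("library dimensions must be positive")
    rng = np.random.default_rng(seed)
    n_total = n_genes * sgrnas_per_gene + n_ntc
    spacers = _random_distinct_spacers(rng, n_total, spacer_length)

    width = max(4, len(str(n_genes)))
    rows = []
    k = 0
    for g in range(n_genes):
        gene = f"GENE{g + 1:0{width}d}"
        tss = f"{gene}_TSS1"
        for j in range(sgrnas_per_gene):
            rows.append((f"{gene}_sg{j + 1}", gene, tss, spacers[k], library_id))
            k += 1
    for i in range(n_ntc):
        rows.append((f"NTC_{i + 1:04d}", NTC_TARGET, "", spacers[k], library_id))
        k += 1
    df = pd.DataFrame(
        rows, columns=["sgrna_id", "target", "tss_id", "spacer", "library_id"]
    )
    return LibraryDesign(df)


def assign_gene_effects(
    library: LibraryDesign, spec: EffectSpec, seed: int = 0
) -> GeneEffectMap:
    """Draw ground-truth effects: round(fraction x n_genes) positive and
    negative regulators with signed magnitudes, zero beta elsewhere, and a
    knockdown activity per gene-targeting guide."""
    rng = np.random.default_rng(seed)
    genes = library.targets()["target"].unique()
    n = len(genes)
    n_pos = round(spec.fraction_positive * n)
    n_neg = round(spec.fraction_negative * n)
    if n_pos + n_neg > n:
        raise ConfigurationError("more regulators requested than genes")

    order = rng.permutation(n)
    beta = pd.Series(0.0, index=pd.Index(genes, name="gene"))
    pos_genes = genes[order[:n_pos]]
    neg_genes = genes[order[n_pos : n_pos + n_neg]]
    # positive regulators: silencing lowers reporter output => negative shift
    beta[pos_genes] = -spec.sample_magnitudes(rng, n_pos)
    beta[neg_genes] = spec.sample_magnitudes(rng, n_neg)

    mask = library.entries["target"] != NTC_TARGET
    gene_sgrnas = library.entries.loc[mask, "sgrna_id"]
    activity = pd.Series(
        spec.sample_activities(rng, len(gene_sgrnas)),
        index=pd.Index(gene_sgrnas, name="sgrna_id"),
    )
    return GeneEffectMap(beta=beta, activity=activity)


def simulate_cells(
    library: LibraryDesign, effects: GeneEffectMap, config: ScreenSimConfig,
    seed: int | None = None,
) -> CellPopulation:
    """Simulate the sorted cell pool: 3 x coverage x library-size cells, one
    uniformly drawn guide each.

    A cell is a non-responder with probability ``pi_off`` (log10 fluorescence
    ``mu_off + sigma z``); otherwise its log10 fluorescence is
    ``mu_induced + a_i beta_g + sigma z`` where ``a_i`` is its guide's
    activity and ``beta_g`` the silenced gene's effect (0 for NTC guides).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_sg = len(library)
    n_cells = 3 * config.coverage * n_sg

    targets = library.entries["target"].to_numpy()
    ids = library.entries["sgrna_id"].to_numpy()
    shift = np.zeros(n_sg)
    gene_mask = targets != NTC_TARGET
    if gene_mask.any():
        beta_per_sg = effects.beta.reindex(targets[gene_mask]).to_numpy()
        act_per_sg = effects.activity.reindex(ids[gene_mask]).to_numpy()
        if np.isnan(beta_per_sg).any() or np.isnan(act_per_sg).any():
            raise ConfigurationError("effects do not cover every library gene/guide")
        shift[gene_mask] = act_per_sg * beta_per_sg

    if n_cells == 0:
        return CellPopulation(
            np.empty(0, dtype=np.int64), np.empty(0), sgrna_ids=ids
        )
    sg_idx = rng.integers(0, n_sg, size=n_cells)
    non_responder = rng.random(n_cells) < config.pi_off
    z = rng.standard_normal(n_cells)
    log10_f = np.where(
        non_responder, config.mu_off, config.mu_induced + shift[sg_idx]
    ) + config.sigma * z
    return CellPopulation(
        sgrna_index=sg_idx.astype(np.int64),
        fluorescence=10.0**log10_f,
        sgrna_ids=ids,
    )


def gate_cells(
    population: CellPopulation,
    fallback_quantile: float = 0.15,
    n_bins: int = 256,
) -> SortedFractions:
    """Place the low gate at the valley between the two largest modes of the
    smoothed log10-fluorescence histogram; split the remaining cells at their
    median into equal "medium" and "high" halves.

    The histogram uses ``n_bins`` bins smoothed with a Gaussian kernel whose
    bandwidth follows Silverman's rule.  If fewer than two modes are found
    the gate falls back to the ``fallback_quantile`` quantile (with a logged
    warning).  The partition is always exact.
    """
    n = len(population)
    if n < 10:
        raise ConfigurationError("gating needs at least 10 cells")
    x = np.log10(population.fluorescence)
    valley_x, used_fallback = _find_valley(x, fallback_quantile, n_bins)

    low_mask = x < valley_x
    low = np.flatnonzero(low_mask)
    rest = np.flatnonzero(~low_mask)
    order = np.argsort(x[rest], kind="stable")
    n_medium = (len(rest) + 1) // 2
    medium = rest[order[:n_medium]]
    high = rest[order[n_medium:]]
    return SortedFractions(
        low=low,
        medium=medium,
        high=high,
        valley=float(10.0**valley_x),
        used_fallback=used_fallback,
    )


def _find_valley(
    x: np.ndarray, fallback_quantile: float, n_bins: int
) -> tuple[float, bool]:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return float(np.quantile(x, fallback_quantile)), True
    hist, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]
    # Silverman bandwidth on the raw data, expressed in bins
    sd = float(np.std(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = bin_width
    bandwidth = 0.9 * scale * len(x) ** (-0.2)
    smooth = gaussian_filter1d(
        hist.astype(float), max(bandwidth / bin_width, 1e-6), mode="constant"
    )
    # pad so modes sitting in the first or last bin still count as peaks
    padded = np.concatenate([[-1.0], smooth, [-1.0]])
    peaks, _ = find_peaks(padded)
    peaks -= 1
    if len(peaks) < 2:
        logger.warning(
            "histogram is unimodal; falling back to the %.2f quantile gate",
            fallback_quantile,
        )
        return float(np.quantile(x, fallback_quantile)), True
    top_two = peaks[np.argsort(smooth[peaks])[-2:]]
    left, right = int(top_two.min()), int(top_two.max())
    between = smooth[left : right + 1]
    minima = np.flatnonzero(between == between.min())
    valley_bin = left + int(minima[len(minima) // 2])  # middle of a flat valley
    return float(centers[valley_bin]), False


def sequence_fractions(
    fractions: SortedFractions,
    population: CellPopulation,
    depth: int,
    seed: int = 0,
    library_id: str = "",
) -> CountMatrix:
    """Sequence each sorted fraction to ``depth`` reads: a multinomial draw
    with probabilities proportional to the fraction's per-guide cell tallies.
    Every column sums to ``depth`` exactly (all-zero for an empty fraction)."""
    if depth <= 0:
        raise ConfigurationError("sequencing depth must be positive")
    rng = np.random.default_rng(seed)
    n_sg = len(population.sgrna_ids)
    columns = {}
    for name, idx in fractions.as_dict().items():
        tally = np.bincount(population.sgrna_index[idx], minlength=n_sg)
        total = tally.sum()
        if total == 0:
            logger.warning("fraction %r contains no cells; zero counts", name)
            columns[name] = np.zeros(n_sg, dtype=np.int64)
        else:
            columns[name] = rng.multinomial(depth, tally / total)
    counts = pd.DataFrame(
        columns, index=pd.Index(population.sgrna_ids, name="sgrna_id")
    )
    return CountMatrix(counts[list(_FRACTIONS)], library_id=library_id)


@dataclass(frozen=True)
class SimulatedScreen:
    counts: CountMatrix
    effects: GeneEffectMap
    library: LibraryDesign
    fractions: SortedFractions


def simulate_screen(
    config: ScreenSimConfig,
    spec: EffectSpec | None = None,
    library: LibraryDesign | None = None,
    effects: GeneEffectMap | None = None,
) -> SimulatedScreen:
    """Run the full generative chain (library -> effects -> cells -> gates ->
    counts) under one top-level seed, deterministically split per stage.

    A pre-built ``library`` and/or ``effects`` may be supplied, e.g. to plant
    a specific ground truth.
    """
    if spec is None:
        spec = EffectSpec()
    seeds = [s.generate_state(1)[0] % 2**31
             for s in np.random.SeedSequence(config.seed).spawn(4)]
    if library is None:
        library = build_library(
            config.n_genes,
            config.sgrnas_per_gene,
            config.n_ntc,
            seed=seeds[0],
            spacer_length=config.spacer_length,
            library_id=config.library_id,
        )
    if effects is None:
        effects = assign_gene_effects(library, spec, seed=seeds[1])
    population = simulate_cells(library, effects, config, seed=seeds[2])
    fractions = gate_cells(population)
    counts = sequence_fractions(
        fractions, population, config.depth, seed=seeds[3],
        library_id=config.library_id,
    )
    return SimulatedScreen(counts, effects, library, fractions)


def write_truth_table(effects: GeneEffectMap, path: Union[str, Path]) -> None:
    effects.beta.rename("beta").to_csv(path, sep="\t", index_label="gene")


def write_fraction_fastq(
    counts: CountMatrix,
    library: LibraryDesign,
    sample: str,
    path: Union[str, Path],
    crop_offset: int = 0,
    seed: int = 0,
) -> None:
    """Synthesize a FASTQ whose reads reproduce one count column exactly:
    each guide's spacer is emitted ``count`` times (prefixed by random bases
    when ``crop_offset`` > 0), in shuffled order."""
    rng = np.random.default_rng(seed)
    col = counts.counts[sample]
    spacers = library.entries.set_index("sgrna_id")["spacer"]
    reads = []
    for sgrna_id, c in col.items():
        if c > 0:
            reads.extend([spacers[sgrna_id]] * int(c))
    rng.shuffle(reads)
    bases = "ACGT"
    with open(path, "w") as out:
        for i, spacer in enumerate(reads):
            prefix = "".join(rng.choice(list(bases), size=crop_offset))
            seq = prefix + spacer
            out.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
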