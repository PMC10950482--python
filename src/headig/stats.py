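"""Across-protein statistics on the head x layer grid.

The pipeline mirrors how attribution maps are judged against per-residue
annotations at population level:

1. per protein, the point-biserial correlation r between a head's
   per-residue relevance sequence and the binary annotation vector (this is
   numerically the Pearson correlation of a continuous and a 0/1 variable);
2. per (layer, head) cell, a one-sided Wilcoxon signed-rank test across
   proteins that the cell's r values are centered above zero;
3. Benjamini-Hochberg step-up correction across all testable cells of the
   grid (one condition = one grid; n_layers * n_heads hypotheses, e.g.
   30 x 16 = 480 for a ProtBert-sized model);
4. thresholding at alpha and display as -log10 of the surviving adjusted
   p-values.

The same machinery applies to sequence-summed relevances ("does this head
carry significantly positive relevance at all?"); the overlay of the two
masks singles out heads that are both annotation-aligned and relevant.

`HeadAnnotationAnalysis` packages the whole procedure statsmodels-style:
construct from per-protein matrices, `fit()` returns a results object with
the grids and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .attribution import HeadAttributionMap

__all__ = [
    "TestConfig",
    "HeadStatMatrix",
    "point_biserial",
    "correlate_protein",
    "wilcoxon_positive",
    "bh_adjust",
    "count_hypothesis_tests",
    "aggregate_correlations",
    "summed_relevance",
    "positive_relevance_test",
    "mask_overlay",
    "AggregateResult",
    "HeadAnnotationAnalysis",
    "HeadAnnotationResults",
]

_CONTENT_KINDS = (
    "correlation_r", "p_value", "p_adjusted", "neglog10_p", "mask", "relevance_sum",
)


@dataclass(frozen=True)
class TestConfig:
    alpha: float = 0.05
    sidedness: str = "greater"          # "greater" | "two_sided"
    zero_policy: str = "discard_zeros"  # "discard_zeros" | "pratt"
    min_n: int = 5                      # minimum proteins per cell
    exact_n_max: int = 25               # exact null up to here, else normal approx

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.sidedness not in ("greater", "two_sided"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")
        if self.zero_policy not in ("discard_zeros", "pratt"):
            raise ValueError(f"unknown zero_policy {self.zero_policy!r}")


@dataclass
class HeadStatMatrix:
    """An n_layers x n_heads grid of one statistic kind; NaN = missing."""

    values: np.ndarray
    content_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expected a 2-D (n_layers, n_heads) matrix")
        if self.content_kind not in _CONTENT_KINDS:
            raise ValueError(f"unknown content kind {self.content_kind!r}")
        finite = self.values[np.isfinite(self.values)]
        if self.content_kind == "correlation_r" and finite.size:
            if np.any(np.abs(finite) > 1 + 1e-12):
                raise ValueError("correlation entries must lie in [-1, 1]")
        if self.content_kind in ("p_value", "p_adjusted") and finite.size:
            if np.any((finite < 0) | (finite > 1)):
                raise ValueError("p-values must lie in [0, 1]")
        if self.content_kind == "neglog10_p" and finite.size:
            if np.any(finite < 0):
                raise ValueError("-log10 p entries must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def point_biserial(relevance: np.ndarray, annotation: np.ndarray) -> float:
    """Correlation between continuous relevance and a binary annotation.

    Identical to the Pearson correlation of the pair. Returns NaN for the
    undefined cases (annotation all 0 or all 1, or constant relevance).
    """
    x = np.asarray(relevance, dtype=np.float64)
    y = np.asarray(annotation, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"length mismatch: relevance has {x.shape}, annotation has {y.shape}"
        )
    if x.size < 3:
        raise ValueError("need at least 3 positions")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("annotation vector must be binary")
    if y.min() == y.max():
        return np.nan  # annotation has a single class
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return np.nan  # constant relevance
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlate_protein(
    head_maps: Sequence[HeadAttributionMap],
    annotation: np.ndarray,
) -> HeadStatMatrix:
    """Per-head correlation grid for one protein.

    ``head_maps`` holds one seq x n_heads map per layer; special-token
    positions are excluded before correlating, so the annotation vector
    must have the residue count of the protein.
    """
    annotation = np.asarray(annotation)
    n_layers = len(head_maps)
    n_heads = head_maps[0].values.shape[1]
    grid = np.full((n_layers, n_heads), np.nan)
    for l, hm in enumerate(head_maps):
        rel = hm.residue_values  # (n_residues, n_heads)
        if rel.shape[0] != annotation.shape[0]:
            raise ValueError(
                f"layer {l}: relevance covers {rel.shape[0]} residues but the "
                f"annotation vector has {annotation.shape[0]}"
            )
        for h in range(n_heads):
            grid[l, h] = point_biserial(rel[:, h], annotation)
    return HeadStatMatrix(grid, "correlation_r")


def wilcoxon_positive(values: np.ndarray, cfg: TestConfig = TestConfig()) -> float:
    """One-sided signed-rank p-value for median(values) > 0; NaN if n too small."""
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    zero_method = "wilcox" if cfg.zero_policy == "discard_zeros" else "pratt"
    effective = v[v != 0] if cfg.zero_policy == "discard_zeros" else v
    if effective.size < cfg.min_n:
        return np.nan
    has_ties = np.unique(np.abs(effective)).size < effective.size
    if effective.size <= cfg.exact_n_max and not has_ties and zero_method == "wilcox":
        method = "exact"
        correction = False
    else:
        method = "approx"
        correction = True
    alternative = "greater" if cfg.sidedness == "greater" else "two-sided"
    res = sps.wilcoxon(v, zero_method=zero_method, correction=correction,
                       alternative=alternative, method=method)
    return float(res.pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries pass through."""
    p = np.asarray(p, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    valid = np.isfinite(p)
    if valid.sum():
        flat = p[valid]
        if np.any((flat < 0) | (flat > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out[valid] = multipletests(flat, method="fdr_bh")[1]
    return out


def count_hypothesis_tests(n_layers: int, n_heads: int) -> int:
    """Tests per condition: one per (layer, head) cell of the grid."""
    if n_layers < 1 or n_heads < 1:
        raise ValueError("layer and head counts must be positive")
    return n_layers * n_heads


@dataclass
class AggregateResult:
    """Across-protein aggregation of one grid statistic."""

    median: HeadStatMatrix        # per-cell median of the input values
    p_raw: HeadStatMatrix
    p_adjusted: HeadStatMatrix
    significant: np.ndarray       # bool mask; missing cells are False
    neglog10: HeadStatMatrix      # -log10 p_adj where significant, 0 else, NaN missing
    n_per_cell: np.ndarray
    config: TestConfig

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def _aggregate(stacks: np.ndarray, cfg: TestConfig, kind: str) -> AggregateResult:
    """Wilcoxon per cell over axis 0, BH over the grid, threshold at alpha."""
    n_prot, n_layers, n_heads = stacks.shape
    p_raw = np.full((n_layers, n_heads), np.nan)
    med = np.full((n_layers, n_heads), np.nan)
    n_per_cell = np.zeros((n_layers, n_heads), dtype=int)
    for l in range(n_layers):
        for h in range(n_heads):
            vals = stacks[:, l, h]
            vals = vals[np.isfinite(vals)]
            n_per_cell[l, h] = vals.size
            if vals.size:
                med[l, h] = float(np.median(vals))
            p_raw[l, h] = wilcoxon_positive(vals, cfg)
    p_adj = bh_adjust(p_raw)
    significant = np.where(np.isfinite(p_adj), p_adj <= cfg.alpha, False)
    neglog = np.where(np.isfinite(p_adj),
                      np.where(significant, -np.log10(np.maximum(p_adj, 1e-300)), 0.0),
                      np.nan)
    return AggregateResult(
        median=HeadStatMatrix(med, kind),
        p_raw=HeadStatMatrix(p_raw, "p_value"),
        p_adjusted=HeadStatMatrix(p_adj, "p_adjusted"),
        significant=significant,
        neglog10=HeadStatMatrix(neglog, "neglog10_p"),
        n_per_cell=n_per_cell,
        config=cfg,
    )


def aggregate_correlations(
    matrices: Sequence[HeadStatMatrix],
    cfg: TestConfig = TestConfig(),
) -> AggregateResult:
    """Population statistics over per-protein correlation grids.

    Missing per-protein entries (degenerate annotations) are excluded
    pairwise per cell; cells with fewer than ``cfg.min_n`` contributing
    proteins stay missing (NaN), never zero.
    """
    shapes = {m.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent grid shapes {shapes}")
    for m in matrices:
        if m.content_kind != "correlation_r":
            raise ValueError("expected correlation_r matrices")
    stacks = np.stack([m.values for m in matrices])
    return _aggregate(stacks, cfg, "correlation_r")


def summed_relevance(head_maps: Sequence[HeadAttributionMap]) -> np.ndarray:
    """n_layers x n_heads matrix of sequence-summed head relevance
    (special-token positions excluded) for one protein."""
    return np.stack([hm.summed() for hm in head_maps])


def positive_relevance_test(
    summed: Sequence[np.ndarray],
    cfg: TestConfig = TestConfig(),
) -> AggregateResult:
    """Which heads carry significantly positive total relevance across proteins."""
    shapes = {np.asarray(s).shape for s in summed}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent grid shapes {shapes}")
    stacks = np.stack([np.asarray(s, dtype=np.float64) for s in summed])
    return _aggregate(stacks, cfg, "relevance_sum")


def mask_overlay(
    corr_sig: AggregateResult, relevance_sig: AggregateResult
) -> HeadStatMatrix:
    """Keep the correlation grid's -log10 p only where relevance is significant."""
    if corr_sig.neglog10.shape != relevance_sig.neglog10.shape:
        raise ValueError("grid shapes differ between the two analyses")
    a = corr_sig.neglog10.values
    keep = corr_sig.significant & relevance_sig.significant
    out = np.where(np.isfinite(a), np.where(keep, a, 0.0), np.nan)
    return HeadStatMatrix(out, "neglog10_p")


def jointly_significant(corr: AggregateResult, rel: AggregateResult) -> np.ndarray:
    return corr.significant & rel.significant


# ---------------------------------------------------------------------------
# Model/Results facade
# ---------------------------------------------------------------------------

class HeadAnnotationAnalysis:
    """Joint head-level analysis of attribution-annotation agreement.

    Parameters
    ----------
    correlation_matrices : per-protein ``HeadStatMatrix`` (correlation_r)
    summed_matrices : per-protein n_layers x n_heads summed-relevance arrays
    config : test configuration (alpha, sidedness, zero policy)
    """

    def __init__(
        self,
        correlation_matrices: Sequence[HeadStatMatrix],
        summed_matrices: Sequence[np.ndarray],
        config: TestConfig = TestConfig(),
    ):
        if len(correlation_matrices) != len(summed_matrices):
            raise ValueError("one correlation grid and one summed grid per protein")
        self.correlation_matrices = list(correlation_matrices)
        self.summed_matrices = [np.asarray(s) for s in summed_matrices]
        self.config = config

    def fit(self) -> "HeadAnnotationResults":
        corr = aggregate_correlations(self.correlation_matrices, self.config)
        rel = positive_relevance_test(self.summed_matrices, self.config)
        overlay = mask_overlay(corr, rel)
        return HeadAnnotationResults(self, corr, rel, overlay)


@dataclass
class HeadAnnotationResults:
    analysis: HeadAnnotationAnalysis
    correlation: AggregateResult
    relevance: AggregateResult
    overlay: HeadStatMatrix

    @property
    def joint_mask(self) -> np.ndarray:
        return self.correlation.significant & self.relevance.significant

    @property
    def n_joint(self) -> int:
        return int(self.joint_mask.sum())

    def summary(self) -> str:
        cfg = self.analysis.config
        L, H = self.overlay.shape
        n_tests = count_hypothesis_tests(L, H)
        lines = [
            "Head-annotation agreement analysis",
            "=" * 46,
            f"grid: {L} layers x {H} heads = {n_tests} hypothesis tests per track",
            f"proteins: {len(self.analysis.correlation_matrices)}",
            f"alpha (BH-FDR): {cfg.alpha}; sidedness: {cfg.sidedness}",
            "",
            f"significant correlation cells: {self.correlation.n_significant}",
            f"significant positive-relevance cells: {self.relevance.n_significant}",
            f"jointly significant cells: {self.n_joint}",
            "",
            "layer  head  median_r  p_adj(corr)  p_adj(rel)  joint",
        ]
        for l in range(L):
            for h in range(H):
                lines.append(
                    f"{l:5d}  {h:4d}  {self.correlation.median.values[l, h]:8.3f}"
                    f"  {self.correlation.p_adjusted.values[l, h]:11.3g}"
                    f"  {self.relevance.p_adjusted.values[l, h]:10.3g}"
                    f"  {'*' if self.joint_mask[l, h] else ''}"
                )
        return "\n".join(lines)
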