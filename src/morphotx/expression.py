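"""Normalization and filtering of a regions x genes expression matrix.

Covers the in-scope downstream steps of microarray expression
preprocessing: intensity filtering of poorly detected genes, scaled
robust sigmoid (SRS) normalization, and restriction to the left
hemisphere (donor coverage of the right hemisphere is too sparse in the
source atlas, so the analysis is left-hemisphere only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "intensity_filter", "srs_normalize", "restrict_left_hemisphere"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Regions x genes expression values (rows indexed by region_id)."""

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix must not contain missing values")

    @property
    def regions(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path) -> None:
        from .io import write_tsv

        write_tsv(self.values, path, index=True)

    @classmethod
    def from_tsv(cls, path, normalized: bool = False) -> "ExpressionMatrix":
        from .io import read_tsv

        return cls(read_tsv(path, index_col=0), normalized=normalized)


def intensity_filter(
    values: pd.DataFrame, detected: pd.DataFrame, threshold: float = 0.5
) -> ExpressionMatrix:
    """Drop genes detected above background in fewer than ``threshold`` of regions.

    A gene is retained iff its detected fraction across regions is >= the
    threshold (a gene detected in exactly 50% of regions survives the
    default cut).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if values.shape != detected.shape:
        raise ValueError("values and detection mask must be conformable")
    frac = detected.astype(bool).to_numpy().mean(axis=0)
    keep = frac >= threshold
    if not keep.any():
        raise ValueError("intensity filter removed every gene")
    return ExpressionMatrix(values.loc[:, values.columns[keep]])


def srs_normalize(values: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid: an outlier-robust normalization to [0, 1].

    Values pass through a sigmoid centred at the median with width
    IQR / 1.35 (the normal-consistency factor, so the width estimates one
    SD under Gaussian data), then are min-max rescaled to [0, 1]:

        s(x) = 1 / (1 + exp(-(x - median) / (IQR / 1.35)))

    A degenerate input with zero IQR falls back to plain min-max scaling
    with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        warnings.warn("zero IQR: falling back to min-max scaling", stacklevel=2)
        span = x.max() - x.min()
        return (x - x.min()) / span if span > 0 else np.zeros_like(x)
    s = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    return (s - s.min()) / (s.max() - s.min())


def srs_normalize_matrix(
    expr: ExpressionMatrix, per_gene: bool = True, per_region: bool = True
) -> ExpressionMatrix:
    """Apply SRS across regions within each gene, then across genes within
    each region (both passes individually switchable)."""
    vals = expr.values.to_numpy(float).copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if per_gene:
            for j in range(vals.shape[1]):
                vals[:, j] = srs_normalize(vals[:, j])
        if per_region:
            for i in range(vals.shape[0]):
                vals[i, :] = srs_normalize(vals[i, :])
    return ExpressionMatrix(
        pd.DataFrame(vals, index=expr.values.index, columns=expr.values.columns),
        normalized=True,
    )


def restrict_left_hemisphere(expr: ExpressionMatrix, atlas) -> ExpressionMatrix:
    """Keep only left-hemisphere regions, preserving row order."""
    atlas_ids = set(atlas.region_ids.tolist())
    unknown = [r for r in expr.regions if r not in atlas_ids]
    if unknown:
        raise ValueError(f"expression regions absent from atlas: {unknown[:5]}")
    left_ids = set(atlas.region_ids[atlas.mask(hemisphere="left")].tolist())
    keep = [r in left_ids for r in expr.regions]
    if not any(keep):
        raise ValueError("no left-hemisphere regions in expression matrix")
    return ExpressionMatrix(expr.values.loc[keep], normalized=expr.normalized)
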