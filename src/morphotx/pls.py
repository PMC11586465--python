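"""PLS1 association between regional gene expression and a case-control map.

For a single response, the first partial-least-squares weight vector has a
closed form: it is X^T y normalized to unit length. Component scores are
X @ w and the explained variance is the squared Pearson correlation of the
scores with the response, sign-fixed so scores correlate non-negatively
with y. On top of the fit:

* a permutation test of the explained variance (spatial spin nulls by
  default, plain shuffling for non-spatial responses and calibration);
* bootstrap z-scores per gene — regions are resampled with replacement,
  the component is refit, each bootstrap weight vector's sign is aligned
  to the original (sign indeterminacy of a PLS component would otherwise
  inflate the SE), and z = weight / bootstrap SE, with BH-FDR across all
  genes defining the positively (PLS+) and negatively (PLS-) weighted
  gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import bh_fdr, z_normalize
from .spin import SpinNull, spin_pvalue

__all__ = [
    "PLSResult",
    "fit_pls1",
    "permutation_test_variance",
    "bootstrap_gene_stats",
    "top_gene_map_correlation",
]


@dataclass(frozen=True)
class PLSResult:
    """PLS1 scores, explained variance, and bootstrap gene statistics."""

    gene_table: pd.DataFrame  # gene, weight, se, z, p, q, list
    scores: pd.Series  # region_id -> PLS1 score
    variance_explained: float
    p_perm: float | None = None
    alpha: float = 0.05

    @property
    def pls_plus(self) -> list[str]:
        return self._ranked("PLS+")

    @property
    def pls_minus(self) -> list[str]:
        return self._ranked("PLS-")

    def _ranked(self, which: str) -> list[str]:
        sub = self.gene_table[self.gene_table["list"] == which]
        # |z| descending; lexicographic gene id as the deterministic tie-break
        sub = sub.sort_values(["abs_z", "gene"], ascending=[False, True])
        return sub["gene"].tolist()

    def weights(self, which: str | None = None) -> pd.Series:
        """gene -> weight, optionally restricted to one list ("PLS+"/"PLS-")."""
        tab = self.gene_table if which is None else self.gene_table[self.gene_table["list"] == which]
        return pd.Series(tab["weight"].to_numpy(), index=tab["gene"].to_numpy())

    def summary(self) -> dict:
        return {
            "variance_explained": self.variance_explained,
            "p_perm": self.p_perm,
            "n_pls_plus": len(self.pls_plus),
            "n_pls_minus": len(self.pls_minus),
            "alpha": self.alpha,
        }

    def to_files(self, gene_path, scores_path, json_path) -> None:
        from .io import write_json, write_tsv

        cols = ["gene", "weight", "se", "z", "p", "q", "list"]
        write_tsv(self.gene_table[cols], gene_path)
        scores_df = self.scores.rename("pls1_score").rename_axis("region_id").reset_index()
        write_tsv(scores_df, scores_path)
        write_json(self.summary(), json_path)


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be regions x genes with rows aligned to y")
    return X, y


def fit_pls1(X, y) -> tuple[np.ndarray, np.ndarray, float]:
    """First PLS component of the regression of y on X.

    Inputs are expected pre-normalized (z-scored columns). Returns
    (weights, scores, variance_explained) with weights unit-length
    proportional to X^T y and the sign fixed so corr(scores, y) >= 0.
    """
    X, y = _as_xy(X, y)
    if np.ptp(y) == 0:
        raise ValueError("constant response: PLS undefined")
    w = X.T @ y
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("X^T y vanished: no association to extract")
    w = w / norm
    scores = X @ w
    if scores.std() == 0:
        raise ValueError("degenerate scores (constant)")
    r = float(np.corrcoef(scores, y)[0, 1])
    if r < 0:  # unreachable for w = X^T y but kept as the sign convention
        w, scores, r = -w, -scores, -r
    return w, scores, r * r


def _batch_variance_explained(X: np.ndarray, Yp: np.ndarray) -> np.ndarray:
    """Explained variance of the PLS1 fit for each response column of Yp."""
    W = X.T @ Yp  # genes x B (normalization cancels in the correlation)
    S = X @ W  # regions x B
    Sc = S - S.mean(axis=0)
    Yc = Yp - Yp.mean(axis=0)
    denom = np.sqrt((Sc**2).sum(axis=0) * (Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Sc * Yc).sum(axis=0) / denom, 0.0)
    return r**2


def permutation_test_variance(
    X,
    y,
    n_perm: int = 1000,
    null_scheme: str = "spin",
    spins: SpinNull | None = None,
    seed: int = 0,
) -> float:
    """Permutation p-value for the PLS1 explained variance.

    Under the default spin scheme the response map is reindexed by each
    spatial spin (preserving its autocorrelation); under ``shuffle`` it is
    fully permuted. p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    X, y = _as_xy(X, y)
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    _, _, observed = fit_pls1(X, y)
    if null_scheme == "spin":
        if spins is None:
            raise ValueError("spin scheme requires a SpinNull covering y's regions")
        if len(spins.region_ids) != y.size:
            raise ValueError("spin scope does not match the response map")
        perms = spins.permutations[:n_perm]
        if perms.shape[0] < n_perm:
            raise ValueError(f"SpinNull holds only {perms.shape[0]} spins; {n_perm} requested")
        Yp = y[perms].T
        n_used = perms.shape[0]
    elif null_scheme == "shuffle":
        rng = np.random.default_rng(seed)
        Yp = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
        n_used = n_perm
    else:
        raise ValueError("null_scheme must be 'spin' or 'shuffle'")
    null = _batch_variance_explained(X, Yp)
    return float((1.0 + np.count_nonzero(null >= observed)) / (n_used + 1.0))


def bootstrap_gene_stats(
    X,
    y,
    genes=None,
    region_ids=None,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PLSResult:
    """Bootstrap z-scored gene weights for PLS1.

    X columns and y are z-normalized first (so the statistics are invariant
    to the scale of the raw inputs), regions are resampled with
    replacement, PLS1 is refit per resample, each bootstrap weight vector
    is sign-aligned to the original, and z = original weight / bootstrap
    SE with a two-sided normal p and BH-FDR across all genes. Genes with
    q < alpha form the PLS+ (z > 0) and PLS- (z < 0) lists, ranked by |z|.
    """
    X, y = _as_xy(X, y)
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100 for a stable bootstrap SE")
    n, p = X.shape
    genes = [f"g{j}" for j in range(p)] if genes is None else list(genes)
    region_ids = list(range(n)) if region_ids is None else list(region_ids)
    Xz = np.apply_along_axis(z_normalize, 0, X)
    yz = z_normalize(y)
    w0, scores, ve = fit_pls1(Xz, yz)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, p))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        wb = Xz[idx].T @ yz[idx]
        norm = np.linalg.norm(wb)
        if norm == 0:  # degenerate resample; treat as uninformative
            boots[b] = 0.0
            continue
        wb /= norm
        if wb @ w0 < 0:
            wb = -wb
        boots[b] = wb
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, w0 / se, np.inf * np.sign(w0))
    pvals = 2.0 * _sps.norm.sf(np.abs(z))
    q = bh_fdr(pvals)
    membership = np.where(q < alpha, np.where(z > 0, "PLS+", "PLS-"), "none")
    tab = pd.DataFrame(
        {
            "gene": genes,
            "weight": w0,
            "se": se,
            "z": z,
            "p": pvals,
            "q": q,
            "list": membership,
            "abs_z": np.abs(z),
        }
    )
    return PLSResult(
        gene_table=tab,
        scores=pd.Series(scores, index=pd.Index(region_ids, name="region_id")),
        variance_explained=ve,
        alpha=alpha,
    )


def top_gene_map_correlation(gene: str, expr, y, spins: SpinNull) -> tuple[float, float]:
    """Spearman correlation of one gene's regional expression with a map,
    with a spin-test p-value."""
    if gene not in expr.values.columns:
        raise ValueError(f"unknown gene {gene!r}")
    x = expr.values[gene].to_numpy(float)
    return spin_pvalue(x, np.asarray(y, dtype=float), spins, stat="spearman")
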