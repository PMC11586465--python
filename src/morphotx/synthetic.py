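"""Synthetic data generators for the whole pipeline.

These generators emulate, at the parcellated-table level, the statistical
structure the analysis assumes: a two-hemisphere cortical + subcortical
parcellation with unit-sphere centroids and network labels; a three-group
subject cohort (healthy controls and two patient groups) whose regional
gray-matter volumes follow the additive covariate model with planted
regional atrophy and spatially autocorrelated noise; a regions x genes
expression matrix with spatially smooth gene fields, a planted subset of
which is mixed with a target map; gene sets with planted intersection
enrichment; and a receptor density map with a prescribed expected Spearman
correlation to a reference map.

Every generator is a pure function of its arguments and seed: identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSet
from .expression import ExpressionMatrix
from .stats import rankdata, z_normalize

__all__ = [
    "ParcellationAtlas",
    "AtrophySpec",
    "CovariateParams",
    "SubjectTable",
    "GROUPS",
    "YEO_NETWORKS",
    "VON_ECONOMO_CLASSES",
    "make_atlas",
    "simulate_cohort",
    "simulate_expression",
    "simulate_gene_sets",
    "simulate_receptor_map",
    "spatial_covariance",
]

GROUPS = ("HC", "FBTCS-", "FBTCS+")

YEO_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)

VON_ECONOMO_CLASSES = (
    "primary_motor",
    "primary_sensory",
    "secondary_sensory",
    "association_1",
    "association_2",
    "limbic",
    "insular",
)

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class ParcellationAtlas:
    """Region identities, hemispheres, unit-sphere centroids and labels.

    Backed by a DataFrame with columns ``region_id, name, hemisphere,
    tissue_class, cx, cy, cz, yeo_label, veconomo_label``. Subcortical
    regions carry no centroid (NaN coordinates) and no network labels.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t["region_id"].duplicated().any():
            raise ValueError("region_ids must be unique")
        cort = t["tissue_class"] == "cortical"
        norms = np.linalg.norm(t.loc[cort, ["cx", "cy", "cz"]].to_numpy(float), axis=1)
        if cort.any() and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("cortical centroids must lie on the unit sphere")

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def mask(self, hemisphere: str | None = None, tissue_class: str | None = None) -> np.ndarray:
        m = np.ones(len(self.table), dtype=bool)
        if hemisphere is not None:
            m &= (self.table["hemisphere"] == hemisphere).to_numpy()
        if tissue_class is not None:
            m &= (self.table["tissue_class"] == tissue_class).to_numpy()
        return m

    def subset(self, mask: np.ndarray) -> "ParcellationAtlas":
        return ParcellationAtlas(self.table.loc[mask].reset_index(drop=True))

    def centroids(self) -> np.ndarray:
        """(n_regions, 3) array; NaN rows for subcortical regions."""
        return self.table[["cx", "cy", "cz"]].to_numpy(float)

    def to_tsv(self, path) -> None:
        from .io import write_tsv

        write_tsv(self.table, path)

    @classmethod
    def from_tsv(cls, path) -> "ParcellationAtlas":
        from .io import read_tsv

        return cls(read_tsv(path))


@dataclass(frozen=True)
class AtrophySpec:
    """A planted group effect: which regions atrophy and by how much.

    ``effect_size`` is the standardized mean GMV reduction per affected
    region, in units of the within-region noise SD. ``spatial_corr_length``
    records the angular scale (radians) of the noise correlation kernel
    the cohort was generated with.
    """

    affected_regions: tuple[int, ...]
    effect_size: float
    spatial_corr_length: float = 0.3

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        object.__setattr__(self, "affected_regions", tuple(self.affected_regions))


@dataclass(frozen=True)
class CovariateParams:
    """Linear covariate effects on regional GMV (per unit of covariate)."""

    beta_age: float = -0.03
    beta_sex: float = 0.4
    beta_tiv: float = 0.002
    noise_sd: float = 1.0
    age_range: tuple[float, float] = (18.0, 45.0)
    tiv_log_mean: float = np.log(1500.0)
    tiv_log_sd: float = 0.07


@dataclass(frozen=True)
class SubjectTable:
    """Per-subject covariates, clinical fields, and per-region GMV values.

    Region columns are named by region_id as strings; covariate columns are
    ``group, age, sex, tiv, onset_age, seizure_frequency,
    years_since_last_fbtcs``.
    """

    table: pd.DataFrame
    region_ids: tuple[int, ...]

    @property
    def region_columns(self) -> list[str]:
        return [str(r) for r in self.region_ids]

    def gmv(self) -> np.ndarray:
        """(n_subjects, n_regions) GMV matrix in atlas region order."""
        return self.table[self.region_columns].to_numpy(float)

    def select(self, mask: np.ndarray) -> "SubjectTable":
        return SubjectTable(self.table.loc[mask].reset_index(drop=True), self.region_ids)

    def to_tsv(self, path) -> None:
        from .io import write_tsv

        write_tsv(self.table, path)

    @classmethod
    def from_tsv(cls, path, region_ids) -> "SubjectTable":
        from .io import read_tsv

        return cls(read_tsv(path), tuple(region_ids))


def _hemisphere_lattice(n: int, side: str) -> np.ndarray:
    """Deterministic Fibonacci lattice on one hemisphere of the unit sphere.

    The hemisphere axis is +-x (left: x < 0), matching the mirrored-rotation
    convention of the spin null.
    """
    k = np.arange(n)
    a = (k + 0.5) / n  # distance from the mid-plane along the hemisphere axis
    r = np.sqrt(1.0 - a**2)
    phi = k * _GOLDEN_ANGLE
    x = -a if side == "left" else a
    pts = np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _sector_labels(order_value: np.ndarray, labels: tuple[str, ...]) -> np.ndarray:
    """Assign labels by contiguous blocks of the sorted order statistic."""
    n = order_value.size
    ranks = np.argsort(np.argsort(order_value, kind="mergesort"))
    sector = (ranks * len(labels)) // n
    return np.asarray(labels, dtype=object)[sector]


def make_atlas(
    n_cortical_per_hemi: int,
    n_subcortical_per_hemi: int,
    seed: int,
    n_cortical_right_hemi: int | None = None,
) -> ParcellationAtlas:
    """Build a two-hemisphere parcellation with unit-sphere cortical centroids.

    Cortical centroids are placed on a deterministic Fibonacci lattice on
    each hemisphere's half-sphere; network and cytoarchitectonic labels are
    assigned by contiguous angular sectors (rotated by a seed-dependent
    azimuth origin) so labelled networks are spatially coherent.
    Subcortical regions carry no centroid. Backtracking parcellations of
    real cortex are not hemisphere-symmetric (e.g. 152 left / 156 right
    parcels); pass ``n_cortical_right_hemi`` to reproduce that.
    """
    if n_cortical_right_hemi is None:
        n_cortical_right_hemi = n_cortical_per_hemi
    if min(n_cortical_per_hemi, n_cortical_right_hemi) < 7:
        raise ValueError("need at least 7 cortical regions per hemisphere to cover all labels")
    if n_subcortical_per_hemi < 0:
        raise ValueError("subcortical count must be non-negative")
    rng = np.random.default_rng(seed)
    azimuth_origin = rng.uniform(0.0, 2.0 * np.pi)

    n_cortical = {"left": n_cortical_per_hemi, "right": n_cortical_right_hemi}
    rows = []
    region_id = 0
    for side in ("left", "right"):
        pts = _hemisphere_lattice(n_cortical[side], side)
        azimuth = np.mod(np.arctan2(pts[:, 2], pts[:, 1]) + azimuth_origin, 2.0 * np.pi)
        polar = np.abs(pts[:, 0])
        yeo = _sector_labels(azimuth, YEO_NETWORKS)
        veco = _sector_labels(polar, VON_ECONOMO_CLASSES)
        for i in range(n_cortical[side]):
            rows.append(
                {
                    "region_id": region_id,
                    "name": f"{side[0].upper()}_cort_{i:03d}",
                    "hemisphere": side,
                    "tissue_class": "cortical",
                    "cx": pts[i, 0],
                    "cy": pts[i, 1],
                    "cz": pts[i, 2],
                    "yeo_label": yeo[i],
                    "veconomo_label": veco[i],
                }
            )
            region_id += 1
        for i in range(n_subcortical_per_hemi):
            rows.append(
                {
                    "region_id": region_id,
                    "name": f"{side[0].upper()}_subcort_{i:02d}",
                    "hemisphere": side,
                    "tissue_class": "subcortical",
                    "cx": np.nan,
                    "cy": np.nan,
                    "cz": np.nan,
                    "yeo_label": "",
                    "veconomo_label": "",
                }
            )
            region_id += 1
    return ParcellationAtlas(pd.DataFrame(rows))


def spatial_covariance(atlas: ParcellationAtlas, corr_length: float) -> np.ndarray:
    """Exponential covariance on inter-centroid angle for cortical regions.

    ``K_ij = exp(-theta_ij / corr_length)`` for cortical pairs (a valid
    covariance for geodesic distance on the sphere); subcortical regions
    are independent (identity block).
    """
    n = atlas.n_regions
    K = np.eye(n)
    cort = np.flatnonzero(atlas.mask(tissue_class="cortical"))
    if cort.size and corr_length > 0:
        C = atlas.centroids()[cort]
        cosang = np.clip(C @ C.T, -1.0, 1.0)
        theta = np.arccos(cosang)
        K[np.ix_(cort, cort)] = np.exp(-theta / corr_length)
    return K


def _correlated_noise(K: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """(n_draws, n_regions) Gaussian fields with covariance K."""
    L = np.linalg.cholesky(K + 1e-10 * np.eye(K.shape[0]))
    return (L @ rng.standard_normal((K.shape[0], n_draws))).T


def simulate_cohort(
    atlas: ParcellationAtlas,
    n_per_group: dict[str, int],
    atrophy_specs: dict[str, AtrophySpec] | None = None,
    covariate_params: CovariateParams | None = None,
    seed: int = 0,
    spatial_corr_length: float = 0.3,
) -> SubjectTable:
    """Simulate a three-group cohort with planted regional atrophy.

    Per-region GMV is ``baseline_r + beta_age*age + beta_sex*sex +
    beta_tiv*TIV - delta_r * 1[subject in group] + noise`` with noise
    spatially correlated over cortical regions by an exponential kernel on
    inter-centroid angle (scale ``spatial_corr_length`` radians; subcortical
    noise independent). Clinical fields: seizure onset age uniform on
    [5, 25] years; seizure frequency "frequent" with probability 0.54
    (patients only); years since the last bilateral tonic-clonic seizure
    uniform on [0, 6] (FBTCS+ only).
    """
    atrophy_specs = dict(atrophy_specs or {})
    params = covariate_params or CovariateParams()
    for g in list(n_per_group) + list(atrophy_specs):
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
    if "HC" in atrophy_specs and atrophy_specs["HC"].effect_size > 0:
        raise ValueError("healthy controls cannot carry a planted atrophy effect")
    region_ids = atlas.region_ids
    id_to_col = {rid: i for i, rid in enumerate(region_ids)}
    for g, spec in atrophy_specs.items():
        unknown = set(spec.affected_regions) - set(region_ids.tolist())
        if unknown:
            raise ValueError(f"atrophy regions not in atlas: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n_total = sum(n_per_group.values())
    baseline = 10.0 + 2.0 * rng.standard_normal(atlas.n_regions)
    K = spatial_covariance(atlas, spatial_corr_length)
    noise = _correlated_noise(K, n_total, rng) * params.noise_sd

    rows = []
    gmv_rows = []
    i_subj = 0
    for group in GROUPS:
        n = n_per_group.get(group, 0)
        for _ in range(n):
            age = rng.uniform(*params.age_range)
            sex = float(rng.integers(0, 2))
            tiv = float(np.exp(rng.normal(params.tiv_log_mean, params.tiv_log_sd)))
            gmv = baseline + params.beta_age * age + params.beta_sex * sex + params.beta_tiv * tiv
            gmv = gmv + noise[i_subj]
            spec = atrophy_specs.get(group)
            if spec is not None and spec.effect_size > 0:
                cols = [id_to_col[r] for r in spec.affected_regions]
                gmv = gmv.copy()
                gmv[cols] -= spec.effect_size * params.noise_sd
            is_patient = group != "HC"
            rows.append(
                {
                    "subject_id": f"S{i_subj:04d}",
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "tiv": tiv,
                    "onset_age": rng.uniform(5.0, 25.0) if is_patient else np.nan,
                    "seizure_frequency": (
                        ("frequent" if rng.uniform() < 0.54 else "infrequent") if is_patient else ""
                    ),
                    "years_since_last_fbtcs": rng.uniform(0.0, 6.0) if group == "FBTCS+" else np.nan,
                }
            )
            gmv_rows.append(gmv)
            i_subj += 1

    df = pd.DataFrame(rows)
    gmv_df = pd.DataFrame(np.vstack(gmv_rows), columns=[str(r) for r in region_ids])
    return SubjectTable(pd.concat([df, gmv_df], axis=1), tuple(region_ids))


def simulate_expression(
    atlas: ParcellationAtlas,
    n_genes: int,
    target_map: pd.Series,
    n_aligned: int,
    alignment_strength: float,
    seed: int = 0,
    spatial_corr_length: float = 0.3,
) -> ExpressionMatrix:
    """Simulate a regions x genes expression matrix with planted alignment.

    Each gene is a spatially smooth field over the atlas (the same
    exponential kernel as cohort noise; independent over subcortex). The
    first ``n_aligned`` genes are mixed with the standardized ``target_map``
    at weight ``alignment_strength`` on the left-hemisphere regions where
    the target is defined, so their regional expression correlates with it.
    Gene identifiers are G000001, G000002, ...
    """
    if not 0.0 <= alignment_strength <= 1.0:
        raise ValueError("alignment_strength must lie in [0, 1]")
    if n_aligned > n_genes:
        raise ValueError("n_aligned cannot exceed n_genes")
    region_ids = atlas.region_ids
    missing = set(target_map.index) - set(region_ids.tolist())
    if missing:
        raise ValueError(f"target_map regions not in atlas: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    K = spatial_covariance(atlas, spatial_corr_length)
    fields = _correlated_noise(K, n_genes, rng).T  # regions x genes

    target_rows = [np.flatnonzero(region_ids == r)[0] for r in target_map.index]
    target_z = z_normalize(target_map.to_numpy(float))
    for j in range(n_aligned):
        fields[target_rows, j] = (
            alignment_strength * target_z + (1.0 - alignment_strength) * fields[target_rows, j]
        )

    values = 5.0 + 1.5 * fields  # microarray-like log-intensity scale
    genes = [f"G{j + 1:06d}" for j in range(n_genes)]
    df = pd.DataFrame(values, index=pd.Index(region_ids, name="region_id"), columns=genes)
    return ExpressionMatrix(df, normalized=False)


def simulate_gene_sets(
    universe,
    planted_genes,
    n_sets: int,
    planted_fraction: float,
    seed: int = 0,
    set_size: int | list[int] = 60,
) -> list[GeneSet]:
    """Build gene sets drawing ``planted_fraction`` of members from a pool.

    Each set takes ``round(planted_fraction * size)`` members from
    ``planted_genes`` and the remainder uniformly (without replacement)
    from the rest of the universe.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must lie in [0, 1]")
    universe = list(universe)
    planted = [g for g in planted_genes if g in set(universe)]
    if list(planted_genes) and len(planted) < len(set(planted_genes)):
        raise ValueError("planted_genes must be a subset of the universe")
    rest = [g for g in universe if g not in set(planted)]
    sizes = [set_size] * n_sets if isinstance(set_size, int) else list(set_size)
    if len(sizes) != n_sets:
        raise ValueError("set_size list must have n_sets entries")
    rng = np.random.default_rng(seed)
    out = []
    for i, size in enumerate(sizes):
        k = min(int(round(planted_fraction * size)), len(planted))
        take_planted = list(rng.choice(planted, size=k, replace=False)) if k else []
        take_rest = list(rng.choice(rest, size=size - k, replace=False)) if size - k else []
        out.append(GeneSet(name=f"SET{i + 1:02d}", genes=tuple(take_planted + take_rest)))
    return out


def simulate_receptor_map(reference_map: pd.Series, target_rho: float, seed: int = 0) -> pd.Series:
    """A per-region map whose expected Spearman with the reference is target_rho.

    Rank-mixture construction: mix the standardized ranks of the reference
    with Gaussian noise at Pearson weight ``r* = 2 sin(pi * target_rho / 6)``
    (the Gaussian-copula inversion of Spearman's rho), so the *expected
    Spearman* correlation of the result with the reference equals
    ``target_rho``; the realized value varies with sampling error.
    """
    if abs(target_rho) > 1.0:
        raise ValueError("target_rho must lie in [-1, 1]")
    ref = reference_map.to_numpy(float)
    if ref.size < 10:
        raise ValueError("reference_map needs at least 10 regions")
    rng = np.random.default_rng(seed)
    u = z_normalize(rankdata(ref))
    r_star = 2.0 * np.sin(np.pi * target_rho / 6.0)
    noise = rng.standard_normal(ref.size)
    y = r_star * u + np.sqrt(max(0.0, 1.0 - r_star**2)) * noise
    return pd.Series(y, index=reference_map.index, name="receptor_density")
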