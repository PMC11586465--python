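"""Covariate-adjusted case-control analysis of regional gray-matter volume.

Per region, an ordinary least squares model

    GMV_i = intercept + b1*age + b2*sex + b3*TIV + b4*group

yields the t statistic of the group coefficient (group coded 0 = control,
1 = patient, so regional atrophy produces negative t). Benjamini-Hochberg
FDR is applied across all regions of one contrast. Region-level GMV is
z-normalized first; the group t statistic is invariant to any affine
rescaling of the response, so this changes presentation only.

The same machinery provides network-level contrasts (mean GMV over the
regions of each functional network or cytoarchitectonic class) and
clinical associations restricted to significant regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import bh_fdr, spearman_correlation, z_normalize

__all__ = [
    "CaseControlMap",
    "CONTRAST_NAMES",
    "fit_region_model",
    "case_control_map",
    "network_contrast",
    "clinical_associations",
    "select_subgroup",
]

CONTRAST_NAMES = ("TLE", "FBTCS-", "FBTCS+", "current-FBTCS+", "remote-FBTCS+")


@dataclass(frozen=True)
class CaseControlMap:
    """Per-region group-coefficient t, p, BH q and significance mask."""

    table: pd.DataFrame  # columns: region_id (or label), t, p, q, significant
    contrast_name: str
    alpha: float = 0.05

    @property
    def t_values(self) -> np.ndarray:
        return self.table["t"].to_numpy(float)

    @property
    def significant_regions(self) -> np.ndarray:
        return self.table.loc[self.table["significant"], self.table.columns[0]].to_numpy()

    def to_tsv(self, path) -> None:
        from .io import write_tsv

        write_tsv(self.table, path)

    def summary(self) -> dict:
        return {
            "contrast": self.contrast_name,
            "alpha": self.alpha,
            "n_regions": int(len(self.table)),
            "n_significant": int(self.table["significant"].sum()),
        }


def _ols_t(Y: np.ndarray, X: np.ndarray, coef_index: int) -> tuple[np.ndarray, np.ndarray]:
    """t and two-sided p of one coefficient, for every column of Y at once.

    The design matrix is shared across responses, so a single pseudo-inverse
    serves all regions.
    """
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} subjects for a {p}-predictor model")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient (collinear predictors)")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[coef_index, coef_index])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[coef_index] / se, np.inf * np.sign(beta[coef_index]))
    pvals = 2.0 * _sps.t.sf(np.abs(t), df)
    return t, pvals


def _design(age, sex, tiv, group) -> np.ndarray:
    age, sex, tiv, group = (np.asarray(v, dtype=float) for v in (age, sex, tiv, group))
    n = age.size
    if not all(v.size == n for v in (sex, tiv, group)):
        raise ValueError("covariates and group indicator must have equal length")
    return np.column_stack([np.ones(n), age, sex, tiv, group])


def fit_region_model(gmv, age, sex, tiv, group) -> tuple[float, float]:
    """OLS fit for one region; returns (t, two-sided p) of the group coefficient."""
    y = np.asarray(gmv, dtype=float)[:, None]
    X = _design(age, sex, tiv, group)
    if y.shape[0] <= X.shape[1]:
        raise ValueError("too few subjects for the five-parameter model")
    t, p = _ols_t(y, X, coef_index=4)
    return float(t[0]), float(p[0])


def _contrast_masks(subjects, patient_group, control_group: str = "HC"):
    """Boolean subject masks (controls, patients) for a named contrast."""
    g = subjects.table["group"]
    if isinstance(patient_group, str):
        if patient_group == "TLE":
            patient_mask = g.isin(["FBTCS-", "FBTCS+"]).to_numpy()
        elif patient_group in ("current-FBTCS+", "remote-FBTCS+"):
            rule = "current" if patient_group.startswith("current") else "remote"
            sub = select_subgroup(subjects, rule)
            patient_mask = subjects.table["subject_id"].isin(sub.table["subject_id"]).to_numpy()
        elif patient_group in ("FBTCS-", "FBTCS+"):
            patient_mask = (g == patient_group).to_numpy()
        else:
            raise ValueError(f"unknown contrast {patient_group!r}")
    else:
        patient_mask = g.isin(list(patient_group)).to_numpy()
    control_mask = (g == control_group).to_numpy() & ~patient_mask
    if not patient_mask.any() or not control_mask.any():
        raise ValueError("both groups of a contrast must be non-empty")
    return control_mask, patient_mask


def case_control_map(
    subjects,
    patient_group="TLE",
    alpha: float = 0.05,
    control_group: str = "HC",
) -> CaseControlMap:
    """Covariate-adjusted group t-map over all regions, with BH-FDR.

    ``patient_group`` may be a contrast name ("TLE" pools both patient
    groups; "current-FBTCS+"/"remote-FBTCS+" select by recency of the last
    bilateral tonic-clonic seizure) or an explicit set of group labels.
    ``control_group`` defaults to healthy controls; pass "FBTCS-" for the
    direct patient-vs-patient contrast.
    """
    control_mask, patient_mask = _contrast_masks(subjects, patient_group, control_group)
    sel = control_mask | patient_mask
    tab = subjects.table.loc[sel]
    Y = tab[subjects.region_columns].to_numpy(float)
    # per-region standardization across subjects; t is invariant to this
    Y = np.apply_along_axis(z_normalize, 0, Y)
    X = _design(tab["age"], tab["sex"], tab["tiv"], patient_mask[sel].astype(float))
    t, p = _ols_t(Y, X, coef_index=4)
    q = bh_fdr(p)
    name = patient_group if isinstance(patient_group, str) else "+".join(sorted(patient_group))
    out = pd.DataFrame(
        {
            "region_id": list(subjects.region_ids),
            "t": t,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    )
    return CaseControlMap(out, contrast_name=f"{name}-vs-{control_group}", alpha=alpha)


def network_contrast(
    subjects, atlas, scheme: str = "yeo", patient_group="TLE", alpha: float = 0.05
) -> CaseControlMap:
    """Group contrast on mean GMV per network of a cortical labelling scheme."""
    col = {"yeo": "yeo_label", "veconomo": "veconomo_label"}.get(scheme)
    if col is None:
        raise ValueError("scheme must be 'yeo' or 'veconomo'")
    labels = atlas.table.loc[atlas.mask(tissue_class="cortical"), col]
    networks = sorted(labels.unique())
    control_mask, patient_mask = _contrast_masks(subjects, patient_group)
    sel = control_mask | patient_mask
    tab = subjects.table.loc[sel]
    gmv = tab[subjects.region_columns].to_numpy(float)
    net_means = np.column_stack(
        [
            gmv[:, (atlas.table[col] == net).to_numpy()].mean(axis=1)
            for net in networks
        ]
    )
    net_means = np.apply_along_axis(z_normalize, 0, net_means)
    X = _design(tab["age"], tab["sex"], tab["tiv"], patient_mask[sel].astype(float))
    t, p = _ols_t(net_means, X, coef_index=4)
    q = bh_fdr(p)
    name = patient_group if isinstance(patient_group, str) else "+".join(sorted(patient_group))
    out = pd.DataFrame({"network": networks, "t": t, "p": p, "q": q, "significant": q < alpha})
    return CaseControlMap(out, contrast_name=f"{scheme}:{name}-vs-HC", alpha=alpha)


def clinical_associations(patients, ccmap: CaseControlMap, alpha: float = 0.05) -> dict:
    """Clinical correlates of GMV in the regions a contrast flagged.

    Restricted to significant regions: (a) Spearman correlation of seizure
    onset age with regional GMV; (b) the group coefficient of a
    frequent-vs-infrequent seizure indicator from the same covariate-
    adjusted model. Both tables are BH-FDR corrected. Empty tables (not an
    error) when the map has no significant region.
    """
    sig = [r for r in ccmap.significant_regions]
    onset_rows, freq_rows = [], []
    if sig:
        tab = patients.table
        onset = tab["onset_age"].to_numpy(float)
        freq = tab["seizure_frequency"].astype(str)
        has_freq = freq.isin(["frequent", "infrequent"]).to_numpy()
        for r in sig:
            gmv_r = tab[str(r)].to_numpy(float)
            res = spearman_correlation(onset, gmv_r)
            onset_rows.append({"region_id": r, "rho": res.statistic, "p": res.p_value})
        ft = tab.loc[has_freq]
        Y = ft[[str(r) for r in sig]].to_numpy(float)
        Y = np.apply_along_axis(z_normalize, 0, Y)
        ind = (ft["seizure_frequency"] == "frequent").to_numpy(float)
        X = _design(ft["age"], ft["sex"], ft["tiv"], ind)
        t, p = _ols_t(Y, X, coef_index=4)
        for r, ti, pi in zip(sig, t, p):
            freq_rows.append({"region_id": r, "t": ti, "p": pi})
    onset_df = pd.DataFrame(onset_rows, columns=["region_id", "rho", "p"])
    freq_df = pd.DataFrame(freq_rows, columns=["region_id", "t", "p"])
    for df in (onset_df, freq_df):
        df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
        df["significant"] = df["q"] < alpha if len(df) else []
    return {"onset_age": onset_df, "seizure_frequency": freq_df}


def select_subgroup(subjects, rule: str):
    """Partition FBTCS+ patients by recency of the last bilateral seizure.

    ``remote``: strictly more than 2 years since the last episode;
    ``current``: within the last 2 years (the 2-year boundary falls in the
    current subgroup). The two rules partition FBTCS+ exhaustively.
    """
    if rule not in ("remote", "current"):
        raise ValueError("rule must be 'remote' or 'current'")
    tab = subjects.table
    fb = (tab["group"] == "FBTCS+").to_numpy()
    years = tab["years_since_last_fbtcs"].to_numpy(float)
    if np.isnan(years[fb]).any():
        raise ValueError("FBTCS+ subjects must carry years_since_last_fbtcs")
    with np.errstate(invalid="ignore"):
        mask = fb & (years > 2.0) if rule == "remote" else fb & (years <= 2.0)
    return subjects.select(mask)
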