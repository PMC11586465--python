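"""Config-driven orchestration of the full analysis.

Sequences, on synthetic or user-supplied tables: (1) case-control GMV
maps per contrast, (2) network-level contrasts, (3) clinical
associations, (4) left-hemisphere PLS association with permutation and
bootstrap inference, (5) gene-set and cell-type enrichment-ratio
batteries, (6) receptor-map correlation. Every stage writes TSV/JSON
outputs under the run directory and the run manifest records per-stage
seeds (derived from the master seed by stable hashing of stage names, so
adding a stage never perturbs earlier stages' randomness).

In synthetic mode the generators plant known effects — atrophic regions,
expression-aligned genes, an enriched gene set, a receptor map with a
prescribed correlation — and the run report carries a ``recovery``
section measuring how well the analysis recovered each of them.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sps

from . import __version__
from .enrichment import CELL_CLASSES, GeneSet, celltype_enrichment, gene_list_battery, gene_list_overlap
from .expression import (
    ExpressionMatrix,
    intensity_filter,
    restrict_left_hemisphere,
    srs_normalize_matrix,
)
from .io import read_gmt, read_tsv, write_gmt, write_json, write_tsv
from .morphometry import case_control_map, clinical_associations, network_contrast
from .pls import bootstrap_gene_stats, permutation_test_variance, top_gene_map_correlation
from .receptor import receptor_correlation
from .spin import generate_spins
from .stats import z_normalize
from .synthetic import (
    AtrophySpec,
    ParcellationAtlas,
    SubjectTable,
    make_atlas,
    simulate_cohort,
    simulate_expression,
    simulate_gene_sets,
    simulate_receptor_map,
)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "stage_seed"]

STAGES = (
    "case_control",
    "network_contrast",
    "clinical",
    "pls",
    "enrichment",
    "receptor",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """A stable per-stage seed below 2**31, independent of stage order."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults are the synthetic study.

    Synthetic defaults emulate the study scale: a 322-region parcellation
    (152 cortical + 7 subcortical per hemisphere), cohorts of 60 controls
    and 37 + 89 patients, 2,000 genes of which 100 are aligned to the
    atrophy map at strength 0.6, atrophy of 2 noise-SD on 10 left
    cortical regions, one gene set planted at fraction 0.5, and a
    receptor map at expected Spearman 0.24 with the t-map.
    """

    mode: str = "synthetic"
    out_dir: str = "morphotx_run"
    master_seed: int = 0
    # contrasts
    contrasts: tuple[str, ...] = ("TLE", "FBTCS-", "FBTCS+")
    pls_contrasts: tuple[str, ...] = ("FBTCS-", "FBTCS+")
    alpha: float = 0.05
    posthoc_alpha: float = 0.017
    # inference sizes
    n_perm_spin: int = 1000
    n_perm_er: int = 10_000
    n_boot: int = 1000
    # synthetic-mode generator parameters
    n_cortical_per_hemi: int = 152
    n_cortical_right_hemi: int = 156  # real backtracking parcellations are asymmetric
    n_subcortical_per_hemi: int = 7
    n_per_group: dict = field(default_factory=lambda: {"HC": 60, "FBTCS-": 37, "FBTCS+": 89})
    n_atrophy_regions: int = 10
    atrophy_effect_size: float = 2.0
    spatial_corr_length: float = 0.3
    n_genes: int = 2000
    n_aligned: int = 100
    alignment_strength: float = 0.6
    n_gene_sets: int = 6
    planted_set_fraction: float = 0.5
    gene_set_size: int = 60
    n_celltype_genes: int = 700
    receptor_target_rho: float = 0.24
    detection_prob: float = 0.95
    # real-mode input paths
    atlas_path: str | None = None
    subjects_path: str | None = None
    expression_path: str | None = None
    gene_sets_path: str | None = None
    celltype_path: str | None = None
    receptor_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if self.n_perm_spin < 100 or self.n_perm_er < 100:
            raise ValueError("permutation counts must be at least 100")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.contrasts = tuple(self.contrasts)
        self.pls_contrasts = tuple(self.pls_contrasts)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# input assembly


def _synthesize_inputs(config: RunConfig) -> dict:
    """Generate the full synthetic input bundle with planted effects."""
    seed = stage_seed(config.master_seed, "synthesize")
    rng = np.random.default_rng(seed)
    atlas = make_atlas(
        config.n_cortical_per_hemi,
        config.n_subcortical_per_hemi,
        seed=seed,
        n_cortical_right_hemi=config.n_cortical_right_hemi,
    )
    left_cortical = atlas.region_ids[atlas.mask(hemisphere="left", tissue_class="cortical")]
    planted_regions = tuple(
        int(r) for r in rng.choice(left_cortical, size=config.n_atrophy_regions, replace=False)
    )
    spec = AtrophySpec(planted_regions, config.atrophy_effect_size, config.spatial_corr_length)
    subjects = simulate_cohort(
        atlas,
        dict(config.n_per_group),
        atrophy_specs={"FBTCS-": spec, "FBTCS+": spec},
        seed=stage_seed(config.master_seed, "cohort"),
        spatial_corr_length=config.spatial_corr_length,
    )
    # the expression alignment target is the pooled-patient t-map (left hemisphere)
    tle_map = case_control_map(subjects, "TLE", alpha=config.alpha)
    left_mask = atlas.mask(hemisphere="left")
    left_ids = atlas.region_ids[left_mask]
    tmap_series = pd.Series(tle_map.t_values, index=atlas.region_ids)
    target = tmap_series.loc[left_ids]
    expr = simulate_expression(
        atlas,
        config.n_genes,
        target_map=target,
        n_aligned=config.n_aligned,
        alignment_strength=config.alignment_strength,
        seed=stage_seed(config.master_seed, "expression"),
        spatial_corr_length=config.spatial_corr_length,
    )
    aligned_genes = tuple(expr.genes[: config.n_aligned])
    gene_sets = simulate_gene_sets(
        expr.genes,
        planted_genes=aligned_genes,
        n_sets=1,
        planted_fraction=config.planted_set_fraction,
        seed=stage_seed(config.master_seed, "gene_sets"),
        set_size=config.gene_set_size,
    )
    gene_sets[0] = GeneSet("PLANTED", gene_sets[0].genes, description="planted enrichment")
    null_sets = simulate_gene_sets(
        expr.genes,
        planted_genes=(),
        n_sets=max(config.n_gene_sets - 1, 0),
        planted_fraction=0.0,
        seed=stage_seed(config.master_seed, "null_sets"),
        set_size=config.gene_set_size,
    )
    gene_sets = gene_sets + null_sets
    ct_rng = np.random.default_rng(stage_seed(config.master_seed, "celltypes"))
    ct_genes = ct_rng.choice(expr.genes, size=min(config.n_celltype_genes, len(expr.genes)), replace=False)
    celltype_table = pd.Series(
        ct_rng.choice(CELL_CLASSES, size=ct_genes.size), index=ct_genes, name="cell_class"
    )
    receptor = simulate_receptor_map(
        tmap_series,
        target_rho=config.receptor_target_rho,
        seed=stage_seed(config.master_seed, "receptor"),
    )
    det_rng = np.random.default_rng(stage_seed(config.master_seed, "detection"))
    detected = pd.DataFrame(
        det_rng.random(expr.shape) < config.detection_prob,
        index=expr.values.index,
        columns=expr.values.columns,
    )
    return {
        "atlas": atlas,
        "subjects": subjects,
        "expression": expr,
        "detected": detected,
        "gene_sets": gene_sets,
        "celltype_table": celltype_table,
        "receptor": receptor,
        "planted": {
            "regions": planted_regions,
            "aligned_genes": aligned_genes,
            "gene_set": "PLANTED",
            "receptor_rho": config.receptor_target_rho,
        },
    }


def _load_inputs(config: RunConfig) -> dict:
    atlas = ParcellationAtlas.from_tsv(config.atlas_path)
    subjects = SubjectTable.from_tsv(config.subjects_path, atlas.region_ids)
    expr = ExpressionMatrix.from_tsv(config.expression_path)
    gene_sets = [
        GeneSet(name, genes=tuple(genes), description=desc)
        for name, desc, genes in read_gmt(config.gene_sets_path)
    ]
    ct = read_tsv(config.celltype_path)
    celltype_table = pd.Series(ct.iloc[:, 1].to_numpy(), index=ct.iloc[:, 0].to_numpy())
    rec = read_tsv(config.receptor_path)
    receptor = pd.Series(rec.iloc[:, 1].to_numpy(float), index=rec.iloc[:, 0].to_numpy())
    return {
        "atlas": atlas,
        "subjects": subjects,
        "expression": expr,
        "detected": None,
        "gene_sets": gene_sets,
        "celltype_table": celltype_table,
        "receptor": receptor,
        "planted": None,
    }


def validate_inputs(config: RunConfig, inputs: dict | None = None) -> list[dict]:
    """Collect (not raise) schema and cross-file consistency findings."""
    findings: list[dict] = []
    if inputs is None:
        if config.mode == "real":
            for name in ("atlas_path", "subjects_path", "expression_path"):
                path = getattr(config, name)
                if path is None or not Path(path).exists():
                    findings.append({"severity": "error", "message": f"missing input file: {name}={path}"})
            if findings:
                return findings
            inputs = _load_inputs(config)
        else:
            inputs = _synthesize_inputs(config)
    atlas, subjects, expr = inputs["atlas"], inputs["subjects"], inputs["expression"]
    atlas_ids = set(atlas.region_ids.tolist())
    for col in ("group", "age", "sex", "tiv"):
        if col not in subjects.table.columns:
            findings.append({"severity": "error", "message": f"subject table lacks column {col!r}"})
    missing_cols = [r for r in atlas.region_ids if str(r) not in subjects.table.columns]
    if missing_cols:
        findings.append(
            {
                "severity": "error",
                "message": f"subject table lacks GMV columns for regions {missing_cols[:5]}",
            }
        )
    bad_regions = [r for r in expr.regions if r not in atlas_ids]
    if bad_regions:
        findings.append(
            {"severity": "error", "message": f"expression rows with unknown region_id: {bad_regions[:5]}"}
        )
    expr_genes = set(expr.genes)
    for gs in inputs["gene_sets"]:
        outside = [g for g in gs.genes if g not in expr_genes]
        if outside:
            findings.append(
                {
                    "severity": "warning",
                    "message": f"gene set {gs.name!r}: {len(outside)} genes outside the expression universe",
                }
            )
    ct_outside = [g for g in inputs["celltype_table"].index if g not in expr_genes]
    if ct_outside:
        findings.append(
            {
                "severity": "warning",
                "message": f"cell-class table: {len(ct_outside)} genes outside the expression universe",
            }
        )
    missing_rec = [r for r in atlas.region_ids if r not in inputs["receptor"].index]
    if missing_rec:
        findings.append(
            {"severity": "error", "message": f"receptor map misses regions {missing_rec[:5]}"}
        )
    return findings


# ---------------------------------------------------------------------------
# the run itself


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the machine-readable report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    inputs = _synthesize_inputs(config) if config.mode == "synthetic" else _load_inputs(config)
    atlas: ParcellationAtlas = inputs["atlas"]
    subjects: SubjectTable = inputs["subjects"]

    atlas.to_tsv(out / "atlas.tsv")
    subjects.to_tsv(out / "subjects.tsv")
    write_gmt(inputs["gene_sets"], out / "gene_sets.gmt")
    write_tsv(
        inputs["celltype_table"].rename_axis("gene").reset_index(), out / "cell_classes.tsv"
    )
    write_tsv(
        inputs["receptor"].rename_axis("region_id").reset_index(), out / "receptor_map.tsv"
    )

    report: dict = {"config": asdict(config), "stages": {}}
    manifest = {
        "master_seed": config.master_seed,
        "versions": {
            "morphotx": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
    }
    stage_t0 = time.time()

    def _finish(stage: str) -> None:
        nonlocal stage_t0
        manifest["stages"].append(
            {
                "name": stage,
                "seed": stage_seed(config.master_seed, stage),
                "seconds": round(time.time() - stage_t0, 3),
            }
        )
        stage_t0 = time.time()

    def _run(stage: str, fn):
        try:
            result = fn()
        except Exception as exc:  # annotate the failing stage, keep partial outputs
            write_json(report, out / "report.json")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        _finish(stage)
        return result

    # (1) case-control maps -------------------------------------------------
    def _stage_maps():
        maps = {}
        for contrast in config.contrasts:
            alpha = config.alpha if contrast in ("TLE",) else config.alpha
            cc = case_control_map(subjects, contrast, alpha=alpha)
            cc.to_tsv(out / "maps" / f"{contrast}.tsv")
            maps[contrast] = cc
        report["stages"]["case_control"] = {c: m.summary() for c, m in maps.items()}
        return maps

    maps = _run("case_control", _stage_maps)

    # (2) network contrasts -------------------------------------------------
    def _stage_networks():
        nets = {}
        for scheme in ("yeo", "veconomo"):
            for contrast in config.contrasts:
                nc = network_contrast(subjects, atlas, scheme, contrast, alpha=config.alpha)
                nc.to_tsv(out / "networks" / f"{scheme}_{contrast}.tsv")
                nets[f"{scheme}:{contrast}"] = nc.summary()
        report["stages"]["network_contrast"] = nets
        return nets

    _run("network_contrast", _stage_networks)

    # (3) clinical associations --------------------------------------------
    def _stage_clinical():
        patients = subjects.select(subjects.table["group"].isin(["FBTCS-", "FBTCS+"]).to_numpy())
        assoc = clinical_associations(patients, maps[config.contrasts[0]], alpha=config.alpha)
        for key, df in assoc.items():
            write_tsv(df, out / "clinical" / f"{key}.tsv")
        report["stages"]["clinical"] = {
            k: {"n_regions": int(len(df)), "n_significant": int(df["significant"].sum()) if len(df) else 0}
            for k, df in assoc.items()
        }
        return assoc

    _run("clinical", _stage_clinical)

    # (4) left-hemisphere PLS ----------------------------------------------
    left_atlas = atlas.subset(atlas.mask(hemisphere="left"))
    left_ids = left_atlas.region_ids

    def _stage_pls():
        expr = inputs["expression"]
        if inputs["detected"] is not None:
            expr = intensity_filter(expr.values, inputs["detected"])
        expr = srs_normalize_matrix(expr)
        expr_left = restrict_left_hemisphere(expr, atlas)
        expr_left = ExpressionMatrix(expr_left.values.loc[list(left_ids)], normalized=True)
        spins_left = generate_spins(
            left_atlas, n_perm=config.n_perm_spin, seed=stage_seed(config.master_seed, "spins_left")
        )
        Xz = np.apply_along_axis(z_normalize, 0, expr_left.values.to_numpy(float))
        pls_results = {}
        for contrast in config.pls_contrasts:
            t_series = pd.Series(maps[contrast].t_values, index=atlas.region_ids)
            y = z_normalize(t_series.loc[list(left_ids)].to_numpy(float))
            res = bootstrap_gene_stats(
                Xz,
                y,
                genes=expr_left.genes,
                region_ids=list(left_ids),
                n_boot=config.n_boot,
                alpha=config.alpha,
                seed=stage_seed(config.master_seed, f"boot:{contrast}"),
            )
            p_perm = permutation_test_variance(Xz, y, n_perm=config.n_perm_spin, spins=spins_left)
            res = PLSHolder(res, p_perm)
            res.result.to_files(
                out / "pls" / f"{contrast}_genes.tsv",
                out / "pls" / f"{contrast}_scores.tsv",
                out / "pls" / f"{contrast}_summary.json",
            )
            score_rho, score_p = spin_pvalue_scores(res.result, y, spins_left)
            top = {}
            for list_name in ("PLS+", "PLS-"):
                ranked = res.result.pls_plus if list_name == "PLS+" else res.result.pls_minus
                if ranked:
                    rho, p_spin = top_gene_map_correlation(ranked[0], expr_left, y, spins_left)
                    top[list_name] = {"gene": ranked[0], "rho": rho, "p_spin": p_spin}
            pls_results[contrast] = res
            report["stages"].setdefault("pls", {})[contrast] = {
                **res.result.summary(),
                "p_perm": p_perm,
                "score_map_rho": score_rho,
                "score_map_p_spin": score_p,
                "top_genes": top,
            }
        return expr_left, spins_left, pls_results

    expr_left, spins_left, pls_results = _run("pls", _stage_pls)

    # (5) enrichment batteries ---------------------------------------------
    def _stage_enrichment():
        rows = []
        for contrast, holder in pls_results.items():
            battery = gene_list_battery(
                holder.result,
                inputs["gene_sets"],
                n_perm=config.n_perm_er,
                seed=stage_seed(config.master_seed, f"er:{contrast}"),
            )
            cells = celltype_enrichment(
                holder.result,
                inputs["celltype_table"],
                n_perm=config.n_perm_er,
                seed=stage_seed(config.master_seed, f"er_cells:{contrast}"),
            )
            for r in battery + cells:
                rows.append({"contrast": contrast, **r.to_dict()})
        df = pd.DataFrame(rows)
        write_tsv(df, out / "enrichment" / "enrichment.tsv")
        report["stages"]["enrichment"] = {"n_tests": int(len(df))}
        if len(config.pls_contrasts) >= 2:
            a, b = config.pls_contrasts[:2]
            pa, pb = pls_results[a].result.pls_plus, pls_results[b].result.pls_plus
            if pa and pb:
                ab, ba, jac = gene_list_overlap(pa, pb)
                report["stages"]["enrichment"]["pls_plus_overlap"] = {
                    f"{a}_in_{b}": ab,
                    f"{b}_in_{a}": ba,
                    "jaccard": jac,
                }
        return df

    enrichment_df = _run("enrichment", _stage_enrichment)

    # (6) receptor correlation ---------------------------------------------
    def _stage_receptor():
        spins_all = generate_spins(
            atlas, n_perm=config.n_perm_spin, seed=stage_seed(config.master_seed, "spins_full")
        )
        res = {}
        for contrast in config.pls_contrasts:
            rho, p_spin = receptor_correlation(maps[contrast], inputs["receptor"], spins_all)
            res[contrast] = {"rho": rho, "p_spin": p_spin}
        report["stages"]["receptor"] = res
        write_json(res, out / "receptor_correlation.json")
        return res

    _run("receptor", _stage_receptor)

    if inputs["planted"] is not None:
        report["recovery"] = _recovery_metrics(config, inputs, maps, pls_results, enrichment_df)

    manifest["seconds_total"] = round(time.time() - t_start, 3)
    report["manifest"] = manifest
    write_json(manifest, out / "manifest.json")
    write_json(report, out / "report.json")
    return report


class PLSHolder:
    """A PLSResult paired with the permutation p of its explained variance."""

    def __init__(self, result, p_perm: float):
        self.result = result
        self.p_perm = p_perm


def spin_pvalue_scores(pls_result, y: np.ndarray, spins) -> tuple[float, float]:
    """Spin-tested Spearman correlation of the PLS1 score map with the response."""
    from .spin import spin_pvalue

    return spin_pvalue(pls_result.scores.to_numpy(float), y, spins, stat="spearman")


def _recovery_metrics(config, inputs, maps, pls_results, enrichment_df) -> dict:
    """Did the analysis recover what the generators planted?"""
    planted = inputs["planted"]
    primary = config.contrasts[0]
    sig = set(maps[primary].significant_regions.tolist())
    regions_found = sorted(r for r in planted["regions"] if r in sig)
    out = {
        "planted_regions": list(planted["regions"]),
        "planted_regions_recovered": regions_found,
        "n_planted_recovered": len(regions_found),
    }
    aligned = set(planted["aligned_genes"])
    for contrast, holder in pls_results.items():
        tab = holder.result.gene_table.sort_values(["abs_z", "gene"], ascending=[False, True])
        modeled_aligned = aligned & set(tab["gene"])
        top = set(tab["gene"].head(len(modeled_aligned)))
        k = len(top & modeled_aligned)
        m = len(tab)
        # hypergeometric upper tail: overlap of the aligned set with the top-|aligned| ranking
        p_hyper = float(
            _sps.hypergeom.sf(k - 1, m, len(modeled_aligned), len(top))
        ) if modeled_aligned else 1.0
        out[f"aligned_gene_overlap_{contrast}"] = {
            "n_top_overlap": k,
            "n_aligned_modeled": len(modeled_aligned),
            "p_hypergeom": p_hyper,
        }
    mask = (enrichment_df["set_name"] == planted["gene_set"]) & (enrichment_df["list_name"] == "PLS+")
    if mask.any():
        sub = enrichment_df.loc[mask]
        out["planted_set_er"] = {
            row["contrast"]: {"er": row["er"], "p_perm": row["p_perm"], "q": row["q"]}
            for _, row in sub.iterrows()
        }
    return out
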