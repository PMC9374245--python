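"""Config-driven orchestration of the full skull-morphometrics analysis graph.

Three entry points mirror the structure of a two-species + hybrid study:

* :func:`run_cranium_analysis` — missing-landmark estimation per species,
  GPA, PCA on the full and reduced landmark schemes, Procrustes ANOVA
  (allometry, sexual shape/size dimorphism, within-species slopes),
  UPGMA with bootstrap supports, stepwise DFA with cross-validation and
  query assignment, k-means, and allometry-free PCA.
* :func:`run_mandible_analysis` — sliding-semilandmark GPA, PCA,
  allometry regression, UPGMA, k-means.
* :func:`run_integration` — specimen intersection of the two parts,
  zero-padding of the 2-D block, overall and per-species two-block PLS
  with angle comparisons.

Query specimens (putative hybrids) never inform ANOVA groups, stepwise
selection or LDA training; they are projected into the common shape space
and assigned.  Every report carries the package version, a config hash
and all seeds, and identical configs yield identical numeric tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import bootstrap_supports, kmeans_two, lda_classify, stepwise_select, upgma
from .datatypes import LandmarkDataset
from .integration import compare_group_pls, pad_to_3d, two_block_pls
from .io_formats import read_coord_table, read_sliders, read_tps
from .procrustes import estimate_missing, gpa, pairwise_procrustes_distances
from .shape_stats import allometry_free_shapes, procrustes_anova, shape_pca

__all__ = [
    "AnalysisConfig",
    "load_config",
    "run_cranium_analysis",
    "run_mandible_analysis",
    "run_integration",
    "write_report",
]


@dataclass
class AnalysisConfig:
    """Parameters for one analysis run; loadable from a YAML mapping."""

    cranium_path: str | None = None
    cranium_metadata: str | None = None
    mandible_path: str | None = None
    sliders_path: str | None = None
    drop_landmarks: list[int] = field(default_factory=list)  # reduced cranial scheme
    exclude_mandible_landmarks: list[int] = field(default_factory=list)
    query_species: list[str] = field(default_factory=lambda: ["hybrid"])
    query_reference_group: str = "narwhal"  # group used to estimate query missing landmarks
    group_key: str = "species"
    permutations: int = 999
    n_boot: int = 500
    kmeans_restarts: int = 25
    stepwise_f_in: float = 3.84
    stepwise_f_out: float = 2.71
    slide_criterion: str = "bending_energy"
    include_queries_in_gpa: bool = True
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> AnalysisConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def _run_log(config: AnalysisConfig, stage: str) -> dict[str, Any]:
    return {
        "package_version": __version__,
        "stage": stage,
        "config_hash": config.hash(),
        "config": dataclasses.asdict(config),
    }


def _split_queries(
    dataset: LandmarkDataset, config: AnalysisConfig
) -> tuple[list[str], list[str]]:
    meta = dataset.metadata()
    is_query = meta["species"].isin(config.query_species)
    return list(meta.index[~is_query]), list(meta.index[is_query])


def _estimate_with_query_reference(
    dataset: LandmarkDataset, config: AnalysisConfig
) -> LandmarkDataset:
    """Missing-landmark estimation per species; query specimens are
    estimated within the configured reference group."""
    if all(c.is_complete for c in dataset):
        return dataset
    relabelled = []
    originals: dict[str, str] = {}
    for c in dataset:
        c = c.copy()
        if c.species in config.query_species:
            originals[c.specimen_id] = c.species
            c.species = config.query_reference_group
        relabelled.append(c)
    est = estimate_missing(
        LandmarkDataset(relabelled, list(dataset.landmark_labels)), group_by="species"
    )
    for c in est:
        if c.specimen_id in originals:
            c.species = originals[c.specimen_id]
    return est


def _anova_to_frame(result) -> pd.DataFrame:
    return result.table


def run_cranium_analysis(dataset: LandmarkDataset, config: AnalysisConfig) -> dict[str, Any]:
    """Full cranium chain; returns a report bundle of tables and values."""
    try:
        report: dict[str, Any] = {"log": _run_log(config, "cranium"), "tables": {}, "values": {}}
        complete = _estimate_with_query_reference(dataset, config)
        train_ids, query_ids = _split_queries(complete, config)

        aligned = gpa(complete)
        meta = complete.metadata().loc[aligned.specimen_ids]
        report["values"]["n_total"] = aligned.n
        report["values"]["n_training"] = len(train_ids)
        report["values"]["gpa_iterations"] = aligned.iterations

        # ordination: full and reduced landmark schemes
        pca_full = shape_pca(aligned)
        pca_red = shape_pca(aligned, drop_landmarks=config.drop_landmarks or None)
        report["values"]["pc1_pct_full"] = float(pca_full.percent_variance[0])
        report["values"]["pc2_pct_full"] = float(pca_full.percent_variance[1])
        report["values"]["pc1_pct_reduced"] = float(pca_red.percent_variance[0])
        report["values"]["pc2_pct_reduced"] = float(pca_red.percent_variance[1])
        report["tables"]["pc_scores"] = pd.DataFrame(
            pca_red.scores[:, : min(6, pca_red.m)],
            index=pca_red.specimen_ids,
            columns=[f"PC{i + 1}" for i in range(min(6, pca_red.m))],
        )

        # reduced-scheme aligned sample for all downstream statistics
        reduced_ds = complete.drop_landmarks(config.drop_landmarks) if config.drop_landmarks else complete
        aligned_red = gpa(reduced_ds)
        idx_train = [aligned_red.specimen_ids.index(s) for s in train_ids]
        idx_query = [aligned_red.specimen_ids.index(s) for s in query_ids]
        flat = aligned_red.flattened()
        data = pd.DataFrame(
            {
                "log_cs": aligned_red.log_cs,
                "cs": aligned_red.centroid_sizes,
                "species": meta["species"].to_numpy(),
                "sex": meta["sex"].to_numpy(),
            },
            index=aligned_red.specimen_ids,
        )

        # allometry: with queries (size only) and without (full species model)
        report["tables"]["anova_allometry_all"] = _anova_to_frame(
            procrustes_anova(
                flat, ["log_cs"], data, permutations=config.permutations, seed=config.seed
            )
        )
        data_train = data.iloc[idx_train]
        anova_allometry = procrustes_anova(
            flat[idx_train],
            ["log_cs", "species", "log_cs:species"],
            data_train,
            permutations=config.permutations,
            seed=config.seed,
        )
        report["tables"]["anova_allometry"] = _anova_to_frame(anova_allometry)
        report["values"]["allometry_rsq"] = anova_allometry.rsq("log_cs")
        report["values"]["species_rsq"] = anova_allometry.rsq("species")

        # sexual dimorphism on the sexed training subset
        sexed = [
            i for i in idx_train if data["sex"].iloc[i] in ("F", "M")
        ]
        if len(sexed) >= 8 and data["sex"].iloc[sexed].nunique() == 2:
            data_sexed = data.iloc[sexed]
            sshd = procrustes_anova(
                flat[sexed],
                ["sex", "species", "sex:species"],
                data_sexed,
                permutations=config.permutations,
                seed=config.seed + 1,
            )
            ssd = procrustes_anova(
                data_sexed["cs"].to_numpy(),
                ["sex", "species", "sex:species"],
                data_sexed,
                permutations=config.permutations,
                seed=config.seed + 2,
            )
            report["tables"]["anova_sshd"] = _anova_to_frame(sshd)
            report["tables"]["anova_ssd"] = _anova_to_frame(ssd)
            report["values"]["sshd_sex_p"] = sshd.p_value("sex")
            report["values"]["ssd_sex_p"] = ssd.p_value("sex")
            report["values"]["ssd_sex_rsq"] = ssd.rsq("sex")
            # within-species allometric slope models
            for sp in sorted(data_sexed["species"].unique()):
                sub = [i for i in sexed if data["species"].iloc[i] == sp]
                if len(sub) >= 8 and data["sex"].iloc[sub].nunique() == 2:
                    per = procrustes_anova(
                        flat[sub],
                        ["log_cs", "sex", "log_cs:sex"],
                        data.iloc[sub],
                        permutations=config.permutations,
                        seed=config.seed + 3,
                    )
                    report["tables"][f"anova_slopes_{sp}"] = _anova_to_frame(per)

        # UPGMA on Procrustes distances with bootstrap supports
        dist = pairwise_procrustes_distances(aligned_red)
        tree = upgma(dist, labels=aligned_red.specimen_ids)
        report["values"]["cophenetic_r"] = tree.cophenetic_r
        boot_tree = bootstrap_supports(
            flat - flat.mean(axis=0),
            n_boot=config.n_boot,
            seed=config.seed,
            labels=aligned_red.specimen_ids,
        )
        report["values"]["newick"] = tree.to_newick()
        report["tables"]["upgma_supports"] = pd.DataFrame(
            {"height": boot_tree.heights, "support_pct": boot_tree.supports}
        )

        # stepwise DFA on PC scores + log CS, trained on parental species only
        pca_train = shape_pca(aligned_red.subset(np.array(idx_train)))
        predictors = np.column_stack(
            [pca_train.scores, data_train["log_cs"].to_numpy()]
        )
        groups = data_train["species"].to_numpy()
        retained = stepwise_select(
            predictors, groups, f_in=config.stepwise_f_in, f_out=config.stepwise_f_out
        )
        report["values"]["n_predictors_candidate"] = predictors.shape[1]
        report["values"]["n_predictors_retained"] = len(retained)
        if retained:
            # project queries into the training PC space
            train_mean = flat[idx_train].mean(axis=0)
            query_scores = (flat[idx_query] - train_mean) @ pca_train.axes.T if idx_query else None
            query_pred = (
                np.column_stack([query_scores, data["log_cs"].iloc[idx_query].to_numpy()])
                if idx_query
                else None
            )
            dfa = lda_classify(
                predictors[:, retained],
                groups,
                queries=query_pred[:, retained] if query_pred is not None else None,
                query_ids=query_ids or None,
            )
            report["values"]["dfa_cv_rate"] = dfa.cv_rate
            report["values"]["dfa_wilks_lambda"] = dfa.wilks_lambda
            report["values"]["dfa_chi_square"] = dfa.chi_square
            report["values"]["dfa_p"] = dfa.p_value
            report["tables"]["dfa_confusion"] = dfa.confusion
            report["values"]["dfa_per_group"] = dfa.per_group_rates
            report["values"]["dfa_assignments"] = {
                q: grp for q, (grp, _) in dfa.assignments.items()
            }

        # k-means (k = 2) on shape variables, all specimens
        labels, wss, _ = kmeans_two(flat, restarts=config.kmeans_restarts, seed=config.seed)
        report["tables"]["kmeans"] = pd.DataFrame(
            {"cluster": labels}, index=aligned_red.specimen_ids
        )
        report["values"]["kmeans_within_ss"] = wss

        # allometry-free PCA
        free = allometry_free_shapes(
            flat, aligned_red.log_cs, grouping=None
        )
        free_scores = _pc_scores_frame(free, aligned_red.specimen_ids)
        report["tables"]["allometry_free_pc_scores"] = free_scores
        return report
    except Exception as exc:
        raise RuntimeError(f"cranium analysis failed: {exc}") from exc


def _pc_scores_frame(flat: np.ndarray, ids: list[str], m: int = 4) -> pd.DataFrame:
    x = flat - flat.mean(axis=0)
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    m = min(m, int(np.sum(sv > sv[0] * 1e-10)))
    return pd.DataFrame(
        u[:, :m] * sv[:m], index=ids, columns=[f"PC{i + 1}" for i in range(m)]
    )


def run_mandible_analysis(dataset: LandmarkDataset, config: AnalysisConfig) -> dict[str, Any]:
    """Mandible chain: sliding GPA, PCA, allometry, UPGMA, k-means."""
    try:
        report: dict[str, Any] = {"log": _run_log(config, "mandible"), "tables": {}, "values": {}}
        sliders = None
        if config.sliders_path:
            sliders = read_sliders(config.sliders_path, dataset.k)
        ds = dataset
        if config.exclude_mandible_landmarks:
            ds = ds.drop_landmarks(config.exclude_mandible_landmarks)
            if sliders is not None:
                raise ValueError(
                    "landmark exclusion with sliders requires a slider file matching the "
                    "reduced scheme; re-index the slider file"
                )
        complete = _estimate_with_query_reference(ds, config)
        aligned = gpa(complete, sliders=sliders, slide_criterion=config.slide_criterion)
        meta = complete.metadata().loc[aligned.specimen_ids]
        report["values"]["n_total"] = aligned.n
        report["values"]["gpa_iterations"] = aligned.iterations

        pca = shape_pca(aligned)
        report["values"]["pc1_pct"] = float(pca.percent_variance[0])
        report["values"]["pc2_pct"] = float(pca.percent_variance[1])
        report["tables"]["pc_scores"] = pd.DataFrame(
            pca.scores[:, : min(6, pca.m)],
            index=pca.specimen_ids,
            columns=[f"PC{i + 1}" for i in range(min(6, pca.m))],
        )

        train_ids, query_ids = _split_queries(complete, config)
        idx_train = [aligned.specimen_ids.index(s) for s in train_ids]
        flat = aligned.flattened()
        data = pd.DataFrame(
            {"log_cs": aligned.log_cs, "species": meta["species"].to_numpy()},
            index=aligned.specimen_ids,
        )
        allom = procrustes_anova(
            flat[idx_train],
            ["log_cs"],
            data.iloc[idx_train],
            permutations=config.permutations,
            seed=config.seed,
        )
        report["tables"]["anova_allometry"] = allom.table
        report["values"]["allometry_rsq"] = allom.rsq("log_cs")
        report["values"]["allometry_p"] = allom.p_value("log_cs")

        dist = pairwise_procrustes_distances(aligned)
        tree = upgma(dist, labels=aligned.specimen_ids)
        report["values"]["cophenetic_r"] = tree.cophenetic_r
        report["values"]["newick"] = tree.to_newick()

        labels, wss, _ = kmeans_two(flat, restarts=config.kmeans_restarts, seed=config.seed)
        report["tables"]["kmeans"] = pd.DataFrame({"cluster": labels}, index=aligned.specimen_ids)
        report["values"]["kmeans_within_ss"] = wss
        return report
    except Exception as exc:
        raise RuntimeError(f"mandible analysis failed: {exc}") from exc


def run_integration(
    cranium: LandmarkDataset, mandible: LandmarkDataset, config: AnalysisConfig
) -> dict[str, Any]:
    """Cranium-mandible two-block PLS on the specimen intersection."""
    try:
        report: dict[str, Any] = {"log": _run_log(config, "integration"), "tables": {}, "values": {}}
        shared = [s for s in cranium.specimen_ids if s in set(mandible.specimen_ids)]
        if len(shared) < 3:
            raise ValueError(f"only {len(shared)} specimens present in both parts")
        report["values"]["n_shared"] = len(shared)

        cr = _estimate_with_query_reference(cranium.subset(shared), config)
        md = _estimate_with_query_reference(mandible.subset(shared), config)
        aligned_cr = gpa(cr)
        aligned_md = gpa(md)
        if aligned_cr.specimen_ids != aligned_md.specimen_ids:
            raise ValueError("specimen order mismatch between blocks")
        block_a = aligned_cr.flattened()
        block_b = aligned_md.flattened()
        if aligned_cr.d == 3 and aligned_md.d == 2:
            block_b = pad_to_3d(block_b, aligned_md.k)

        pls = two_block_pls(
            block_a, block_b, permutations=config.permutations, seed=config.seed
        )
        report["values"]["sa1_pct_sq_cov"] = float(pls.percent_sq_cov[0])
        report["values"]["sa1_correlation"] = pls.sa1_correlation
        report["values"]["pls_perm_p"] = pls.perm_p
        report["tables"]["pls_scores"] = pd.DataFrame(
            {
                "sa1_cranium": pls.scores_a[:, 0],
                "sa1_mandible": pls.scores_b[:, 0],
            },
            index=aligned_cr.specimen_ids,
        )

        meta = cr.metadata().loc[aligned_cr.specimen_ids]
        parental = ~meta["species"].isin(config.query_species)
        groups = meta["species"][parental].to_numpy()
        if len(np.unique(groups)) == 2:
            per_group, angles = compare_group_pls(
                block_a[parental.to_numpy()],
                block_b[parental.to_numpy()],
                groups,
                permutations=config.permutations,
                seed=config.seed,
            )
            for sp, res in per_group.items():
                report["values"][f"sa1_pct_sq_cov_{sp}"] = float(res.percent_sq_cov[0])
                report["values"][f"sa1_correlation_{sp}"] = res.sa1_correlation
            report["values"]["angle_cranium_deg"] = angles["block_a"].angle_deg
            report["values"]["angle_cranium_p"] = angles["block_a"].p_value
            report["values"]["angle_mandible_deg"] = angles["block_b"].angle_deg
            report["values"]["angle_mandible_p"] = angles["block_b"].p_value
        return report
    except Exception as exc:
        raise RuntimeError(f"integration analysis failed: {exc}") from exc


def load_datasets(config: AnalysisConfig) -> tuple[LandmarkDataset | None, LandmarkDataset | None]:
    cranium = mandible = None
    if config.cranium_path:
        cranium = read_coord_table(
            config.cranium_path, dims=3, metadata_path=config.cranium_metadata, part="cranium"
        )
    if config.mandible_path:
        mandible = read_tps(config.mandible_path, missing_sentinel=True, part="mandible")
    return cranium, mandible


def write_report(report: dict[str, Any], outdir: str | Path) -> None:
    """Write a report bundle: one CSV per table plus a JSON run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = report["log"]["stage"]
    for name, table in report["tables"].items():
        table.to_csv(outdir / f"{stage}_{name}.csv")
    payload = {"log": report["log"], "values": _jsonable(report["values"])}
    (outdir / f"{stage}_report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
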