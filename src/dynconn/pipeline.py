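"""End-to-end orchestration: simulate -> trial FC -> dFC -> NBS ->
network maps -> cross-phase -> CCA, from one structured config.

Every stage runs single-process and deterministically: stage seeds are
derived from the top-level seed with fixed offsets, so re-running an
identical config reproduces every statistic bit-identically.  All written
artifacts carry provenance metadata (stage, parameters, seed, input
hashes) in the run report.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import file_sha256, upper_edge_index, vec_upper
from .cca import PermutationCCA, canonical_loadings
from .cross_phase import CrossPhaseRegression, compare_correlations
from .dynamics import block_average, component_mean_series, delta_fc, differential_change
from .nbs import GroupDesign, NetworkBasedStatistic, component_level_ttest
from .networks import edge_fraction_matrix, load_atlas, load_default_atlas, node_abnormal_degree
from .synthetic import CohortConfig, Cohort, generate_cohort, read_cohort, write_cohort
from .trial_fc import jackknife_trial_fc

__all__ = ["run_pipeline", "default_config", "compute_cohort_deltas",
           "downsample_atlas"]


def default_config() -> dict:
    """A small demonstration config that completes in well under a minute."""
    return {
        "seed": 1,
        "cohort": {"n_per_group": 40, "groups": ["HC", "AX"],
                   "n_regions": 60, "n_trials_per_cs": 16},
        "fc": {"method": "jackknife_zflip"},
        "nbs": {"threshold_p": 0.001, "n_perm": 500,
                "comparisons": [["HC", "AX"]], "direction": "greater"},
        "crossphase": {"n_perm": 500},
        "cca": {"n_perm": 500, "cv": 5, "n_perm_cv": 100},
    }


def downsample_atlas(atlas: pd.DataFrame, n_regions: int) -> pd.DataFrame:
    """Evenly subsample an atlas table to ``n_regions`` rows (keeping the
    network mix) and re-index region_id to 0..n-1."""
    if n_regions > len(atlas):
        raise ValueError("cannot upsample the atlas")
    rows = np.linspace(0, len(atlas) - 1, n_regions).round().astype(int)
    out = atlas.iloc[rows].reset_index(drop=True).copy()
    out["region_id"] = np.arange(n_regions)
    return out


def compute_cohort_deltas(cohort: Cohort, method: str = "jackknife_zflip"):
    """Jackknife FC + block averaging for every subject.

    Returns (delta_plus, delta_minus, differential, block_fcs, edge_index)
    where the delta arrays are subjects x edges in subject-table order.
    """
    d_plus, d_minus, d_diff, blocks = [], [], [], {}
    edge_index = None
    for sid in cohort.subjects["subject_id"]:
        tfc = jackknife_trial_fc(cohort.betas[sid], method=method)
        bfc = block_average(tfc)
        dp = delta_fc(bfc["CSplus"])
        dm = delta_fc(bfc["CSminus"])
        d_plus.append(dp.edge_vector)
        d_minus.append(dm.edge_vector)
        d_diff.append(differential_change(dp, dm).edge_vector)
        blocks[sid] = bfc
        edge_index = dp.edge_index
    return (np.array(d_plus), np.array(d_minus), np.array(d_diff), blocks,
            edge_index)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(config, output_dir=None) -> dict:
    """Execute the full analysis described by ``config``.

    ``config`` is a dict or a path to a YAML file (see
    :func:`default_config` for the schema).  Returns the run report; if
    ``output_dir`` is given, artifacts and ``report.json`` are written
    there.
    """
    input_hashes = {}
    if isinstance(config, (str, Path)):
        input_hashes["config"] = file_sha256(config)
        config = yaml.safe_load(Path(config).read_text())
    cfg = {**default_config(), **config}
    seed = int(cfg.get("seed", 0))
    report: dict = {"stages": {}, "provenance": {
        "seed": seed, "config": _jsonable(cfg), "input_hashes": input_hashes,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S")}}
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if "input_dir" in cfg.get("cohort", {}):
            cohort = read_cohort(cfg["cohort"]["input_dir"])
        else:
            cc = {k: v for k, v in cfg["cohort"].items()}
            cc.setdefault("seed", seed)
            if "groups" in cc:
                cc["groups"] = tuple(cc["groups"])
            cohort = generate_cohort(CohortConfig(**cc))
        report["stages"]["simulate"] = {
            "n_subjects": len(cohort.subjects),
            "groups": {g: int((cohort.subjects["group"] == g).sum())
                       for g in pd.unique(cohort.subjects["group"])},
        }
        if out is not None:
            write_cohort(cohort, out / "cohort")

        stage = "fc+delta"
        method = cfg["fc"]["method"]
        d_plus, d_minus, d_diff, blocks, edge_index = \
            compute_cohort_deltas(cohort, method=method)
        report["stages"]["fc"] = {"method": method,
                                  "n_edges": int(d_plus.shape[1])}
        design = GroupDesign.from_frame(cohort.subjects)
        if out is not None:
            pd.DataFrame(d_plus, index=cohort.subjects["subject_id"]).to_csv(
                out / "delta_csplus.csv")

        stage = "atlas"
        atlas = load_atlas(cfg["atlas"]) if cfg.get("atlas") else \
            load_default_atlas()
        n_regions = cohort.betas[next(iter(cohort.betas))].n_regions \
            if cohort.betas else len(atlas)
        if len(atlas) != n_regions:
            atlas = downsample_atlas(atlas, n_regions)

        stage = "nbs"
        nbs_cfg = cfg["nbs"]
        nbs_out = {}
        main_component = None
        main_pair = None
        for pair in nbs_cfg["comparisons"]:
            pair = tuple(pair)
            sub_design = design.subset(pair)
            sub_rows = np.isin(design.group, pair)
            est = NetworkBasedStatistic(
                threshold_p=nbs_cfg["threshold_p"],
                n_perm=nbs_cfg["n_perm"],
                direction=nbs_cfg.get("direction", "greater"),
                random_state=seed + 1000)
            est.fit(d_plus[sub_rows], sub_design, pair)
            res = est.result_()
            nbs_out["_vs_".join(pair)] = {
                "components": [{"size": c["size"], "p_fwe": c["p_fwe"]}
                               for c in res.components],
                "n_significant": len(res.significant),
                "exact": res.exact,
                "n_perm": res.n_perm,
            }
            if res.significant and main_component is None:
                main_component = res.significant[0]
                main_pair = pair
                if out is not None:
                    pd.DataFrame(main_component["edges"],
                                 columns=["i", "j"]).assign(
                        t=main_component["t"]).to_csv(
                        out / f"component_{'_'.join(pair)}.csv", index=False)
        report["stages"]["nbs"] = nbs_out

        if main_component is None:
            report["stages"]["note"] = ("no significant NBS component; "
                                        "downstream stages skipped")
        else:
            edges = main_component["edges"]
            stage = "network_maps"
            npm = edge_fraction_matrix(edges, atlas)
            deg = node_abnormal_degree(edges, atlas,
                                       weights=main_component["t"])
            report["stages"]["network_maps"] = {
                "edge_fraction": npm.to_frame().round(4).to_dict(),
                "top_degree_regions": deg.sort_values(ascending=False)
                    .head(10).to_dict(),
            }

            stage = "component_dynamics"
            series_plus = np.array([
                component_mean_series(blocks[sid]["CSplus"], edges)
                for sid in cohort.subjects["subject_id"]])
            edge_pos = {e: k for k, e in enumerate(edge_index)}
            cols = [edge_pos[tuple(e)] for e in edges]
            diff_mean = d_diff[:, cols].mean(axis=1)
            sub_rows = np.isin(design.group, main_pair)
            t, df, p = component_level_ttest(
                diff_mean[sub_rows], design.subset(main_pair), main_pair)
            report["stages"]["component_dynamics"] = {
                "group_mean_block_series": {
                    g: series_plus[design.group == g].mean(axis=0).tolist()
                    for g in main_pair},
                "differential_change_ttest": {"t": t, "df": df, "p": p},
            }

            stage = "crossphase"
            predictor = d_plus[:, cols].mean(axis=1)
            recall_mat = cohort.recall.drop(columns="subject_id") \
                .to_numpy(dtype=float)
            cp_out = {}
            group_r = {}
            best_region = None
            for g in main_pair:
                rows = design.group == g
                est = CrossPhaseRegression(
                    n_perm=cfg["crossphase"]["n_perm"],
                    random_state=seed + 2000)
                est.fit(predictor[rows], recall_mat[rows],
                        age=design.age[rows], sex=design.sex[rows])
                sig = np.flatnonzero(est.p_fwe_ < 0.05)
                cp_out[g] = {"significant_regions": sig.tolist(),
                             "max_partial_r": float(est.partial_r_.max())}
                if best_region is None:
                    best_region = int(np.argmax(np.abs(est.t_)))
                group_r[g] = (float(est.partial_r_[best_region]),
                              int(rows.sum()))
            if len(main_pair) == 2:
                (r1, n1), (r2, n2) = (group_r[g] for g in main_pair)
                comp = compare_correlations(r1, n1, r2, n2)
                cp_out["correlation_comparison"] = {
                    "region": best_region, "delta_r": comp.delta_r,
                    "z": comp.z_stat, "p": comp.p}
            report["stages"]["crossphase"] = cp_out

            stage = "cca"
            clin_cols = [c for c in cohort.clinical.columns
                         if c != "subject_id"
                         and cohort.clinical.loc[sub_rows, c].notna().all()]
            if clin_cols:
                cca_est = PermutationCCA(
                    n_perm=cfg["cca"]["n_perm"], cv=cfg["cca"]["cv"],
                    n_perm_cv=cfg["cca"]["n_perm_cv"],
                    random_state=seed + 3000)
                X = d_plus[sub_rows][:, cols]
                Y = cohort.clinical.loc[sub_rows, clin_cols] \
                    .to_numpy(dtype=float)
                cca_est.fit(X, Y)
                res = cca_est.result_()
                sub_edge_index = [tuple(e) for e in edges]
                y_load, x_load = canonical_loadings(
                    res, X, sub_edge_index, atlas,
                    cohort.clinical.loc[sub_rows, clin_cols])
                report["stages"]["cca"] = {
                    "measures": clin_cols,
                    "canonical_r": res.canonical_r,
                    "perm_p": res.perm_p,
                    "cv_r": res.cv_r,
                    "cv_perm_p": res.cv_perm_p,
                    "reduction_rank": res.reduction_rank,
                    "clinical_loadings": y_load.round(4).to_dict(),
                    "network_loadings": x_load.round(4).to_dict(),
                }
    except Exception as err:
        report["failed_stage"] = stage
        report["error"] = str(err)
        if out is not None:
            (out / "report.json").write_text(
                json.dumps(_jsonable(report), indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    report["provenance"]["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if out is not None:
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=1))
    return report
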