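"""End-to-end orchestration: cohort -> networks -> metrics -> statistics.

`analyze_cohort` is the in-memory workhorse; `run_pipeline` wraps it with
file input/output and a JSON manifest; `run_simulation_study` repeats the
generate-analyze cycle to measure recovery of planted effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .connectivity import (
    correlation_matrix,
    group_common_network,
    threshold_by_cost,
    total_connectivity_percent,
)
from .metrics import (
    EfficiencyCurve,
    default_cost_grid,
    efficiency_curves,
    shortest_path_lengths,
    small_world_cost_range,
    smooth_and_peak,
)
from .preprocess import (
    SubjectTimeSeries,
    mean_rt,
    normalize_run,
    segment_and_concatenate,
    subcortical_activity_index,
)
from .roi import load_roi_table, subcortical_names
from .simulate import CohortDataset, SimConfig, generate_cohort
from .stats import (
    edge_key,
    edge_z_table,
    edge_activity_correlation,
    edge_rt_correlation,
    edgewise_group_ttest,
    pathlength_group_comparison,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineParams",
    "PipelineResult",
    "analyze_cohort",
    "run_pipeline",
    "run_simulation_study",
    "load_cohort",
]


@dataclass
class PipelineParams:
    """Analysis settings; defaults mirror the study design the pipeline targets."""

    cost: float = 0.28
    cost_grid: np.ndarray | None = None
    trim_seconds: float = 10.0
    condition: str = "SI"
    n_null: int = 20
    swaps_per_edge: int = 10
    alpha: float = 0.05
    equal_var: bool = True
    dlpfc_nodes: tuple = ("DLPFC1", "DLPFC2", "DLPFC3")
    vlpfc_nodes: tuple = ("VLPFC1", "VLPFC2", "VLPFC3")
    # None: cortical nodes of significant group-diff edges plus the
    # a-priori prefrontal candidates above
    rt_nodes: tuple | None = None
    pathlength_sources: tuple = ("M1-1", "M1-2")
    compute_curves: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cost <= 1:
            raise ValueError("cost must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.cost_grid is None:
            self.cost_grid = default_cost_grid()


@dataclass
class PipelineResult:
    """All tables the pipeline produces, keyed by group label where relevant."""

    groups: tuple[str, str]
    corr_by_subject: dict
    network_by_subject: dict
    activity: pd.DataFrame  # subjects x subcortical ROIs
    rt: pd.DataFrame  # subjects x conditions (ms)
    group_networks: dict
    total_connectivity: dict
    min_retained_r: pd.Series
    group_diff: pd.DataFrame
    activity_corr: dict
    rt_corr: dict
    pathlength: pd.DataFrame
    curves: dict
    small_world: dict
    ce_peak: dict
    params: PipelineParams


def analyze_cohort(cohort: CohortDataset, params: PipelineParams) -> PipelineResult:
    """Run the full network analysis on an in-memory cohort."""
    if cohort.config is not None:
        g1, g2 = cohort.config.group_labels
    else:
        g1, g2 = list(dict.fromkeys(cohort.groups))[:2]
    roi_table = cohort.roi_table
    sub_rois = subcortical_names(roi_table)

    corr_by_subject = {}
    net_by_subject = {}
    dist_by_subject = {}
    activity_rows = {}
    rt_rows = {}
    for subject in cohort.subjects:
        ts = cohort.timeseries[subject]
        normed = SubjectTimeSeries(
            runs=[normalize_run(r) for r in ts.runs],
            roi_names=ts.roi_names,
            tr_seconds=ts.tr_seconds,
            schedule=ts.schedule,
        )
        cond = segment_and_concatenate(
            normed, params.condition, params.trim_seconds
        )
        corr = correlation_matrix(cond)
        corr_by_subject[subject] = corr
        net = threshold_by_cost(corr, params.cost)
        net_by_subject[subject] = net
        dist_by_subject[subject] = shortest_path_lengths(net)
        activity_rows[subject] = subcortical_activity_index(cond, roi_table)
        events = cohort.events[cohort.events["subject"] == subject]
        rt_rows[subject] = {
            c: mean_rt(events, c) for c in ("SI", "ET", "CTL")
        }
    activity = pd.DataFrame.from_dict(activity_rows, orient="index")
    rt = pd.DataFrame.from_dict(rt_rows, orient="index")

    subjects_by_group = {
        g: cohort.group_subjects(g) for g in (g1, g2)
    }
    group_networks = {
        g: group_common_network([net_by_subject[s] for s in subjects_by_group[g]])
        for g in (g1, g2)
    }
    total_conn = {
        g: total_connectivity_percent(group_networks[g]) for g in (g1, g2)
    }
    min_r = pd.Series(
        {s: net_by_subject[s].min_retained_r for s in cohort.subjects},
        name="min_retained_r",
    )

    # edge-wise group comparison over the union of the two group networks
    union_edges = sorted(
        group_networks[g1].edges | group_networks[g2].edges
    )
    z_tables = {
        g: edge_z_table(
            {s: corr_by_subject[s] for s in subjects_by_group[g]}, union_edges
        )
        for g in (g1, g2)
    }
    group_diff = edgewise_group_ttest(
        z_tables[g1],
        z_tables[g2],
        alpha=params.alpha,
        equal_var=params.equal_var,
        group_labels=(g1, g2),
    )

    # edges weakened in group 2: correlate strength with subcortical activity
    weakened = group_diff[
        group_diff["significant"] & (group_diff["direction"] == f"{g1}>{g2}")
    ]
    weak_pairs = list(zip(weakened["node_a"], weakened["node_b"]))
    activity_corr = {}
    if weak_pairs:
        for g in (g1, g2):
            z_weak = edge_z_table(
                {s: corr_by_subject[s] for s in subjects_by_group[g]}, weak_pairs
            )
            activity_corr[g] = edge_activity_correlation(
                z_weak, activity.loc[subjects_by_group[g]], alpha=params.alpha
            )
        # surrogate task-contrast t-values as the group-2 subcortical variable
        if cohort.surrogate_t is not None:
            t_frame = pd.DataFrame(
                {
                    roi: cohort.surrogate_t.loc[subjects_by_group[g2]]
                    for roi in sub_rois
                }
            )
            z_weak2 = edge_z_table(
                {s: corr_by_subject[s] for s in subjects_by_group[g2]}, weak_pairs
            )
            tbl = edge_activity_correlation(z_weak2, t_frame, alpha=params.alpha)
            tbl["analysis"] = "activity-corr-surrogate-t"
            activity_corr[f"{g2}_surrogate_t"] = tbl

    # RT analysis: cortico-subcortical pairs
    if params.rt_nodes is not None:
        rt_nodes = list(params.rt_nodes)
    else:
        sig = group_diff[group_diff["significant"]]
        cortical = set(sig["node_a"]) | set(sig["node_b"])
        cortical |= set(params.dlpfc_nodes) | set(params.vlpfc_nodes)
        cortical &= set(roi_table["name"])
        rt_nodes = sorted(cortical - set(sub_rois))
    rt_pairs = [(c, s) for c in rt_nodes for s in sub_rois]
    rt_corr = {}
    if rt_pairs:
        for g in (g1, g2):
            z_rt = edge_z_table(
                {s: corr_by_subject[s] for s in subjects_by_group[g]}, rt_pairs
            )
            rt_corr[g] = edge_rt_correlation(
                z_rt,
                rt.loc[subjects_by_group[g], "SI"],
                dlpfc_nodes=params.dlpfc_nodes,
                alpha=params.alpha,
            )

    pathlength = pathlength_group_comparison(
        [dist_by_subject[s] for s in subjects_by_group[g1]],
        [dist_by_subject[s] for s in subjects_by_group[g2]],
        source_nodes=params.pathlength_sources,
        alpha=params.alpha,
        group_labels=(g1, g2),
    )

    curves: dict = {}
    small_world: dict = {}
    ce_peak: dict = {}
    if params.compute_curves:
        rng = np.random.default_rng(params.seed)
        for g in (g1, g2):
            tables = []
            for s in subjects_by_group[g]:
                curve = efficiency_curves(
                    corr_by_subject[s],
                    cost_grid=params.cost_grid,
                    n_null=params.n_null,
                    seed=int(rng.integers(2**31)),
                    swaps_per_edge=params.swaps_per_edge,
                )
                tables.append(curve.table)
            mean_table = (
                pd.concat(tables).groupby("cost", as_index=False).mean()
            )
            group_curve = EfficiencyCurve(
                table=mean_table, n_null=params.n_null, seed=params.seed
            )
            curves[g] = group_curve
            small_world[g] = small_world_cost_range(group_curve)
            ce_peak[g] = smooth_and_peak(
                mean_table["cost"], mean_table["ce"]
            )

    return PipelineResult(
        groups=(g1, g2),
        corr_by_subject=corr_by_subject,
        network_by_subject=net_by_subject,
        activity=activity,
        rt=rt,
        group_networks=group_networks,
        total_connectivity=total_conn,
        min_retained_r=min_r,
        group_diff=group_diff,
        activity_corr=activity_corr,
        rt_corr=rt_corr,
        pathlength=pathlength,
        curves=curves,
        small_world=small_world,
        ce_peak=ce_peak,
        params=params,
    )


def load_cohort(cohort_dir, roi_table: pd.DataFrame | None = None) -> CohortDataset:
    """Read back a cohort written by :func:`costnet.simulate.write_cohort`."""
    d = Path(cohort_dir)
    if not d.exists():
        raise FileNotFoundError(f"cohort directory not found: {d}")
    if roi_table is None:
        roi_table = load_roi_table()
    participants = pd.read_csv(d / "participants.tsv", sep="\t")
    schedule_tbl = pd.read_csv(d / "schedule.tsv", sep="\t")
    schedule = schedule_tbl["condition"].to_numpy()
    events = pd.read_csv(d / "events.tsv", sep="\t")
    subjects = participants["subject"].tolist()
    groups = pd.Series(
        participants["group"].to_numpy(), index=subjects, name="group"
    )
    surrogate_t = pd.Series(
        participants["surrogate_t"].to_numpy(), index=subjects, name="surrogate_t"
    )
    tr_seconds = 3.5
    meta_path = d / "cohort_meta.json"
    if meta_path.exists():
        import json

        tr_seconds = float(json.loads(meta_path.read_text())["tr_seconds"])
    timeseries = {}
    for subject in subjects:
        run_files = sorted(d.glob(f"sub-{subject}_run-*.tsv"))
        if not run_files:
            raise FileNotFoundError(f"no run files for subject {subject} in {d}")
        runs = [
            pd.read_csv(f, sep="\t").to_numpy(dtype=float) for f in run_files
        ]
        timeseries[subject] = SubjectTimeSeries(
            runs=runs,
            roi_names=pd.read_csv(run_files[0], sep="\t", nrows=0).columns.tolist(),
            tr_seconds=tr_seconds,
            schedule=[schedule.copy() for _ in runs],
        )
    # no simulation provenance on disk: group labels come from file order
    return CohortDataset(
        subjects=subjects,
        groups=groups,
        timeseries=timeseries,
        events=events,
        surrogate_t=surrogate_t,
        roi_table=roi_table,
        config=None,
    )


def run_pipeline(
    cohort: CohortDataset | None = None,
    cohort_dir=None,
    params: PipelineParams | None = None,
    out_dir="costnet_run",
) -> PipelineResult:
    """Run the analysis and write all tables plus a JSON manifest.

    Provide either an in-memory ``cohort`` or a ``cohort_dir`` of TSV files.
    """
    if params is None:
        params = PipelineParams()
    if cohort is None:
        if cohort_dir is None:
            raise ValueError("provide a cohort or a cohort_dir")
        cohort = load_cohort(cohort_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    result = analyze_cohort(cohort, params)
    g1, g2 = result.groups

    for subject, corr in result.corr_by_subject.items():
        cio.write_correlation_matrix(corr, out / f"corr_{subject}.tsv")
        cio.write_network_edgelist(
            result.network_by_subject[subject], corr, out / f"net_{subject}.tsv"
        )
    for g in (g1, g2):
        cio.write_group_edgelist(
            result.group_networks[g], out / f"group_network_{g}.tsv"
        )
        cio.write_graphml(
            result.group_networks[g], out / f"group_network_{g}.graphml"
        )
    result.group_diff.to_csv(out / "group_diff.tsv", sep="\t", index=False)
    for name, tbl in result.activity_corr.items():
        tbl.to_csv(out / f"activity_corr_{name}.tsv", sep="\t", index=False)
    for name, tbl in result.rt_corr.items():
        tbl.to_csv(out / f"rt_corr_{name}.tsv", sep="\t", index=False)
    result.pathlength.to_csv(out / "pathlength.tsv", sep="\t", index=False)
    result.activity.to_csv(out / "activity_index.tsv", sep="\t")
    result.rt.to_csv(out / "mean_rt_ms.tsv", sep="\t")
    for g, curve in result.curves.items():
        curve.table.to_csv(out / f"efficiency_curve_{g}.tsv", sep="\t", index=False)

    manifest = {
        "params": {
            "cost": params.cost,
            "trim_seconds": params.trim_seconds,
            "condition": params.condition,
            "n_null": params.n_null,
            "swaps_per_edge": params.swaps_per_edge,
            "alpha": params.alpha,
            "equal_var": params.equal_var,
            "dlpfc_nodes": list(params.dlpfc_nodes),
            "pathlength_sources": list(params.pathlength_sources),
            "seed": params.seed,
            "cost_grid": [float(c) for c in params.cost_grid],
        },
        "groups": {
            g: {
                "n_subjects": len(cohort.group_subjects(g)),
                "total_connectivity_percent": result.total_connectivity[g],
                "mean_min_retained_r": float(
                    result.min_retained_r[cohort.group_subjects(g)].mean()
                ),
                "small_world_range": (
                    [result.small_world[g].cost_min, result.small_world[g].cost_max]
                    if result.small_world.get(g)
                    else None
                ),
                "ce_peak_cost": result.ce_peak.get(g),
            }
            for g in (g1, g2)
        },
        "seed_policy": "numpy SeedSequence spawned from params.seed",
    }
    cio.write_json(manifest, out / "manifest.json")
    return result


def run_simulation_study(
    sim_config: SimConfig,
    params: PipelineParams | None = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate generate-analyze cycles and score recovery of planted effects.

    Per replicate: whether every attenuated edge is detected (significant
    with a group1 > group2 direction), whether the activity-coupling sign
    pattern (striatal positive, thalamic negative) is recovered, and whether
    the RT-coupling signs (DLPFC negative, VLPFC positive) are recovered.
    Curves are skipped for speed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if params is None:
        params = PipelineParams(compute_curves=False)
    else:
        params = replace(params, compute_curves=False)
    rows = []
    master = np.random.SeedSequence(seed)
    rep_seeds = master.generate_state(n_replicates) % (2**31)
    for rep in range(n_replicates):
        cfg = replace(sim_config, seed=int(rep_seeds[rep]))
        cohort, truth = generate_cohort(cfg)
        result = analyze_cohort(cohort, params)
        rows.append(
            score_replicate(result, truth, cfg)
            | {"replicate": rep, "seed": int(rep_seeds[rep])}
        )
    return pd.DataFrame(rows)


def score_replicate(result: PipelineResult, truth, cfg: SimConfig) -> dict:
    """Score one replicate's recovery of the three planted sign patterns."""
    g1, g2 = cfg.group_labels
    diff = result.group_diff.set_index(
        result.group_diff.apply(
            lambda r: edge_key(r["node_a"], r["node_b"]), axis=1
        )
    )
    att_keys = [edge_key(a, b) for a, b in truth.attenuated_edges]
    present = [k for k in att_keys if k in diff.index]
    detected = [
        k
        for k in present
        if diff.loc[k, "significant"] and diff.loc[k, "direction"] == f"{g1}>{g2}"
    ]
    attenuation_ok = len(detected) == len(att_keys)

    activity_ok = False
    tbl = result.activity_corr.get(g1)
    if tbl is not None and len(tbl):
        # judge the sign pattern on the planted edges, where truth is defined;
        # chance-significant edges carry no planted activity coupling
        keys = tbl.apply(lambda r: edge_key(r["node_a"], r["node_b"]), axis=1)
        tbl = tbl[keys.isin(att_keys)]
        sig = tbl[tbl["significant"]]
        striatal = sig[~sig["subcortical_roi"].str.startswith("Thal")]
        thalamic = sig[sig["subcortical_roi"].str.startswith("Thal")]
        activity_ok = (
            len(striatal) > 0
            and len(thalamic) > 0
            and (striatal["r"] > 0).all()
            and (thalamic["r"] < 0).all()
        )

    rt_ok = False
    rtm = cfg.rt_model
    tbl = result.rt_corr.get(g1)
    if tbl is not None and rtm.dlpfc_edge and rtm.vlpfc_edge:
        idx = tbl.set_index(
            tbl.apply(lambda r: edge_key(r["node_a"], r["node_b"]), axis=1)
        )
        dk = edge_key(*rtm.dlpfc_edge)
        vk = edge_key(*rtm.vlpfc_edge)
        if dk in idx.index and vk in idx.index:
            rt_ok = bool(
                (idx.loc[dk, "r"] < 0) and (idx.loc[vk, "r"] > 0)
            )

    return {
        "n_attenuated_detected": len(detected),
        "n_attenuated_planted": len(att_keys),
        "attenuation_recovered": attenuation_ok,
        "activity_signs_recovered": activity_ok,
        "rt_signs_recovered": rt_ok,
        "all_recovered": attenuation_ok and activity_ok and rt_ok,
    }
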