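"""Synthetic task-fMRI cohort generator with planted statistical structure.

The generator emulates the study design the pipeline targets: two groups
(14 healthy volunteers "HV", 12 patients "PD"), four runs of 146 frames at
TR 3.5 s, and 62 ROIs whose covariance is modular (dorsal motor, prefrontal,
ventral visual, and subcortical communities).

Signal model. Each ROI series is a unit-variance Gaussian factor model

    x_i(t) = sqrt(b) f_c(i)(t) + sum_e sqrt(k_se) h_e(t) + sigma_i eps_i(t)

where f_c is the latent factor of ROI i's community (b = base within-
community coupling), h_e the factor of each designated edge e incident on i
with per-subject coupling k_se, and sigma_i^2 = 1 - b - sum k_se. The
population correlation of a pair is therefore exactly b.[same community] +
k_se — a closed form the tests exploit.

Planted effects:

* attenuated edges — in group 2 the designated edges' couplings are
  multiplied by a factor in [0, 1], planting an HV > PD difference;
* subcortical activity — a shared per-subject coupling factor shifts the
  mean BOLD of subcortical ROIs during the SI condition, positively for
  striatal ROIs and negatively for thalamic ones, so edge strength
  correlates with striatal activity and anti-correlates with thalamic;
* response times — a subject's mean inter-press interval follows a linear
  model with a negative slope on the DLPFC-striatum edge coupling and a
  positive slope on the VLPFC-striatum coupling.

Everything is deterministic for a fixed master seed; per-subject generators
are spawned from it so cohorts are reproducible subject by subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SubjectTimeSeries
from .roi import default_module_assignment, load_roi_table, subcortical_names

__all__ = [
    "RTModel",
    "SimConfig",
    "GroundTruth",
    "CohortDataset",
    "VolumeFixture",
    "build_schedule",
    "generate_cohort",
    "generate_volume_fixture",
    "planted_truth_report",
    "write_cohort",
]

DEFAULT_ATTENUATED_EDGES = (
    ("PreSMA1", "SMA3"),
    ("PreSMA2", "M1-1"),
    ("SMA1", "IPL5"),
    ("Put2", "Thal2"),
    ("VLPFC3", "Put1"),
)

# Coupling clip range keeps every implied node variance valid.
_COUPLING_LO, _COUPLING_HI = 0.02, 0.70


@dataclass(frozen=True)
class RTModel:
    """Linear model tying response time to cortico-striatal couplings.

    RT(ms) = intercept + dlpfc_slope * (k_dlpfc - k0) + vlpfc_slope *
    (k_vlpfc - k0) + noise, with k0 the population mean coupling. The DLPFC
    slope is negative (stronger coupling, faster responses), the VLPFC slope
    positive. Either edge may be None to drop that term (e.g. for reduced
    test cohorts on custom ROI tables).
    """

    intercept_ms: float = 800.0
    dlpfc_edge: tuple[str, str] | None = ("DLPFC1", "Caudate1")
    dlpfc_slope_ms: float = -1200.0
    vlpfc_edge: tuple[str, str] | None = ("VLPFC2", "VS2")
    vlpfc_slope_ms: float = 1200.0
    noise_sd_ms: float = 40.0

    def edges(self) -> list[tuple[str, str]]:
        return [e for e in (self.dlpfc_edge, self.vlpfc_edge) if e is not None]


@dataclass
class SimConfig:
    """Cohort geometry, coupling structure, and planted effect sizes."""

    n_subjects_group1: int = 14
    n_subjects_group2: int = 12
    n_runs: int = 4
    frames_per_run: int = 146
    tr_seconds: float = 3.5
    roi_table: pd.DataFrame | None = None
    module_assignment: dict[str, str] | None = None
    base_coupling: float = 0.25
    edge_coupling: float = 0.45
    attenuated_edges: tuple = DEFAULT_ATTENUATED_EDGES
    attenuation_multiplier: float = 0.5
    subject_coupling_sd: float = 0.10
    edge_noise_sd: float = 0.02
    rt_edge_coupling: float = 0.30
    rt_edge_coupling_sd: float = 0.20
    rt_model: RTModel = field(default_factory=RTModel)
    activity_coupling_gain: float = 3.0
    activity_noise_sd: float = 0.05
    surrogate_t_baseline: float = 4.0
    surrogate_t_scale: float = 3.0
    surrogate_t_noise_sd: float = 0.3
    block_len_frames: int = 24
    rest_frames: int = 2
    presses_per_condition: int = 20
    press_interval_sd_ms: float = 30.0
    bold_baseline: float = 1000.0
    bold_scale: float = 50.0
    group_labels: tuple[str, str] = ("HV", "PD")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_table is None:
            self.roi_table = load_roi_table()
        if self.module_assignment is None:
            self.module_assignment = default_module_assignment(self.roi_table)
        for name, count in (
            ("n_subjects_group1", self.n_subjects_group1),
            ("n_subjects_group2", self.n_subjects_group2),
            ("n_runs", self.n_runs),
            ("frames_per_run", self.frames_per_run),
        ):
            if count < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 <= self.attenuation_multiplier <= 1:
            raise ValueError("attenuation_multiplier must lie in [0, 1]")
        names = set(self.roi_table["name"])
        for a, b in self.planted_edges():
            if a not in names or b not in names:
                raise ValueError(f"planted edge ({a}, {b}) names unknown ROI")
        self._validate_variance_budget()

    def planted_edges(self) -> list[tuple[str, str]]:
        """All designated edges: attenuated first, then the RT edges."""
        return list(self.attenuated_edges) + self.rt_model.edges()

    def _validate_variance_budget(self) -> None:
        """Reject configs whose implied covariance cannot be positive
        semi-definite (node variance budget exceeded)."""
        load: dict[str, float] = {
            n: self.base_coupling for n in self.roi_table["name"]
        }
        for a, b in self.planted_edges():
            for node in (a, b):
                load[node] += _COUPLING_HI
        bad = [n for n, v in load.items() if v > 1.0]
        if bad:
            raise ValueError(
                "coupling budget exceeds unit variance for node(s) "
                f"{bad}: reduce base_coupling or edge couplings, or move "
                "planted edges off these nodes"
            )


def build_schedule(
    frames_per_run: int, block_len_frames: int = 24, rest_frames: int = 2
) -> np.ndarray:
    """Frame-wise condition labels for one run.

    ``rest_frames`` of rest, then SI/ET/CTL blocks of ``block_len_frames``
    cycling until the run is full (the last block may be truncated). The
    defaults tile 146 frames as rest + 2 x (SI, ET, CTL) x 24.
    """
    labels = ["rest"] * rest_frames
    cycle = ("SI", "ET", "CTL")
    i = 0
    while len(labels) < frames_per_run:
        cond = cycle[i % 3]
        take = min(block_len_frames, frames_per_run - len(labels))
        labels.extend([cond] * take)
        i += 1
    return np.array(labels[:frames_per_run])


@dataclass
class GroundTruth:
    """Planted parameters for recovery tests.

    ``couplings`` is subjects x planted-edge keys (``"A|B"``);
    ``subject_factor`` the shared latent coupling per subject;
    ``activity_signs`` maps each subcortical ROI to the sign of its planted
    activity-coupling; ``rt_true_ms`` the noiseless model RT per subject.
    """

    couplings: pd.DataFrame
    subject_factor: pd.Series
    attenuated_edges: list[tuple[str, str]]
    attenuation_multiplier: float
    activity_signs: dict[str, int]
    rt_model: RTModel
    rt_true_ms: pd.Series
    expected_correlations: pd.DataFrame


@dataclass
class CohortDataset:
    """A generated cohort: time series, events, surrogate contrasts."""

    subjects: list[str]
    groups: pd.Series
    timeseries: dict[str, SubjectTimeSeries]
    events: pd.DataFrame
    surrogate_t: pd.Series
    roi_table: pd.DataFrame
    config: SimConfig | None

    def group_subjects(self, label: str) -> list[str]:
        return [s for s in self.subjects if self.groups[s] == label]


def _edge_key(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


def _striatal_sign(roi_name: str) -> int:
    """+1 for striatal ROIs (caudate/putamen/VS), -1 for thalamic."""
    return -1 if roi_name.startswith("Thal") else 1


def generate_cohort(config: SimConfig) -> tuple[CohortDataset, GroundTruth]:
    """Simulate a full cohort; deterministic for a fixed ``config.seed``."""
    roi = config.roi_table
    names = roi["name"].tolist()
    n_roi = len(names)
    communities = sorted(set(config.module_assignment.values()))
    comm_index = {c: i for i, c in enumerate(communities)}
    planted = config.planted_edges()
    edge_keys = [_edge_key(a, b) for a, b in planted]
    n_factors = len(communities) + len(planted)

    g1, g2 = config.group_labels
    subjects = [f"{g1}{i+1:02d}" for i in range(config.n_subjects_group1)] + [
        f"{g2}{i+1:02d}" for i in range(config.n_subjects_group2)
    ]
    groups = pd.Series(
        [g1] * config.n_subjects_group1 + [g2] * config.n_subjects_group2,
        index=subjects,
        name="group",
    )

    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(len(subjects))

    schedule = build_schedule(
        config.frames_per_run, config.block_len_frames, config.rest_frames
    )
    si_mask = schedule == "SI"
    sub_names = subcortical_names(roi)
    sub_cols = [names.index(n) for n in sub_names]

    rtm = config.rt_model
    dlpfc_key = _edge_key(*rtm.dlpfc_edge) if rtm.dlpfc_edge else None
    vlpfc_key = _edge_key(*rtm.vlpfc_edge) if rtm.vlpfc_edge else None
    rt_keys = [k for k in (dlpfc_key, vlpfc_key) if k is not None]

    couplings = pd.DataFrame(index=subjects, columns=edge_keys, dtype=float)
    subject_factor = pd.Series(index=subjects, dtype=float, name="subject_factor")
    rt_true = pd.Series(index=subjects, dtype=float, name="rt_true_ms")
    surrogate_t = pd.Series(index=subjects, dtype=float, name="surrogate_t")
    timeseries: dict[str, SubjectTimeSeries] = {}
    event_rows: list[dict] = []

    for subject, seed_seq in zip(subjects, subject_seeds):
        rng = np.random.default_rng(seed_seq)
        is_group2 = groups[subject] == g2
        mult = config.attenuation_multiplier if is_group2 else 1.0

        kappa_s = rng.normal(0.0, config.subject_coupling_sd)
        subject_factor[subject] = kappa_s
        edge_coupling: dict[str, float] = {}
        for a, b in config.attenuated_edges:
            k = config.edge_coupling * mult + kappa_s + rng.normal(
                0.0, config.edge_noise_sd
            )
            edge_coupling[_edge_key(a, b)] = float(
                np.clip(k, _COUPLING_LO, _COUPLING_HI)
            )
        for key in rt_keys:
            k = config.rt_edge_coupling + rng.normal(
                0.0, config.rt_edge_coupling_sd
            )
            edge_coupling[key] = float(np.clip(k, _COUPLING_LO, _COUPLING_HI))
        couplings.loc[subject] = [edge_coupling[k] for k in edge_keys]

        # loading matrix: community factors then one factor per planted edge
        loadings = np.zeros((n_roi, n_factors))
        for i, name in enumerate(names):
            loadings[i, comm_index[config.module_assignment[name]]] = np.sqrt(
                config.base_coupling
            )
        for e, (a, b) in enumerate(planted):
            k = edge_coupling[edge_keys[e]]
            for node in (a, b):
                loadings[names.index(node), len(communities) + e] = np.sqrt(k)
        noise_var = 1.0 - (loadings**2).sum(axis=1)
        if (noise_var < -1e-9).any():
            bad = [names[i] for i in np.flatnonzero(noise_var < -1e-9)]
            raise ValueError(
                f"subject {subject}: implied covariance not positive "
                f"semi-definite at node(s) {bad}"
            )
        noise_sd = np.sqrt(np.clip(noise_var, 0.0, None))

        # subject-level subcortical activity shifts during SI
        activity_delta = {}
        for roi_name in sub_names:
            delta = _striatal_sign(roi_name) * (
                config.activity_coupling_gain * kappa_s
            ) + rng.normal(0.0, config.activity_noise_sd)
            activity_delta[roi_name] = delta

        runs = []
        for _ in range(config.n_runs):
            factors = rng.normal(size=(config.frames_per_run, n_factors))
            eps = rng.normal(size=(config.frames_per_run, n_roi)) * noise_sd
            x = factors @ loadings.T + eps
            for roi_name, col in zip(sub_names, sub_cols):
                x[si_mask, col] += activity_delta[roi_name]
            runs.append(config.bold_baseline + config.bold_scale * x)
        timeseries[subject] = SubjectTimeSeries(
            runs=runs,
            roi_names=list(names),
            tr_seconds=config.tr_seconds,
            schedule=[schedule.copy() for _ in range(config.n_runs)],
        )

        # behavioral model
        rt_si = rtm.intercept_ms
        if dlpfc_key is not None:
            rt_si += rtm.dlpfc_slope_ms * (
                edge_coupling[dlpfc_key] - config.rt_edge_coupling
            )
        if vlpfc_key is not None:
            rt_si += rtm.vlpfc_slope_ms * (
                edge_coupling[vlpfc_key] - config.rt_edge_coupling
            )
        rt_true[subject] = rt_si
        rt_obs = rt_si + rng.normal(0.0, rtm.noise_sd_ms)
        cond_offsets = {"SI": 0.0, "ET": 255.0, "CTL": 36.0}
        event_rows.extend(
            _simulate_events(
                rng, subject, schedule, config, rt_obs, cond_offsets
            )
        )

        surrogate_t[subject] = (
            config.surrogate_t_baseline
            + config.surrogate_t_scale * kappa_s
            + rng.normal(0.0, config.surrogate_t_noise_sd)
        )

    events = pd.DataFrame(
        event_rows, columns=["subject", "run", "condition", "block", "time_ms"]
    )
    cohort = CohortDataset(
        subjects=subjects,
        groups=groups,
        timeseries=timeseries,
        events=events,
        surrogate_t=surrogate_t,
        roi_table=roi,
        config=config,
    )

    expected = _expected_correlations(config)
    truth = GroundTruth(
        couplings=couplings,
        subject_factor=subject_factor,
        attenuated_edges=[tuple(e) for e in config.attenuated_edges],
        attenuation_multiplier=config.attenuation_multiplier,
        activity_signs={n: _striatal_sign(n) for n in sub_names},
        rt_model=rtm,
        rt_true_ms=rt_true,
        expected_correlations=expected,
    )
    return cohort, truth


def _simulate_events(rng, subject, schedule, config, rt_si_ms, cond_offsets):
    """Button-press onset times: i.i.d. inter-press intervals per block."""
    rows = []
    tr_ms = config.tr_seconds * 1000.0
    for run in range(config.n_runs):
        for cond in ("SI", "ET", "CTL"):
            blocks = _blocks_of(schedule, cond)
            if not blocks:
                continue
            per_block = max(2, config.presses_per_condition // len(blocks))
            mean_rt = rt_si_ms + cond_offsets[cond]
            for b, (start, stop) in enumerate(blocks):
                intervals = np.clip(
                    rng.normal(mean_rt, config.press_interval_sd_ms, per_block - 1),
                    50.0,
                    None,
                )
                times = start * tr_ms + np.concatenate(([0.0], np.cumsum(intervals)))
                rows.extend(
                    {
                        "subject": subject,
                        "run": run,
                        "condition": cond,
                        "block": b,
                        "time_ms": float(t),
                    }
                    for t in times
                )
    return rows


def _blocks_of(schedule: np.ndarray, condition: str) -> list[tuple[int, int]]:
    mask = schedule == condition
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, stops)]


def _expected_correlations(config: SimConfig) -> pd.DataFrame:
    """Closed-form population correlation of each planted edge per group.

    corr = base_coupling.[same community] + mean edge coupling.
    """
    rows = []
    assign = config.module_assignment
    rtm = config.rt_model
    for a, b in config.planted_edges():
        same = assign[a] == assign[b]
        base = config.base_coupling if same else 0.0
        attenuated = (a, b) in config.attenuated_edges or (
            b,
            a,
        ) in config.attenuated_edges
        if attenuated:
            k1, k2 = (
                config.edge_coupling,
                config.edge_coupling * config.attenuation_multiplier,
            )
        else:
            k1 = k2 = config.rt_edge_coupling
        rows.append(
            {
                "node_a": min(a, b),
                "node_b": max(a, b),
                "attenuated": attenuated,
                "r_group1": base + k1,
                "r_group2": base + k2,
            }
        )
    return pd.DataFrame(rows)


def planted_truth_report(truth: GroundTruth) -> pd.DataFrame:
    """Machine-readable summary of planted effects, one row per edge."""
    rtm = truth.rt_model
    att = {_edge_key(a, b) for a, b in truth.attenuated_edges}
    table = truth.expected_correlations.copy()
    keys = [
        _edge_key(a, b) for a, b in zip(table["node_a"], table["node_b"])
    ]
    table["edge"] = keys
    table["group2_multiplier"] = [
        truth.attenuation_multiplier if k in att else 1.0 for k in keys
    ]
    table["effect_z_diff"] = np.arctanh(table["r_group1"]) - np.arctanh(
        table["r_group2"]
    )
    rt_slopes = {}
    if rtm.dlpfc_edge is not None:
        rt_slopes[_edge_key(*rtm.dlpfc_edge)] = rtm.dlpfc_slope_ms
    if rtm.vlpfc_edge is not None:
        rt_slopes[_edge_key(*rtm.vlpfc_edge)] = rtm.vlpfc_slope_ms
    table["rt_slope_ms"] = [rt_slopes.get(k, 0.0) for k in keys]
    return table[
        [
            "edge",
            "node_a",
            "node_b",
            "attenuated",
            "group2_multiplier",
            "r_group1",
            "r_group2",
            "effect_z_diff",
            "rt_slope_ms",
        ]
    ]


@dataclass
class VolumeFixture:
    """A small 4-D NIfTI-style volume with known per-ROI cube signals."""

    data: np.ndarray  # (x, y, z, t)
    affine: np.ndarray
    peak_table: pd.DataFrame
    signals: np.ndarray  # (t, n_roi)

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)


def generate_volume_fixture(
    roi_table: pd.DataFrame,
    frames: int,
    seed: int = 0,
    voxel_size_mm: float = 3.0,
    noise_sd: float = 0.0,
    signals: np.ndarray | None = None,
) -> VolumeFixture:
    """Build a 4-D volume whose 27-voxel cubes carry known per-ROI signals.

    The affine is ``voxel_size_mm`` isotropic with a translation placing all
    peaks inside the grid with a 1-voxel margin. Cubes that would collide
    (sharing any voxel) or leave the volume raise with the offending ROI
    pairs/names.
    """
    rng = np.random.default_rng(seed)
    names = roi_table["name"].tolist()
    mm = roi_table[["x", "y", "z"]].to_numpy(dtype=float)
    origin = mm.min(axis=0) - 2 * voxel_size_mm
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = origin
    vox = np.rint((mm - origin) / voxel_size_mm).astype(int)

    collisions = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if (np.abs(vox[i] - vox[j]) <= 2).all()
    ]
    if collisions:
        raise ValueError(f"overlapping ROI cubes in fixture grid: {collisions}")

    shape = tuple(vox.max(axis=0) + 3)
    if (vox - 1 < 0).any():
        bad = [names[i] for i in np.flatnonzero((vox - 1 < 0).any(axis=1))]
        raise ValueError(f"ROI cube(s) would leave the volume: {bad}")

    if signals is None:
        signals = rng.normal(size=(frames, len(names)))
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (frames, len(names)):
        raise ValueError("signals must have shape (frames, n_roi)")

    data = rng.normal(0.0, noise_sd, size=shape + (frames,)) if noise_sd else (
        np.zeros(shape + (frames,))
    )
    for k in range(len(names)):
        x, y, z = vox[k]
        data[x - 1 : x + 2, y - 1 : y + 2, z - 1 : z + 2, :] += signals[:, k]

    peak_table = roi_table.copy().reset_index(drop=True)
    peak_mm = vox * voxel_size_mm + origin
    peak_table[["x", "y", "z"]] = peak_mm
    return VolumeFixture(
        data=data, affine=affine, peak_table=peak_table, signals=signals
    )


def write_cohort(cohort: CohortDataset, truth: GroundTruth, out_dir) -> Path:
    """Write a cohort as TSV time series, an events TSV, and a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for subject, ts in cohort.timeseries.items():
        for r, run in enumerate(ts.runs):
            pd.DataFrame(run, columns=ts.roi_names).to_csv(
                out / f"sub-{subject}_run-{r}.tsv", sep="\t", index=False
            )
    cohort.events.to_csv(out / "events.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "subject": cohort.subjects,
            "group": cohort.groups.loc[cohort.subjects].to_numpy(),
            "surrogate_t": cohort.surrogate_t.loc[cohort.subjects].to_numpy(),
        }
    ).to_csv(out / "participants.tsv", sep="\t", index=False)
    schedule = cohort.timeseries[cohort.subjects[0]].schedule[0]
    (out / "schedule.tsv").write_text(
        "frame\tcondition\n"
        + "".join(f"{i}\t{c}\n" for i, c in enumerate(schedule))
    )
    (out / "cohort_meta.json").write_text(
        json.dumps(
            {
                "tr_seconds": cohort.timeseries[cohort.subjects[0]].tr_seconds,
                "group_labels": list(dict.fromkeys(cohort.groups)),
            }
        )
    )
    truth_payload = {
        "couplings": {
            s: truth.couplings.loc[s].to_dict() for s in truth.couplings.index
        },
        "subject_factor": truth.subject_factor.to_dict(),
        "attenuated_edges": [list(e) for e in truth.attenuated_edges],
        "attenuation_multiplier": truth.attenuation_multiplier,
        "activity_signs": truth.activity_signs,
        "rt_true_ms": truth.rt_true_ms.to_dict(),
        "rt_model": {
            "intercept_ms": truth.rt_model.intercept_ms,
            "dlpfc_edge": list(truth.rt_model.dlpfc_edge)
            if truth.rt_model.dlpfc_edge
            else None,
            "dlpfc_slope_ms": truth.rt_model.dlpfc_slope_ms,
            "vlpfc_edge": list(truth.rt_model.vlpfc_edge)
            if truth.rt_model.vlpfc_edge
            else None,
            "vlpfc_slope_ms": truth.rt_model.vlpfc_slope_ms,
            "noise_sd_ms": truth.rt_model.noise_sd_ms,
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_payload, indent=1))
    return out
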