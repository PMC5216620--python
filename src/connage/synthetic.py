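"""Synthetic cohort generator.

Produces subject tables, node time series with prescribed age/group-dependent
correlation structure, and motion traces, so the full pipeline can be
exercised with known ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import InvalidConfigError
from .types import OLDER, YOUNGER, BoldTimeSeries, MotionTrace, SubjectRecord

# Sensorimotor node set; any extra labels are treated as null nodes.
SM_NODES = (
    "M1.L", "M1.R", "S1.L", "S1.R", "SMA",
    "Ins.L", "Ins.R", "RolOp.L", "RolOp.R", "SPL.L", "SPL.R",
)
INSULA_NODES = ("Ins.L", "Ins.R")
PRIMARY_NODES = ("M1.L", "M1.R", "S1.L", "S1.R")
PARIETAL_NODES = ("SPL.L", "SPL.R")

DEFAULT_NODE_LABELS = list(SM_NODES) + [f"Null.{i}" for i in range(1, 6)]

# Motion exclusion thresholds the generator plays against (mm / degrees).
EXCLUDE_TRANS_MM = 1.0
EXCLUDE_ROT_DEG = 1.0

_EIG_FLOOR = 1e-6


@dataclass
class SimulationConfig:
    n_older: int = 52
    n_younger: int = 51
    age_range_older: tuple[float, float] = (51.0, 76.0)
    age_range_younger: tuple[float, float] = (18.0, 26.0)
    n_timepoints: int = 250
    tr: float = 2.0
    node_labels: list[str] = field(default_factory=lambda: list(DEFAULT_NODE_LABELS))
    base_within_network_r: float = 0.3
    insula_decline_slope: float = -0.012  # delta r per year within older group
    parietal_increase_delta: float = 0.08  # delta r added for the older group
    noise_sd: float = 1.0
    high_motion_fraction: float = 0.1
    rng_seed: int = 0
    # free parameters beyond the core contract
    ar1_coef: float = 0.0
    confound_amp: float = 0.0  # common sinusoid added to every node
    confound_freq_hz: float = 0.02
    motion_step_sd: float = 0.02  # mm / deg per volume
    education_mean_older: float = 9.0
    education_mean_younger: float = 13.0
    education_sd: float = 2.0
    gmv_mean_older: float = 550.0
    gmv_mean_younger: float = 640.0
    gmv_sd: float = 35.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_older < 3 or self.n_younger < 3:
            raise InvalidConfigError("group sizes must be >= 3")
        for lo, hi in (self.age_range_older, self.age_range_younger):
            if lo > hi:
                raise InvalidConfigError("age range must satisfy min <= max")
        if self.n_timepoints < 8:
            raise InvalidConfigError("n_timepoints must be >= 8")
        if not self.tr > 0:
            raise InvalidConfigError("tr must be positive")
        if not 0 <= self.base_within_network_r < 1:
            raise InvalidConfigError("base_within_network_r must be in [0, 1)")
        if not 0 <= self.high_motion_fraction <= 1:
            raise InvalidConfigError("high_motion_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if not -1 < self.ar1_coef < 1:
            raise InvalidConfigError("ar1_coef must be in (-1, 1)")
        labels = self.node_labels
        if len(set(labels)) != len(labels):
            raise InvalidConfigError("node labels must be unique")
        missing = [n for n in SM_NODES if n not in labels]
        if missing:
            raise InvalidConfigError(f"missing sensorimotor nodes: {missing}")
        n_null = len(labels) - len(SM_NODES)
        if n_null < 5:
            raise InvalidConfigError("need at least 5 null nodes")


@dataclass
class GroundTruth:
    """Generator-side record of targets and perturbed edges."""

    node_labels: list[str]
    target_matrices: dict[str, np.ndarray]
    age_coupled_edges: list[tuple[str, str]]
    group_shifted_edges: list[tuple[str, str]]

    def to_jsonable(self) -> dict:
        return {
            "node_labels": self.node_labels,
            "age_coupled_edges": [list(e) for e in self.age_coupled_edges],
            "group_shifted_edges": [list(e) for e in self.group_shifted_edges],
            "target_matrices": {
                sid: m.tolist() for sid, m in self.target_matrices.items()
            },
        }


def nearest_correlation(mat: np.ndarray, eig_floor: float = _EIG_FLOOR) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result rescaled back to a
    unit diagonal; raises if the repair fails to produce a valid matrix.
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eig_floor:
        out = sym.copy()
    else:
        out = (vecs * np.clip(vals, eig_floor, None)) @ vecs.T
    d = np.sqrt(np.diag(out))
    if not np.all(d > 0):
        raise InvalidConfigError("correlation repair failed: non-positive diagonal")
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    off = out[~np.eye(out.shape[0], dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        raise InvalidConfigError("correlation repair failed: |r| >= 1 off-diagonal")
    return out


def _edge_pairs(nodes_a, nodes_b):
    return [(a, b) for a in nodes_a for b in nodes_b]


def build_target_correlation(
    subject: SubjectRecord, config: SimulationConfig
) -> np.ndarray:
    """Target N x N correlation for one subject.

    Within-network edges sit at the base level; for older subjects the
    insula<->M1/S1 edges decline linearly with age above the group minimum and
    the M1/S1<->SPL edges are shifted by a constant; null-node edges are zero.
    """
    labels = config.node_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    mat = np.eye(n)
    base = config.base_within_network_r
    for i, a in enumerate(SM_NODES):
        for b in SM_NODES[i + 1:]:
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = base
    if subject.group == OLDER:
        age_min = config.age_range_older[0]
        insula_r = base + config.insula_decline_slope * (subject.age - age_min)
        for a, b in _edge_pairs(INSULA_NODES, PRIMARY_NODES):
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = insula_r
        parietal_r = base + config.parietal_increase_delta
        for a, b in _edge_pairs(PRIMARY_NODES, PARIETAL_NODES):
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = parietal_r
    off = mat[~np.eye(n, dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        raise InvalidConfigError(
            "target correlations leave (-1, 1); adjust slope/delta/base"
        )
    return nearest_correlation(mat)


def simulate_motion(
    config: SimulationConfig,
    subject: SubjectRecord,
    rng: np.random.Generator | None = None,
) -> MotionTrace:
    """Random-walk motion trace; a high-motion subject exceeds the 1 mm bound.

    With ``motion_step_sd == 0`` the trace is identically zero (no motion).
    """
    if rng is None:
        seed = (config.rng_seed, zlib.crc32(subject.subject_id.encode()))
        rng = np.random.default_rng(seed)
    m = config.n_timepoints
    if config.motion_step_sd == 0:
        return MotionTrace(np.zeros((m, 6)))
    steps = rng.normal(0.0, config.motion_step_sd, size=(m, 6))
    steps[0] = 0.0
    trace = np.cumsum(steps, axis=0)
    is_high = rng.random() < config.high_motion_fraction
    # rescale each parameter triplet so ordinary subjects stay inside the
    # exclusion thresholds and high-motion subjects exceed the translation one
    for cols, thr in ((slice(0, 3), EXCLUDE_TRANS_MM), (slice(3, 6), EXCLUDE_ROT_DEG)):
        peak = np.abs(trace[:, cols]).max()
        if peak > 0:
            trace[:, cols] *= 0.8 * thr / peak
    if is_high:
        target = EXCLUDE_TRANS_MM * (1.1 + 0.8 * rng.random())
        peak = np.abs(trace[:, :3]).max()
        trace[:, :3] *= target / peak
    return MotionTrace(trace)


def _ar1_filter(white: np.ndarray, phi: float) -> np.ndarray:
    """Impose AR(1) serial correlation column-wise, preserving unit variance."""
    out = np.empty_like(white)
    out[0] = white[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, white.shape[0]):
        out[t] = phi * out[t - 1] + scale * white[t]
    return out


def simulate_subject_timeseries(
    subject: SubjectRecord,
    config: SimulationConfig,
    rng: np.random.Generator,
    target: np.ndarray | None = None,
) -> BoldTimeSeries:
    if target is None:
        target = build_target_correlation(subject, config)
    chol = np.linalg.cholesky(target)
    white = rng.standard_normal((config.n_timepoints, target.shape[0]))
    if config.ar1_coef != 0.0:
        white = _ar1_filter(white, config.ar1_coef)
    values = (white @ chol.T) * config.noise_sd
    if config.confound_amp > 0:
        t = np.arange(config.n_timepoints) * config.tr
        values = values + config.confound_amp * np.sin(
            2 * np.pi * config.confound_freq_hz * t
        )[:, None]
    return BoldTimeSeries(values, tr=config.tr, node_labels=list(config.node_labels))


def simulate_cohort(config: SimulationConfig):
    """Generate records, time series, motion traces and ground truth.

    Returns ``(records, series, motions, truth)`` where ``series`` and
    ``motions`` map subject_id to their matrices. Fully deterministic for a
    fixed config (including ``rng_seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    records: list[SubjectRecord] = []
    specs = [
        (OLDER, config.n_older, config.age_range_older,
         config.education_mean_older, config.gmv_mean_older),
        (YOUNGER, config.n_younger, config.age_range_younger,
         config.education_mean_younger, config.gmv_mean_younger),
    ]
    for group, n, (lo, hi), edu_mean, gmv_mean in specs:
        for k in range(n):
            age = float(rng.uniform(lo, hi))
            gender = "F" if rng.random() < 0.5 else "M"
            edu = float(max(0.0, rng.normal(edu_mean, config.education_sd)))
            gmv = float(max(1.0, rng.normal(gmv_mean, config.gmv_sd)))
            records.append(SubjectRecord(
                subject_id=f"{group}-{k + 1:03d}", group=group, age=age,
                gender=gender, education_years=edu, gmv=gmv,
            ))
    series: dict[str, BoldTimeSeries] = {}
    motions: dict[str, MotionTrace] = {}
    targets: dict[str, np.ndarray] = {}
    for rec in records:
        target = build_target_correlation(rec, config)
        targets[rec.subject_id] = target
        series[rec.subject_id] = simulate_subject_timeseries(
            rec, config, rng, target=target
        )
        motions[rec.subject_id] = simulate_motion(config, rec, rng=rng)
    truth = GroundTruth(
        node_labels=list(config.node_labels),
        target_matrices=targets,
        age_coupled_edges=_edge_pairs(INSULA_NODES, PRIMARY_NODES),
        group_shifted_edges=_edge_pairs(PRIMARY_NODES, PARIETAL_NODES),
    )
    return records, series, motions, truth


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort_dir(out_dir, records, series, motions, truth, config) -> None:
    """Write the cohort as TSV files plus a ground-truth JSON sidecar."""
    from . import io as cio

    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(parents=True, exist_ok=True)
    cio.write_cohort_table(out / "cohort.tsv", records)
    for sid, ts in series.items():
        cio.write_timeseries(out / "timeseries" / f"{sid}.tsv", ts)
    for sid, tr in motions.items():
        cio.write_motion(out / "motion" / f"{sid}.tsv", tr)
    sidecar = truth.to_jsonable()
    cfg = asdict(config)
    cfg["age_range_older"] = list(config.age_range_older)
    cfg["age_range_younger"] = list(config.age_range_younger)
    sidecar["config"] = cfg
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
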