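"""End-to-end orchestration: cohort files in, prediction report out.

Stages: structural networks -> functional networks -> edge-wise permutation
testing with reward filtering -> cross-modal coupling and feature assembly ->
PLSR BMI prediction under leave-one-subject-out CV.  The file-backed runner
(:func:`run_pipeline`) wraps the in-memory :func:`run_analysis` with TSV/CSV
I/O, per-stage checksums and a run manifest; re-running with the same config
and seed reproduces every stage checksum bit-for-bit.

The ``modality`` switch (combined / dti_only / fmri_only) restricts only the
PLSR design matrix; feature selection upstream is always multimodal.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cross_modal, functional, group_diff, io, plsr
from .errors import ConfigError
from .structural import Atlas, StructuralNetwork, build_structural_matrix

logger = logging.getLogger(__name__)

MODALITIES = ("combined", "dti_only", "fmri_only")

STATUS_OK = "ok"
STATUS_NO_EDGES = "no-significant-edges"
STATUS_NO_FEATURES = "no-retained-features"


@dataclass
class PipelineParams:
    min_fiber_len: float = 20.0
    max_fiber_len: float = 500.0
    bandpass_lo: float = 0.009
    bandpass_hi: float = 0.08
    n_perm: int = 5000
    alpha_edge: float = 0.05
    alpha_coupling: float = 0.05
    max_excluded: float = 0.20
    max_lv: int = 12
    lv_criterion: str = "first"
    modality: str = "combined"

    def validate(self) -> None:
        for name in ("alpha_edge", "alpha_coupling", "max_excluded"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.min_fiber_len < self.max_fiber_len:
            raise ConfigError("need 0 < min_fiber_len < max_fiber_len")
        if not 0 <= self.bandpass_lo < self.bandpass_hi:
            raise ConfigError("need 0 <= bandpass_lo < bandpass_hi")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        if self.max_lv < 1:
            raise ConfigError("max_lv must be >= 1")
        if self.modality not in MODALITIES:
            raise ConfigError(f"modality must be one of {MODALITIES}")
        if self.lv_criterion not in ("first", "min"):
            raise ConfigError("lv_criterion must be 'first' or 'min'")


@dataclass
class PipelineConfig:
    atlas: Path
    fibers: Path
    timeseries_dir: Path
    subjects: Path
    out_dir: Path
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    _PATH_KEYS = ("atlas", "fibers", "timeseries_dir", "subjects", "out_dir")

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - {"paths", "params", "seed"}
        if unknown:
            raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
        paths = raw.get("paths", {})
        unknown = set(paths) - set(cls._PATH_KEYS)
        if unknown:
            raise ConfigError(f"{path}: unknown path keys {sorted(unknown)}")
        missing = [k for k in cls._PATH_KEYS if k not in paths]
        if missing:
            raise ConfigError(f"{path}: missing path keys {missing}")
        params_raw = raw.get("params", {})
        valid_params = set(PipelineParams.__dataclass_fields__)
        unknown = set(params_raw) - valid_params
        if unknown:
            raise ConfigError(f"{path}: unknown param keys {sorted(unknown)}")
        base = Path(path).parent
        resolved = {k: (base / paths[k] if not Path(paths[k]).is_absolute() else Path(paths[k]))
                    for k in cls._PATH_KEYS}
        cfg = cls(**resolved, params=PipelineParams(**params_raw), seed=int(raw.get("seed", 0)))
        cfg.params.validate()
        return cfg


@dataclass
class AnalysisResult:
    status: str
    edge_results: list
    significant: list
    couplings: list
    features: cross_modal.FeatureSet | None
    feature_r2: pd.DataFrame | None
    reports: dict[str, plsr.PredictionReport]
    summaries: dict[str, dict]
    y: np.ndarray | None = None


def _modal_explained_variance(
    X: np.ndarray, y: np.ndarray, report: plsr.PredictionReport
) -> tuple[float, int]:
    """Training R^2 of a full-data fit at the modal fold-selected LV count."""
    ks = np.array(report.per_fold_n_lv)
    modal_k = int(np.bincount(ks).argmax())
    modal_k = max(1, min(modal_k, min(X.shape[0] - 1, X.shape[1])))
    model = plsr.fit_plsr(X, y, modal_k)
    return model.explained_variance_y, modal_k


def run_analysis(
    atlas: Atlas,
    networks: dict[str, StructuralNetwork],
    series: dict[str, functional.RoiTimeSeries],
    subjects: pd.DataFrame,
    params: PipelineParams | None = None,
    seed: int = 0,
    preprocess_series: bool = True,
) -> AnalysisResult:
    """Run stages 3-6 on in-memory inputs; see module docstring."""
    params = params or PipelineParams()
    params.validate()
    order = [str(s) for s in subjects["subject_id"]]
    labels = dict(zip(order, subjects["group"].astype(str)))
    y = subjects["bmi"].to_numpy(dtype=float)

    fnets = {}
    for sid in order:
        ts = series[sid]
        if preprocess_series:
            ts = functional.preprocess(ts, None, params.bandpass_lo, params.bandpass_hi)
        fnets[sid] = functional.correlation_matrix(ts)
    mean_fc = pd.DataFrame(
        {r: [fnets[sid].mean_fc[r] for sid in order] for r in range(atlas.n_regions)},
        index=order,
    )

    samples = group_diff.collect_edge_samples(networks, labels, params.max_excluded)
    results = group_diff.permutation_test(samples, params.n_perm, seed)
    significant = group_diff.filter_reward_edges(results, atlas, params.alpha_edge)
    if not significant:
        logger.warning("no significant reward-system edges; short-circuiting")
        return AnalysisResult(STATUS_NO_EDGES, results, [], [], None, None, {}, {}, y)

    densities = pd.DataFrame(
        {
            r.edge: [
                networks[sid].density[r.edge]
                if networks[sid].present[r.edge]
                else np.nan
                for sid in order
            ]
            for r in significant
        },
        index=order,
    )
    couplings = []
    for r in significant:
        u, v = r.edge
        rec = cross_modal.couple_edge(
            densities[r.edge].to_numpy(dtype=float),
            mean_fc[u].to_numpy(dtype=float),
            mean_fc[v].to_numpy(dtype=float),
            alpha=params.alpha_coupling,
            edge=r.edge,
        )
        couplings.append(rec)
    retained = [c for c in couplings if c.retained]
    if not retained:
        logger.warning("no coupled edges retained; short-circuiting")
        return AnalysisResult(STATUS_NO_FEATURES, results, significant, couplings, None, None, {}, {}, y)

    features = cross_modal.assemble_features(retained, densities, mean_fc, atlas)

    r2_rows = []
    for col in features.X.columns:
        r2, p = plsr.simple_feature_r2(features.X[col].to_numpy(), y)
        r2_rows.append({"feature": col, "r_squared": r2, "p_value": p})
    feature_r2 = pd.DataFrame(r2_rows)

    modality_cols = {
        "combined": list(features.X.columns),
        "dti_only": features.structural_columns,
        "fmri_only": features.functional_columns,
    }
    to_run = MODALITIES if params.modality == "combined" else (params.modality,)
    reports: dict[str, plsr.PredictionReport] = {}
    summaries: dict[str, dict] = {}
    for mod in to_run:
        cols = modality_cols[mod]
        if not cols:
            continue
        X = features.X[cols].to_numpy(dtype=float)
        report = plsr.loocv_predict(X, y, params.max_lv, criterion=params.lv_criterion)
        ev, modal_k = _modal_explained_variance(X, y, report)
        reports[mod] = report
        summaries[mod] = {
            "explained_variance": ev,
            "modal_n_lv": modal_k,
            "rms_error": report.rms_error,
            "percent_error": report.percent_error,
            "pearson_r": report.pearson_r,
            "n_features": len(cols),
        }
    return AnalysisResult(
        STATUS_OK, results, significant, couplings, features, feature_r2, reports, summaries, y
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """File-backed end-to-end run; returns (and writes) the run manifest."""
    config.params.validate()
    for key in ("atlas", "fibers", "timeseries_dir", "subjects"):
        if not Path(getattr(config, key)).exists():
            raise ConfigError(f"input path {key}={getattr(config, key)} does not exist")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            "paths": {k: str(getattr(config, k)) for k in config._PATH_KEYS},
            "params": asdict(config.params),
            "seed": config.seed,
        },
        "stages": {},
        "checksums": {},
        "status": STATUS_OK,
    }

    def finish_stage(name: str, t0: float, files: list[Path], rows: int) -> None:
        manifest["stages"][name] = {"wall_seconds": round(time.perf_counter() - t0, 3),
                                    "rows": rows}
        for f in files:
            manifest["checksums"][str(Path(f).relative_to(out))] = _sha256(f)

    # stage: load + structural networks
    t0 = time.perf_counter()
    atlas = io.read_atlas(config.atlas)
    subjects = io.read_subjects(config.subjects)
    fibers = io.read_fibers(config.fibers)
    order = [str(s) for s in subjects["subject_id"]]
    networks = {}
    sn_dir = out / "structural"
    sn_dir.mkdir(exist_ok=True)
    files: list[Path] = []
    for sid in order:
        fs = fibers.get(sid)
        if fs is None:
            raise ConfigError(f"subject {sid} has no fiber records")
        net = build_structural_matrix(fs, atlas, config.params.min_fiber_len,
                                      config.params.max_fiber_len)
        networks[sid] = net
        dpath, ppath = sn_dir / f"density_{sid}.csv", sn_dir / f"present_{sid}.csv"
        io.write_structural_network(net, dpath, ppath)
        files += [dpath, ppath]
    finish_stage("structural_network", t0, files, len(order))

    # stage: functional networks
    t0 = time.perf_counter()
    series = {}
    fn_dir = out / "functional"
    fn_dir.mkdir(exist_ok=True)
    files = []
    mean_fc_rows = {}
    for sid in order:
        ts = io.read_timeseries(Path(config.timeseries_dir) / f"{sid}.csv", sid)
        ts = functional.preprocess(ts, None, config.params.bandpass_lo, config.params.bandpass_hi)
        series[sid] = ts
        fnet = functional.correlation_matrix(ts)
        zpath = fn_dir / f"z_{sid}.csv"
        io.write_matrix(fnet.z, zpath)
        files.append(zpath)
        mean_fc_rows[sid] = fnet.mean_fc
    mfc = pd.DataFrame.from_dict(mean_fc_rows, orient="index",
                                 columns=[str(i) for i in range(atlas.n_regions)])
    mfc.index.name = "subject_id"
    mfc_path = fn_dir / "mean_fc.csv"
    mfc.to_csv(mfc_path, float_format=io.FLOAT_FMT)
    files.append(mfc_path)
    finish_stage("functional_network", t0, files, len(order))

    # stages: group difference, cross-modal, PLSR (in memory, preprocessing done)
    t0 = time.perf_counter()
    result = run_analysis(atlas, networks, series, subjects, config.params,
                          seed=config.seed, preprocess_series=False)
    edges_path = out / "edges.tsv"
    io.write_tsv(io.edge_results_frame(result.edge_results, atlas), edges_path)
    finish_stage("group_difference", t0, [edges_path], len(result.edge_results))

    t0 = time.perf_counter()
    files = []
    if result.couplings:
        coupling_path = out / "coupling.tsv"
        io.write_tsv(io.coupling_frame(result.couplings, atlas), coupling_path)
        files.append(coupling_path)
    if result.features is not None:
        feat_path = out / "features.csv"
        result.features.X.rename_axis("subject_id").to_csv(feat_path, float_format=io.FLOAT_FMT)
        files.append(feat_path)
    finish_stage("cross_modal", t0, files, len(result.couplings))

    t0 = time.perf_counter()
    files = []
    if result.feature_r2 is not None:
        r2_path = out / "feature_r2.tsv"
        io.write_tsv(result.feature_r2, r2_path)
        files.append(r2_path)
    summary = {"status": result.status, "n_subjects": len(order),
               "n_edges_tested": len(result.edge_results),
               "n_significant_edges": len(result.significant),
               "n_retained_edges": sum(1 for c in result.couplings if c.retained),
               "modalities": result.summaries}
    if result.features is not None:
        summary["n_structural_features"] = len(result.features.structural_columns)
        summary["n_functional_features"] = len(result.features.functional_columns)
    mod = config.params.modality
    if mod in result.reports:
        rep = result.reports[mod]
        pred_path = out / "predictions.csv"
        pd.DataFrame({
            "subject_id": order,
            "group": subjects["group"],
            "actual_bmi": rep.actual,
            "predicted_bmi": rep.predicted,
            "fold_n_lv": rep.per_fold_n_lv,
        }).to_csv(pred_path, index=False, float_format=io.FLOAT_FMT)
        files.append(pred_path)
    summary_path = out / "summary.json"
    io.write_json(summary, summary_path)
    files.append(summary_path)
    finish_stage("bmi_plsr", t0, files, len(order))

    manifest["status"] = result.status
    io.write_json(manifest, out / "manifest.json")
    return manifest
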