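"""Plain-text readers and writers for every pipeline artifact.

Formats are TSV/CSV with required headers and JSON summaries.  Write-then-read
round-trips are lossless (floats printed with 17 significant digits).
Validation failures raise :class:`ParseError` naming the offending line where
that is cheap to determine.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cross_modal import CouplingRecord
from .errors import ParseError
from .functional import RoiTimeSeries
from .group_diff import HW, NON_HW, EdgeTestResult
from .structural import Atlas, FiberSet, StructuralNetwork
from .synthetic import Cohort

FLOAT_FMT = "%.17g"  # lossless float round trip


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------- atlas

def write_atlas(atlas: Atlas, path: Path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_atlas(path: Path) -> Atlas:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["region_id", "name", "surface_area_mm2", "reward_flag"], path)
    bad = df.index[df["surface_area_mm2"] <= 0]
    if len(bad):
        raise ParseError(f"{path}: nonpositive surface area at line {bad[0] + 2}")
    return Atlas.from_frame(df)


# ---------------------------------------------------------------- fibers

def write_fibers(fiber_sets: dict[str, FiberSet], path: Path) -> None:
    frames = [fiber_sets[s].to_frame() for s in sorted(fiber_sets)]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["subject_id", "region_u", "region_v", "length_mm"])
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_fibers(path: Path) -> dict[str, FiberSet]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["subject_id", "region_u", "region_v", "length_mm"], path)
    bad = df.index[df["length_mm"] <= 0]
    if len(bad):
        raise ParseError(f"{path}: nonpositive fiber length at line {bad[0] + 2}")
    bad = df.index[df["region_u"] == df["region_v"]]
    if len(bad):
        raise ParseError(f"{path}: self-loop fiber at line {bad[0] + 2}")
    out: dict[str, FiberSet] = {}
    for sid, sub in df.groupby("subject_id", sort=True):
        out[str(sid)] = FiberSet(
            str(sid),
            sub["region_u"].to_numpy(),
            sub["region_v"].to_numpy(),
            sub["length_mm"].to_numpy(),
        )
    return out


# ---------------------------------------------------------------- subjects

def write_subjects(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_subjects(path: Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", "group", "bmi"], path)
    for i, row in df.iterrows():
        want = HW if row["bmi"] < 25.0 else NON_HW
        if row["group"] != want:
            raise ParseError(
                f"{path}: line {i + 2}: group {row['group']!r} inconsistent with "
                f"BMI {row['bmi']} (boundary 25 belongs to {NON_HW})"
            )
    if df["subject_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate subject ids")
    return df


# ---------------------------------------------------------------- time series

def write_timeseries(ts: RoiTimeSeries, path: Path) -> None:
    df = pd.DataFrame(ts.values, columns=[str(i) for i in range(ts.n_regions)])
    with open(path, "w") as fh:
        fh.write(f"# sampling_interval={ts.sampling_interval!r}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_timeseries(path: Path, subject_id: str | None = None) -> RoiTimeSeries:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# sampling_interval="):
            raise ParseError(f"{path}: line 1: missing sampling_interval header")
        try:
            dt = float(header.split("=", 1)[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line 1: bad sampling_interval") from exc
        df = pd.read_csv(fh)
    sid = subject_id if subject_id is not None else path.stem
    return RoiTimeSeries(sid, df.to_numpy(dtype=float), dt)


# ---------------------------------------------------------------- matrices

def write_matrix(matrix: np.ndarray, path: Path) -> None:
    pd.DataFrame(matrix).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_matrix(path: Path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)


def write_structural_network(net: StructuralNetwork, density_path: Path, present_path: Path) -> None:
    write_matrix(net.density, density_path)
    pd.DataFrame(net.present.astype(int)).to_csv(present_path, index=False)


def read_structural_network(subject_id: str, density_path: Path, present_path: Path) -> StructuralNetwork:
    density = read_matrix(density_path)
    present = pd.read_csv(present_path).to_numpy(dtype=int).astype(bool)
    return StructuralNetwork(subject_id, density, present)


# ---------------------------------------------------------------- results tables

def edge_results_frame(results: list[EdgeTestResult], atlas: Atlas) -> pd.DataFrame:
    names = atlas.names
    return pd.DataFrame(
        {
            "region_u": [r.edge[0] for r in results],
            "region_v": [r.edge[1] for r in results],
            "region_u_name": [names[r.edge[0]] for r in results],
            "region_v_name": [names[r.edge[1]] for r in results],
            "t_stat": [r.t_stat for r in results],
            "p_uncorrected": [r.p_uncorrected for r in results],
            "p_corrected": [r.p_corrected for r in results],
            "eligible": [int(r.eligible) for r in results],
            "reward_hit": [int(r.reward_hit) for r in results],
        }
    )


def coupling_frame(records: list[CouplingRecord], atlas: Atlas) -> pd.DataFrame:
    names = atlas.names
    return pd.DataFrame(
        {
            "region_u": [r.edge[0] for r in records],
            "region_v": [r.edge[1] for r in records],
            "region_u_name": [names[r.edge[0]] for r in records],
            "region_v_name": [names[r.edge[1]] for r in records],
            "r1": [r.r1 for r in records],
            "p1": [r.p1 for r in records],
            "r2": [r.r2 for r in records],
            "p2": [r.p2 for r in records],
            "retained": [int(r.retained) for r in records],
        }
    )


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_json(obj: dict, path: Path) -> None:
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    tmp.replace(path)


# ---------------------------------------------------------------- cohort round trip

def write_cohort(cohort: Cohort, out_dir: Path) -> None:
    """Write a synthetic cohort in the formats the pipeline consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.atlas, out_dir / "atlas.tsv")
    write_fibers({s.id: s.fiber_set for s in cohort.subjects}, out_dir / "fibers.tsv")
    write_subjects(cohort.subject_table, out_dir / "subjects.csv")
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for s in cohort.subjects:
        write_timeseries(s.roi_timeseries, ts_dir / f"{s.id}.csv")


def read_cohort(in_dir: Path) -> Cohort:
    from .synthetic import SubjectRecord  # local import to avoid cycle at module load

    in_dir = Path(in_dir)
    atlas = read_atlas(in_dir / "atlas.tsv")
    fibers = read_fibers(in_dir / "fibers.tsv")
    table = read_subjects(in_dir / "subjects.csv")
    subjects = []
    for row in table.itertuples(index=False):
        sid = str(row.subject_id)
        ts = read_timeseries(in_dir / "timeseries" / f"{sid}.csv", sid)
        fs = fibers.get(sid, FiberSet(sid))
        subjects.append(SubjectRecord(sid, str(row.group), float(row.bmi), fs, ts))
    return Cohort(atlas, subjects)
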