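"""Plain-text I/O: time-series TSV, phenotype/parcellation CSV, JSON sidecars.

All matrices are written with 17 significant digits so write-then-read is
exact for finite doubles.  Time-series files are TSV without a header
(regions x timepoints, row order = parcellation order); tables are CSV with
a header.  Parcellation files may be 0- or 1-based (explicit flag).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .parcellation import ParcellationInfo
from .simulate import GroundTruth, SimulatedStudy, SubjectRecord, subjects_to_frame

FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(path, mat: np.ndarray) -> None:
    np.savetxt(path, np.asarray(mat, dtype=float), fmt=FLOAT_FMT, delimiter="\t")


def read_matrix(path) -> np.ndarray:
    path = Path(path)
    try:
        mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        # find the offending line for a useful message
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            try:
                [float(x) for x in line.split("\t")]
            except ValueError:
                raise DataError(f"{path}: malformed row at line {lineno}") from None
        raise DataError(f"{path}: {exc}") from None
    return mat


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ["subject_id", "group", "age", "sex", "site",
                     "mean_fd", "max_fd", "panss_pos", "panss_neg", "panss_gen"]


def write_phenotype(path, subjects: list[SubjectRecord] | pd.DataFrame) -> None:
    df = subjects if isinstance(subjects, pd.DataFrame) else subjects_to_frame(subjects)
    df.to_csv(path, index=False, columns=PHENOTYPE_COLUMNS, float_format="%.17g")


def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise DataError(f"phenotype file lacks column(s) {sorted(missing)}")
    return df


def phenotype_to_subjects(df: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for _, row in df.iterrows():
        panss = {k: (None if pd.isna(row.get(k)) else float(row[k]))
                 for k in ("panss_pos", "panss_neg", "panss_gen")}
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            age=float(row["age"]), sex=str(row["sex"]), site=str(row["site"]),
            mean_fd=float(row["mean_fd"]), max_fd=float(row["max_fd"]), **panss))
    return records


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

def write_parcellation(path, parcellation: ParcellationInfo) -> None:
    parcellation.to_frame().to_csv(path, index=False)


def read_parcellation(path, one_based: bool = False) -> ParcellationInfo:
    """Read a parcellation CSV; ``one_based=True`` shifts ids down by 1."""
    df = pd.read_csv(path)
    required = {"region_id", "hemisphere", "partner_id", "network"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"parcellation file lacks column(s) {sorted(missing)}")
    shift = 1 if one_based else 0
    return ParcellationInfo(
        region_id=df["region_id"].to_numpy(dtype=int) - shift,
        hemisphere=df["hemisphere"].to_numpy(dtype=object),
        partner_id=df["partner_id"].to_numpy(dtype=int) - shift,
        network=df["network"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# study directories
# ---------------------------------------------------------------------------

def write_study(study: SimulatedStudy, out_dir) -> Path:
    """Write a simulated study in the on-disk layout the pipeline reads.

    ``<out>/timeseries/<subject>.tsv``, ``<out>/phenotype.csv``,
    ``<out>/parcellation.csv`` and ``<out>/ground_truth.json``.
    """
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    for sid, ts in study.timeseries.items():
        write_matrix(out / "timeseries" / f"{sid}.tsv", ts)
    write_phenotype(out / "phenotype.csv", study.subjects)
    write_parcellation(out / "parcellation.csv", study.parcellation)
    (out / "ground_truth.json").write_text(study.truth.to_json())
    return out


def read_study(in_dir) -> tuple[ParcellationInfo, pd.DataFrame, dict, GroundTruth | None]:
    in_dir = Path(in_dir)
    parc_path = in_dir / "parcellation.csv"
    if not parc_path.exists():
        raise DataError(f"missing parcellation file {parc_path}")
    parcellation = read_parcellation(parc_path)
    phenotype = read_phenotype(in_dir / "phenotype.csv")
    series = {}
    for sid in phenotype["subject_id"]:
        p = in_dir / "timeseries" / f"{sid}.tsv"
        if not p.exists():
            raise DataError(f"missing time series for subject {sid}: {p}")
        series[str(sid)] = read_matrix(p)
    truth = None
    truth_path = in_dir / "ground_truth.json"
    if truth_path.exists():
        truth = GroundTruth.from_json(truth_path.read_text())
    return parcellation, phenotype, series, truth


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
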