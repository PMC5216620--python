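"""Plain-text readers/writers (TSV) and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BoldTimeSeries, MotionTrace, SubjectRecord

COHORT_COLUMNS = ["subject_id", "group", "age", "gender", "education_years", "gmv"]


def write_cohort_table(path, records: list[SubjectRecord]) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "gender": r.gender,
                "education_years": r.education_years,
                "gmv": r.gmv,
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            group=str(row.group),
            age=float(row.age),
            gender=str(row.gender),
            education_years=float(row.education_years),
            gmv=float(row.gmv),
        )
        for row in df.itertuples(index=False)
    ]


def write_timeseries(path, ts: BoldTimeSeries) -> None:
    df = pd.DataFrame(ts.values, columns=ts.node_labels)
    with open(path, "w") as fh:
        fh.write(f"# tr={ts.tr}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_timeseries(path, tr: float | None = None) -> BoldTimeSeries:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# tr="):
            tr = float(first.strip().split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    if tr is None:
        raise ValueError(f"{path}: tr not recorded in file and not supplied")
    return BoldTimeSeries(df.to_numpy(dtype=float), tr=tr,
                          node_labels=[str(c) for c in df.columns])


def write_motion(path, trace: MotionTrace) -> None:
    np.savetxt(path, trace.values, delimiter="\t", fmt="%.10g")


def read_motion(path, units: str = "deg") -> MotionTrace:
    """Read a 6-column motion file; ``units`` converts rotation columns."""
    vals = np.loadtxt(path, ndmin=2)
    if units == "rad":
        vals = vals.copy()
        vals[:, 3:] = np.degrees(vals[:, 3:])
    elif units != "deg":
        raise ValueError("units must be 'deg' or 'rad'")
    return MotionTrace(vals)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, stage: str, params: dict, inputs: list, outputs: list,
                   seed=None) -> None:
    """Write a reproducibility manifest; content is time-independent."""
    from . import __version__

    base = Path(path).parent

    def rel(p):
        p = Path(p)
        try:
            return str(p.relative_to(base))
        except ValueError:
            return str(p)

    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "params": params,
        "inputs": {rel(p): sha256_file(p) for p in inputs if Path(p).is_file()},
        "outputs": {rel(p): sha256_file(p) for p in outputs
                    if Path(p).is_file()},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
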