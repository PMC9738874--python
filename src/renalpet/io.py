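"""File I/O: the TAC CSV dialect, cohort manifests, and NIfTI TAC extraction.

TAC CSV dialect (fixed so fixtures are byte-exact): comma-separated, UTF-8,
'.' decimal, header ``frame_start_s,frame_end_s,<region>[,<region>...]``,
one row per frame, concentrations in kBq/mL.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .frames import FramingSchedule, TimeActivityCurve

__all__ = [
    "write_tac_csv",
    "read_tac_csv",
    "write_cohort_manifest",
    "read_cohort_manifest",
    "extract_tac",
]


def write_tac_csv(path, tacs: Mapping[str, TimeActivityCurve]) -> None:
    """Write one subject's curves (sharing one schedule) to a TAC CSV."""
    if not tacs:
        raise InvalidParameterError("no curves to write")
    tacs = dict(tacs)
    first = next(iter(tacs.values()))
    for name, tac in tacs.items():
        if not tac.schedule.same_as(first.schedule):
            raise InvalidParameterError(f"curve {name!r} is on a different schedule")
    df = pd.DataFrame(
        {
            "frame_start_s": first.schedule.start,
            "frame_end_s": first.schedule.end,
            **{name: tac.values for name, tac in tacs.items()},
        }
    )
    df.to_csv(path, index=False)


def read_tac_csv(path) -> dict[str, TimeActivityCurve]:
    """Read a TAC CSV back into named curves on a shared schedule."""
    df = pd.read_csv(path)
    required = {"frame_start_s", "frame_end_s"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    schedule = FramingSchedule(
        start=df["frame_start_s"].to_numpy(float), end=df["frame_end_s"].to_numpy(float)
    )
    regions = [c for c in df.columns if c not in required]
    return {
        r: TimeActivityCurve(schedule, df[r].to_numpy(float), region=r) for r in regions
    }


def write_cohort_manifest(path, records) -> None:
    """Write the per-subject manifest CSV for a simulated cohort."""
    rows = []
    for rec in records:
        s = rec.spec
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "weight_g": s.weight_g,
                "dose_MBq": s.dose_mbq,
                "glycemia_mg_dL": s.glycemia_mg_dl,
                "seed": s.seed,
                "qc_tail_depot": bool(rec.qc_truth.get("tail_depot", False)),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def extract_tac(
    image4d, mask, schedule: FramingSchedule, labels=None
) -> dict[int, TimeActivityCurve]:
    """Per-label mean time-activity curves from a dynamic image and a VOI mask.

    ``image4d`` is a 4-D NIfTI image (or path) whose last axis is time;
    ``mask`` an integer-label 3-D NIfTI on the same grid.  Concentration
    units pass through from the image.  Empty labels are skipped.
    """
    img = nib.load(str(image4d)) if isinstance(image4d, (str, Path)) else image4d
    msk = nib.load(str(mask)) if isinstance(mask, (str, Path)) else mask
    data = np.asarray(img.dataobj, dtype=float)
    lab = np.asarray(msk.dataobj)
    lab = np.rint(lab).astype(int)
    if data.ndim != 4:
        raise InvalidParameterError("dynamic image must be 4-D")
    if lab.shape != data.shape[:3]:
        raise InvalidParameterError(
            f"mask grid {lab.shape} does not match image grid {data.shape[:3]}"
        )
    if data.shape[3] != schedule.n_frames:
        raise InvalidParameterError(
            f"image has {data.shape[3]} frames but the schedule has {schedule.n_frames}"
        )
    if labels is None:
        labels = [int(v) for v in np.unique(lab) if v != 0]
    out: dict[int, TimeActivityCurve] = {}
    for label in labels:
        sel = lab == label
        if not np.any(sel):
            continue  # empty label: skip (missing-region)
        out[int(label)] = TimeActivityCurve(
            schedule, data[sel, :].mean(axis=0), region=str(label)
        )
    return out
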