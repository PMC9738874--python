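"""End-to-end analysis pipeline and group summaries.

Order of operations mirrors how the acquisition is analysed: blood-curve QC
first (subjects with a tail-depot artifact are excluded from every PET
analysis and listed in an exclusions table), then static SUV, early-Patlak
slope markers, compartmental Ki fits and morphometry, finishing with
descriptive per-group summaries and age-control ratios.  Statistics stay
descriptive (n, mean, median, min, max) - with n of 8-10 per group, ratios
and distributions carry the information; no hypothesis tests are produced.

Outputs are tidy tables (pandas DataFrames, written as CSV):
``markers``, ``suv``, ``ki``, ``morphometry``, ``summary``, ``exclusions``,
plus a YAML echo of the configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import AGE_CONTROL_OF, SubjectRecord
from .errors import DegenerateInputError, InsufficientDataError, RenalPetError
from .frames import TimeActivityCurve
from .kinetics import fit_2tcm
from .morphometry import growth_rate
from .patlak import (
    detect_linear_segment,
    first_nonzero_frame,
    fit_slope,
    patlak_transform,
    prescribed_window,
    qc_blood_curve,
)
from .suv import STATIC_WINDOWS, blood_normalized, renal_output_marker, suv, window_mean

logger = logging.getLogger("renalpet.pipeline")

__all__ = ["PipelineConfig", "AnalysisSubject", "run_pipeline", "summarize_groups"]

MARKER_REGIONS: tuple[str, ...] = ("cortex", "medulla", "pelvis", "liver")
FIT_ORGANS: tuple[str, ...] = ("cortex", "medulla", "liver", "myocardium", "muscle")


@dataclass(frozen=True)
class PipelineConfig:
    """Fully-defaulted pipeline settings; an empty config runs the default path."""

    qc_flatness_ceiling: float = 0.10
    patlak_threshold_frac: float = 0.01
    first_nonzero_threshold_frac: float = 0.02
    #: anchor the region windows at the aorta arrival frame ("aorta") or at
    #: each region's own first supra-threshold frame ("region")
    window_anchor: str = "aorta"
    #: optional per-region (start_offset_s, end_offset_s) overrides
    window_overrides: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    #: detect linearity windows automatically instead of using the prescribed ones
    auto_windows: bool = False
    auto_min_points: int = 5
    auto_r2_min: float = 0.95
    fit_ki: bool = True
    fit_t_max: float | None = None
    fit_organs: tuple[str, ...] = FIT_ORGANS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_overrides"] = {k: list(v) for k, v in self.window_overrides.items()}
        d["fit_organs"] = list(self.fit_organs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = dict(d)
        if "window_overrides" in kwargs:
            kwargs["window_overrides"] = {
                k: tuple(v) for k, v in kwargs["window_overrides"].items()
            }
        if "fit_organs" in kwargs:
            kwargs["fit_organs"] = tuple(kwargs["fit_organs"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class AnalysisSubject:
    """The minimal per-subject input the pipeline needs (e.g. loaded from CSV)."""

    subject_id: str
    group: str
    weight_g: float
    dose_mbq: float
    glycemia_mg_dl: float
    tacs: Mapping[str, TimeActivityCurve]
    morphometry: object | None = None


def _as_analysis_subject(item) -> AnalysisSubject:
    if isinstance(item, AnalysisSubject):
        return item
    if isinstance(item, SubjectRecord):
        return AnalysisSubject(
            subject_id=item.spec.subject_id,
            group=item.spec.group,
            weight_g=item.spec.weight_g,
            dose_mbq=item.spec.dose_mbq,
            glycemia_mg_dl=item.spec.glycemia_mg_dl,
            tacs=item.tacs,
            morphometry=item.morphometry,
        )
    raise RenalPetError(f"cannot analyse object of type {type(item).__name__}")


def _marker_rows(subject: AnalysisSubject, aorta: TimeActivityCurve, cfg: PipelineConfig) -> list[dict]:
    t0_aorta = aorta.schedule.start[
        first_nonzero_frame(aorta, cfg.first_nonzero_threshold_frac)
    ]
    support_end = aorta.schedule.end[-1]
    rows = []
    for region in MARKER_REGIONS:
        if region not in subject.tacs:
            logger.warning("%s: region %r missing, skipped", subject.subject_id, region)
            continue
        tac = subject.tacs[region]
        points = patlak_transform(tac, aorta, cfg.patlak_threshold_frac)
        if cfg.window_anchor == "region":
            t0 = tac.schedule.start[first_nonzero_frame(tac, cfg.first_nonzero_threshold_frac)]
        else:
            t0 = t0_aorta
        if region in cfg.window_overrides:
            off0, off1 = cfg.window_overrides[region]
            window = prescribed_window(region, 0.0, support_end)  # validate region
            window = dataclasses.replace(window, t_start=t0 + off0, t_end=min(t0 + off1, support_end))
        else:
            window = prescribed_window(region, t0, support_end)
        if cfg.auto_windows:
            auto = detect_linear_segment(points, cfg.auto_min_points, cfg.auto_r2_min)
            if auto is not None:
                window = auto
        marker = fit_slope(points, window, region=region)
        rows.append(
            {
                "subject_id": subject.subject_id,
                "group": subject.group,
                "region": region,
                "marker": f"patlak_{region}",
                "window_start_s": marker.window.t_start,
                "window_end_s": marker.window.t_end,
                "slope_per_min": marker.slope_per_min,
                "intercept": marker.intercept,
                "r2": marker.r_squared,
            }
        )
    return rows


def _suv_rows(subject: AnalysisSubject, aorta: TimeActivityCurve) -> list[dict]:
    rows = []
    for w in STATIC_WINDOWS:
        blood = window_mean(aorta, w)
        for region, tac in subject.tacs.items():
            if region == "aorta":
                continue
            mean = window_mean(tac, w)
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "region": region,
                    "window_label": w.label,
                    "suv": suv(mean, subject.dose_mbq, subject.weight_g),
                    "suv_blood_norm": blood_normalized(mean, blood) if blood > 0 else np.nan,
                }
            )
        if "pelvis" in subject.tacs and "cortex" in subject.tacs:
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "region": "pelvis_over_cortex",
                    "window_label": w.label,
                    "suv": np.nan,
                    "suv_blood_norm": renal_output_marker(
                        subject.tacs["pelvis"], subject.tacs["cortex"], w
                    ),
                }
            )
    return rows


def _ki_rows(subject: AnalysisSubject, aorta: TimeActivityCurve, cfg: PipelineConfig) -> list[dict]:
    rows = []
    for organ in cfg.fit_organs:
        if organ not in subject.tacs:
            continue
        try:
            kp, diag = fit_2tcm(subject.tacs[organ], aorta, t_max=cfg.fit_t_max)
        except (DegenerateInputError, InsufficientDataError) as exc:
            logger.warning("%s/%s: Ki fit skipped (%s)", subject.subject_id, organ, exc)
            continue
        rows.append(
            {
                "subject_id": subject.subject_id,
                "group": subject.group,
                "region": organ,
                "K1": kp.K1,
                "k2": kp.k2,
                "k3": kp.k3,
                "Vb": kp.Vb,
                "Ki": kp.ki,
                "converged": diag.converged,
                "rss": diag.residual_sum_squares,
            }
        )
    return rows


def _morphometry_rows(subject: AnalysisSubject) -> list[dict]:
    m = subject.morphometry
    if m is None:
        return []
    return [
        {
            "subject_id": subject.subject_id,
            "group": subject.group,
            "age_weeks": m.age_weeks,
            "length_mm": m.kidney_axes.length,
            "width_mm": m.kidney_axes.width,
            "depth_mm": m.kidney_axes.depth,
            "volume_mm3": m.kidney_volume_mm3,
            "growth_rate_per_day": growth_rate(m.growth),
        }
    ]


def summarize_groups(
    per_subject: pd.DataFrame,
    age_control_map: Mapping[str, str] = AGE_CONTROL_OF,
    value_col: str = "value",
) -> pd.DataFrame:
    """Descriptive per group x marker statistics with age-control ratios.

    ``per_subject`` needs columns ``group``, ``marker`` and ``value_col``.
    The ratio divides the group mean by the mean of its age-control group
    (absent when the control group is missing from the table).
    """
    if per_subject.empty:
        raise DegenerateInputError("no per-subject values to summarize")
    rows = []
    grouped = per_subject.groupby(["group", "marker"])[value_col]
    means = grouped.mean()
    for (group, marker), vals in grouped:
        ratio = np.nan
        control = age_control_map.get(group)
        if control is not None and (control, marker) in means.index:
            control_mean = means.loc[(control, marker)]
            if control_mean > 0:
                ratio = float(means.loc[(group, marker)] / control_mean)
            else:
                logger.warning("non-positive control mean for %s/%s", group, marker)
        elif control is not None:
            logger.warning("age-control group %r missing; no ratio for %s/%s", control, group, marker)
        rows.append(
            {
                "group": group,
                "marker": marker,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "median": float(vals.median()),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "ratio_to_age_control": ratio,
            }
        )
    return pd.DataFrame(rows).sort_values(["marker", "group"]).reset_index(drop=True)


def run_pipeline(
    cohort: Sequence, config: PipelineConfig | None = None, output_dir=None
) -> dict[str, pd.DataFrame]:
    """QC -> static SUV -> Patlak markers -> Ki fits -> morphometry -> summary.

    ``cohort`` is a sequence of :class:`~renalpet.cohort.SubjectRecord` or
    :class:`AnalysisSubject`.  Subjects failing blood-curve QC are excluded
    from all PET analyses and reported in the ``exclusions`` table, so the
    summary n plus exclusions always add up to the cohort size.  The run is
    deterministic given inputs and config; tables (and a config echo) are
    written to ``output_dir`` when given.
    """
    cfg = config or PipelineConfig()
    subjects = [_as_analysis_subject(item) for item in cohort]
    if not subjects:
        raise DegenerateInputError("empty cohort")

    exclusions, markers, suvs, kis, morpho = [], [], [], [], []
    n_passed = 0
    for subject in subjects:
        if "aorta" not in subject.tacs:
            raise DegenerateInputError(f"{subject.subject_id}: no aorta curve")
        aorta = subject.tacs["aorta"]
        qc = qc_blood_curve(aorta, cfg.qc_flatness_ceiling, cfg.first_nonzero_threshold_frac)
        if not qc.passed:
            exclusions.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "reason": qc.reason,
                    "flatness_index": qc.flatness_index,
                }
            )
            morpho.extend(_morphometry_rows(subject))  # morphometry is PET-independent
            continue
        n_passed += 1
        markers.extend(_marker_rows(subject, aorta, cfg))
        suvs.extend(_suv_rows(subject, aorta))
        if cfg.fit_ki:
            kis.extend(_ki_rows(subject, aorta, cfg))
        morpho.extend(_morphometry_rows(subject))

    if n_passed == 0:
        raise DegenerateInputError(
            "no subject passed blood-curve QC; nothing to analyse "
            "(check injections for tail-depot artifacts)"
        )

    markers_df = pd.DataFrame(markers)
    suv_df = pd.DataFrame(suvs)

    summary_input = markers_df.rename(columns={"slope_per_min": "value"})[
        ["group", "marker", "value"]
    ]
    renal_out = suv_df[suv_df["region"] == "pelvis_over_cortex"].copy()
    if not renal_out.empty:
        renal_out["marker"] = "renal_output_" + renal_out["window_label"]
        renal_out = renal_out.rename(columns={"suv_blood_norm": "value"})[
            ["group", "marker", "value"]
        ]
        summary_input = pd.concat([summary_input, renal_out], ignore_index=True)
    summary_df = summarize_groups(summary_input)

    tables = {
        "markers": markers_df,
        "suv": suv_df,
        "ki": pd.DataFrame(kis),
        "morphometry": pd.DataFrame(morpho),
        "summary": summary_df,
        "exclusions": pd.DataFrame(
            exclusions, columns=["subject_id", "group", "reason", "flatness_index"]
        ),
    }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        cfg.to_yaml(out / "config_echo.yaml")
        logger.info("wrote %d tables to %s", len(tables), out)
    return tables
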