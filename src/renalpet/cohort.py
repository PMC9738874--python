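"""Synthetic study cohort generator.

Emulates the statistical structure of a preclinical cardiorenal-syndrome
imaging study: groups L1 (control), L2 (doxorubicin heart failure), L3
(cardiorenal), L4 (renocardiac) plus age-control groups L2Aco and L34Aco,
with 8/8/8/10 + 2 + 2 = 38 animals by default.  Every subject gets framed,
noisy time-activity curves for aorta, renal cortex, medulla, pelvis, liver,
myocardium and skeletal muscle on the 430-frame dynamic schedule, plus
morphometry (kidney axes, body-weight series).

Disease is encoded as multiplicative kinetic degradation relative to healthy
baselines: renal K1 falls progressively L2 -> L3 -> L4 (vascular-delivery
loss), the pelvic excretion rate falls in parallel (extraction loss, worst in
L4), and myocardial/muscle trapping k3 rises where chemotoxic metabolic
remodelling applies.  Baseline rate constants are literature-plausible
healthy-rat FDG values; no attempt is made to estimate any real cohort's
effect sizes - the factors encode directions and approximate fold-changes
only.  The medullary early vascular fraction Vb exceeds the cortical one so
the cortex/medulla transit-peak amplitude ratio sits near 0.5 in healthy
animals.

Noise is additive Gaussian with variance inversely proportional to frame
duration (framed reconstructed PET is approximately Gaussian); everything is
a pure function of the spec and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError
from .frames import FramingSchedule, TimeActivityCurve, dynamic_framing_schedule
from .input_function import InputFunctionParams, default_rat_bolus, eval_input_function
from .kinetics import KineticParams, _framed_from_nodes
from .morphometry import GrowthSeries, KidneyAxes, SigmoidGrowth, ellipsoid_volume, sigmoid_reference

__all__ = [
    "ORGANS",
    "GROUPS",
    "AGE_CONTROL_OF",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_NOISE_SCALE",
    "SubjectSpec",
    "Morphometry",
    "SubjectRecord",
    "default_group_params",
    "simulate_subject",
    "simulate_pelvis",
    "add_noise",
    "inject_tail_depot",
    "generate_cohort",
]

ORGANS: tuple[str, ...] = ("cortex", "medulla", "pelvis", "liver", "myocardium", "muscle")
GROUPS: tuple[str, ...] = ("L1", "L2", "L3", "L4", "L2Aco", "L34Aco")

#: which age-control group each disease group is compared against
AGE_CONTROL_OF: dict[str, str] = {"L2": "L2Aco", "L3": "L34Aco", "L4": "L34Aco"}

DEFAULT_GROUP_SIZES: dict[str, int] = {
    "L1": 8, "L2": 8, "L3": 8, "L4": 10, "L2Aco": 2, "L34Aco": 2,
}

DEFAULT_NOISE_SCALE = 0.05
DEFAULT_BETWEEN_SUBJECT_CV = 0.15

#: healthy-rat FDG baselines (rates per minute).  The larger medullary
#: vascular-window amplitude is carried jointly by a larger vascular fraction
#: Vb and a larger delivery K1 (a pure-Vb encoding would leave the medullary
#: early slope, ~(1-Vb)*K1, with no group-separable signal); medullary k3 is
#: kept low so medullary Ki stays below cortical Ki.
BASELINE_ORGAN_PARAMS: dict[str, KineticParams] = {
    "cortex": KineticParams(K1=0.8, k2=1.4, k3=0.06, Vb=0.10),
    "medulla": KineticParams(K1=0.9, k2=1.2, k3=0.02, Vb=0.50),
    "liver": KineticParams(K1=0.5, k2=0.9, k3=0.01, Vb=0.25),
    "myocardium": KineticParams(K1=0.6, k2=1.2, k3=0.02, Vb=0.30),
    "muscle": KineticParams(K1=0.10, k2=0.8, k3=0.02, Vb=0.04),
}

BASELINE_PELVIS_DELAY_S = 55.0
BASELINE_PELVIS_RATE_PER_MIN = 0.45

#: multiplicative degradation factors per group: organ -> {rate: factor}.
#: "pelvis" carries the excretion-rate factor.  Renal K1 falls progressively
#: (L2 mild, L3 marked, L4 severe), pelvic extraction falls in parallel and
#: collapses in L4; myocardial k3 rises in L3 (and less in L4) to give the
#: ~2x / ~1.5x late blood-normalised uptake of chemotoxic remodelling; L4
#: adds systemic muscle/liver trapping increases.
GROUP_KINETIC_FACTORS: dict[str, dict[str, dict[str, float]]] = {
    "L1": {},
    "L2Aco": {},
    "L34Aco": {},
    "L2": {
        "cortex": {"K1": 0.78},
        "medulla": {"K1": 0.78},
        "pelvis": {"rate": 0.80},
    },
    "L3": {
        "cortex": {"K1": 0.60},
        "medulla": {"K1": 0.60},
        "pelvis": {"rate": 0.60},
        "myocardium": {"k3": 3.8},
    },
    "L4": {
        "cortex": {"K1": 0.45},
        "medulla": {"K1": 0.45},
        "pelvis": {"rate": 0.35},
        "myocardium": {"k3": 2.3},
        "muscle": {"k3": 3.0},
        "liver": {"k3": 2.5},
    },
}

GROUP_GLYCEMIA_MG_DL: dict[str, float] = {
    "L1": 120.0, "L2": 120.0, "L3": 155.0, "L4": 130.0, "L2Aco": 120.0, "L34Aco": 120.0,
}

#: kidney volume scale (mm^3) and study age per group; values inside the
#: plausibility band of healthy/stunted developing rat kidneys.
GROUP_KIDNEY_VOLUME_MM3: dict[str, float] = {
    "L1": 1590.0, "L2": 1480.0, "L2Aco": 2101.0,
    "L3": 1900.0, "L4": 1750.0, "L34Aco": 2200.0,
}
GROUP_AGE_WEEKS: dict[str, float] = {
    "L1": 14.0, "L2": 20.0, "L2Aco": 20.0, "L3": 26.0, "L4": 26.0, "L34Aco": 26.0,
}

#: reference growth anchors for a male laboratory rat (postnatal day, g);
#: the 5-point logistic through them is the healthy growth trajectory.
REFERENCE_GROWTH_ANCHORS: tuple[tuple[float, float], ...] = (
    (28.0, 95.0), (56.0, 290.0), (84.0, 420.0), (112.0, 480.0), (140.0, 515.0),
)

_reference_sigmoid: SigmoidGrowth | None = None


def reference_growth_curve() -> SigmoidGrowth:
    """The healthy-control growth trajectory (5-anchor logistic), cached."""
    global _reference_sigmoid
    if _reference_sigmoid is None:
        days, weights = zip(*REFERENCE_GROWTH_ANCHORS)
        _reference_sigmoid = sigmoid_reference(days, weights)
    return _reference_sigmoid


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to deterministically simulate one subject."""

    subject_id: str
    group: str
    weight_g: float
    dose_mbq: float
    glycemia_mg_dl: float
    organ_params: Mapping[str, KineticParams]
    input_params: InputFunctionParams
    pelvis_delay_s: float
    pelvis_rate_per_min: float
    noise_scale: float
    seed: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidParameterError(f"unknown group {self.group!r}")
        if self.weight_g <= 0 or self.dose_mbq <= 0:
            raise InvalidParameterError("weight and dose must be positive")
        missing = [o for o in ORGANS if o != "pelvis" and o not in self.organ_params]
        if missing:
            raise InvalidParameterError(f"missing organ parameters: {missing}")
        if self.pelvis_delay_s < 0 or self.pelvis_rate_per_min < 0:
            raise InvalidParameterError("pelvis delay and rate must be non-negative")
        if self.noise_scale < 0:
            raise InvalidParameterError("noise_scale must be non-negative")


@dataclass(frozen=True)
class Morphometry:
    """Synthetic per-subject morphometry."""

    kidney_axes: KidneyAxes
    kidney_volume_mm3: float
    age_weeks: float
    growth: GrowthSeries


@dataclass(frozen=True)
class SubjectRecord:
    """A simulated subject: spec, framed curves, QC ground truth, morphometry."""

    spec: SubjectSpec
    tacs: Mapping[str, TimeActivityCurve]
    qc_truth: Mapping[str, bool]
    morphometry: Morphometry


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def default_group_params(
    group: str,
    rng_seed: int,
    subject_id: str | None = None,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    between_subject_cv: float = DEFAULT_BETWEEN_SUBJECT_CV,
) -> SubjectSpec:
    """Draw one subject's spec from the group's population distribution.

    Baseline healthy kinetics are degraded by the group's factor table, then
    every rate gets an independent log-normal between-subject multiplier
    (default CV 15%).  Deterministic: same (group, seed) -> identical spec.
    """
    if group not in GROUPS:
        raise InvalidParameterError(f"unknown group {group!r}")
    rng = np.random.default_rng(rng_seed)
    factors = GROUP_KINETIC_FACTORS[group]

    organ_params: dict[str, KineticParams] = {}
    for organ, base in BASELINE_ORGAN_PARAMS.items():
        f = factors.get(organ, {})
        k1 = base.K1 * f.get("K1", 1.0) * _lognormal_factor(rng, between_subject_cv)
        k2 = base.k2 * f.get("k2", 1.0) * _lognormal_factor(rng, between_subject_cv)
        k3 = base.k3 * f.get("k3", 1.0) * _lognormal_factor(rng, between_subject_cv)
        vb = min(0.85, base.Vb * _lognormal_factor(rng, 0.10))
        organ_params[organ] = KineticParams(K1=k1, k2=k2, k3=k3, Vb=vb)

    pelvis_f = factors.get("pelvis", {}).get("rate", 1.0)
    pelvis_rate = (
        BASELINE_PELVIS_RATE_PER_MIN * pelvis_f * _lognormal_factor(rng, between_subject_cv)
    )
    pelvis_delay = float(np.clip(rng.normal(BASELINE_PELVIS_DELAY_S, 5.0), 20.0, 120.0))

    weight = float(np.clip(rng.normal(300.0, 18.0), 240.0, 380.0))
    dose_per_100g = float(np.clip(rng.normal(9.56, 0.7), 6.0, 14.0))
    dose = dose_per_100g * weight / 100.0
    glycemia = float(np.clip(rng.normal(GROUP_GLYCEMIA_MG_DL[group], 15.0), 70.0, 250.0))

    bolus = default_rat_bolus()
    input_params = InputFunctionParams(
        A1=bolus.A1 * _lognormal_factor(rng, 0.10),
        A2=bolus.A2 * _lognormal_factor(rng, 0.10),
        A3=bolus.A3 * _lognormal_factor(rng, 0.10),
        lam1=bolus.lam1,
        lam2=bolus.lam2,
        lam3=bolus.lam3,
        t_delay=float(np.clip(rng.normal(bolus.t_delay, 1.0), 2.0, 20.0)),
    )

    return SubjectSpec(
        subject_id=subject_id if subject_id is not None else f"{group}-{rng_seed}",
        group=group,
        weight_g=weight,
        dose_mbq=dose,
        glycemia_mg_dl=glycemia,
        organ_params=organ_params,
        input_params=input_params,
        pelvis_delay_s=pelvis_delay,
        pelvis_rate_per_min=pelvis_rate,
        noise_scale=noise_scale,
        seed=int(rng_seed),
    )


# ---------------------------------------------------------------------------
# piecewise-linear antiderivatives (exact pelvic accumulation)
# ---------------------------------------------------------------------------

def _pl_antiderivatives(t: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second antiderivatives of a piecewise-linear curve at its nodes."""
    h = np.diff(t)
    m = np.diff(v) / h
    int_v = v[:-1] * h + 0.5 * m * h**2
    z = np.concatenate([[0.0], np.cumsum(int_v)])
    int_z = z[:-1] * h + v[:-1] * h**2 / 2 + m * h**3 / 6
    w = np.concatenate([[0.0], np.cumsum(int_z)])
    return z, w


def _pl_eval_antideriv(
    t: np.ndarray, v: np.ndarray, z: np.ndarray, q: np.ndarray, w: np.ndarray | None = None
) -> np.ndarray:
    """Evaluate Z(q) (or W(q) when ``w`` is given) exactly; 0 left of support."""
    q = np.asarray(q, float)
    qc = np.clip(q, t[0], t[-1])
    i = np.clip(np.searchsorted(t, qc, side="right") - 1, 0, t.size - 2)
    dt = qc - t[i]
    m = (v[i + 1] - v[i]) / (t[i + 1] - t[i])
    if w is None:
        out = z[i] + v[i] * dt + 0.5 * m * dt**2
    else:
        out = w[i] + z[i] * dt + v[i] * dt**2 / 2 + m * dt**3 / 6
    return np.where(q < t[0], 0.0, out)


def simulate_pelvis(
    free_times: Sequence[float],
    free_values: Sequence[float],
    delay: float,
    rate: float,
    t_grid: Sequence[float],
) -> np.ndarray:
    """Pelvic accumulation: dC_pelvis/dt = rate * C_free(t - delay).

    ``free_values`` is the feeding (cortical free-compartment) concentration,
    treated as piecewise linear on ``free_times``; the pelvis integrates its
    delayed outflow irreversibly, so the returned curve is monotone
    non-decreasing and zero before the delayed tracer arrives.  ``rate`` is
    per minute, times in seconds.
    """
    if delay < 0 or rate < 0:
        raise InvalidParameterError("delay and rate must be non-negative")
    ft = np.asarray(free_times, float)
    fv = np.asarray(free_values, float)
    if ft.ndim != 1 or ft.size != fv.size or ft.size < 2:
        raise InvalidParameterError("free curve needs matching 1-D times and values")
    z, _ = _pl_antiderivatives(ft, fv)
    return (rate / 60.0) * _pl_eval_antideriv(ft, fv, z, np.asarray(t_grid, float) - delay)


def _pelvis_framed(
    free_times: np.ndarray,
    free_values: np.ndarray,
    delay: float,
    rate: float,
    schedule: FramingSchedule,
) -> np.ndarray:
    """Exact frame-interval averages of the pelvic accumulation curve."""
    z, w = _pl_antiderivatives(free_times, free_values)
    w_end = _pl_eval_antideriv(free_times, free_values, z, schedule.end - delay, w)
    w_start = _pl_eval_antideriv(free_times, free_values, z, schedule.start - delay, w)
    return (rate / 60.0) * (w_end - w_start) / schedule.duration


# ---------------------------------------------------------------------------
# noise and artifacts
# ---------------------------------------------------------------------------

def add_noise(tac: TimeActivityCurve, noise_scale: float, seed: int) -> TimeActivityCurve:
    """Additive Gaussian frame noise, sigma_k = scale * sqrt(max(C_k, floor)/dt_k).

    Variance scales with activity and inversely with frame duration, the
    leading behaviour of reconstructed count statistics; the floor (1% of the
    curve peak) keeps empty pre-arrival frames from being noiseless.  Results
    are clipped at zero and deterministic under the seed.
    """
    if noise_scale < 0:
        raise InvalidParameterError("noise_scale must be non-negative")
    if noise_scale == 0:
        return tac
    peak = tac.peak
    floor = 0.01 * peak if peak > 0 else 0.0
    sigma = noise_scale * np.sqrt(np.maximum(tac.values, floor) / tac.schedule.duration)
    rng = np.random.default_rng(seed)
    noisy = np.clip(tac.values + rng.normal(0.0, 1.0, tac.values.size) * sigma, 0.0, None)
    return tac.with_values(noisy)


DEPOT_RELEASE_TAU_S = 1.0e4  # depot release time constant, >> scan duration


def _depot_blood_curve(
    nodes: np.ndarray, cp_clean: np.ndarray, leak_fraction: float, tau: float
) -> np.ndarray:
    """Blood curve with a fraction of the dose trapped at the injection site.

    The trapped fraction releases first-order (time constant ``tau`` much
    longer than the scan) toward the bolus peak concentration scale, so the
    blood curve keeps ascending for the whole acquisition instead of showing
    bolus transit - the shape the QC screen is built to reject.
    """
    release = np.max(cp_clean) * -np.expm1(-np.asarray(nodes, float) / tau)
    return (1.0 - leak_fraction) * cp_clean + leak_fraction * release


# ---------------------------------------------------------------------------
# subject and cohort simulation
# ---------------------------------------------------------------------------

_SIM_MAX_STEP_S = 0.5  # internal grid refinement for the forward model


def _synthesize_morphometry(spec: SubjectSpec, rng: np.random.Generator) -> Morphometry:
    aspect = np.array([1.55, 1.0, 1.03])  # length : width : depth
    target_vol = GROUP_KIDNEY_VOLUME_MM3[spec.group]
    width = (6.0 * target_vol / (math.pi * aspect[0] * aspect[2])) ** (1.0 / 3.0)
    axes_arr = aspect * width * rng.normal(1.0, 0.04, 3).clip(0.85, 1.15)
    axes = KidneyAxes(length=float(axes_arr[0]), width=float(axes_arr[1]), depth=float(axes_arr[2]))

    sig = reference_growth_curve()
    age_weeks = GROUP_AGE_WEEKS[spec.group]
    days = np.arange(56.0, age_weeks * 7.0 + 1e-9, 7.0)
    healthy = np.asarray(sig(days), float)
    if spec.group in ("L2", "L3"):  # blunted gain under doxorubicin
        weights = healthy[0] + 0.85 * (healthy - healthy[0])
    elif spec.group == "L4":  # plateau with mild fluid gain after regimen start
        weights = np.minimum(healthy, float(sig(100.0))) * 1.03
    else:
        weights = healthy
    scale = spec.weight_g / healthy[0]
    weights = weights * scale * rng.normal(1.0, 0.02, days.size).clip(0.9, 1.1)
    return Morphometry(
        kidney_axes=axes,
        kidney_volume_mm3=ellipsoid_volume(axes),
        age_weeks=age_weeks,
        growth=GrowthSeries(postnatal_day=days, weight=weights),
    )


def simulate_subject(
    spec: SubjectSpec,
    depot_leak: float = 0.0,
    depot_tau: float = DEPOT_RELEASE_TAU_S,
) -> SubjectRecord:
    """Forward-simulate one subject's framed organ curves from its spec.

    The aorta curve is the framed input function; parenchymal organs are the
    framed irreversible-2TCM response; the pelvis integrates the delayed
    cortical free-compartment outflow.  All frame means are exact integrals
    of the piecewise-linear-input model; noise is added per curve afterwards
    with seeds derived from ``spec.seed``, so the record is a pure function
    of (spec, depot_leak).
    """
    schedule = dynamic_framing_schedule()
    nodes, frame_idx = schedule.refined(_SIM_MAX_STEP_S)
    durations = schedule.duration

    cp = np.asarray(eval_input_function(spec.input_params, nodes), float)
    if depot_leak > 0.0:
        cp = _depot_blood_curve(nodes, cp, depot_leak, depot_tau)

    int_cp = 0.5 * (cp[:-1] + cp[1:]) * np.diff(nodes)
    aorta_means = np.bincount(frame_idx, weights=int_cp, minlength=schedule.n_frames) / durations

    curves: dict[str, np.ndarray] = {"aorta": aorta_means}
    free_cortex: np.ndarray | None = None
    for organ in ("cortex", "medulla", "liver", "myocardium", "muscle"):
        means, fwd = _framed_from_nodes(nodes, cp, frame_idx, durations, spec.organ_params[organ])
        curves[organ] = means
        if organ == "cortex":
            free_cortex = fwd.free
    assert free_cortex is not None
    curves["pelvis"] = _pelvis_framed(
        nodes, free_cortex, spec.pelvis_delay_s, spec.pelvis_rate_per_min, schedule
    )

    order = ("aorta",) + ORGANS
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(len(order) + 1)
    tacs: dict[str, TimeActivityCurve] = {}
    for name, child in zip(order, child_seeds):
        clean = TimeActivityCurve(schedule, curves[name], region=name)
        tacs[name] = add_noise(clean, spec.noise_scale, int(child))

    morpho_rng = np.random.default_rng(int(child_seeds[-1]))
    return SubjectRecord(
        spec=spec,
        tacs=tacs,
        qc_truth={"tail_depot": depot_leak > 0.0},
        morphometry=_synthesize_morphometry(spec, morpho_rng),
    )


def inject_tail_depot(
    record: SubjectRecord,
    leak_fraction: float = 0.9,
    tau: float = DEPOT_RELEASE_TAU_S,
) -> SubjectRecord:
    """Re-simulate a subject with a fraction of the dose trapped at the tail vein.

    The aorta and every downstream organ input are replaced consistently; the
    record's ``qc_truth['tail_depot']`` flag is set.  ``leak_fraction=0``
    returns the record unchanged.
    """
    if not (0.0 <= leak_fraction <= 1.0):
        raise InvalidParameterError("leak_fraction must lie in [0, 1]")
    if leak_fraction == 0.0:
        return record
    return simulate_subject(record.spec, depot_leak=leak_fraction, depot_tau=tau)


def generate_cohort(
    group_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    between_subject_cv: float = DEFAULT_BETWEEN_SUBJECT_CV,
) -> list[SubjectRecord]:
    """Deterministically simulate a full cohort.

    Default sizes mirror the study design (L1/L2/L3/L4 = 8/8/8/10 plus 2+2
    age controls = 38 subjects).  Per-subject seeds are spawned from ``seed``
    so the cohort is a pure function of (group_sizes, seed, noise, CV).
    """
    sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    for group, n in sizes.items():
        if group not in GROUPS:
            raise InvalidParameterError(f"unknown group {group!r}")
        if n < 0:
            raise InvalidParameterError("group sizes must be non-negative")
    total = sum(sizes.values())
    subject_seeds = np.random.SeedSequence(seed).generate_state(max(total, 1))
    records: list[SubjectRecord] = []
    k = 0
    for group in GROUPS:
        for i in range(sizes.get(group, 0)):
            spec = default_group_params(
                group,
                rng_seed=int(subject_seeds[k]),
                subject_id=f"{group}-{i + 1:02d}",
                noise_scale=noise_scale,
                between_subject_cv=between_subject_cv,
            )
            records.append(simulate_subject(spec))
            k += 1
    return records
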