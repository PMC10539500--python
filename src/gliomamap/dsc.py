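"""DSC-MRI relaxation-rate conversion and Boxerman leakage-model fitting.

The gradient-echo DSC signal is converted to the transverse relaxation-rate
change dR2*(t) = -(1/TE) ln(S(t)/S0), with S0 the pre-bolus baseline mean.
Contrast leakage in enhancing tumor is quantified with the Boxerman
two-parameter linear model: the measured tumor curve is regressed on the
non-enhancing whole-brain reference curve and its running integral,

    dR2*_tumor(t) ~ K1 * dR2*_ref(t) - K2 * int_0^t dR2*_ref(t') dt',

so K1 captures blood-volume scaling and K2 the leakage term. Derived
per-ROI metrics: nK2 = K2_roi / K2_NAWM (NAWM = contralateral
normal-appearing white matter), leakage-corrected rCBV normalized to NAWM,
percent signal recovery (PSR), MTT, relative time-to-peak and a Tmax
surrogate. ROI extraction (8x8x1 voxel windows) and whole-brain median
normalization of parametric maps live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFN = {
    "psr": "100*(S_post - S_min)/(S0 - S_min); S_post = mean of final 20% of frames",
    "rcbv": "trapezoid area of leakage-corrected dR2* / same for NAWM",
    "mtt": "area/height of leakage-corrected dR2* curve (s)",
    "rttp": "t(peak dR2*) - t(bolus arrival) (s)",
    "tmax_surrogate": "t(peak dR2*_roi) - t(peak dR2*_ref) (s); no AIF deconvolution",
    "bolus_arrival": "first index where reference dR2* > baseline mean + 5 sd",
    "roi_window": "even windows anchored low: recorded voxel at window index (4,4,0)",
}


@dataclass
class SignalTimeCourse:
    """One ROI's DSC signal on a uniform TR grid."""

    roi_id: str
    t: np.ndarray  # seconds
    signal: np.ndarray  # arbitrary units, > 0
    te: float  # seconds
    baseline_n: int  # number of pre-bolus points
    role: str = "tumor-ROI"  # tumor-ROI | whole-brain-reference | NAWM

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.signal = np.asarray(self.signal, float)
        if self.te <= 0:
            raise ValueError("TE must be > 0")
        if self.baseline_n < 5:
            raise ValueError("baseline window must span >= 5 points")
        dt = np.diff(self.t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time grid must be uniform")

    @property
    def tr(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def s0(self) -> float:
        return float(self.signal[: self.baseline_n].mean())


@dataclass
class DeltaR2Curve:
    roi_id: str
    t: np.ndarray
    dr2: np.ndarray  # 1/s
    s0: float
    baseline_n: int


@dataclass
class LeakageFit:
    roi_id: str
    k1: float
    k2: float  # 1/s; positive = signal-increasing (T1-dominant) leakage
    residual_rms: float
    fit_window: tuple[int, int]


@dataclass
class PerfusionMetrics:
    roi_id: str
    rcbv: float
    nk2: float | None
    psr: float
    mtt: float
    rttp: float
    tmax_surrogate: float
    k1: float
    k2: float
    definitions: dict = field(default_factory=lambda: dict(DEFN))


def delta_r2(course: SignalTimeCourse) -> DeltaR2Curve:
    """dR2*(t) = -(1/TE) ln(S(t)/S0), S0 = mean of the pre-bolus baseline."""
    bad = np.flatnonzero(course.signal <= 0)
    if len(bad):
        raise ValueError(f"non-positive signal at index {int(bad[0])}")
    s0 = course.s0
    if s0 <= 0:
        raise ValueError("baseline mean must be > 0")
    dr2 = -(1.0 / course.te) * np.log(course.signal / s0)
    return DeltaR2Curve(course.roi_id, course.t, dr2, s0, course.baseline_n)


def cumulative_integral(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Running trapezoid integral from t[0], same length as y."""
    out = np.zeros_like(y, dtype=float)
    out[1:] = np.cumsum((y[1:] + y[:-1]) / 2.0 * np.diff(t))
    return out


def bolus_arrival_index(reference: DeltaR2Curve, n_sd: float = 5.0) -> int:
    """First index where the reference curve exceeds baseline mean + n_sd * sd."""
    base = reference.dr2[: reference.baseline_n]
    thr = base.mean() + n_sd * base.std(ddof=1)
    above = np.flatnonzero(reference.dr2 > thr)
    if not len(above):
        raise ValueError("no bolus detected in reference curve")
    return int(above[0])


def fit_leakage(
    tumor: DeltaR2Curve,
    reference: DeltaR2Curve,
    fit_window: tuple[int, int] | None = None,
) -> LeakageFit:
    """OLS fit of the tumor curve on [reference, cumint(reference)].

    Coefficients map to (K1, -K2). The default fit window runs from bolus
    arrival (reference exceeding baseline + 5 sd) to the end of the series.
    """
    if tumor.t.shape != reference.t.shape or not np.allclose(tumor.t, reference.t):
        raise ValueError("tumor and reference must share one time grid")
    if fit_window is None:
        fit_window = (bolus_arrival_index(reference), len(reference.t))
    lo, hi = fit_window
    ref = reference.dr2
    cum = cumulative_integral(reference.t, ref)
    x = np.column_stack([ref[lo:hi], cum[lo:hi]])
    if np.linalg.matrix_rank(x) < 2:
        raise ValueError("collinear regressors: reference curve carries no bolus")
    coef, _, _, _ = np.linalg.lstsq(x, tumor.dr2[lo:hi], rcond=None)
    resid = tumor.dr2[lo:hi] - x @ coef
    return LeakageFit(
        roi_id=tumor.roi_id,
        k1=float(coef[0]),
        k2=float(-coef[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        fit_window=(int(lo), int(hi)),
    )


def perfusion_metrics(
    tumor_course: SignalTimeCourse,
    tumor: DeltaR2Curve,
    tumor_fit: LeakageFit,
    reference: DeltaR2Curve,
    nawm: DeltaR2Curve,
    nawm_fit: LeakageFit,
    psr_tail_fraction: float = 0.2,
) -> PerfusionMetrics:
    """Derived per-ROI perfusion metrics with every definition recorded.

    The leakage-corrected curve adds K2 * cumint(reference) back to the
    measured tumor curve; rCBV is its trapezoid area over the NAWM area
    (NAWM corrected with its own fit). nK2 is None (explicit null) when the
    NAWM K2 is zero.
    """
    t = tumor.t
    cum_ref = cumulative_integral(t, reference.dr2)
    corrected = tumor.dr2 + tumor_fit.k2 * cum_ref
    nawm_corrected = nawm.dr2 + nawm_fit.k2 * cum_ref
    arrival = bolus_arrival_index(reference)

    area = float(np.trapezoid(corrected[arrival:], t[arrival:]))
    nawm_area = float(np.trapezoid(nawm_corrected[arrival:], t[arrival:]))
    if nawm_area == 0:
        raise ValueError("NAWM area is zero; rCBV undefined")
    rcbv = area / nawm_area

    nk2 = None if nawm_fit.k2 == 0 else tumor_fit.k2 / nawm_fit.k2

    sig = tumor_course.signal
    s0 = tumor_course.s0
    n_tail = max(1, int(round(psr_tail_fraction * len(sig))))
    s_post = float(sig[-n_tail:].mean())
    s_min = float(sig.min())
    psr = 100.0 * (s_post - s_min) / (s0 - s_min) if s0 != s_min else float("nan")

    peak_idx = int(np.argmax(corrected))
    height = float(corrected[peak_idx])
    mtt = area / height if height > 0 else float("nan")
    rttp = float(t[peak_idx] - t[arrival])
    ref_peak = int(np.argmax(reference.dr2))
    tmax = float(t[peak_idx] - t[ref_peak])

    return PerfusionMetrics(
        roi_id=tumor.roi_id,
        rcbv=rcbv,
        nk2=nk2,
        psr=psr,
        mtt=mtt,
        rttp=rttp,
        tmax_surrogate=tmax,
        k1=tumor_fit.k1,
        k2=tumor_fit.k2,
    )


def extract_roi_mean(
    volume: np.ndarray,
    center: tuple[int, int, int],
    window: tuple[int, int, int] = (8, 8, 1),
) -> tuple[float, int]:
    """Mean of a voxel window centered on a recorded biopsy location.

    Even window dimensions are anchored low: for the default 8x8x1 window
    the recorded voxel sits at in-window index (4, 4, 0). The window is
    clipped to the volume; NaN voxels are excluded. Returns (mean,
    n_excluded_nan).
    """
    volume = np.asarray(volume, float)
    if volume.ndim != 3:
        raise ValueError("volume must be 3-D")
    slices = []
    for axis in range(3):
        w = window[axis]
        lo = center[axis] - w // 2
        hi = lo + w
        lo_c, hi_c = max(lo, 0), min(hi, volume.shape[axis])
        if hi_c <= lo_c:
            raise ValueError("ROI window lies fully outside the volume")
        slices.append(slice(lo_c, hi_c))
    block = volume[tuple(slices)]
    n_nan = int(np.isnan(block).sum())
    if n_nan == block.size:
        raise ValueError("ROI window contains only NaN voxels")
    return float(np.nanmean(block)), n_nan


def normalize_map(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide a parametric map by the median intensity inside a brain mask."""
    volume = np.asarray(volume, float)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    med = float(np.median(volume[mask]))
    if med == 0:
        raise ValueError("in-mask median is zero; normalization undefined")
    return volume / med


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------


def courses_from_table(
    table: pd.DataFrame, te: float, baseline_n: int
) -> dict[str, SignalTimeCourse]:
    """Build SignalTimeCourse objects from a long-format timecourses table."""
    out = {}
    for roi_id, grp in table.groupby("roi_id"):
        grp = grp.sort_values("t_index")
        role = {
            "reference": "whole-brain-reference",
            "nawm": "NAWM",
        }.get(str(roi_id), "tumor-ROI")
        out[str(roi_id)] = SignalTimeCourse(
            roi_id=str(roi_id),
            t=grp["t_s"].to_numpy(float),
            signal=grp["signal"].to_numpy(float),
            te=te,
            baseline_n=baseline_n,
            role=role,
        )
    return out


def analyze_timecourses(
    table: pd.DataFrame,
    te: float,
    baseline_n: int,
    reference_roi: str = "reference",
    nawm_roi: str = "nawm",
) -> pd.DataFrame:
    """Fit every tumor ROI against the reference and derive all metrics.

    Returns one row per ROI (metrics.tsv dialect); the metric definitions
    travel in ``DataFrame.attrs['definitions']``.
    """
    courses = courses_from_table(table, te=te, baseline_n=baseline_n)
    for required in (reference_roi, nawm_roi):
        if required not in courses:
            raise ValueError(f"missing required ROI {required!r}")
    ref = delta_r2(courses[reference_roi])
    nawm_course = courses[nawm_roi]
    nawm = delta_r2(nawm_course)
    nawm_fit = fit_leakage(nawm, ref)
    rows = []
    for roi_id, course in courses.items():
        if roi_id == reference_roi:
            continue
        cur = delta_r2(course)
        fit = fit_leakage(cur, ref)
        m = perfusion_metrics(course, cur, fit, ref, nawm, nawm_fit)
        rows.append(
            {
                "roi_id": roi_id,
                "K1": m.k1,
                "K2": m.k2,
                "nK2": m.nk2,
                "rCBV": m.rcbv,
                "PSR": m.psr,
                "MTT": m.mtt,
                "RTTP": m.rttp,
                "Tmax_surrogate": m.tmax_surrogate,
                "residual_rms": fit.residual_rms,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["definitions"] = dict(DEFN)
    return out
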