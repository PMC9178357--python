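"""The accuracy-vs-framerate study.

A simulated high-speed recording (600 fps, 1 s) of every cilium in one or
more tissue populations is decimated onto a grid of lower frame rates
(default 300, 200, 150, 100, 60, 30 fps); CBF is quantified at every rate
by both estimators; the 300 fps estimate of each cilium is its *reference
CBF*.  The analyses carried out on the resulting record table are the ones
behind the "sample 3–4× the fastest expected CBF, not Nyquist" rule:

- per-framerate ordinary least squares of estimated CBF on reference CBF,
  restricted to reference-CBF bands (0–15, 0–30, 0–50 Hz);
- a pooled two-group slope-heterogeneity (ANCOVA-style) test of each fitted
  line against an idealized dataset in which every estimate equals its
  reference (slope 1, zero residual);
- group mean ± SD and failure-fraction summaries per tissue × fps × method;
- a Nyquist-margin table binning records by fps / reference CBF and
  reporting the mean relative error per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import cbf_fft, cbf_peak_spacing
from .simulate import BeatModel, PopulationSpec, sample_population, simulate_kymograph
from .video import Kymograph, downsample_kymograph

__all__ = [
    "StudyRecord",
    "RegressionResult",
    "GroupSummary",
    "run_study",
    "records_to_frame",
    "pairwise_regression",
    "slope_vs_identity_test",
    "regression_table",
    "group_summary",
    "nyquist_margin",
    "DEFAULT_FPS_GRID",
    "DEFAULT_BANDS",
]

DEFAULT_FPS_GRID: tuple[int, ...] = (300, 200, 150, 100, 60, 30)
DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((0, 15), (0, 30), (0, 50))
DEFAULT_METHODS: tuple[str, ...] = ("peak_spacing", "fft")


@dataclass
class StudyRecord:
    """One cilium × framerate × method measurement."""

    cilium_id: str
    group: str
    true_cbf: float | None
    fps: float
    method: str
    cbf: float | None
    failed: bool
    reference_cbf: float | None = None


@dataclass
class RegressionResult:
    """A fitted accuracy line (estimate vs reference) for one fps × method
    × reference-CBF band, with the slope-vs-identity test attached."""

    fps: float
    method: str
    cbf_band: tuple[float, float]
    n: int
    slope: float
    intercept: float
    r_squared: float
    slope_standard_error: float
    p_slope_vs_identity: float | None = None
    significant: bool | None = None


@dataclass
class GroupSummary:
    """Mean ± SD CBF and failure fraction for one group × fps × method."""

    group: str
    fps: float
    method: str
    n: int
    mean_cbf: float | None
    sd_cbf: float | None
    failure_fraction: float


# ---------------------------------------------------------------------------
# Study execution
# ---------------------------------------------------------------------------

def run_study(populations: Sequence[PopulationSpec],
              fps_grid: Sequence[float] = DEFAULT_FPS_GRID,
              reference_fps: float = 300.0,
              methods: Sequence[str] = DEFAULT_METHODS,
              seed: int = 0,
              simulation_fps: float = 600.0,
              duration: float = 1.0,
              n_positions: int = 20,
              estimator_config: dict | None = None,
              return_kymographs: bool = False):
    """Simulate every cilium once at ``simulation_fps`` and measure its CBF
    at every grid framerate by every method.

    The same 600 fps realization is decimated to each target rate, so each
    record row compares estimates of the *identical* recording — the
    pairwise design.  Fully reproducible under ``seed``.

    Returns the list of :class:`StudyRecord` (and, when
    ``return_kymographs`` is set, a dict cilium_id → 600 fps kymograph).
    """
    fps_grid = sorted(set(float(f) for f in fps_grid), reverse=True)
    if float(reference_fps) not in fps_grid:
        raise ValueError(
            f"reference_fps {reference_fps} must be in fps_grid {fps_grid}")
    if max(fps_grid) > simulation_fps:
        raise ValueError(
            f"fps_grid values must be <= simulation_fps {simulation_fps}")
    cfg = dict(estimator_config or {})
    peak_cfg = {k: cfg[k] for k in ("min_separation", "smoothing") if k in cfg}
    fft_cfg = {k: cfg[k] for k in ("min_freq", "min_prominence") if k in cfg}
    unknown = set(cfg) - {"min_separation", "smoothing", "min_freq", "min_prominence"}
    if unknown:
        raise ValueError(f"unknown estimator_config keys: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    records: list[StudyRecord] = []
    kymos: dict[str, Kymograph] = {}
    for spec in populations:
        pop_seed = int(rng.integers(0, 2**31))
        models = sample_population(spec, seed=pop_seed)
        for i, model in enumerate(models):
            cid = f"{spec.label}_{i:03d}"
            kymo_full = simulate_kymograph(
                model, simulation_fps, duration, n_positions, cilium_id=cid)
            if return_kymographs:
                kymos[cid] = kymo_full
            per_fps: dict[tuple[float, str], StudyRecord] = {}
            for fps in fps_grid:
                kd = downsample_kymograph(kymo_full, fps)
                for method in methods:
                    if method == "peak_spacing":
                        est = cbf_peak_spacing(kd, **peak_cfg)
                    elif method == "fft":
                        est = cbf_fft(kd, **fft_cfg)
                    else:
                        raise ValueError(f"unknown method {method!r}")
                    rec = StudyRecord(
                        cilium_id=cid, group=spec.label,
                        true_cbf=model.true_cbf, fps=fps, method=method,
                        cbf=est.cbf, failed=est.failed)
                    per_fps[(fps, method)] = rec
                    records.append(rec)
            for method in methods:
                ref = per_fps[(float(reference_fps), method)].cbf
                for fps in fps_grid:
                    per_fps[(fps, method)].reference_cbf = ref
    if return_kymographs:
        return records, kymos
    return records


def records_to_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Record table as a DataFrame (the CSV export schema)."""
    return pd.DataFrame(
        [{
            "cilium_id": r.cilium_id, "group": r.group,
            "true_cbf_hz": r.true_cbf, "fps": r.fps, "method": r.method,
            "cbf_hz": r.cbf, "failed": r.failed,
            "reference_cbf_hz": r.reference_cbf,
        } for r in records]
    )


# ---------------------------------------------------------------------------
# Pairwise regression and slope-vs-identity test
# ---------------------------------------------------------------------------

def _subset(records: Sequence[StudyRecord], fps: float, method: str,
            cbf_band: tuple[float, float]) -> tuple[np.ndarray, np.ndarray, dict]:
    """Usable (reference, estimate) pairs for one fps × method × band.

    Band filtering applies to the reference CBF only; failed records and
    records without a reference are excluded (and counted).
    """
    lo, hi = cbf_band
    x, y = [], []
    n_failed = n_out_of_band = 0
    for r in records:
        if r.fps != fps or r.method != method:
            continue
        if r.reference_cbf is None:
            n_failed += 1
            continue
        if not (lo <= r.reference_cbf <= hi):
            n_out_of_band += 1
            continue
        if r.failed or r.cbf is None:
            n_failed += 1
            continue
        x.append(r.reference_cbf)
        y.append(r.cbf)
    counts = {"n_used": len(x), "n_failed": n_failed,
              "n_out_of_band": n_out_of_band}
    return np.asarray(x), np.asarray(y), counts


def pairwise_regression(records: Sequence[StudyRecord], fps: float,
                        method: str,
                        cbf_band: tuple[float, float] = (0, 50)) -> RegressionResult:
    """OLS of estimated CBF (y) on reference CBF (x) for one framerate.

    Mirrors the pairwise best-fit-line analysis: failures excluded, band
    filter applied to the reference CBF.  Raises when fewer than 3 usable
    records remain.
    """
    x, y, counts = _subset(records, fps, method, cbf_band)
    if len(x) < 3:
        raise ValueError(
            f"insufficient data for regression at {fps} fps / {method} / "
            f"band {cbf_band}: {counts}")
    fit = stats.linregress(x, y)
    return RegressionResult(
        fps=fps, method=method, cbf_band=tuple(cbf_band), n=len(x),
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        slope_standard_error=float(fit.stderr),
    )


def slope_vs_identity_test(result: RegressionResult,
                           records: Sequence[StudyRecord]) -> float:
    """Two-group slope-heterogeneity test against the idealized identity line.

    The observed points are pooled with an idealized companion dataset that
    has the same reference values and y = x exactly (slope 1, zero residual
    sum of squares, contributing n − 2 degrees of freedom).  The standard
    heterogeneity-of-slopes statistic

        t = (b_obs − 1) / sqrt(s² (1/Sxx_obs + 1/Sxx_ideal)),
        s² = (RSS_obs + 0) / ((n_obs − 2) + (n_ideal − 2))

    is referred to a t distribution on the pooled residual df; the
    two-sided p-value is returned.  "Significant impairment" is declared at
    p < 0.05 by the caller.
    """
    x, y, _ = _subset(records, result.fps, result.method, result.cbf_band)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 usable records for the slope test")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in reference values; slope undefined")
    yhat = result.intercept + result.slope * x
    rss_obs = float(np.sum((y - yhat) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    if rss_obs <= 1e-12 * max(syy, 1.0):  # numerically perfect fit
        return 1.0 if abs(result.slope - 1.0) <= 1e-9 else 0.0
    df = (n - 2) + (n - 2)  # idealized group: same x, zero RSS
    s2 = rss_obs / df
    se_diff = np.sqrt(s2 * (1.0 / sxx + 1.0 / sxx))
    t = (result.slope - 1.0) / se_diff
    return float(2 * stats.t.sf(abs(t), df))


def regression_table(records: Sequence[StudyRecord],
                     fps_values: Sequence[float],
                     methods: Sequence[str] = DEFAULT_METHODS,
                     bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
                     alpha: float = 0.05) -> list[RegressionResult]:
    """Full fps × method × band regression table with slope tests attached.

    Combinations with fewer than 3 usable records are skipped.
    """
    out: list[RegressionResult] = []
    for band in bands:
        for method in methods:
            for fps in fps_values:
                try:
                    res = pairwise_regression(records, fps, method, band)
                except ValueError:
                    continue
                res.p_slope_vs_identity = slope_vs_identity_test(res, records)
                res.significant = bool(res.p_slope_vs_identity < alpha)
                out.append(res)
    return out


def regression_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "fps": r.fps, "method": r.method,
            "band_low_hz": r.cbf_band[0], "band_high_hz": r.cbf_band[1],
            "n": r.n, "slope": r.slope, "intercept": r.intercept,
            "r_squared": r.r_squared,
            "slope_se": r.slope_standard_error,
            "p_slope_vs_identity": r.p_slope_vs_identity,
            "significant": r.significant,
        } for r in results]
    )


# ---------------------------------------------------------------------------
# Group summaries and the Nyquist margin
# ---------------------------------------------------------------------------

def group_summary(records: Sequence[StudyRecord]) -> list[GroupSummary]:
    """Mean ± SD CBF and failure fraction per group × fps × method.

    Failed estimates are excluded from mean/SD but counted in the failure
    fraction; SD is the sample (ddof=1) standard deviation, None when fewer
    than two non-failed records exist.
    """
    if not records:
        raise ValueError("no records to summarize")
    out: list[GroupSummary] = []
    df = records_to_frame(records)
    for (group, fps, method), sub in df.groupby(["group", "fps", "method"],
                                                sort=True):
        ok = sub.loc[~sub["failed"], "cbf_hz"].to_numpy(dtype=float)
        out.append(GroupSummary(
            group=group, fps=float(fps), method=method, n=len(sub),
            mean_cbf=float(np.mean(ok)) if len(ok) else None,
            sd_cbf=float(np.std(ok, ddof=1)) if len(ok) > 1 else None,
            failure_fraction=float(sub["failed"].mean()),
        ))
    return out


def summary_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "group": s.group, "fps": s.fps, "method": s.method, "n": s.n,
            "mean_cbf_hz": s.mean_cbf, "sd_cbf_hz": s.sd_cbf,
            "failure_fraction": s.failure_fraction,
        } for s in summaries]
    )


def nyquist_margin(records: Sequence[StudyRecord],
                   bin_edges: Sequence[float] = (0, 1, 2, 3, 4, np.inf)
                   ) -> pd.DataFrame:
    """Relative CBF error as a function of the sampling margin.

    Records are binned by the ratio fps / reference CBF; each bin reports
    the mean and SD of (estimate − reference)/reference and its count.
    A ratio of 2 is the Nyquist point; the bins quantify how much margin
    beyond it is needed for accurate CBF measurement (the 3–4× rule).
    """
    rows = [r for r in records
            if not r.failed and r.cbf is not None and r.reference_cbf]
    if not rows:
        raise ValueError("no usable records for the Nyquist-margin table")
    ratio = np.array([r.fps / r.reference_cbf for r in rows])
    rel_err = np.array([(r.cbf - r.reference_cbf) / r.reference_cbf
                        for r in rows])
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.digitize(ratio, edges) - 1
    out = []
    for b in range(len(edges) - 1):
        sel = idx == b
        out.append({
            "ratio_low": edges[b], "ratio_high": edges[b + 1],
            "n": int(sel.sum()),
            "mean_rel_error": float(rel_err[sel].mean()) if sel.any() else np.nan,
            "sd_rel_error": (float(rel_err[sel].std(ddof=1))
                             if sel.sum() > 1 else np.nan),
        })
    return pd.DataFrame(out)
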