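"""SO2-tolerance growth kinetics: OD correction, Richards fits, lag times,
and the two-way variance decomposition of fitness traits.

OD600 plate-reader readings saturate at high cell densities and are first
linearised with a cubic calibration polynomial.  Each corrected curve is fit
with the Richards (generalised logistic) model

    y(t) = K * (1 + nu * exp(-k * (t - t_m)))**(-1/nu)

with carrying capacity K, shape nu, rate k and inflection-position t_m, all
positive.  The maximum specific growth rate mu_max is defined operationally
as the maximum of d(ln y)/dt of the fitted curve over the observed time
window, which is robust to the particular Richards parameterisation.  Lag
time is the first crossing of twice the inoculum OD, linearly interpolated;
curves that never cross are right-censored at the last time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: calibration polynomial (c3, c2, c1, c0), increasing on the 0-2 OD range
DEFAULT_OD_CORRECTION = (-0.0018, 0.1464, 0.7757, 0.0386)


@dataclass
class GrowthCurve:
    strain_id: str
    time_h: np.ndarray
    od_raw: np.ndarray
    chr16_config: str = "NA"
    so2_mg_per_l: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od_raw = np.asarray(self.od_raw, dtype=float)
        if self.time_h.shape != self.od_raw.shape:
            raise ValueError("time and OD lengths differ")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly ascending")


@dataclass(frozen=True)
class GrowthParams:
    mu_max: float  # 1/h
    lag_time_h: float
    lag_censored: bool
    K: float = float("nan")
    nu: float = float("nan")
    k: float = float("nan")
    t_m: float = float("nan")
    rss: float = float("nan")
    converged: bool = True


@dataclass
class AnovaResult:
    """Two-way fixed-effects decomposition: % variance and p per term."""

    pct_variance: Dict[str, float]
    p_values: Dict[str, float]
    levene_p: float
    n_censored_excluded: int = 0
    table: Optional[pd.DataFrame] = None


def correct_od(raw, coefficients: Sequence[float] = DEFAULT_OD_CORRECTION):
    """Linearise raw OD readings with the cubic calibration polynomial."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw OD must be non-negative")
    return np.polyval(coefficients, raw)


def lag_time(
    curve: GrowthCurve, inoculum_od: float, *, use_corrected: bool = True
) -> Tuple[float, bool]:
    """Hours to reach twice the inoculum OD, or (last time, censored=True).

    The crossing is linearly interpolated between the flanking samples; a
    curve already at or above the threshold at its first sample has lag 0.
    By default the threshold is applied to the corrected curve (the inoculum
    OD given should then be on the corrected scale); ``use_corrected=False``
    evaluates raw readings instead.
    """
    if inoculum_od <= 0:
        raise ValueError("inoculum_od must be positive")
    od = correct_od(curve.od_raw) if use_corrected else curve.od_raw
    thr = 2.0 * inoculum_od
    t = curve.time_h
    if od[0] >= thr:
        return 0.0, False
    above = np.nonzero(od >= thr)[0]
    if len(above) == 0:
        return float(t[-1]), True
    i = int(above[0])
    frac = (thr - od[i - 1]) / (od[i] - od[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1])), False


def richards_od(t, K: float, nu: float, k: float, t_m: float):
    """Richards generalised-logistic OD curve."""
    t = np.asarray(t, dtype=float)
    z = np.clip(-k * (t - t_m), -500, 500)
    return K * (1.0 + nu * np.exp(z)) ** (-1.0 / nu)


def mu_max_of_fit(params: Sequence[float], t_window: Tuple[float, float]) -> float:
    """Max of d(ln y)/dt of a Richards curve over the observed window.

    For the Richards model d(ln y)/dt = k*u / (1 + nu*u) with
    u = exp(-k*(t - t_m)), monotone decreasing in t, so the maximum over a
    window sits at its left edge; it is still evaluated on a grid to keep the
    definition purely operational.
    """
    K, nu, k, t_m = params
    grid = np.linspace(t_window[0], t_window[1], 2001)
    u = np.exp(np.clip(-k * (grid - t_m), -500, 500))
    dlny = k * u / (1.0 + nu * u)
    return float(dlny.max())


def fit_richards(
    curve: GrowthCurve, *, already_corrected: bool = False, seed: int = 0
) -> GrowthParams:
    """Least-squares Richards fit of one growth curve.

    The optimiser is restarted from several seeded initialisations (shape nu
    spanning sub- and super-logistic, rate from a crude log-slope estimate)
    and the best residual sum of squares wins.  Degenerate, non-increasing
    curves are flagged with mu_max 0 instead of fitted.
    """
    t = curve.time_h
    y = curve.od_raw if already_corrected else correct_od(curve.od_raw)
    if len(t) < 6:
        raise ValueError("need at least 6 time points")
    if y.max() - y.min() < 1e-6 or y[-1] <= y[0]:
        lag, cens = _lag_from_series(t, y)
        return GrowthParams(0.0, lag, cens, rss=float("nan"), converged=False)

    k0 = _crude_rate(t, y)
    t_m0 = float(t[np.argmax(np.gradient(y, t))])
    rng = np.random.default_rng(seed)
    starts = []
    for nu0 in (0.5, 1.0, 2.0):
        starts.append((y.max(), nu0, k0, max(t_m0, 1.0)))
    # two seeded perturbations around the logistic start
    for _ in range(2):
        jit = rng.uniform(0.5, 1.5, size=4)
        starts.append((y.max() * jit[0], jit[1], k0 * jit[2], max(t_m0 * jit[3], 1.0)))

    def resid(theta):
        return richards_od(t, *theta) - y

    best = None
    lb = [1e-6, 1e-3, 1e-4, 1e-6]
    ub = [10 * max(y.max(), 1e-3), 50.0, 10.0, 10 * max(t[-1], 1.0)]
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", max_nfev=2000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        lag, cens = _lag_from_series(t, y)
        return GrowthParams(0.0, lag, cens, rss=float("nan"), converged=False)
    rss, sol = best
    K, nu, k, t_m = (float(v) for v in sol.x)
    mu = mu_max_of_fit((K, nu, k, t_m), (float(t[0]), float(t[-1])))
    lag, cens = _lag_from_series(t, y)
    return GrowthParams(
        mu_max=mu, lag_time_h=lag, lag_censored=cens,
        K=K, nu=nu, k=k, t_m=t_m, rss=rss, converged=bool(sol.success),
    )


def _lag_from_series(t, y) -> Tuple[float, bool]:
    inoc = max(float(y[0]), 1e-9)
    thr = 2.0 * inoc
    if y[0] >= thr:  # unreachable by construction, kept for symmetry
        return 0.0, False
    above = np.nonzero(y >= thr)[0]
    if len(above) == 0:
        return float(t[-1]), True
    i = int(above[0])
    frac = (thr - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1])), False


def _crude_rate(t, y) -> float:
    ylog = np.log(np.clip(y, 1e-6, None))
    slopes = np.gradient(ylog, t)
    return float(max(slopes.max(), 1e-3))


def anova_lm1(
    table: pd.DataFrame,
    trait: str = "value",
    chr16_col: str = "chr16_config",
    so2_col: str = "so2",
    censored_col: Optional[str] = None,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction on a fitness trait.

    The model is trait ~ ChrXVI + SO2 + ChrXVI:SO2 with sequential (type I)
    sums of squares; on the balanced design used here term order is
    immaterial.  The percent variance of a term is its SS share of the total
    SS.  Homoscedasticity is checked with the median-centred (Brown-
    Forsythe) Levene test across design cells.  Rows flagged censored are
    excluded, with the exclusion count reported.
    """
    df = table.copy()
    n_censored = 0
    if censored_col is not None and censored_col in df.columns:
        n_censored = int(df[censored_col].sum())
        df = df[~df[censored_col].astype(bool)]
    df = df.rename(columns={trait: "y", chr16_col: "chr16", so2_col: "so2"})
    for col in ("chr16", "so2"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    cells = df.groupby(["chr16", "so2"], observed=True).size()
    expected_cells = df["chr16"].nunique() * df["so2"].nunique()
    if len(cells) < expected_cells:
        have = set(cells.index)
        missing = [
            (a, b)
            for a in df["chr16"].unique()
            for b in df["so2"].unique()
            if (a, b) not in have
        ]
        raise ValueError(f"empty design cells: {missing}")

    model = smf.ols("y ~ C(chr16) * C(so2)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    ss_total = float(aov["sum_sq"].sum())
    key_map = {
        "C(chr16)": "chr16",
        "C(so2)": "so2",
        "C(chr16):C(so2)": "interaction",
        "Residual": "residual",
    }
    pct = {key_map[k]: 100.0 * float(aov.loc[k, "sum_sq"]) / ss_total for k in key_map}
    pvals = {
        key_map[k]: float(aov.loc[k, "PR(>F)"])
        for k in key_map
        if k != "Residual"
    }
    groups = [g["y"].to_numpy() for _, g in df.groupby(["chr16", "so2"], observed=True)]
    levene_p = float(sps.levene(*groups, center="median").pvalue)
    return AnovaResult(
        pct_variance=pct,
        p_values=pvals,
        levene_p=levene_p,
        n_censored_excluded=n_censored,
        table=aov,
    )
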