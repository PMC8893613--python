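"""Evidence for temporal change in phrase prevalence.

For each phrase the binned prevalence series is regressed on the bin
midpoint year, and a Bayes factor BF10 compares the linear-trend model
against the intercept-only null. The trend model places the
Jeffreys–Zellner–Siow (JZS) default prior on the standardized slope — a
Cauchy with scale ``r``, expressed as a mixture of g-priors — which reduces
the marginal-likelihood ratio to a one-dimensional integral over g
(Liang et al.'s mixture representation, one covariate):

    BF10 = ∫ (1+g)^((n-2)/2) (1+g(1-R²))^(-(n-1)/2) π(g) dg,
    π(g) = (n r²/2)^(1/2) Γ(1/2)^(-1) g^(-3/2) exp(-n r² / (2g)),

i.e. g follows an inverse-gamma(1/2, n r²/2) prior. The integrand depends
on the data only through n and the OLS R², so BF10 is invariant to affine
rescaling of x and shifts of y. The default scale r = √2/4 is the
conventional "medium" prior for a single continuous covariate.

Evidence bands follow the classical ladder: BF ≤ 3.2 "not worth more than
a bare mention", 3.2–10 "substantial", 10–100 "strong", >100 "decisive".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special

from .prevalence_stats import Z_95

__all__ = [
    "BFConfig",
    "TrendResult",
    "fit_linear",
    "jzs_bf10",
    "jzs_bf10_from_r2",
    "classify_evidence",
    "trend_table",
    "EVIDENCE_BANDS",
]

#: (upper BF10 bound, label); bounds closed on the left of each upper bound
EVIDENCE_BANDS = ((3.2, "mention"), (10.0, "substantial"), (100.0, "strong"))


@dataclass(frozen=True)
class BFConfig:
    """Settings for the Bayes-factor trend analysis.

    ``prior_scale`` is the Cauchy scale r on the standardized slope
    (default "medium", √2/4). Phrases observed in fewer than
    ``min_timepoints`` nonempty bins are not evaluated. ``report_threshold``
    is the BF10 floor for the reporting variant of the trend table.
    """

    prior_scale: float = math.sqrt(2.0) / 4.0
    min_timepoints: int = 5
    report_threshold: float = 2.0
    rtol: float = 1e-8

    def __post_init__(self) -> None:
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        if self.min_timepoints < 3:
            raise ValueError("min_timepoints must be >= 3")


@dataclass(frozen=True)
class TrendResult:
    phrase: str
    n_timepoints: int
    slope: float
    intercept: float
    r_squared: float
    bf10: float
    evidence_band: str
    evaluated: bool = True
    reason: str = ""


def fit_linear(
    y: np.ndarray, x: np.ndarray
) -> tuple[float, float, float, np.ndarray]:
    """Ordinary least squares of y on x.

    Returns ``(slope, intercept, r_squared, band)`` where ``band`` is the
    ±1.959964-standard-error half-width of the mean response at each x
    (pointwise uncertainty for display). Requires n >= 3 and non-constant x.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 points")
    if len(x) != n:
        raise ValueError("x and y lengths differ")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("x is constant")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r_squared = 0.0 if tss == 0.0 else 1.0 - rss / tss
    r_squared = min(max(r_squared, 0.0), 1.0)
    sigma2 = rss / (n - 2)
    se_mean = np.sqrt(sigma2 * (1.0 / n + (x - x.mean()) ** 2 / sxx))
    return slope, intercept, r_squared, Z_95 * se_mean


def jzs_bf10_from_r2(n: int, r_squared: float, cfg: BFConfig | None = None) -> float:
    """BF10 of linear trend vs intercept-only from the sufficient pair (n, R²).

    The integral over g is computed in log space after the substitution
    u = g/(1+g), which maps (0, ∞) to (0, 1); the integrand's log maximum
    is subtracted before exponentiation so large n or R² near 1 cannot
    overflow.
    """
    cfg = cfg or BFConfig()
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError("R² must lie in [0, 1]")
    if r_squared == 1.0:
        return math.inf
    a = n * cfg.prior_scale**2 / 2.0
    log_norm = 0.5 * math.log(a) - special.gammaln(0.5)
    one_m_r2 = 1.0 - r_squared

    def log_f(v: float) -> float:
        # v = log g; jacobian dg = g dv contributes +v
        g = math.exp(v)
        return (
            log_norm
            - 1.5 * v
            - a / g
            + (n - 2) / 2.0 * math.log1p(g)
            - (n - 1) / 2.0 * math.log1p(g * one_m_r2)
            + v
        )

    # The integrand has its mass near the prior mode g = 2a and/or the
    # likelihood mode g ~ 1/(1-R²); bracket both so neither spike is missed.
    v_prior = math.log(2.0 * a)
    v_like = math.log(1.0 / one_m_r2) if one_m_r2 < 1.0 else v_prior
    peaks = sorted({v_prior, v_like})
    lo, hi = peaks[0] - 80.0, peaks[-1] + 120.0
    grid = np.linspace(lo, hi, 4097)
    log_m = max(max(log_f(float(v)) for v in grid), max(log_f(p) for p in peaks))
    val, _ = integrate.quad(
        lambda v: math.exp(log_f(v) - log_m),
        lo,
        hi,
        points=peaks,
        epsrel=cfg.rtol,
        epsabs=0.0,
        limit=500,
    )
    return float(math.exp(log_m) * val)


def jzs_bf10(y: np.ndarray, x: np.ndarray, cfg: BFConfig | None = None) -> float:
    """BF10 for a linear trend of y on x under the JZS prior."""
    cfg = cfg or BFConfig()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in y")
    _, _, r_squared, _ = fit_linear(y, x)
    return jzs_bf10_from_r2(len(y), r_squared, cfg)


def classify_evidence(bf10: float) -> str:
    """Evidence band for a BF10 (boundaries belong to the weaker band)."""
    if not bf10 > 0:
        raise ValueError("bf10 must be positive")
    for bound, label in EVIDENCE_BANDS:
        if bf10 <= bound:
            return label
    return "decisive"


def trend_table(
    prevalence: pd.DataFrame,
    cfg: BFConfig | None = None,
    report_only: bool = False,
    include_partial_2020: bool = False,
) -> pd.DataFrame:
    """Per-phrase trend fits and Bayes factors from a binned prevalence table.

    ``prevalence`` is the per-phrase slice of ``prevalence_table`` output
    (columns ``phrase, bin_start_year, bin_width_years, n_total,
    prevalence``). Bins with no documents are dropped (0/0 carries no
    information; 0/n contributes prevalence 0); the partial terminal 2020
    bin is excluded unless ``include_partial_2020``. Phrases with fewer than
    ``cfg.min_timepoints`` usable bins are flagged, not evaluated. Output is
    sorted by BF10 descending; ``report_only`` keeps rows with
    BF10 >= ``cfg.report_threshold``.
    """
    cfg = cfg or BFConfig()
    rows: list[TrendResult] = []
    for phrase, grp in prevalence.groupby("phrase", sort=True):
        grp = grp[grp["n_total"] > 0]
        if not include_partial_2020:
            # 2020 is observed only through September; its bin is incomplete
            grp = grp[grp["bin_start_year"] != 2020]
        n = len(grp)
        if n < cfg.min_timepoints:
            rows.append(
                TrendResult(
                    phrase, n, math.nan, math.nan, math.nan, math.nan, "", False,
                    f"only {n} time points (minimum {cfg.min_timepoints})",
                )
            )
            continue
        x = grp["bin_start_year"].to_numpy(float) + (
            grp["bin_width_years"].to_numpy(float) - 1.0
        ) / 2.0
        y = grp["prevalence"].to_numpy(float)
        slope, intercept, r_squared, _ = fit_linear(y, x)
        bf10 = jzs_bf10_from_r2(n, r_squared, cfg)
        rows.append(
            TrendResult(
                phrase, n, slope, intercept, r_squared, bf10, classify_evidence(bf10)
            )
        )
    frame = pd.DataFrame([r.__dict__ for r in rows])
    if len(frame):
        frame = frame.sort_values(
            ["evaluated", "bf10", "phrase"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
        if report_only:
            frame = frame[
                frame["evaluated"] & (frame["bf10"] >= cfg.report_threshold)
            ].reset_index(drop=True)
    return frame
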