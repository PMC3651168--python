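"""Habitat-structure regression: OLS with optional transforms, adjusted
R-squared, leave-one-out cross-validation, residual semivariograms,
model-ranking tables, and predictive raster surfaces.

Each candidate model regresses a per-point response (a species' density or
species richness) on one per-point predictor (a vegetation index or a
zonal texture summary), optionally square-root transforming the response,
log transforming the predictor, and adding a quadratic term.  Models are
compared by adjusted R-squared (reported only when the overall F test is
significant) and by LOOCV mean squared prediction error on the transformed
response scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist

from .raster import Raster


@dataclass(frozen=True)
class ModelSpec:
    response: str = "y"
    predictor: str = "x"
    sqrt_response: bool = False
    log_predictor: bool = False
    quadratic: bool = False


@dataclass
class RegressionResult:
    spec: ModelSpec
    coefficients: np.ndarray  # intercept, linear[, quadratic]
    adj_r2: float
    p_value: float
    loocv_error: float
    n: int
    log_offset: float = 0.0  # 1.0 when log(x + 1) was used, else 0
    cov_params: np.ndarray | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Evaluate on the original predictor/response scales."""
        xt = _transform_x(np.asarray(x, dtype=np.float64), self.spec,
                          self.log_offset)
        yhat = self.coefficients[0] + self.coefficients[1] * xt
        if self.spec.quadratic:
            yhat = yhat + self.coefficients[2] * xt * xt
        if self.spec.sqrt_response:
            yhat = yhat ** 2
        return yhat


def _transform_x(x, spec: ModelSpec, offset: float):
    return np.log(x + offset) if spec.log_predictor else x


def _design(x, spec: ModelSpec):
    cols = [np.ones_like(x), x]
    if spec.quadratic:
        cols.append(x * x)
    return np.column_stack(cols)


def _prepare(y, x, spec: ModelSpec):
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    offset = 0.0
    if spec.log_predictor:
        # guard: texture SD summaries can be exactly 0
        offset = 1.0 if np.any(x <= 0) else 0.0
        x = np.log(x + offset)
    if spec.sqrt_response:
        if np.any(y < 0):
            raise ValueError("sqrt transform requires non-negative response")
        y = np.sqrt(y)
    return y, x, offset


def fit_habitat_model(y, x, spec: ModelSpec = ModelSpec()
                      ) -> RegressionResult:
    """OLS on the transformed variables.

    adjusted R2 = 1 - (1 - R2)(n - 1)/(n - p - 1); the model p-value is
    that of the overall F statistic.  A constant predictor makes the
    design singular and is an explicit failure.
    """
    yt, xt, offset = _prepare(y, x, spec)
    n = yt.size
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(xt) == 0:
        raise ValueError("constant predictor: singular design")
    X = _design(xt, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(yt, X).fit()
    coefs = np.asarray(fit.params)
    result = RegressionResult(spec, coefs, float(fit.rsquared_adj),
                              float(fit.f_pvalue), np.nan, n, offset,
                              np.asarray(fit.cov_params()))
    result.loocv_error = loocv_error(y, x, spec)
    return result


def loocv_error(y, x, spec: ModelSpec = ModelSpec()) -> float:
    """LOOCV mean squared prediction error on the transformed scale.

    Uses the exact hat-matrix identity for linear least squares,
    mean[(e_i / (1 - h_ii))^2]; the literal n-refit loop is the test
    oracle.
    """
    yt, xt, _ = _prepare(y, x, spec)
    if yt.size < 6:
        raise ValueError("need at least 6 observations for LOOCV")
    X = _design(xt, spec)
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = X @ XtX_inv @ X.T
    h = np.diag(H)
    if np.any(h >= 1 - 1e-12):
        raise ValueError("leverage 1: some leave-one-out refit is singular")
    resid = yt - H @ yt
    return float(np.mean((resid / (1.0 - h)) ** 2))


# ---------------------------------------------------------------------------
# residual semivariogram

@dataclass
class Semivariogram:
    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_m": self.lag_centers, "gamma": self.gamma,
                             "n_pairs": self.pair_counts})


def residual_semivariogram(residuals, coords, n_bins: int = 10,
                           max_lag: float | None = None) -> Semivariogram:
    """Matheron estimator gamma(h) = (1 / 2N(h)) sum (r_i - r_j)^2 over
    point pairs binned by separation distance.

    Default ``max_lag`` is half the maximum pairwise distance.  Empty bins
    report gamma 0 with zero pair count.
    """
    r = np.asarray(residuals, dtype=np.float64)
    c = np.asarray(coords, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] != r.size:
        raise ValueError("coords must be (n, 2) matching residuals")
    d = pdist(c)
    if max_lag is None:
        max_lag = d.max() / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    sq = pdist(r[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    idx = np.digitize(d, edges[1:-1])
    keep = d <= max_lag
    gamma = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        sel = keep & (idx == b)
        counts[b] = sel.sum()
        if counts[b]:
            gamma[b] = sq[sel].sum() / (2.0 * counts[b])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Semivariogram(centers, gamma, counts)


# ---------------------------------------------------------------------------
# ranking and mapping

def rank_candidate_models(results: list[RegressionResult],
                          alpha: float = 0.05) -> pd.DataFrame:
    """Table of adjusted R2 per candidate model, blanking non-significant
    cells and flagging the best (highest adjusted R2) model.

    Columns: predictor, adj_r2 (NaN when p > alpha), p_value,
    loocv_error, best.
    """
    rows = []
    for res in results:
        sig = res.p_value <= alpha
        rows.append({"predictor": res.spec.predictor,
                     "adj_r2": res.adj_r2 if sig else np.nan,
                     "p_value": res.p_value,
                     "loocv_error": res.loocv_error,
                     "significant": sig})
    table = pd.DataFrame(rows)
    table["best"] = False
    if table["adj_r2"].notna().any():
        table.loc[table["adj_r2"].idxmax(), "best"] = True
    return table


def predict_surface(covariate: Raster, result: RegressionResult,
                    clamp_nonnegative: bool = True) -> Raster:
    """Pixelwise evaluation of a fitted model over a covariate raster.

    Applies the model's predictor transform, evaluates the polynomial,
    back-transforms square-rooted responses by squaring, and optionally
    clamps negative predictions (densities cannot be negative) to zero.
    Covariate nodata propagates.
    """
    vals = np.asarray(covariate.band(0), dtype=np.float64)
    out = np.zeros_like(vals)
    m = covariate.mask
    out[m] = result.predict(vals[m])
    if clamp_nonnegative:
        out = np.maximum(out, 0.0)
    out[~m] = 0.0
    return covariate.like(out)
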