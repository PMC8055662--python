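"""Correlation and Granger-causality analysis of sentiment vs. offline series.

Two association tools are provided, both operating after joint
stationarization (see :mod:`oge.stationarity`):

* Pearson correlation between differenced series — across city pairs of the
  same GMS topic, and between a city's GMS and its offline indicators
  (mobility modes, local/national daily cases and deaths).
* Granger (non-)causality of a mobility series M by a GMS series G: the
  univariate autoregression order p of M is chosen by BIC, lagged G terms
  are added,

      M_t = sum_{i<=p} alpha_i M_{t-i} + sum_{i<=p} omega_i G_{t-i} + eps_t,

  and the null omega_1 = ... = omega_p = 0 is tested with a chi-squared
  (Wald) statistic.  Rejection at 0.05 means G carries predictive
  information for M beyond M's own past.

No multiple-testing correction is applied by default; a Benjamini-Hochberg
adjustment is available as an option on the panel-level tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.ar_model import ar_select_order

from .stationarity import difference_to_stationary_pair

logger = logging.getLogger(__name__)

MIN_OVERLAP = 10


@dataclass
class CorrelationResult:
    """Pearson correlation of a jointly stationarized series pair."""

    pair: tuple[str, str]
    diff_order: int
    r: float
    p_value: float
    significant: bool
    n_obs: int


def _align_pair(x: pd.Series, y: pd.Series) -> tuple[pd.Series, pd.Series]:
    joined = pd.concat({"x": x, "y": y}, axis=1, join="inner").dropna()
    return joined["x"], joined["y"]


def correlate_pair(
    x: pd.Series,
    y: pd.Series,
    alpha: float = 0.05,
    max_order: int = 3,
    names: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Jointly stationarize two aligned series and report their Pearson r."""
    xa, ya = _align_pair(pd.Series(x), pd.Series(y))
    if len(xa) < MIN_OVERLAP:
        raise ValueError(f"overlap {len(xa)} below minimum {MIN_OVERLAP}")
    pair = difference_to_stationary_pair(xa, ya, alpha=alpha, max_order=max_order)
    xd, yd = _align_pair(pair.x, pair.y)
    r, p = stats.pearsonr(xd, yd)
    return CorrelationResult(
        pair=names,
        diff_order=pair.order,
        r=float(r),
        p_value=float(p),
        significant=bool(p < alpha),
        n_obs=int(len(xd)),
    )


def pairwise_city_correlations(
    gms_wide: pd.DataFrame,
    alpha: float = 0.05,
    max_order: int = 3,
    fdr: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Pearson correlations between every pair of city GMS series.

    Parameters
    ----------
    gms_wide
        DataFrame indexed by date with one column per city (a single topic).
    fdr
        Apply a Benjamini-Hochberg adjustment to the significance flags
        (off by default; raw 0.05 flags otherwise).

    Returns the per-pair results table and a summary dict with the 10th,
    25th, 50th, 75th and 90th percentiles of r and the percent of pairs
    significant.  Pairs with fewer than 10 overlapping days are skipped with
    a warning.
    """
    cities = list(gms_wide.columns)
    if len(cities) < 2:
        raise ValueError("need at least two cities")
    rows = []
    for c1, c2 in combinations(cities, 2):
        try:
            res = correlate_pair(
                gms_wide[c1], gms_wide[c2], alpha=alpha, max_order=max_order,
                names=(c1, c2),
            )
        except ValueError as exc:
            logger.warning("pair (%s, %s) skipped: %s", c1, c2, exc)
            continue
        rows.append(
            {
                "city_1": c1,
                "city_2": c2,
                "diff_order": res.diff_order,
                "r": res.r,
                "p_value": res.p_value,
                "significant": res.significant,
                "n_obs": res.n_obs,
            }
        )
    table = pd.DataFrame(rows)
    if fdr and len(table):
        table["significant"] = multipletests(
            table["p_value"], alpha=alpha, method="fdr_bh"
        )[0]
    qs = table["r"].quantile([0.10, 0.25, 0.50, 0.75, 0.90]) if len(table) else pd.Series(dtype=float)
    summary = {
        "percentiles": {f"p{int(q * 100)}": float(v) for q, v in qs.items()},
        "percent_significant": float(100 * table["significant"].mean()) if len(table) else float("nan"),
        "n_pairs": int(len(table)),
    }
    return table, summary


def gms_offline_correlation(
    gms: pd.Series,
    offline: pd.Series,
    alpha: float = 0.05,
    max_order: int = 3,
    truncate_offline: bool = False,
    names: tuple[str, str] = ("gms", "offline"),
) -> CorrelationResult:
    """Correlate a GMS series with an offline indicator.

    With ``truncate_offline=True`` (epidemic series) the offline series is
    first cut to start at its first nonzero value, and the GMS series is
    restricted to the same dates.
    """
    if truncate_offline:
        from .stationarity import truncate_at_first_nonzero

        offline = truncate_at_first_nonzero(pd.Series(offline))
        gms = pd.Series(gms).loc[lambda s: s.index.isin(offline.index)]
    return correlate_pair(gms, offline, alpha=alpha, max_order=max_order, names=names)


@dataclass
class GrangerResult:
    """Outcome of one two-step Granger test of a mobility series on a GMS series."""

    mobility_id: str
    gms_id: str
    lag: int
    cross_coeffs: np.ndarray
    chi2: float
    p_value: float
    significant: bool
    diff_order: int | None = None
    n_obs: int = 0


def _lag_matrix(x: np.ndarray, p: int) -> np.ndarray:
    """Columns x_{t-1} .. x_{t-p} aligned to x_t for t = p..n-1."""
    return np.column_stack([x[p - i: len(x) - i] for i in range(1, p + 1)])


def granger_lag_select(m, max_lag: int = 14, trend: str = "c") -> int:
    """BIC-optimal order of the univariate autoregression of ``m``.

    The scan floor is lag 1 (an order-0 autoregression is degenerate for the
    two-step test); if the series is too short for ``max_lag`` the range is
    shrunk with a warning.
    """
    m = np.asarray(pd.Series(m).dropna(), dtype=float)
    cap = (len(m) - 1) // 3
    if max_lag > cap:
        logger.warning("granger_lag_select: shrinking max_lag %d -> %d", max_lag, cap)
        max_lag = cap
    if max_lag < 1:
        raise ValueError("series too short for any autoregression")
    sel = ar_select_order(m, maxlag=max_lag, ic="bic", trend=trend, glob=False)
    lags = sel.ar_lags
    if not lags:
        return 1
    return max(1, int(max(lags)))


class GrangerCausality(BaseEstimator):
    """Two-step Granger causality test of a GMS series driving a mobility series.

    ``fit(m, g)`` expects both series already jointly stationarized and
    aligned.  When ``lag`` is None the BIC-optimal univariate lag of ``m``
    is selected first and reused for the augmented regression.

    Attributes: ``lag_``, ``ar_coeffs_``, ``cross_coeffs_``, ``chi2_``,
    ``p_value_``, ``significant_``, ``n_obs_``.
    """

    def __init__(
        self,
        lag: int | None = None,
        max_lag: int = 14,
        alpha: float = 0.05,
        method: str = "wald",
        trend: str = "c",
    ):
        self.lag = lag
        self.max_lag = max_lag
        self.alpha = alpha
        self.method = method
        self.trend = trend

    def fit(self, m, g):
        ma, ga = _align_pair(pd.Series(m), pd.Series(g))
        mv = ma.to_numpy(dtype=float)
        gv = ga.to_numpy(dtype=float)
        p = self.lag if self.lag is not None else granger_lag_select(
            mv, max_lag=self.max_lag, trend=self.trend
        )
        if p >= len(mv) / 3:
            raise ValueError(f"lag {p} too large for {len(mv)} observations")
        target = mv[p:]
        X_m = _lag_matrix(mv, p)
        X_g = _lag_matrix(gv, p)
        full = OLS(target, add_constant(np.hstack([X_m, X_g]))).fit()
        # omega coefficients occupy the last p columns (after const + m lags)
        restriction = np.zeros((p, 1 + 2 * p))
        for i in range(p):
            restriction[i, 1 + p + i] = 1.0
        if self.method == "wald":
            wt = full.wald_test(restriction, use_f=False, scalar=True)
            chi2 = float(wt.statistic)
            pvalue = float(wt.pvalue)
        elif self.method == "lr":
            restricted = OLS(target, add_constant(X_m)).fit()
            chi2 = float(2 * (full.llf - restricted.llf))
            pvalue = float(stats.chi2.sf(chi2, df=p))
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.lag_ = int(p)
        self.ar_coeffs_ = np.asarray(full.params[1: 1 + p], dtype=float)
        self.cross_coeffs_ = np.asarray(full.params[1 + p:], dtype=float)
        self.chi2_ = chi2
        self.p_value_ = pvalue
        self.significant_ = bool(pvalue < self.alpha)
        self.n_obs_ = int(len(target))
        return self


def granger_test(
    m, g, p: int | None = None, max_lag: int = 14, alpha: float = 0.05,
    method: str = "wald", names: tuple[str, str] = ("M", "G"),
) -> GrangerResult:
    """Run one Granger test (thin wrapper over :class:`GrangerCausality`)."""
    gc = GrangerCausality(lag=p, max_lag=max_lag, alpha=alpha, method=method).fit(m, g)
    return GrangerResult(
        mobility_id=names[0],
        gms_id=names[1],
        lag=gc.lag_,
        cross_coeffs=gc.cross_coeffs_,
        chi2=gc.chi2_,
        p_value=gc.p_value_,
        significant=gc.significant_,
        n_obs=gc.n_obs_,
    )


def granger_matrix(
    mobility: dict[str, pd.Series],
    gms: dict[str, pd.Series],
    max_lag: int = 14,
    alpha: float = 0.05,
    max_order: int = 3,
    fdr: bool = False,
) -> pd.DataFrame:
    """Granger-test every {mobility series, GMS series} pair.

    Both members of each pair are jointly differenced to a common order
    before the two-step test.  Per-pair failures (too short, degenerate) are
    recorded in the ``error`` column, not raised.  The reported ``lag`` is
    only meaningful where ``significant`` is True; non-significant rows keep
    their selected lag for transparency.
    """
    rows = []
    for m_id, m in mobility.items():
        for g_id, g in gms.items():
            row = {"mobility_id": m_id, "gms_id": g_id}
            try:
                ma, ga = _align_pair(pd.Series(m), pd.Series(g))
                if len(ma) < MIN_OVERLAP:
                    raise ValueError(f"overlap {len(ma)} below minimum")
                pair = difference_to_stationary_pair(ma, ga, max_order=max_order)
                res = granger_test(
                    pair.x, pair.y, max_lag=max_lag, alpha=alpha,
                    names=(m_id, g_id),
                )
                row.update(
                    lag=res.lag, chi2=res.chi2, p_value=res.p_value,
                    significant=res.significant, diff_order=pair.order,
                    n_obs=res.n_obs, error="",
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                row.update(
                    lag=np.nan, chi2=np.nan, p_value=np.nan, significant=False,
                    diff_order=np.nan, n_obs=0, error=str(exc),
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    if fdr and len(table):
        ok = table["p_value"].notna()
        adj = np.zeros(len(table), dtype=bool)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                table.loc[ok, "p_value"], alpha=alpha, method="fdr_bh"
            )[0]
        table["significant"] = adj
    return table
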