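"""Stationarization by iterated differencing under ADF unit-root testing.

Every association or intervention analysis first removes stochastic trends:
run an Augmented Dickey-Fuller test on each series involved, and while any
of them fails to reject the unit-root null at the significance level, first-
difference *all* of them jointly and retest.  The shared number of
differences is the pair's stationarization order.  Epidemic series are
truncated to start at the first nonzero count before entering this protocol.

The ADF regression includes a constant and no deterministic trend, with the
lag length chosen by information criterion (configurable); in practice
almost all series need at most one difference, and more than ``max_order``
(default 3) differences is treated as an error rather than accepted
silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "DegenerateSeriesError",
    "NonStationarizableError",
    "StationarizedPair",
    "Stationarizer",
    "adf_test",
    "difference_to_stationary",
    "difference_to_stationary_pair",
    "truncate_at_first_nonzero",
]

MIN_ADF_LENGTH = 12


class DegenerateSeriesError(ValueError):
    """The series is constant or too short for a unit-root test."""


class NonStationarizableError(ValueError):
    """Differencing up to the order cap never made every series stationary."""


def _clean(series) -> np.ndarray:
    x = np.asarray(pd.Series(series).dropna(), dtype=float)
    if len(x) < MIN_ADF_LENGTH:
        raise DegenerateSeriesError(
            f"need >= {MIN_ADF_LENGTH} observations for an ADF test, got {len(x)}"
        )
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("ADF test undefined for a constant series")
    return x


def adf_test(
    series, regression: str = "c", autolag: str | None = "AIC"
) -> tuple[float, float]:
    """Augmented Dickey-Fuller test; returns ``(statistic, p_value)``.

    The null hypothesis is that the series has a unit root; small p-values
    mean stationary.  Missing values are dropped before testing.
    """
    x = _clean(series)
    stat, pvalue = adfuller(x, regression=regression, autolag=autolag)[:2]
    return float(stat), float(pvalue)


class Stationarizer(TransformerMixin, BaseEstimator):
    """Joint differencing transformer driven by ADF tests.

    ``fit`` receives one or more aligned series (a 1-D array/Series or a 2-D
    array/DataFrame with one series per column) and finds the smallest common
    differencing order at which every column rejects the ADF null at
    ``alpha``.  ``transform`` applies that many first differences.

    Attributes
    ----------
    order_ : int
        Number of joint differences applied.
    adf_pvalues_ : ndarray
        Final per-column ADF p-values (all below ``alpha``).
    adf_stats_ : ndarray
        Final per-column ADF statistics.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        max_order: int = 3,
        regression: str = "c",
        autolag: str | None = "AIC",
    ):
        self.alpha = alpha
        self.max_order = max_order
        self.regression = regression
        self.autolag = autolag

    @staticmethod
    def _columns(X) -> list:
        if isinstance(X, pd.DataFrame):
            return [X[c] for c in X.columns]
        if isinstance(X, pd.Series):
            return [X]
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return [X]
        return [X[:, j] for j in range(X.shape[1])]

    def fit(self, X, y=None):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        cols = self._columns(X)
        current = [pd.Series(np.asarray(c, dtype=float)) for c in cols]
        for order in range(self.max_order + 1):
            results = [
                adf_test(c, regression=self.regression, autolag=self.autolag)
                for c in current
            ]
            if all(p < self.alpha for _, p in results):
                self.order_ = order
                self.adf_stats_ = np.array([s for s, _ in results])
                self.adf_pvalues_ = np.array([p for _, p in results])
                self.n_series_ = len(cols)
                return self
            # A difference across an interior gap is a missing value, not a
            # long-lag difference: pandas diff() propagates NaN on both sides.
            current = [c.diff().iloc[1:] for c in current]
        raise NonStationarizableError(
            f"series not jointly stationary after {self.max_order} differences"
        )

    def transform(self, X):
        if not hasattr(self, "order_"):
            raise ValueError("Stationarizer is not fitted")
        out = X
        for _ in range(self.order_):
            if isinstance(out, (pd.Series, pd.DataFrame)):
                out = out.diff().iloc[1:]
            else:
                out = np.diff(np.asarray(out, dtype=float), axis=0)
        return out


@dataclass
class StationarizedPair:
    """Two jointly differenced series with their shared order and final p-values."""

    x: pd.Series
    y: pd.Series
    order: int
    adf_pvalues: tuple[float, float]


def difference_to_stationary(
    series, alpha: float = 0.05, max_order: int = 3, **adf_kwargs
):
    """Difference a single series until the ADF null is rejected.

    Returns ``(differenced_series, order)``.
    """
    st = Stationarizer(alpha=alpha, max_order=max_order, **adf_kwargs).fit(series)
    return st.transform(series), st.order_


def difference_to_stationary_pair(
    x, y, alpha: float = 0.05, max_order: int = 3, **adf_kwargs
) -> StationarizedPair:
    """Jointly difference two aligned series until both reject the ADF null.

    Both series are differenced together even if one is already stationary,
    so they end at the same order (required before correlating or Granger
    testing them).
    """
    x = pd.Series(x, dtype=float) if not isinstance(x, pd.Series) else x.astype(float)
    y = pd.Series(y, dtype=float) if not isinstance(y, pd.Series) else y.astype(float)
    if len(x) != len(y):
        raise ValueError("series must be aligned to equal length")
    st = Stationarizer(alpha=alpha, max_order=max_order, **adf_kwargs).fit(
        pd.DataFrame({"x": x.to_numpy(), "y": y.to_numpy()})
    )
    return StationarizedPair(
        x=st.transform(x),
        y=st.transform(y),
        order=st.order_,
        adf_pvalues=(float(st.adf_pvalues_[0]), float(st.adf_pvalues_[1])),
    )


def truncate_at_first_nonzero(series: pd.Series) -> pd.Series:
    """Drop the leading run of exact zeros (epidemic-series onset rule)."""
    s = pd.Series(series)
    nonzero = np.flatnonzero(s.to_numpy() != 0)
    if len(nonzero) == 0:
        raise DegenerateSeriesError("series is identically zero")
    return s.iloc[nonzero[0]:]
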