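"""ARMAX intervention analysis of sentiment series against policy events.

The daily (stationarized) GMS series of a city is modelled as an
ARMAX(p, q) process

    G_t = sum_i alpha_i G_{t-i} - sum_i gamma_i eps_{t-i}
          + sum_k beta_k z_{kt} + eps_t,

where the z_{kt} are binary policy indicators: single-day impulses for the
three federal announcements (national emergency, distancing-guidelines
extension, reopening guidelines) and a step over the local shelter-in-place
interval.  (p, q) is chosen by scanning a grid and keeping the fit with the
lowest BIC; the standardized effect size of policy k is the z-score
Z_k = beta_k / se(beta_k), judged against the standard normal at the 0.05
level.

Estimation is exact maximum likelihood via the state-space ARIMA machinery
in statsmodels.  Note statsmodels parameterizes the MA polynomial with a
plus sign; reported ``ma_coeffs_`` are negated so they follow the minus
convention of the model written above.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.tsa.arima.model import ARIMA

from .ingest import EVENT_NAMES, PolicyEvent

logger = logging.getLogger(__name__)

#: Two-sided 5% critical value of the standard normal.
Z_CRIT = float(stats.norm.ppf(0.975))


class ScanError(RuntimeError):
    """No cell of the (p, q) grid produced a converged fit."""


def build_policy_indicators(
    events: Iterable[PolicyEvent],
    city: str,
    date_range: Sequence[dt.date] | pd.Index,
) -> pd.DataFrame:
    """Expand policy events into a binary indicator matrix for one city.

    Returns a DataFrame indexed by the dates of ``date_range`` with one
    column per event key k=1..4 (named after the event).  Impulse columns
    carry a single 1 on the announcement date; the shelter-in-place step
    carries 1 over ``[start, end]`` inclusive, with a missing end running to
    the window end.  An event dated outside the window yields an all-zero
    column with a warning.
    """
    idx = pd.Index(list(date_range), name="date")
    z = pd.DataFrame(0, index=idx, columns=[EVENT_NAMES[k] for k in (1, 2, 3, 4)])
    for ev in events:
        if ev.kind == "impulse":
            if ev.date in idx:
                z.loc[ev.date, ev.name] = 1
            else:
                logger.warning(
                    "impulse %s on %s is outside the window; all-zero column",
                    ev.name, ev.date,
                )
        else:
            if ev.city != city:
                continue
            end = ev.end if ev.end is not None else idx[-1]
            mask = [(ev.start <= d <= end) for d in idx]
            if not any(mask):
                logger.warning(
                    "step %s for %s (%s..%s) is outside the window",
                    ev.name, city, ev.start, ev.end,
                )
            z.loc[mask, ev.name] = 1
    return z


class ArmaxIntervention(BaseEstimator):
    """ARMAX(p, q) intervention model with optional BIC order scan.

    Parameters
    ----------
    p, q : int or None
        ARMA orders.  When either is None, ``fit`` scans the grid
        ``[0, p_max] x [0, q_max]`` and keeps the converged fit with the
        lowest BIC (ties within 1e-9 broken by smaller p + q, then smaller
        q).
    p_max, q_max : int
        Grid bounds for the scan.
    trend : str
        Deterministic term passed to the ARIMA backend ("c" keeps an
        intercept, appropriate for sentiment series with nonzero mean).
    alpha : float
        Two-sided significance level for the effect z-scores.

    Attributes
    ----------
    p_, q_ : selected orders.
    ar_coeffs_, ma_coeffs_ : fitted ARMA coefficients (MA in the minus
        convention of the model equation).
    beta_, se_, zscores_ : per-indicator effect estimates, standard errors
        and standardized z-scores (indexed by indicator name).
    sigma2_ : innovation variance.
    bic_ : BIC of the selected fit.
    converged_ : bool.
    dropped_exog_ : indicator columns dropped for having no variation.
    scan_table_ : DataFrame of (p, q, bic, converged) when a scan ran.
    """

    def __init__(
        self,
        p: int | None = None,
        q: int | None = None,
        p_max: int = 7,
        q_max: int = 7,
        trend: str = "c",
        alpha: float = 0.05,
    ):
        self.p = p
        self.q = q
        self.p_max = p_max
        self.q_max = q_max
        self.trend = trend
        self.alpha = alpha

    # -- internal ---------------------------------------------------------

    def _fit_cell(self, y, exog, p, q):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                # OIM covariance: the default outer-product-of-gradients
                # standard errors degenerate for one-day impulse dummies
                # (the dummy absorbs its own residual, so its score vanishes).
                res = ARIMA(
                    y, exog=exog, order=(p, 0, q), trend=self.trend
                ).fit(cov_type="oim", method_kwargs={"maxiter": 200})
            except (np.linalg.LinAlgError, ValueError) as exc:
                logger.warning("ARMAX(%d,%d) failed: %s", p, q, exc)
                return None, False
        converged = bool(res.mle_retvals.get("converged", True))
        if not np.isfinite(res.bic):
            converged = False
        return res, converged

    # -- sklearn surface --------------------------------------------------

    def fit(self, y, X=None):
        """Fit to a stationarized series ``y`` and indicator matrix ``X``.

        ``X`` columns with no variation (e.g. an event outside the window)
        are dropped and recorded in ``dropped_exog_``; with no informative
        column left the model reduces to a plain ARMA.
        """
        y = pd.Series(y, dtype=float).dropna() if not isinstance(y, pd.Series) else y.dropna().astype(float)
        exog = None
        self.exog_names_: list[str] = []
        self.dropped_exog_: list[str] = []
        if X is not None:
            X = pd.DataFrame(X).loc[y.index] if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
            for col in X.columns:
                if X[col].nunique() > 1:
                    self.exog_names_.append(str(col))
                else:
                    self.dropped_exog_.append(str(col))
            if self.exog_names_:
                exog = X[[c for c in X.columns if str(c) in self.exog_names_]].to_numpy(dtype=float)
        n_beta = len(self.exog_names_)
        min_len = (self.p or 0) + (self.q or 0) + n_beta + 5
        if len(y) <= min_len:
            raise ValueError(f"series too short ({len(y)}) for the requested model")
        yv = y.to_numpy(dtype=float)
        if np.ptp(yv) == 0:
            raise ValueError("cannot fit an ARMAX model to a constant series")

        if self.p is not None and self.q is not None:
            res, converged = self._fit_cell(yv, exog, self.p, self.q)
            if res is None:
                raise ScanError(f"ARMAX({self.p},{self.q}) did not fit")
            self.p_, self.q_ = self.p, self.q
            self.scan_table_ = None
        else:
            rows = []
            best = None
            for p in range(self.p_max + 1):
                for q in range(self.q_max + 1):
                    r, ok = self._fit_cell(yv, exog, p, q)
                    bic = float(r.bic) if (r is not None and ok) else np.nan
                    rows.append({"p": p, "q": q, "bic": bic, "converged": ok})
                    if r is not None and ok:
                        key = (bic, p + q, q)
                        if best is None or _bic_better(key, best[0]):
                            best = (key, p, q, r)
            self.scan_table_ = pd.DataFrame(rows)
            if best is None:
                raise ScanError("no (p, q) cell converged in the BIC scan")
            _, self.p_, self.q_, res = best
            converged = True

        self.results_ = res
        self.converged_ = converged
        self.ar_coeffs_ = np.asarray(res.arparams, dtype=float)
        self.ma_coeffs_ = -np.asarray(res.maparams, dtype=float)  # minus convention
        self.sigma2_ = float(res.params[-1])
        self.bic_ = float(res.bic)
        params = pd.Series(res.params, index=res.param_names)
        bses = pd.Series(res.bse, index=res.param_names)
        # statsmodels names exog params x1..xk in input order
        keys = [f"x{i + 1}" for i in range(n_beta)]
        self.beta_ = pd.Series(
            [float(params[k]) for k in keys], index=self.exog_names_, dtype=float
        )
        self.se_ = pd.Series(
            [float(bses[k]) for k in keys], index=self.exog_names_, dtype=float
        )
        if (self.se_ == 0).any():
            raise ZeroDivisionError("zero standard error; effect size undefined")
        self.zscores_ = self.beta_ / self.se_
        return self

    def significant(self) -> pd.Series:
        """Boolean per-indicator flags: |Z| at or beyond the normal critical value."""
        crit = float(stats.norm.ppf(1 - self.alpha / 2))
        return self.zscores_.abs() >= crit


def _bic_better(key, ref) -> bool:
    """Order scan cells by BIC with a 1e-9 tie window, then parsimony (p+q, q)."""
    if key[0] < ref[0] - 1e-9:
        return True
    if key[0] > ref[0] + 1e-9:
        return False
    return key[1:] < ref[1:]


def fit_armax(y, z, p: int, q: int, trend: str = "c") -> ArmaxIntervention:
    """Fit a single ARMAX(p, q) cell (thin wrapper over :class:`ArmaxIntervention`)."""
    return ArmaxIntervention(p=p, q=q, trend=trend).fit(y, z)


def scan_armax(y, z, p_max: int = 7, q_max: int = 7, trend: str = "c") -> ArmaxIntervention:
    """BIC scan over the (p, q) grid; returns the best converged fit."""
    return ArmaxIntervention(p_max=p_max, q_max=q_max, trend=trend).fit(y, z)


def intervention_zscores(
    model: ArmaxIntervention, city: str = "", topic: str = ""
) -> pd.DataFrame:
    """Tabulate standardized policy effects Z_k = beta_k / se_k of a fitted model.

    Returns one row per indicator with columns
    ``city, topic, k, event, beta_hat, se, z, significant, p, q, bic``.
    """
    if not getattr(model, "converged_", False):
        raise ValueError("effects require a converged fit")
    name_to_k = {v: k for k, v in EVENT_NAMES.items()}
    sig = model.significant()
    rows = []
    for name in model.beta_.index:
        rows.append(
            {
                "city": city,
                "topic": topic,
                "k": name_to_k.get(name, np.nan),
                "event": name,
                "beta_hat": model.beta_[name],
                "se": model.se_[name],
                "z": model.zscores_[name],
                "significant": bool(sig[name]),
                "p": model.p_,
                "q": model.q_,
                "bic": model.bic_,
            }
        )
    return pd.DataFrame(rows)


def count_significant_responses(
    effects: pd.DataFrame, city: str, topic: str = "overall"
) -> int:
    """Number of policy events (0-4) with |Z| past the critical value."""
    sel = effects[(effects["city"] == city) & (effects["topic"] == topic)]
    return int((sel["z"].abs() >= Z_CRIT).sum())


def regress_effect_sizes(
    effects: pd.DataFrame,
    topic: str,
    k_x: int,
    k_y: int,
    outlier_cut: float = 10.0,
):
    """OLS of per-city effect sizes for one policy against another.

    Cities where either |Z| exceeds ``outlier_cut`` are treated as extreme
    outliers and omitted.  Returns
    ``(slope, intercept, pearson_r, p_value, n_used)``; the p-value is the
    two-sided test of zero correlation.
    """
    sel = effects[effects["topic"] == topic]
    wide = sel.pivot(index="city", columns="k", values="z")
    if k_x not in wide.columns or k_y not in wide.columns:
        raise ValueError(f"effects table lacks events {k_x} and/or {k_y}")
    pair = wide[[k_x, k_y]].dropna()
    pair = pair[(pair.abs() <= outlier_cut).all(axis=1)]
    if len(pair) < 3:
        raise ValueError(f"only {len(pair)} cities after outlier cut; need >= 3")
    fit = stats.linregress(pair[k_x], pair[k_y])
    return (
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue),
        float(fit.pvalue),
        int(len(pair)),
    )
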