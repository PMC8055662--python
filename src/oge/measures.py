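"""Geolocalized mean sentiment (GMS) and cross-city coherence.

The daily GMS of a city for a topic scores each post +1 (positive),
0 (neutral or mixed) or -1 (negative) and averages:

    G = (P - N) / T,   T = P + M + N > 0,

which equals the positive fraction minus the negative fraction and lies in
[-1, 1].  Stacking the five subtopic values gives a city's GMS vector in R^5
(fixed component order below); the coherence phi(t) is the average pairwise
angle, in degrees, between all usable city vectors on day t.  Low coherence
values mean cities' topic-sentiment profiles point the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Fixed component order of the five-topic GMS vector.
VECTOR_TOPICS = ("distancing", "China", "TA", "economy", "mask")

#: Tolerance for clamping cosines into [-1, 1] before arccos.
_COS_CLAMP_TOL = 1e-12


def gms(P: float, M: float, N: float) -> float:
    """Mean sentiment of ``P`` positive, ``M`` neutral/mixed, ``N`` negative posts.

    Returns ``(P - N) / (P + M + N)``; ``nan`` when there are no posts
    (a day with no posts is missing, never zero).
    """
    if min(P, M, N) < 0:
        raise ValueError("counts must be non-negative")
    T = P + M + N
    if T == 0:
        return math.nan
    return (P - N) / T


def gms_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add a ``gms`` column to a ``(city, date, topic, P, M, N, T)`` counts table."""
    out = counts.copy()
    T = out["T"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["gms"] = np.where(T > 0, (out["P"] - out["N"]) / np.where(T > 0, T, 1), np.nan)
    return out


def gms_series(
    table: pd.DataFrame, city: str, topic: str, dates: pd.Index | None = None
) -> pd.Series:
    """Extract one city/topic GMS series indexed by date.

    ``dates`` (optional) reindexes onto a full calendar so absent days become
    missing values.
    """
    sel = table[(table["city"] == city) & (table["topic"] == topic)]
    s = pd.Series(sel["gms"].to_numpy(), index=pd.Index(sel["date"], name="date"))
    if dates is not None:
        s = s.reindex(dates)
    return s.rename(f"{city}:{topic}")


def gms_vector_table(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a GMS table to per-(city, date) five-topic vectors.

    Returns a frame indexed by ``(city, date)`` with one column per
    :data:`VECTOR_TOPICS` entry plus a boolean ``usable`` column.  A vector is
    unusable when any component is missing or all components are exactly zero
    (its direction, hence any angle, is undefined).
    """
    wide = (
        table[table["topic"].isin(VECTOR_TOPICS)]
        .pivot(index=["city", "date"], columns="topic", values="gms")
        .reindex(columns=list(VECTOR_TOPICS))
    )
    comp = wide.to_numpy(dtype=float)
    usable = ~np.isnan(comp).any(axis=1) & (np.abs(comp).sum(axis=1) > 0)
    wide["usable"] = usable
    return wide


def pair_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees between two GMS vectors (arccos of cosine similarity).

    Scale-invariant and symmetric; 0 for collinear, 90 for orthogonal, 180
    for anti-parallel vectors.  Zero-norm inputs have no direction and raise.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("angle undefined for zero-norm GMS vector")
    c = float(v1 @ v2) / (n1 * n2)
    if c > 1 + _COS_CLAMP_TOL or c < -1 - _COS_CLAMP_TOL:
        raise ValueError(f"cosine {c} outside [-1, 1]")
    # snap to the endpoints so collinear vectors give exactly 0 / 180 degrees
    if c >= 1 - _COS_CLAMP_TOL:
        return 0.0
    if c <= -1 + _COS_CLAMP_TOL:
        return 180.0
    return math.degrees(math.acos(c))


def coherence(vectors: np.ndarray) -> tuple[float, int]:
    """Average pairwise angle (degrees) over a set of usable GMS vectors.

    Parameters
    ----------
    vectors
        Array of shape ``(n, 5)`` of nonzero vectors.

    Returns
    -------
    ``(phi, n_pairs)`` where ``phi`` is the unweighted mean of the angle over
    all unordered pairs and ``n_pairs = n(n-1)/2``.  With fewer than two
    vectors the day carries no information: ``(nan, 0)``.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(vectors, axis=1)
    if (norms == 0).any():
        raise ValueError("coherence requires nonzero vectors")
    n = len(vectors)
    if n < 2:
        return math.nan, 0
    unit = vectors / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    iu = np.triu_indices(n, k=1)
    angles = np.degrees(np.arccos(cos[iu]))
    angles[cos[iu] >= 1 - _COS_CLAMP_TOL] = 0.0  # same endpoint snap as pair_angle
    angles[cos[iu] <= -1 + _COS_CLAMP_TOL] = 180.0
    return float(angles.mean()), n * (n - 1) // 2


@dataclass
class CoherenceSeries:
    """Daily coherence values and the number of city pairs each one used."""

    values: pd.Series  # date -> phi in degrees
    n_pairs_used: pd.Series  # date -> int


def coherence_series(table: pd.DataFrame, exclude: tuple[str, ...] = ()) -> CoherenceSeries:
    """Compute the daily coherence across cities from a GMS table.

    Cities listed in ``exclude`` (e.g. the pooled national pseudo-city) are
    left out.  Days with fewer than two usable vectors are missing.
    """
    vectors = gms_vector_table(table)
    if exclude:
        keep = ~vectors.index.get_level_values("city").isin(exclude)
        vectors = vectors[keep]
    phis, npairs, dates = [], [], []
    for date, group in vectors.groupby(level="date", sort=True):
        usable = group[group["usable"]]
        dates.append(date)
        if len(usable) < 2:
            phis.append(math.nan)
            npairs.append(0)
        else:
            phi, n = coherence(usable[list(VECTOR_TOPICS)].to_numpy())
            phis.append(phi)
            npairs.append(n)
    idx = pd.Index(dates, name="date")
    return CoherenceSeries(
        values=pd.Series(phis, index=idx, name="phi_degrees"),
        n_pairs_used=pd.Series(npairs, index=idx, name="n_pairs"),
    )


def moving_average(series: pd.Series, window: int, align: str = "trailing") -> pd.Series:
    """Moving mean over the last ``window`` available values.

    Trailing (right-aligned) by default so smoothed values never use future
    data; ``align="centered"`` is available for presentation.  Missing values
    are skipped — the divisor is the count of present values in the window —
    and the first ``window - 1`` positions use the shorter available prefix.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    center = {"trailing": False, "centered": True}.get(align)
    if center is None:
        raise ValueError(f"unknown alignment {align!r}")
    return series.rolling(window, min_periods=1, center=center).mean()
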