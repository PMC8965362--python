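"""Tree-ring processing: BAI conversion, spline detrending, dating checks,
robust-mean chronologies, and bootstrapped climate-growth correlations.

Ring widths are converted to basal area increments as annulus areas,
BAI_t = pi * (r_t^2 - r_{t-1}^2) with r_t the cumulative radius.  Detrending
divides each BAI series by a cubic smoothing-spline growth curve whose
flexibility is set by its frequency response f at a chosen wavelength
(the Cook-Peters convention: f = 0.7 at two thirds of the series length unless
told otherwise), yielding dimensionless growth indices that fluctuate around 1.
Site/family chronologies are per-year Tukey biweight robust means of those
indices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded

__all__ = [
    "RingSeries",
    "Chronology",
    "width_to_bai",
    "bai_to_width",
    "smoothing_spline",
    "detrend_spline",
    "check_dating",
    "tukey_biweight_mean",
    "build_chronology",
    "bootstrap_climate_correlation",
]


@dataclass
class RingSeries:
    """Yearly series for one tree: ring width (mm), BAI (mm^2) or unitless index."""

    tree_id: str
    first_year: int
    values: np.ndarray
    kind: str = "width"  # width | bai | index

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("ring series must be a non-empty 1-d array")
        if self.kind not in ("width", "bai", "index"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.kind in ("width", "bai") and (self.values <= 0).any():
            year = self.first_year + int(np.argmax(self.values <= 0))
            raise ValueError(f"non-positive {self.kind} value in year {year}")

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(len(self.values))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    def value_in(self, year: int) -> float:
        if not self.first_year <= year <= self.last_year:
            raise KeyError(f"{self.tree_id}: year {year} outside series")
        return float(self.values[year - self.first_year])

    def window(self, lo: int, hi: int) -> np.ndarray:
        """Values for years lo..hi inclusive; raises if not fully covered."""
        if lo < self.first_year or hi > self.last_year:
            raise KeyError(f"{self.tree_id}: window {lo}-{hi} outside series")
        return self.values[lo - self.first_year : hi - self.first_year + 1]


@dataclass
class Chronology:
    """Robust mean index per year with the number of contributing series."""

    data: pd.DataFrame  # columns: year, index, depth

    def __post_init__(self) -> None:
        if (self.data["depth"] < 1).any():
            raise ValueError("chronology has years with zero sample depth")

    def value_in(self, year: int) -> float:
        row = self.data[self.data["year"] == year]
        if row.empty:
            raise KeyError(f"no chronology value for {year}")
        return float(row["index"].iloc[0])

    @property
    def years(self) -> np.ndarray:
        return self.data["year"].to_numpy()

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.8g")


def width_to_bai(series: RingSeries, r0: float = 0.0) -> RingSeries:
    """Basal area increment from ring widths (annulus areas from the pith by default)."""
    if series.kind != "width":
        raise ValueError("width_to_bai expects a width series")
    radii = r0 + np.cumsum(series.values)
    prev = np.concatenate([[r0], radii[:-1]])
    bai = np.pi * (radii**2 - prev**2)
    return replace(series, values=bai, kind="bai")


def bai_to_width(series: RingSeries, r0: float = 0.0) -> RingSeries:
    """Exact inverse of :func:`width_to_bai`."""
    if series.kind != "bai":
        raise ValueError("bai_to_width expects a BAI series")
    areas = np.pi * r0**2 + np.cumsum(series.values)
    radii = np.sqrt(areas / np.pi)
    widths = np.diff(np.concatenate([[r0], radii]))
    return replace(series, values=widths, kind="width")


def _spline_smoothing_parameter(f: float, wavelength: float) -> float:
    """Penalty weight giving amplitude response ``f`` at ``wavelength`` years.

    The discrete cubic smoothing spline acts on equally spaced data as the
    filter (I + a*K)^-1 whose symbol is 1 / (1 + a*12(1-cos t)^2/(2+cos t));
    solving for a at t = 2*pi/wavelength gives the Cook-Peters style mapping
    from a stated frequency response to a penalty weight.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError("frequency response f must be in (0, 1]")
    if wavelength <= 2.0:
        raise ValueError("wavelength must exceed 2 years")
    if f == 1.0:
        return 0.0
    t = 2.0 * np.pi / wavelength
    return (1.0 / f - 1.0) * (2.0 + np.cos(t)) / (12.0 * (1.0 - np.cos(t)) ** 2)


def smoothing_spline(y: np.ndarray, f: float = 0.7, wavelength: float | None = None) -> np.ndarray:
    """Natural cubic smoothing spline on unit-spaced data (Reinsch banded solve)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("series too short to detrend (need >= 4 years)")
    if wavelength is None:
        wavelength = 0.67 * n
    lam = _spline_smoothing_parameter(f, wavelength)
    if lam == 0.0:
        return y.copy()
    # Reinsch: solve (R + lam * Q'Q) c = Q'y, then s = y - lam * Q c,
    # Q the (n x n-2) second-difference matrix, R tridiag(1/6, 2/3, 1/6).
    m = n - 2
    d2 = y[:-2] - 2.0 * y[1:-1] + y[2:]
    # banded upper form of R + lam Q'Q (pentadiagonal symmetric)
    ab = np.zeros((3, m))
    ab[2, :] = 2.0 / 3.0 + 6.0 * lam
    ab[1, 1:] = 1.0 / 6.0 - 4.0 * lam
    ab[0, 2:] = lam
    c = solveh_banded(ab, d2)
    # s = y - lam * Q c  (Q c expands c by the second-difference stencil)
    qc = np.zeros(n)
    qc[:-2] += c
    qc[1:-1] -= 2.0 * c
    qc[2:] += c
    return y - lam * qc


def detrend_spline(
    series: RingSeries, f: float = 0.7, wavelength: float | None = None
) -> tuple[RingSeries, np.ndarray]:
    """Ratio-detrend a BAI series against its smoothing-spline growth curve.

    Returns the index series and the fitted curve.  The curve must stay
    strictly positive; otherwise ratio detrending is undefined and an error
    suggests a different detrending choice.
    """
    if series.kind != "bai":
        raise ValueError("detrend_spline expects a BAI series")
    curve = smoothing_spline(series.values, f=f, wavelength=wavelength)
    if (curve <= 0).any():
        year = series.first_year + int(np.argmax(curve <= 0))
        raise ValueError(
            f"{series.tree_id}: fitted growth curve non-positive at {year}; "
            "use a stiffer spline or a different detrending method"
        )
    index = series.values / curve
    return replace(series, values=index, kind="index"), curve


def check_dating(
    series_set: list[RingSeries], threshold: float = 0.2, min_overlap: int = 5
) -> pd.DataFrame:
    """Flag series whose correlation with the leave-one-out site master is low.

    Each (detrended) series is correlated against the mean of all other series
    over the overlapping years; low correlation is the classic symptom of a
    dating (ring-assignment) error.
    """
    if len(series_set) < 3:
        raise ValueError("dating check needs at least 3 series")
    years_all = np.arange(
        min(s.first_year for s in series_set), max(s.last_year for s in series_set) + 1
    )
    mat = np.full((len(series_set), len(years_all)), np.nan)
    for i, s in enumerate(series_set):
        lo = s.first_year - years_all[0]
        mat[i, lo : lo + len(s.values)] = s.values

    rows = []
    for i, s in enumerate(series_set):
        others = np.delete(mat, i, axis=0)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            master = np.nanmean(others, axis=0)
        both = np.isfinite(mat[i]) & np.isfinite(master)
        if both.sum() < min_overlap:
            rows.append((s.tree_id, np.nan, True, "insufficient overlap"))
            continue
        x, y = mat[i][both], master[both]
        r = float(np.corrcoef(x, y)[0, 1]) if (x.std() > 0 and y.std() > 0) else np.nan
        flagged = (not np.isfinite(r)) or r < threshold
        rows.append((s.tree_id, r, flagged, "low master correlation" if flagged else ""))
    return pd.DataFrame(rows, columns=["tree_id", "master_correlation", "flagged", "reason"])


def tukey_biweight_mean(values: np.ndarray, c: float = 9.0, max_iter: int = 20) -> float:
    """Tukey biweight robust location (median start, MAD scale), the standard
    dendro robust mean."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("no finite values")
    m = float(np.median(v))
    for _ in range(max_iter):
        s = float(np.median(np.abs(v - m)))
        if s == 0.0:
            return m
        u = (v - m) / (c * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0.0:
            return m
        new = float(np.sum(w * v) / np.sum(w))
        if abs(new - m) < 1e-12:
            return new
        m = new
    return m


def build_chronology(
    series_set: list[RingSeries],
    min_depth: int = 1,
    min_depth_fraction: float | None = None,
) -> Chronology:
    """Per-year Tukey biweight mean of index series with sample depth.

    ``min_depth_fraction`` applies the "at least this share of trees present"
    subsetting (e.g. 0.5) on top of the absolute ``min_depth``.
    """
    if not series_set:
        raise ValueError("cannot build a chronology from no series")
    year_lo = min(s.first_year for s in series_set)
    year_hi = max(s.last_year for s in series_set)
    rows = []
    for year in range(year_lo, year_hi + 1):
        vals = [
            s.values[year - s.first_year]
            for s in series_set
            if s.first_year <= year <= s.last_year
        ]
        depth = len(vals)
        if depth < max(min_depth, 1):
            continue
        if min_depth_fraction is not None and depth < min_depth_fraction * len(series_set):
            continue
        rows.append((year, tukey_biweight_mean(np.array(vals)), depth))
    return Chronology(pd.DataFrame(rows, columns=["year", "index", "depth"]))


def bootstrap_climate_correlation(
    chron: Chronology,
    climate,
    months: tuple[int, ...] = (5, 6, 7, 8),
    lags: tuple[str, ...] = ("previous", "current"),
    n_boot: int = 1000,
    seed: int = 0,
    column: str = "dc_raw",
) -> pd.DataFrame:
    """Bootstrapped Pearson correlations between a chronology and monthly DC.

    For each (month, lag) pair growth in year t is aligned with that month's DC
    of year t (current) or t-1 (previous); years are resampled with replacement
    to form a 95% percentile confidence interval, and the correlation is called
    significant when the interval excludes zero.
    """
    rng = np.random.default_rng(seed)
    cl = climate.data
    rows = []
    for lag in lags:
        if lag not in ("previous", "current"):
            raise ValueError(f"unknown lag {lag!r}")
        offset = 0 if lag == "current" else 1
        for month in months:
            mdc = cl[cl["month"] == month].set_index("year")[column]
            growth_years = chron.years
            pairs = [
                (chron.value_in(t), mdc.loc[t - offset])
                for t in growth_years
                if (t - offset) in mdc.index
            ]
            if len(pairs) < 8:
                raise ValueError(
                    f"month {month} lag {lag}: only {len(pairs)} overlapping years (need >= 8)"
                )
            g = np.array([p[0] for p in pairs])
            d = np.array([p[1] for p in pairs])
            r = float(np.corrcoef(g, d)[0, 1])
            n = len(g)
            idx = rng.integers(0, n, size=(n_boot, n))
            gs, ds = g[idx], d[idx]
            gm = gs - gs.mean(axis=1, keepdims=True)
            dm = ds - ds.mean(axis=1, keepdims=True)
            denom = np.sqrt((gm**2).sum(axis=1) * (dm**2).sum(axis=1))
            ok = denom > 0
            boots = np.where(ok, (gm * dm).sum(axis=1) / np.where(ok, denom, 1.0), np.nan)
            lo, hi = np.nanpercentile(boots, [2.5, 97.5])
            rows.append((month, lag, r, float(lo), float(hi), bool(lo > 0 or hi < 0)))
    return pd.DataFrame(
        rows, columns=["month", "lag", "r", "ci_low", "ci_high", "significant"]
    )
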