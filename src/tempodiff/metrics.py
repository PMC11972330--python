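"""Twelve time-series dissimilarity measures between a gene's WT and KO series.

Each measure compares the two jointly minmax-scaled series of one profile
pair. The set spans complementary notions of divergence: pointwise magnitude
(euclidean, cid, fourier), local slope (sts), elastic alignment (dtw, tam,
frechet), linear association (cor), serial dependence (acf), spectral shape
(per, int.per) and algorithmic similarity (cdm). The canonical published
definition is used for every name; free parameters live in
:class:`MetricParams` and are recorded in output metadata.

Per-pair functions take ``(x, y, time_vector=None, params=None)`` and return
a non-negative float. :func:`compute_distance_table` evaluates all requested
metrics over a whole :class:`~tempodiff.normalize.ProfileSet` with vectorized
fast paths that are tested to match the per-pair definitions exactly.
"""

from __future__ import annotations

import lzma
import zlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import fft as sfft

from ._errors import ConfigError, DataError
from .normalize import ProfilePair, ProfileSet

__all__ = [
    "MetricParams",
    "METRIC_NAMES",
    "d_euclidean",
    "d_sts",
    "d_dtw",
    "d_tam",
    "d_acf",
    "d_fourier",
    "d_cdm",
    "d_cid",
    "d_cor",
    "d_per",
    "d_intper",
    "d_frechet",
    "compute_distance",
    "compute_distance_table",
]

#: Canonical metric names, in screen output order.
METRIC_NAMES = (
    "euclidean",
    "sts",
    "dtw",
    "tam",
    "acf",
    "fourier",
    "cdm",
    "cid",
    "cor",
    "int.per",
    "per",
    "frechet",
)


@dataclass(frozen=True)
class MetricParams:
    """Free parameters of the metric family.

    ``None`` means "derive the conventional default from the series length T":
    acf_max_lag = T-2, fourier_n_coef = floor(T/2)+1, per_n_freq = floor(T/2).
    """

    acf_max_lag: int | None = None
    fourier_n_coef: int | None = None
    cdm_alphabet_size: int = 8
    cdm_compressor: str = "lzma"  # or "deflate"
    cid_epsilon: float = 1e-12
    per_n_freq: int | None = None
    frechet_embedding: str = "value_only"  # or "time_value"

    def resolve(self, n_timepoints: int) -> "ResolvedParams":
        T = n_timepoints
        acf_lag = self.acf_max_lag if self.acf_max_lag is not None else max(T - 2, 1)
        n_coef = self.fourier_n_coef if self.fourier_n_coef is not None else T // 2 + 1
        n_freq = self.per_n_freq if self.per_n_freq is not None else max(T // 2, 1)
        if not 1 <= acf_lag <= T - 1:
            raise ConfigError(f"acf_max_lag={acf_lag} outside [1, T-1]={T - 1}")
        if not 1 <= n_coef <= T:
            raise ConfigError(f"fourier_n_coef={n_coef} outside [1, T]={T}")
        if not 1 <= n_freq <= T - 1:
            raise ConfigError(f"per_n_freq={n_freq} outside [1, T-1]")
        if self.cdm_alphabet_size < 2:
            raise ConfigError("cdm_alphabet_size must be >= 2")
        if self.cdm_compressor not in ("lzma", "deflate"):
            raise ConfigError("cdm_compressor must be 'lzma' or 'deflate'")
        if self.frechet_embedding not in ("value_only", "time_value"):
            raise ConfigError("frechet_embedding must be 'value_only' or 'time_value'")
        return ResolvedParams(
            acf_max_lag=acf_lag,
            fourier_n_coef=n_coef,
            cdm_alphabet_size=self.cdm_alphabet_size,
            cdm_compressor=self.cdm_compressor,
            cid_epsilon=self.cid_epsilon,
            per_n_freq=n_freq,
            frechet_embedding=self.frechet_embedding,
        )


@dataclass(frozen=True)
class ResolvedParams:
    acf_max_lag: int
    fourier_n_coef: int
    cdm_alphabet_size: int
    cdm_compressor: str
    cid_epsilon: float
    per_n_freq: int
    frechet_embedding: str


def _prep(x, y, time_vector, params: MetricParams | None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("series must be 1-D and of equal length")
    if x.size < 2:
        raise DataError("series must have at least 2 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in series")
    if time_vector is None:
        t = np.arange(x.size, dtype=float)
    else:
        t = np.asarray(time_vector, dtype=float)
        if t.size != x.size or not np.all(np.diff(t) > 0):
            raise DataError("time_vector must be strictly increasing and match series length")
    p = (params or MetricParams()).resolve(x.size)
    return x, y, t, p


def _as_pair(pair_or_x, y):
    if isinstance(pair_or_x, ProfilePair):
        return pair_or_x.wt, pair_or_x.ko, pair_or_x.time_vector
    return pair_or_x, y, None


# ---------------------------------------------------------------------------
# pointwise / slope / complexity
# ---------------------------------------------------------------------------
def d_euclidean(x, y=None, time_vector=None, params=None) -> float:
    """Euclidean distance sqrt(sum_i (x_i - y_i)^2)."""
    x, y, tv = _as_pair(x, y)
    x, y, _, _ = _prep(x, y, time_vector if tv is None else tv, params)
    return float(np.sqrt(np.sum((x - y) ** 2)))


def d_sts(x, y=None, time_vector=None, params=None) -> float:
    """Short-time-series distance: Euclidean distance between slope sequences.

    Slopes are first differences divided by the time-grid spacing, so the
    measure ignores constant offsets and weights changes by how fast they
    happen on the actual (possibly uneven) sampling grid.
    """
    x, y, tv = _as_pair(x, y)
    x, y, t, _ = _prep(x, y, time_vector if tv is None else tv, params)
    dt = np.diff(t)
    sx = np.diff(x) / dt
    sy = np.diff(y) / dt
    return float(np.sqrt(np.sum((sy - sx) ** 2)))


def d_cid(x, y=None, time_vector=None, params=None) -> float:
    """Complexity-invariant distance: Euclidean distance times a complexity ratio.

    CE(z) = sqrt(sum (z_{i+1} - z_i)^2); the correction factor
    (max(CEx, CEy) + eps) / (min(CEx, CEy) + eps) penalizes comparing a
    wiggly series with a smooth one.
    """
    x, y, tv = _as_pair(x, y)
    x, y, _, p = _prep(x, y, time_vector if tv is None else tv, params)
    ce_x = np.sqrt(np.sum(np.diff(x) ** 2))
    ce_y = np.sqrt(np.sum(np.diff(y) ** 2))
    eps = p.cid_epsilon
    factor = (max(ce_x, ce_y) + eps) / (min(ce_x, ce_y) + eps)
    return float(np.sqrt(np.sum((x - y) ** 2)) * factor)


def d_cor(x, y=None, time_vector=None, params=None) -> float:
    """Pearson-correlation dissimilarity sqrt(2(1 - rho)).

    If either series is constant, rho is undefined and set to 0 by
    convention, giving sqrt(2).
    """
    x, y, tv = _as_pair(x, y)
    x, y, _, _ = _prep(x, y, time_vector if tv is None else tv, params)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    rho = 0.0 if denom == 0 else float(np.sum(xc * yc) / denom)
    rho = min(max(rho, -1.0), 1.0)
    return float(np.sqrt(2.0 * (1.0 - rho)))


# ---------------------------------------------------------------------------
# autocorrelation / spectral
# ---------------------------------------------------------------------------
def _acf_vector(z: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelations rho(1..max_lag); constant series -> 0."""
    zc = z - z.mean()
    denom = np.sum(zc**2)
    if denom == 0:
        return np.zeros(max_lag)
    return np.array([np.sum(zc[:-k] * zc[k:]) / denom for k in range(1, max_lag + 1)])


def d_acf(x, y=None, time_vector=None, params=None) -> float:
    """Autocorrelation-based dissimilarity: Euclidean distance between the
    biased sample autocorrelation vectors at lags 1..acf_max_lag."""
    x, y, tv = _as_pair(x, y)
    x, y, _, p = _prep(x, y, time_vector if tv is None else tv, params)
    rx = _acf_vector(x, p.acf_max_lag)
    ry = _acf_vector(y, p.acf_max_lag)
    return float(np.sqrt(np.sum((rx - ry) ** 2)))


def d_fourier(x, y=None, time_vector=None, params=None) -> float:
    """Distance between the first ``fourier_n_coef`` unnormalized DFT
    coefficients: sqrt(sum_k |X_k - Y_k|^2)."""
    x, y, tv = _as_pair(x, y)
    x, y, _, p = _prep(x, y, time_vector if tv is None else tv, params)
    X = sfft.fft(x)[: p.fourier_n_coef]
    Y = sfft.fft(y)[: p.fourier_n_coef]
    return float(np.sqrt(np.sum(np.abs(X - Y) ** 2)))


def _periodogram(z: np.ndarray, n_freq: int) -> np.ndarray:
    """P(k) = |Z_k|^2 / T at Fourier frequencies k = 1..n_freq (DC excluded)."""
    Z = sfft.fft(z)
    return (np.abs(Z[1 : n_freq + 1]) ** 2) / z.size


def d_per(x, y=None, time_vector=None, params=None) -> float:
    """Periodogram dissimilarity: Euclidean distance between raw periodogram
    ordinates at the first ``per_n_freq`` nonzero Fourier frequencies."""
    x, y, tv = _as_pair(x, y)
    x, y, _, p = _prep(x, y, time_vector if tv is None else tv, params)
    px = _periodogram(x, p.per_n_freq)
    py = _periodogram(y, p.per_n_freq)
    return float(np.sqrt(np.sum((px - py) ** 2)))


def _cumulative_periodogram(z: np.ndarray, n_freq: int) -> np.ndarray:
    """Normalized cumulative periodogram F(1..K); zero total power -> k/K ramp."""
    p = _periodogram(z, n_freq)
    total = p.sum()
    if total == 0:
        return np.arange(1, n_freq + 1) / n_freq
    return np.cumsum(p) / total


def d_intper(x, y=None, time_vector=None, params=None) -> float:
    """Integrated-periodogram dissimilarity: L1 distance between the
    normalized cumulative periodograms, sum_k |F_x(k) - F_y(k)|."""
    x, y, tv = _as_pair(x, y)
    x, y, _, p = _prep(x, y, time_vector if tv is None else tv, params)
    fx = _cumulative_periodogram(x, p.per_n_freq)
    fy = _cumulative_periodogram(y, p.per_n_freq)
    return float(np.sum(np.abs(fx - fy)))


# ---------------------------------------------------------------------------
# alignment (DTW family, Fréchet)
# ---------------------------------------------------------------------------
def _dtw_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    T, U = x.size, y.size
    c = np.abs(x[:, None] - y[None, :])
    D = np.empty((T, U))
    D[0, 0] = c[0, 0]
    for j in range(1, U):
        D[0, j] = D[0, j - 1] + c[0, j]
    for i in range(1, T):
        D[i, 0] = D[i - 1, 0] + c[i, 0]
        row, prev = D[i], D[i - 1]
        for j in range(1, U):
            row[j] = c[i, j] + min(prev[j - 1], prev[j], row[j - 1])
    return D


def d_dtw(x, y=None, time_vector=None, params=None) -> float:
    """Dynamic time warping with local cost |x_i - y_j|, symmetric steps
    (diagonal, vertical, horizontal), no window, no path normalization."""
    x, y, tv = _as_pair(x, y)
    x, y, _, _ = _prep(x, y, time_vector if tv is None else tv, params)
    return float(_dtw_matrix(x, y)[-1, -1])


def _backtrack_counts(D: np.ndarray) -> tuple[int, int, int]:
    """Step counts (diag, vert, horiz) of the diagonal-preferred optimal path.

    From each cell the predecessor with the smallest accumulated cost is
    taken; ties are broken diagonal first, then vertical (previous x index),
    then horizontal.
    """
    i, j = D.shape[0] - 1, D.shape[1] - 1
    n_d = n_v = n_h = 0
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
            n_h += 1
        elif j == 0:
            i -= 1
            n_v += 1
        else:
            diag, vert, horiz = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            best = min(diag, vert, horiz)
            if diag == best:
                i -= 1
                j -= 1
                n_d += 1
            elif vert == best:
                i -= 1
                n_v += 1
            else:
                j -= 1
                n_h += 1
    return n_d, n_v, n_h


def _lex_leq(x: np.ndarray, y: np.ndarray) -> bool:
    diff = x - y
    nz = np.flatnonzero(diff)
    return True if nz.size == 0 else diff[nz[0]] < 0


def d_tam(x, y=None, time_vector=None, params=None) -> float:
    """Time alignment measurement: how far the optimal DTW path departs from
    the diagonal.

    With p total path steps of which n_d are diagonal, n_h horizontal and n_v
    vertical, TAM = n_h/p + n_v/p + (1 - n_d/p), in [0, 2]; 0 means perfectly
    in-phase. TAM depends on which optimal path is taken, so the path is fixed
    deterministically: diagonal-preferred backtracking on the lexicographically
    ordered argument pair (the ordering makes the measure exactly symmetric).
    """
    x, y, tv = _as_pair(x, y)
    x, y, _, _ = _prep(x, y, time_vector if tv is None else tv, params)
    if not _lex_leq(x, y):
        x, y = y, x
    D = _dtw_matrix(x, y)
    n_d, n_v, n_h = _backtrack_counts(D)
    p = n_d + n_v + n_h
    if p == 0:  # single-point series cannot occur (T >= 2), but be safe
        return 0.0
    return float(n_h / p + n_v / p + (1.0 - n_d / p))


def d_frechet(x, y=None, time_vector=None, params=None) -> float:
    """Discrete Fréchet distance (Eiter-Mannila recursion):
    D(i,j) = max(c(i,j), min(D(i-1,j), D(i,j-1), D(i-1,j-1))).

    Ground cost is |x_i - y_j| by default; with
    ``frechet_embedding='time_value'`` points are embedded in the
    (time, value) plane and the cost is planar Euclidean.
    """
    x, y, tv = _as_pair(x, y)
    x, y, t, p = _prep(x, y, time_vector if tv is None else tv, params)
    if p.frechet_embedding == "time_value":
        c = np.sqrt((t[:, None] - t[None, :]) ** 2 + (x[:, None] - y[None, :]) ** 2)
    else:
        c = np.abs(x[:, None] - y[None, :])
    T, U = c.shape
    D = np.empty((T, U))
    D[0, 0] = c[0, 0]
    for j in range(1, U):
        D[0, j] = max(D[0, j - 1], c[0, j])
    for i in range(1, T):
        D[i, 0] = max(D[i - 1, 0], c[i, 0])
        row, prev = D[i], D[i - 1]
        for j in range(1, U):
            row[j] = max(c[i, j], min(prev[j - 1], prev[j], row[j - 1]))
    return float(D[-1, -1])


# ---------------------------------------------------------------------------
# compression
# ---------------------------------------------------------------------------
_LZMA_FILTERS = [{"id": lzma.FILTER_LZMA2, "preset": 9, "dict_size": 1 << 16}]


@lru_cache(maxsize=1 << 20)
def _compressed_size(data: bytes, compressor: str) -> int:
    if compressor == "lzma":
        # Raw LZMA2 stream at maximum preset: no container header, so the
        # length reflects content; the 64 KiB dictionary far exceeds any
        # input and does not change compressed lengths.
        return len(lzma.compress(data, format=lzma.FORMAT_RAW, filters=_LZMA_FILTERS))
    return len(zlib.compress(data, 9))


def _quantize(z: np.ndarray, alphabet: int) -> bytes:
    """Uniform quantization of [0,1] values to one byte per point."""
    sym = np.floor(np.clip(z, 0.0, 1.0) * alphabet).astype(np.uint8)
    return np.minimum(sym, alphabet - 1).tobytes()


def d_cdm(x, y=None, time_vector=None, params=None) -> float:
    """Compression-based dissimilarity measure.

    Both series are quantized into ``cdm_alphabet_size`` uniform bins over
    [0,1] (one byte per point); with C the compressed byte length,
    CDM = (C(x+y) + C(y+x)) / (2 (C(x) + C(y))), symmetrized over
    concatenation order. Note CDM(x, x) > 0: it measures shared information,
    not a metric with identity. At T=7 its resolution is very coarse; it is
    retained for completeness of the metric family.
    """
    x, y, tv = _as_pair(x, y)
    x, y, _, p = _prep(x, y, time_vector if tv is None else tv, params)
    bx = _quantize(x, p.cdm_alphabet_size)
    by = _quantize(y, p.cdm_alphabet_size)
    cx = _compressed_size(bx, p.cdm_compressor)
    cy = _compressed_size(by, p.cdm_compressor)
    cxy = _compressed_size(bx + by, p.cdm_compressor)
    cyx = _compressed_size(by + bx, p.cdm_compressor)
    return float((cxy + cyx) / (2.0 * (cx + cy)))


# ---------------------------------------------------------------------------
# dispatch and table computation
# ---------------------------------------------------------------------------
_METRIC_FUNCS = {
    "euclidean": d_euclidean,
    "sts": d_sts,
    "dtw": d_dtw,
    "tam": d_tam,
    "acf": d_acf,
    "fourier": d_fourier,
    "cdm": d_cdm,
    "cid": d_cid,
    "cor": d_cor,
    "int.per": d_intper,
    "per": d_per,
    "frechet": d_frechet,
}


def compute_distance(metric: str, x, y=None, time_vector=None, params=None) -> float:
    """Evaluate one named metric on a pair."""
    try:
        func = _METRIC_FUNCS[metric]
    except KeyError:
        raise ConfigError(
            f"unknown metric {metric!r}; valid names: {list(METRIC_NAMES)}"
        ) from None
    return func(x, y, time_vector=time_vector, params=params)


def _acf_rows(Z: np.ndarray, max_lag: int) -> np.ndarray:
    zc = Z - Z.mean(axis=1, keepdims=True)
    denom = np.sum(zc**2, axis=1)
    out = np.zeros((Z.shape[0], max_lag))
    ok = denom > 0
    for k in range(1, max_lag + 1):
        num = np.sum(zc[:, :-k] * zc[:, k:], axis=1)
        out[ok, k - 1] = num[ok] / denom[ok]
    return out


def _table_vectorized(name: str, wt, ko, t, p: ResolvedParams) -> np.ndarray | None:
    """Vectorized fast path over (N, T) arrays; None if the metric needs the
    per-pair route."""
    if name == "euclidean":
        return np.sqrt(np.sum((wt - ko) ** 2, axis=1))
    if name == "sts":
        dt = np.diff(t)
        return np.sqrt(np.sum(((np.diff(ko, axis=1) - np.diff(wt, axis=1)) / dt) ** 2, axis=1))
    if name == "cid":
        ce_x = np.sqrt(np.sum(np.diff(wt, axis=1) ** 2, axis=1))
        ce_y = np.sqrt(np.sum(np.diff(ko, axis=1) ** 2, axis=1))
        eps = p.cid_epsilon
        factor = (np.maximum(ce_x, ce_y) + eps) / (np.minimum(ce_x, ce_y) + eps)
        return np.sqrt(np.sum((wt - ko) ** 2, axis=1)) * factor
    if name == "cor":
        xc = wt - wt.mean(axis=1, keepdims=True)
        yc = ko - ko.mean(axis=1, keepdims=True)
        denom = np.sqrt(np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1))
        num = np.sum(xc * yc, axis=1)
        rho = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        rho = np.clip(rho, -1.0, 1.0)
        return np.sqrt(2.0 * (1.0 - rho))
    if name == "acf":
        rx = _acf_rows(wt, p.acf_max_lag)
        ry = _acf_rows(ko, p.acf_max_lag)
        return np.sqrt(np.sum((rx - ry) ** 2, axis=1))
    if name == "fourier":
        X = sfft.fft(wt, axis=1)[:, : p.fourier_n_coef]
        Y = sfft.fft(ko, axis=1)[:, : p.fourier_n_coef]
        return np.sqrt(np.sum(np.abs(X - Y) ** 2, axis=1))
    if name in ("per", "int.per"):
        T = wt.shape[1]
        K = p.per_n_freq
        Px = (np.abs(sfft.fft(wt, axis=1)[:, 1 : K + 1]) ** 2) / T
        Py = (np.abs(sfft.fft(ko, axis=1)[:, 1 : K + 1]) ** 2) / T
        if name == "per":
            return np.sqrt(np.sum((Px - Py) ** 2, axis=1))
        ramp = np.arange(1, K + 1) / K
        tx, ty = Px.sum(axis=1), Py.sum(axis=1)
        Fx = np.where(tx[:, None] > 0, np.cumsum(Px, axis=1) / np.where(tx, tx, 1.0)[:, None], ramp)
        Fy = np.where(ty[:, None] > 0, np.cumsum(Py, axis=1) / np.where(ty, ty, 1.0)[:, None], ramp)
        return np.sum(np.abs(Fx - Fy), axis=1)
    return None


def compute_distance_table(
    profiles: ProfileSet,
    metrics: tuple[str, ...] | list[str] | None = None,
    params: MetricParams | None = None,
) -> pd.DataFrame:
    """Evaluate the requested metrics on every pair in a scaled ProfileSet.

    Returns a gene x metric DataFrame. Degenerate (constant) pairs yield NaN
    for every metric and are expected to have been filtered upstream.
    """
    names = tuple(metrics) if metrics is not None else METRIC_NAMES
    unknown = [m for m in names if m not in _METRIC_FUNCS]
    if unknown:
        raise ConfigError(f"unknown metric names {unknown}; valid names: {list(METRIC_NAMES)}")
    if not profiles.scaled:
        raise DataError("profiles must be jointly minmax-scaled before distance computation")
    mp = params or MetricParams()
    p = mp.resolve(profiles.time_vector.size)
    wt, ko, t = profiles.wt, profiles.ko, profiles.time_vector
    n = len(profiles)
    table = pd.DataFrame(index=profiles.gene_ids, columns=list(names), dtype=float)

    for name in names:
        fast = _table_vectorized(name, wt, ko, t, p)
        if fast is not None:
            table[name] = fast
        else:
            func = _METRIC_FUNCS[name]
            table[name] = [func(wt[i], ko[i], time_vector=t, params=mp) for i in range(n)]

    if profiles.degenerate is not None and profiles.degenerate.any():
        table.loc[np.asarray(profiles.degenerate), :] = np.nan
    return table
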