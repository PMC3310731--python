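"""Transfer-entropy effective-connectivity estimation on quantized signals.

Signals are quantized into ``n`` equal-width bins and treated as symbol
streams.  Causal influence of ``x`` on ``y`` at lag ``tau`` is the
first-Markov-order transfer entropy (in bits)

    TE(x -> y) = sum p(y_{t+tau}, y_t, x_t)
                 * log2[ p(y_{t+tau} | y_t, x_t) / p(y_{t+tau} | y_t) ],

a plug-in conditional mutual information, hence non-negative.  For three
areas, the partialized variant conditions additionally on the third series
to discard indirect influences.  The causal unbalance
``U = (TE_xy - TE_yx) / (TE_xy + TE_yx)`` summarizes directional asymmetry
in [-1, 1].

Estimates carry the sample count actually used and an under-sampling flag
(fewer than ``10 * n**k`` transition tuples).  Absolute TE values depend on
``(n, tau)``; the scan utilities map that dependence so that conclusions
rest on the (robust) motif topology rather than on a single working point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SymbolSeries",
    "TeEstimate",
    "UnbalanceResult",
    "TeScan",
    "quantize",
    "transfer_entropy",
    "partialized_te",
    "unbalance",
    "te_scan",
    "surrogate_bias",
]


@dataclass
class SymbolSeries:
    """Quantized signal: symbols over {0..n_bins-1} with the bin edges used."""

    symbols: np.ndarray
    n_bins: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        if self.symbols.size and (self.symbols.min() < 0 or self.symbols.max() >= self.n_bins):
            raise ValueError("symbols out of alphabet range")


@dataclass
class TeEstimate:
    value: float                 # bits, >= 0
    n_bins: int
    lag: int
    n_samples: int               # transition tuples used
    direction: tuple[int, int] | None = None
    under_sampled: bool = False
    conditioned: bool = False    # True for the partialized estimator


@dataclass
class UnbalanceResult:
    u: float
    defined: bool = True


@dataclass
class TeScan:
    """TE / unbalance matrices over an (n_bins, tau) grid for one pair."""

    n_grid: np.ndarray
    tau_grid: np.ndarray
    te_xy: np.ndarray            # (len(n_grid), len(tau_grid))
    te_yx: np.ndarray
    unbalance: np.ndarray        # NaN where undefined
    significant_xy: np.ndarray | None = None
    significant_yx: np.ndarray | None = None
    peak_lag_xy: dict[int, float] = field(default_factory=dict)  # n -> first-peak tau
    peak_lag_yx: dict[int, float] = field(default_factory=dict)


def quantize(signal: np.ndarray, n_bins: int, value_range: tuple[float, float] | None = None) -> SymbolSeries:
    """Equal-width quantization over the signal's own [min, max] (top edge inclusive)."""
    x = np.asarray(signal, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    lo, hi = value_range if value_range is not None else (x.min(), x.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    if hi <= lo:
        if n_bins > 1:
            warnings.warn("constant signal quantized to a single symbol", stacklevel=2)
        return SymbolSeries(np.zeros(x.size, dtype=np.int64), n_bins, edges)
    sym = np.clip(((x - lo) / (hi - lo) * n_bins).astype(np.int64), 0, n_bins - 1)
    return SymbolSeries(sym, n_bins, edges)


def _entropy_from_counts(counts: np.ndarray) -> float:
    c = counts[counts > 0].astype(float)
    p = c / c.sum()
    return float(-(p * np.log2(p)).sum())


def _as_symbols(x) -> tuple[np.ndarray, int]:
    if isinstance(x, SymbolSeries):
        return x.symbols, x.n_bins
    s = np.asarray(x)
    if not np.issubdtype(s.dtype, np.integer):
        raise TypeError("expected SymbolSeries or integer array")
    return s.astype(np.int64), int(s.max()) + 1 if s.size else 1


def _valid_pairs_mask(mask: np.ndarray | None, length: int, tau: int) -> np.ndarray:
    """Boolean index over t of usable transition tuples (t and t+tau both valid)."""
    if mask is None:
        return np.ones(length - tau, dtype=bool)
    m = np.asarray(mask, dtype=bool)
    if m.size != length:
        raise ValueError("mask length must match series length")
    return m[:-tau] & m[tau:]


def transfer_entropy(
    x,
    y,
    tau: int,
    mask: np.ndarray | None = None,
    n_bins: int | None = None,
    direction: tuple[int, int] | None = None,
) -> TeEstimate:
    """Plug-in first-order transfer entropy x -> y at lag ``tau`` (bits).

    ``mask`` marks valid samples; tuples straddling masked-out epochs (for
    instance switching transients) are dropped.
    """
    xs, nx = _as_symbols(x)
    ys, ny = _as_symbols(y)
    if xs.size != ys.size:
        raise ValueError("series must have equal length")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    n = n_bins or max(nx, ny)
    valid = _valid_pairs_mask(mask, xs.size, tau)
    yf, yp, xp = ys[tau:][valid], ys[:-tau][valid], xs[:-tau][valid]
    m = yf.size
    # TE = H(y+, y) - H(y) ... computed from one joint histogram
    joint = np.bincount((yf * n + yp) * n + xp, minlength=n ** 3).reshape(n, n, n)
    h_yy = _entropy_from_counts(joint.sum(axis=2).ravel())
    h_y = _entropy_from_counts(joint.sum(axis=(0, 2)))
    h_yyx = _entropy_from_counts(joint.ravel())
    h_yx = _entropy_from_counts(joint.sum(axis=0).ravel())
    val = max(0.0, (h_yy - h_y) - (h_yyx - h_yx))
    return TeEstimate(
        value=val, n_bins=n, lag=tau, n_samples=m, direction=direction,
        under_sampled=m < 10 * n ** 3,
    )


def partialized_te(
    x,
    y,
    z,
    tau: int,
    mask: np.ndarray | None = None,
    n_bins: int | None = None,
    cond_lag: int = 0,
    direction: tuple[int, int] | None = None,
) -> TeEstimate:
    """Transfer entropy x -> y conditioned additionally on the third series z.

    ``cond_lag`` places the conditioning sample at ``z_{t + cond_lag}``
    (default 0: condition on z at the same time as the source sample, which
    discounts indirect influences routed through the ongoing state of z).
    """
    xs, nx = _as_symbols(x)
    ys, ny = _as_symbols(y)
    zs, nz = _as_symbols(z)
    if not (xs.size == ys.size == zs.size):
        raise ValueError("series must have equal length")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if not 0 <= cond_lag <= tau:
        raise ValueError("cond_lag must be in [0, tau]")
    n = n_bins or max(nx, ny, nz)
    valid = _valid_pairs_mask(mask, xs.size, tau)
    yf, yp, xp = ys[tau:][valid], ys[:-tau][valid], xs[:-tau][valid]
    zc = zs[cond_lag:][: xs.size - tau][valid] if cond_lag else zs[:-tau][valid]
    m = yf.size
    joint = np.bincount(
        ((yf * n + yp) * n + xp) * n + zc, minlength=n ** 4
    ).reshape(n, n, n, n)
    # pTE = [H(y+, y, z) - H(y, z)] - [H(y+, y, x, z) - H(y, x, z)]
    h_yyz = _entropy_from_counts(joint.sum(axis=2).ravel())
    h_yz = _entropy_from_counts(joint.sum(axis=(0, 2)).ravel())
    h_yyxz = _entropy_from_counts(joint.ravel())
    h_yxz = _entropy_from_counts(joint.sum(axis=0).ravel())
    val = max(0.0, (h_yyz - h_yz) - (h_yyxz - h_yxz))
    return TeEstimate(
        value=val, n_bins=n, lag=tau, n_samples=m, direction=direction,
        under_sampled=m < 10 * n ** 4, conditioned=True,
    )


def unbalance(te_ab: TeEstimate | float, te_ba: TeEstimate | float) -> UnbalanceResult:
    """Normalized directional asymmetry U = (TE_ab - TE_ba) / (TE_ab + TE_ba)."""
    a = te_ab.value if isinstance(te_ab, TeEstimate) else float(te_ab)
    b = te_ba.value if isinstance(te_ba, TeEstimate) else float(te_ba)
    if isinstance(te_ab, TeEstimate) and isinstance(te_ba, TeEstimate):
        if (te_ab.n_bins, te_ab.lag) != (te_ba.n_bins, te_ba.lag):
            raise ValueError("unbalance requires estimates at matching (n_bins, lag)")
    if a == 0.0 and b == 0.0:
        return UnbalanceResult(u=np.nan, defined=False)
    return UnbalanceResult(u=(a - b) / (a + b))


def _first_peak_lag(values: np.ndarray, tau_grid: np.ndarray) -> float:
    """Lag of the first local maximum of TE(tau) (parabola-free, grid resolution)."""
    v = values
    for i in range(1, v.size - 1):
        if v[i] >= v[i - 1] and v[i] > v[i + 1]:
            return float(tau_grid[i])
    return float(tau_grid[np.argmax(v)])


def te_scan(
    x_raw: np.ndarray,
    y_raw: np.ndarray,
    n_grid,
    tau_grid,
    mask: np.ndarray | None = None,
    significance=None,
) -> TeScan:
    """TE in both directions plus unbalance over an (n_bins, tau) grid.

    ``significance`` is an optional callable
    ``(x_raw, y_raw, n, tau) -> (bool, bool)`` giving per-direction flags
    (typically a closure over the geometric-bootstrap test); absent that,
    significance masks are left None.
    """
    n_grid = np.asarray(list(n_grid), dtype=int)
    tau_grid = np.asarray(list(tau_grid), dtype=int)
    shape = (n_grid.size, tau_grid.size)
    te_xy = np.zeros(shape)
    te_yx = np.zeros(shape)
    ub = np.full(shape, np.nan)
    sig_xy = np.zeros(shape, dtype=bool) if significance else None
    sig_yx = np.zeros(shape, dtype=bool) if significance else None
    for i, n in enumerate(n_grid):
        xs = quantize(x_raw, int(n))
        ys = quantize(y_raw, int(n))
        for j, tau in enumerate(tau_grid):
            fwd = transfer_entropy(xs, ys, int(tau), mask=mask)
            bwd = transfer_entropy(ys, xs, int(tau), mask=mask)
            te_xy[i, j] = fwd.value
            te_yx[i, j] = bwd.value
            u = unbalance(fwd, bwd)
            ub[i, j] = u.u if u.defined else np.nan
            if significance:
                sig_xy[i, j], sig_yx[i, j] = significance(x_raw, y_raw, int(n), int(tau))
    scan = TeScan(n_grid=n_grid, tau_grid=tau_grid, te_xy=te_xy, te_yx=te_yx,
                  unbalance=ub, significant_xy=sig_xy, significant_yx=sig_yx)
    for i, n in enumerate(n_grid):
        scan.peak_lag_xy[int(n)] = _first_peak_lag(te_xy[i], tau_grid)
        scan.peak_lag_yx[int(n)] = _first_peak_lag(te_yx[i], tau_grid)
    return scan


def surrogate_bias(
    x,
    y,
    tau: int,
    n_surrogates: int = 20,
    seed: int | None = None,
    mask: np.ndarray | None = None,
    quantile: float = 0.975,
    z=None,
    cond_lag: int = 0,
) -> float:
    """Finite-sampling bias bound: the given quantile of the estimator over
    circular-shift surrogates of the source (causal structure destroyed,
    marginals and autocorrelations preserved).  With ``z`` given the bound
    is computed for the partialized estimator at matching ``cond_lag``."""
    xs, nx = _as_symbols(x)
    ys, ny = _as_symbols(y)
    n = max(nx, ny)
    if z is not None:
        zs, nz = _as_symbols(z)
        n = max(n, nz)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_surrogates)
    for k in range(n_surrogates):
        shift = int(rng.integers(xs.size // 4, 3 * xs.size // 4))
        xr = np.roll(xs, shift)
        if z is None:
            vals[k] = transfer_entropy(xr, ys, tau, mask=mask, n_bins=n).value
        else:
            vals[k] = partialized_te(xr, ys, zs, tau, mask=mask, n_bins=n,
                                     cond_lag=cond_lag).value
    return float(np.quantile(vals, quantile))
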