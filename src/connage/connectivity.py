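"""Connectivity construction.

Static functional connectivity (Pearson correlation of regional time
series), sliding-window dynamic FC, the nodal temporal-variability
statistic, volume-scaled structural connectivity, and synchronization
likelihood (a generalized-synchronization measure built on time-delay
embedding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "WindowSpec",
    "WindowedFC",
    "SLParams",
    "DegenerateInputError",
    "static_fc",
    "make_windows",
    "dynamic_fc",
    "temporal_variability",
    "scale_sc",
    "synchronization_likelihood",
    "sl_matrix",
]


class DegenerateInputError(ValueError):
    """Raised when an input is degenerate (e.g. a constant time series)."""


@dataclass
class ConnectivityMatrix:
    """Symmetric R x R edge-weight matrix.

    ``kind`` is ``"fc"`` (Pearson correlation, unit diagonal, entries in
    [-1, 1]), ``"sc"`` (volume-scaled streamline counts, zero diagonal) or
    ``"sl"`` (synchronization likelihood in [0, 1], zero diagonal).
    """

    values: np.ndarray
    kind: str
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.kind not in ("fc", "sc", "sl"):
            raise ValueError(f"unknown connectivity kind {self.kind!r}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v
        if not self.region_labels:
            self.region_labels = [str(i) for i in range(v.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window specification (lengths in timepoints / TRs).

    Defaults reproduce the reference protocol: 50-TR windows stepped by 2
    across 265 retained volumes, yielding 108 windows.
    """

    length: int = 50
    step: int = 2
    n_timepoints: int = 265

    def __post_init__(self) -> None:
        if not 1 <= self.length <= self.n_timepoints:
            raise ValueError(
                f"window length {self.length} must lie in [1, {self.n_timepoints}]"
            )
        if self.step < 1:
            raise ValueError("step must be >= 1")

    @property
    def n_windows(self) -> int:
        return (self.n_timepoints - self.length) // self.step + 1


@dataclass
class WindowedFC:
    """Ordered sequence of per-window FC matrices."""

    windows: list[ConnectivityMatrix]
    spec: WindowSpec

    def __post_init__(self) -> None:
        if len(self.windows) != self.spec.n_windows:
            raise ValueError("window count inconsistent with spec")
        dims = {w.n_regions for w in self.windows}
        if len(dims) > 1:
            raise ValueError("windows have inconsistent dimensions")

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class SLParams:
    """Synchronization-likelihood parameters.

    ``m``: embedding dimension; ``lag``: embedding delay in timepoints;
    ``w1``/``w2``: inner/outer Theiler windows bounding the temporal
    separation of candidate recurrence pairs (w1 < |i-j| < w2); ``p_ref``:
    target recurrence probability fixing each reference point's critical
    distance.  A ``w2`` beyond the embedded-series length simply means no
    upper bound.
    """

    m: int = 25
    lag: int = 20
    w1: int = 960
    w2: int = 1959
    p_ref: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.lag < 1:
            raise ValueError("embedding lag must be >= 1")
        if not 0 < self.p_ref < 1:
            raise ValueError("p_ref must lie in (0, 1)")
        if not self.w1 < self.w2:
            raise ValueError("w1 must be < w2")

    @property
    def min_timepoints(self) -> int:
        return (self.m - 1) * self.lag + 2


def _check_no_constant_column(ts: np.ndarray, context: str = "") -> None:
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        where = f" in {context}" if context else ""
        raise DegenerateInputError(
            f"constant time series for region(s) {bad.tolist()}{where}"
        )


def static_fc(ts: np.ndarray, region_labels: list[str] | None = None) -> ConnectivityMatrix:
    """Pearson-correlation FC matrix of a T x R time-series matrix."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a T x R matrix")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    _check_no_constant_column(ts)
    c = np.corrcoef(ts, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(c, kind="fc", region_labels=region_labels or [])


def make_windows(spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open 0-based [start, start + length) index pairs, ordered by
    start."""
    return [
        (s, s + spec.length)
        for s in range(0, spec.n_timepoints - spec.length + 1, spec.step)
    ]


def dynamic_fc(ts: np.ndarray, spec: WindowSpec) -> WindowedFC:
    """Sliding-window FC: one correlation matrix per window."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] != spec.n_timepoints:
        raise ValueError(
            f"time series has {ts.shape[0]} timepoints; spec expects {spec.n_timepoints}"
        )
    windows = []
    for w_idx, (start, end) in enumerate(make_windows(spec)):
        chunk = ts[start:end]
        try:
            windows.append(static_fc(chunk))
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"window {w_idx}: {exc}") from None
    return WindowedFC(windows=windows, spec=spec)


def temporal_variability(wfc: WindowedFC) -> np.ndarray:
    """Nodal temporal variability.

    For node k, the FC profile in window i is row k of that window's matrix
    with the self-entry removed.  V_k = 1 - mean over ordered window pairs
    (i != j) of the Pearson correlation between the two profiles; values lie
    in [0, 2], 0 meaning perfectly stable coupling.
    """
    n = wfc.n_windows
    if n < 2:
        raise ValueError("temporal variability needs at least 2 windows")
    R = wfc.windows[0].n_regions
    if R < 3:
        raise ValueError("need at least 3 regions for off-diagonal profiles")
    stack = np.stack([w.values for w in wfc.windows])  # n x R x R
    V = np.empty(R)
    mask = ~np.eye(R, dtype=bool)
    for k in range(R):
        profiles = stack[:, k, :][:, mask[k]]  # n x (R-1)
        sd = profiles.std(axis=1)
        if np.any(sd == 0):
            raise DegenerateInputError(
                f"constant FC profile for region {k} in some window"
            )
        c = np.corrcoef(profiles)
        V[k] = 1.0 - (c.sum() - n) / (n * (n - 1))
    return V


def scale_sc(
    counts: np.ndarray,
    volumes: np.ndarray,
    convention: str = "sum",
    region_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Scale streamline counts by the inverse of the two node volumes.

    ``convention="sum"`` (default): entry (i, j) = counts(i, j) * 2 /
    (v_i + v_j), i.e. the inverse of the mean volume.  ``"product"``:
    counts(i, j) / (v_i * v_j).
    """
    counts = np.asarray(counts, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be square")
    if not np.allclose(counts, counts.T):
        raise ValueError("counts must be symmetric")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if volumes.shape != (counts.shape[0],):
        raise ValueError("one volume per region required")
    if np.any(volumes <= 0):
        bad = np.flatnonzero(volumes <= 0).tolist()
        raise ValueError(f"non-positive node volume(s) at region(s) {bad}")
    if convention == "sum":
        scale = 2.0 / np.add.outer(volumes, volumes)
    elif convention == "product":
        scale = 1.0 / np.multiply.outer(volumes, volumes)
    else:
        raise ValueError(f"unknown scaling convention {convention!r}")
    out = counts * scale
    np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(out, kind="sc", region_labels=region_labels or [])


# ---------------------------------------------------------------------------
# Synchronization likelihood


def _embed(x: np.ndarray, m: int, lag: int) -> np.ndarray:
    """Time-delay embedding: row i = (x_i, x_{i+lag}, ..., x_{i+(m-1)lag})."""
    n = x.size - (m - 1) * lag
    idx = np.arange(n)[:, None] + lag * np.arange(m)[None, :]
    return x[idx]


def synchronization_likelihood(
    x: np.ndarray, y: np.ndarray, params: SLParams = SLParams()
) -> float:
    """Synchronization likelihood between two scalar series.

    Both series are time-delay embedded; for each reference point i the
    critical distance of each channel is set so that a fraction ``p_ref`` of
    the Theiler-valid partners j (w1 < |i - j| < w2) recur within it.  The
    statistic is the joint-recurrence fraction normalized by ``p_ref``,
    averaged over reference points and clipped to [0, 1]: 1 for identical
    channels, ~p_ref for independent ones.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    p = params
    if x.size < p.min_timepoints:
        raise ValueError(
            f"series too short for embedding: need T >= {p.min_timepoints}, got {x.size}"
        )
    ex, ey = _embed(x, p.m, p.lag), _embed(y, p.m, p.lag)
    n = ex.shape[0]
    dx = np.linalg.norm(ex[:, None, :] - ex[None, :, :], axis=-1)
    dy = np.linalg.norm(ey[:, None, :] - ey[None, :, :], axis=-1)
    lagsep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    valid = (lagsep > p.w1) & (lagsep < p.w2)

    total, n_ref = 0.0, 0
    for i in range(n):
        vj = np.flatnonzero(valid[i])
        if vj.size == 0:
            continue
        k = max(1, int(round(p.p_ref * vj.size)))
        eps_x = np.partition(dx[i, vj], k - 1)[k - 1]
        eps_y = np.partition(dy[i, vj], k - 1)[k - 1]
        joint = np.count_nonzero((dx[i, vj] <= eps_x) & (dy[i, vj] <= eps_y))
        total += joint / (p.p_ref * vj.size)
        n_ref += 1
    if n_ref == 0:
        raise ValueError("Theiler windows leave no valid pairs")
    return float(np.clip(total / n_ref, 0.0, 1.0))


def sl_matrix(
    ts: np.ndarray,
    params: SLParams = SLParams(),
    region_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Pairwise synchronization likelihood over all region pairs of a T x R
    time-series matrix (symmetric, zero diagonal)."""
    ts = np.asarray(ts, dtype=float)
    R = ts.shape[1]
    out = np.zeros((R, R))
    for i in range(R):
        for j in range(i + 1, R):
            out[i, j] = out[j, i] = synchronization_likelihood(
                ts[:, i], ts[:, j], params
            )
    return ConnectivityMatrix(out, kind="sl", region_labels=region_labels or [])
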