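"""Functional connectivity from ROI time series.

Time series are cleaned with nuisance regression and a hard Fourier band-pass
(default 0.009-0.08 Hz, the conventional resting-state band), optionally
concatenated across runs, and summarised as a Pearson correlation matrix.
Correlations are variance-stabilised with the Fisher r-to-z transform; a
region's mean functional connectivity (a scaled degree centrality) is the mean
of its z values to every other region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError, ReferentialIntegrityError

DEFAULT_BAND = (0.009, 0.08)  # Hz
_R_CLAMP = 1.0 - 1e-7


@dataclass
class RoiTimeSeries:
    """ROI signal matrix, rows = time points, columns = atlas regions."""

    subject_id: str
    values: np.ndarray  # (n_timepoints, n_regions)
    sampling_interval: float  # seconds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("time series must be 2-D (time x regions)")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("time series contain non-finite values")
        if self.sampling_interval <= 0:
            raise InvalidArgumentError("sampling interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.sampling_interval


@dataclass
class FunctionalNetwork:
    """Correlation matrix ``r``, Fisher-z matrix ``z`` (zero diagonal) and the
    per-region mean functional connectivity vector."""

    subject_id: str
    r: np.ndarray
    z: np.ndarray
    mean_fc: np.ndarray


def regress_nuisance(ts: RoiTimeSeries, nuisance: np.ndarray | None = None) -> RoiTimeSeries:
    """Replace each region's series by its residual after least-squares
    projection onto [intercept, nuisance columns]."""
    t = ts.n_timepoints
    if nuisance is None:
        nuisance = np.empty((t, 0))
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim != 2 or nuisance.shape[0] != t:
        raise InvalidArgumentError("nuisance row count must equal the time-point count")
    design = np.column_stack([np.ones(t), nuisance])
    if design.shape[1] >= t or np.linalg.matrix_rank(design) < design.shape[1]:
        raise InvalidArgumentError("nuisance design is rank deficient or overdetermined")
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    resid = ts.values - design @ beta
    return RoiTimeSeries(ts.subject_id, resid, ts.sampling_interval)


def bandpass(
    ts: RoiTimeSeries,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
) -> RoiTimeSeries:
    """Hard discrete-Fourier mask: frequencies outside [f_lo, f_hi] (and DC)
    are zeroed; the inverse transform is returned."""
    nyq = ts.nyquist
    if not (0 <= f_lo < f_hi):
        raise InvalidArgumentError(f"need 0 <= f_lo < f_hi, got [{f_lo}, {f_hi}]")
    if f_hi > nyq:
        raise InvalidArgumentError(f"f_hi={f_hi} Hz exceeds Nyquist {nyq:.4g} Hz")
    t = ts.n_timepoints
    freqs = np.fft.rfftfreq(t, d=ts.sampling_interval)
    mask = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    spec = np.fft.rfft(ts.values, axis=0)
    spec[~mask, :] = 0.0
    filtered = np.fft.irfft(spec, n=t, axis=0)
    return RoiTimeSeries(ts.subject_id, filtered, ts.sampling_interval)


def concatenate_runs(ts_a: RoiTimeSeries, ts_b: RoiTimeSeries) -> RoiTimeSeries:
    """Demean each run per region, then stack in time.  Demeaning first
    prevents run-offset artifacts from inflating correlations."""
    if ts_a.n_regions != ts_b.n_regions:
        raise InvalidArgumentError(
            f"region count mismatch: {ts_a.n_regions} vs {ts_b.n_regions}"
        )
    if ts_a.sampling_interval != ts_b.sampling_interval:
        raise InvalidArgumentError("sampling intervals differ between runs")
    stacked = np.vstack(
        [ts_a.values - ts_a.values.mean(axis=0), ts_b.values - ts_b.values.mean(axis=0)]
    )
    return RoiTimeSeries(ts_a.subject_id, stacked, ts_a.sampling_interval)


def correlation_matrix(ts: RoiTimeSeries) -> FunctionalNetwork:
    """Pearson correlation of every region pair, then Fisher z and mean FC."""
    sd = ts.values.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise DegenerateInputError(f"region {int(dead[0])} has zero variance")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    z = fisher_z_matrix(r)
    n = r.shape[0]
    mean_fc = z.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)
    return FunctionalNetwork(ts.subject_id, r, z, mean_fc)


def fisher_z(r_value: float) -> float:
    """Fisher r-to-z: atanh(r), with |r| = 1 clamped to +/-(1 - 1e-7)."""
    if abs(r_value) > 1:
        raise InvalidArgumentError(f"|r| must be <= 1, got {r_value}")
    return float(np.arctanh(np.clip(r_value, -_R_CLAMP, _R_CLAMP)))


def fisher_z_matrix(r: np.ndarray) -> np.ndarray:
    """Elementwise Fisher transform with zero diagonal."""
    if np.any(np.abs(r) > 1):
        raise InvalidArgumentError("correlation entries must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))
    np.fill_diagonal(z, 0.0)
    return z


def mean_functional_connectivity(net: FunctionalNetwork, region: int) -> float:
    """Mean of z[region][j] over j != region (scaled degree centrality)."""
    n = net.z.shape[0]
    if not (0 <= region < n):
        raise ReferentialIntegrityError(f"region {region} not in network of size {n}")
    if n < 2:
        raise InvalidArgumentError("need at least 2 regions")
    return float(net.mean_fc[region])


def preprocess(
    ts: RoiTimeSeries,
    nuisance: np.ndarray | None = None,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
) -> RoiTimeSeries:
    """Standard temporal cleaning: nuisance regression then band-pass."""
    return bandpass(regress_nuisance(ts, nuisance), f_lo, f_hi)
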