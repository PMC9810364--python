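"""Band-filtered, windowed phase-lag connectivity.

The connectivity estimator is the weighted phase lag index (wPLI) of the
analytic signals of a pair of channels, computed inside non-overlapping
fixed-length windows.  For channels i, j with analytic signals z_i, z_j and
per-sample cross-spectrum X = z_i * conj(z_j),

    Phi_ij = |E{Im X}| / E{|Im X|}

with the expectation taken as the sample mean within the window.  Phi is in
[0, 1], is blind to zero-lag (in-phase) coupling, and is invariant to
channel-wise amplitude rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "MONTAGE_1020",
    "DEFAULT_BANDS",
    "BandDefinition",
    "EegRecording",
    "ConnectivitySeries",
    "CovSummary",
    "bandpass_filter",
    "window_signal",
    "wpli_matrix",
    "connectivity_series",
    "temporal_cov",
]

#: 20-sensor International 10-20 montage used throughout.
MONTAGE_1020 = (
    "Fz", "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Cz", "C3", "C4",
    "T3", "T4", "T5", "T6", "O1", "O2", "Pz", "POz", "P3", "P4",
)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band (edges in Hz)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_for_rate(self, rate: float) -> None:
        if self.high >= rate / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz is at/above "
                f"Nyquist for rate {rate} Hz"
            )


#: Default analysis bands.  Edges are kept verbatim (including the 13-21 Hz
#: gap and the 25-30 Hz beta/gamma overlap).
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 3.0),
    BandDefinition("theta", 3.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 21.0, 30.0),
    BandDefinition("gamma", 25.0, 40.0),
)


@dataclass
class EegRecording:
    """Multichannel EEG: ``data`` is channels x samples, in microvolts."""

    labels: tuple[str, ...]
    rate: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(str(x) for x in self.labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class ConnectivitySeries:
    """Ordered stack of L symmetric N x N wPLI matrices for one band."""

    band: BandDefinition
    window_seconds: float
    layers: np.ndarray  # (L, N, N)
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3 or self.layers.shape[1] != self.layers.shape[2]:
            raise ValueError("layers must be a (L, N, N) stack")
        if self.layers.min(initial=0.0) < 0 or self.layers.max(initial=0.0) > 1:
            raise ValueError("wPLI entries must lie in [0, 1]")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


@dataclass
class CovSummary:
    """Per-edge temporal coefficient of variation and its session mean."""

    edge_cov: np.ndarray  # (N, N), NaN on diagonal and degenerate edges
    session_mean: float
    n_excluded_edges: int
    band: BandDefinition | None = None
    context: str | None = None


def bandpass_filter(recording: EegRecording, band: BandDefinition) -> EegRecording:
    """Order-3 Butterworth band-pass applied forward and reverse (zero phase)."""
    band.validate_for_rate(recording.rate)
    order = 3
    sos = butter(order, [band.low, band.high], btype="bandpass",
                 fs=recording.rate, output="sos")
    # forward+reverse filtering needs some run-in; 3x the order is a floor,
    # sosfiltfilt's own padlen requirement is checked by scipy itself
    if recording.n_samples <= 3 * order:
        raise ValueError(
            f"signal of {recording.n_samples} samples is shorter than the "
            f"filter warm-up ({3 * order} samples)"
        )
    filtered = sosfiltfilt(sos, recording.data, axis=1)
    return EegRecording(recording.labels, recording.rate, filtered)


def window_signal(recording: EegRecording, window_seconds: float) -> list[np.ndarray]:
    """Cut into consecutive non-overlapping windows; trailing remainder dropped."""
    if window_seconds <= 0:
        raise ValueError(f"window_seconds must be positive, got {window_seconds}")
    n_per = int(round(window_seconds * recording.rate))
    if n_per < 2:
        raise ValueError("window must contain at least 2 samples")
    n_win = recording.n_samples // n_per
    if n_win == 0:
        raise ValueError(
            f"recording of {recording.duration:.3f} s is shorter than one "
            f"{window_seconds} s window"
        )
    return [recording.data[:, i * n_per:(i + 1) * n_per] for i in range(n_win)]


def wpli_matrix(block: np.ndarray, rate: float | None = None) -> np.ndarray:
    """wPLI of every channel pair within one (already band-filtered) block.

    Pairs whose imaginary cross-spectrum is identically zero (e.g. exact
    zero-lag copies) get Phi = 0 by convention.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[0] < 2:
        raise ValueError("block must be channels x samples with >= 2 channels")
    if not np.all(np.isfinite(block)):
        raise ValueError("block contains non-finite samples")
    z = hilbert(block, axis=1)
    # imag cross-spectrum for all pairs at every sample: (N, N, T)
    imx = np.imag(z[:, None, :] * np.conj(z[None, :, :]))
    num = np.abs(imx.mean(axis=2))
    den = np.abs(imx).mean(axis=2)
    # an identically-zero imaginary cross-spectrum (exact zero-lag coupling)
    # only cancels to ~1e-16 relative in floating point; the cutoff scales
    # with the pair's amplitude product so rescaling invariance is preserved
    power = (np.abs(z) ** 2).mean(axis=1)
    tol = 1e-10 * np.sqrt(np.outer(power, power))
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > tol, num / den, 0.0)
    np.fill_diagonal(phi, 0.0)
    # numerically phi is symmetric already (|Im X_ij| = |Im X_ji|); enforce
    phi = 0.5 * (phi + phi.T)
    return np.clip(phi, 0.0, 1.0)


def connectivity_series(
    recording: EegRecording,
    bands: "BandDefinition | tuple[BandDefinition, ...] | list[BandDefinition]" = DEFAULT_BANDS,
    window_seconds: float = 10.0,
) -> list[ConnectivitySeries]:
    """Filter -> window -> wPLI per window, for each band.

    Returns one :class:`ConnectivitySeries` per band, all with identical L.
    A single-window result is allowed but flagged with a warning: no dynamic
    metric can be computed from it.
    """
    if isinstance(bands, BandDefinition):
        bands = [bands]
    out: list[ConnectivitySeries] = []
    for band in bands:
        filtered = bandpass_filter(recording, band)
        blocks = window_signal(filtered, window_seconds)
        layers = np.stack([wpli_matrix(b, recording.rate) for b in blocks])
        if layers.shape[0] < 2:
            warnings.warn(
                f"band {band.name!r}: only L={layers.shape[0]} window(s); "
                "dynamic metrics require L >= 2",
                stacklevel=2,
            )
        out.append(
            ConnectivitySeries(band, window_seconds, layers, recording.labels)
        )
    return out


def temporal_cov(series: ConnectivitySeries) -> CovSummary:
    """Temporal coefficient of variation of each edge's wPLI time series.

    CoV = population std over layers / mean over layers, per edge; the
    session value is the mean over off-diagonal edges with nonzero temporal
    mean.  Degenerate edges (zero mean) are excluded and counted.
    """
    if series.n_layers < 2:
        raise ValueError("temporal CoV requires L >= 2 layers")
    mean = series.layers.mean(axis=0)
    sd = series.layers.std(axis=0)  # population (divide-by-L) convention
    n = series.n_nodes
    offdiag = ~np.eye(n, dtype=bool)
    valid = offdiag & (mean > 0)
    cov = np.full((n, n), np.nan)
    cov[valid] = sd[valid] / mean[valid]
    n_excluded = int(offdiag.sum() - valid.sum())
    if valid.sum() == 0:
        raise ValueError("all edges are degenerate (zero temporal mean)")
    iu = np.triu_indices(n, k=1)
    vals = cov[iu]
    session_mean = float(np.nanmean(vals))
    return CovSummary(cov, session_mean, n_excluded // 2, band=series.band)
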