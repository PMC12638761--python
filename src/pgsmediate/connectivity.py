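"""Band-specific spectral-coherence networks from ROI time series.

The connectivity measure is magnitude-squared-free spectral coherence,
``|S_xy| / sqrt(S_xx * S_yy)``, estimated Welch-style: the recording is cut
into Hann-tapered epochs, auto- and cross-spectra are averaged across epochs,
and the per-bin coherence is then averaged over the FFT bins falling inside a
frequency band.  Each band yields one symmetric ROI-by-ROI weighted network
per recording session; the two resting-state sessions are combined by the
element-wise mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "EpochSet",
    "WeightedNetwork",
    "segment_epochs",
    "band_coherence",
    "average_sessions",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[f_lo, f_hi]`` in Hz (closed interval)."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo <= self.f_hi):
            raise ValueError(f"invalid band limits {self.f_lo}-{self.f_hi} Hz")


#: The five resting-state bands used throughout: delta 2-3, theta 4-7,
#: low alpha 8-10, high alpha 11-13, beta 16-30 Hz.  The delta lower bound is
#: configurable (1 Hz is a common alternative convention).
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("low_alpha", 8.0, 10.0),
    BandDefinition("high_alpha", 11.0, 13.0),
    BandDefinition("beta", 16.0, 30.0),
)


@dataclass
class EpochSet:
    """Equal-length ROI x samples epochs cut from one recording."""

    epochs: np.ndarray  # (n_epochs, n_rois, n_samples)
    sample_rate: float
    epoch_length: float
    overlap: float

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_rois(self) -> int:
        return self.epochs.shape[1]


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative coherence network over labelled ROIs.

    Weights live in [0, 1]; the diagonal is stored as zero and never enters
    any metric.
    """

    w: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    band: BandDefinition | None = None
    session: str = ""

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(self.w, self.w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if np.any(self.w < -1e-12):
            raise ValueError("weights must be nonnegative")
        np.fill_diagonal(self.w, 0.0)
        if not self.roi_labels:
            self.roi_labels = [f"roi{i}" for i in range(self.w.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.w.shape[0]


def segment_epochs(
    timeseries: np.ndarray,
    sample_rate: float,
    epoch_length: float = 8.0,
    overlap: float = 0.5,
) -> EpochSet:
    """Cut a continuous ROI x samples recording into overlapping epochs.

    Epochs start every ``epoch_length * (1 - overlap)`` seconds; a trailing
    partial epoch is discarded.  The defaults (8 s, 50% overlap) give 30
    epochs from a 124 s recording.
    """
    ts = np.atleast_2d(np.asarray(timeseries, dtype=float))
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    n_per = int(round(epoch_length * sample_rate))
    step = int(round(epoch_length * (1.0 - overlap) * sample_rate))
    if step <= 0:
        raise ValueError("epoch step is zero; decrease overlap")
    n_samples = ts.shape[1]
    if n_samples < n_per:
        raise ValueError(
            f"recording of {n_samples} samples shorter than one "
            f"{n_per}-sample epoch"
        )
    starts = range(0, n_samples - n_per + 1, step)
    epochs = np.stack([ts[:, s : s + n_per] for s in starts])
    return EpochSet(epochs, sample_rate, epoch_length, overlap)


def _epoch_spectra(epochset: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered rFFT of every epoch after per-epoch mean removal.

    Returns (Z, freqs) with Z of shape (n_epochs, n_rois, n_bins).
    """
    x = epochset.epochs
    x = x - x.mean(axis=2, keepdims=True)
    taper = np.hanning(x.shape[2])
    z = np.fft.rfft(x * taper, axis=2)
    freqs = np.fft.rfftfreq(x.shape[2], d=1.0 / epochset.sample_rate)
    return z, freqs


def cross_spectra(epochset: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-averaged cross-spectral matrices S[f] (n_bins, n_rois, n_rois)."""
    z, freqs = _epoch_spectra(epochset)
    # batch over frequency: S_f = Z_f^H Z_f summed over epochs
    zf = np.transpose(z, (2, 0, 1))  # (bins, epochs, rois)
    s = np.matmul(np.conjugate(np.transpose(zf, (0, 2, 1))), zf)
    return s / epochset.n_epochs, freqs


def _band_bins(freqs: np.ndarray, band: BandDefinition, nyquist: float) -> np.ndarray:
    if band.f_hi >= nyquist:
        raise ValueError(f"band {band.name} upper edge {band.f_hi} Hz at/above Nyquist {nyquist} Hz")
    idx = np.flatnonzero((freqs >= band.f_lo) & (freqs <= band.f_hi))
    if idx.size == 0:
        raise ValueError(f"band {band.name} contains no FFT bin")
    return idx


def band_coherence(
    epochset: EpochSet,
    band: BandDefinition,
    roi_labels: list[str] | None = None,
    session: str = "",
    squared: bool = False,
) -> WeightedNetwork:
    """Mean spectral coherence over a band's FFT bins, as a network.

    Per bin, coherence = |S_xy| / sqrt(S_xx S_yy) from epoch-averaged
    spectra; the network weight is the mean over bins with
    ``f_lo <= f <= f_hi`` (bin centres, closed interval).  With ``squared``
    the magnitude-squared coherence is averaged instead.
    """
    if epochset.n_epochs < 2:
        raise ValueError("coherence needs at least 2 epochs")
    s, freqs = cross_spectra(epochset)
    auto = np.real(np.einsum("fii->fi", s))
    if np.any(auto <= 0):
        raise ValueError("constant (zero-variance) channel in epochs")
    idx = _band_bins(freqs, band, epochset.sample_rate / 2.0)
    sb = s[idx]
    ab = auto[idx]
    denom = np.sqrt(ab[:, :, None] * ab[:, None, :])
    coh = np.abs(sb) / denom
    if squared:
        coh = coh**2
    w = coh.mean(axis=0)
    w = np.clip(0.5 * (w + w.T), 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    labels = roi_labels or [f"roi{i}" for i in range(w.shape[0])]
    return WeightedNetwork(w=w, roi_labels=list(labels), band=band, session=session)


def all_band_coherence(
    epochset: EpochSet,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    roi_labels: list[str] | None = None,
    session: str = "",
) -> dict[str, WeightedNetwork]:
    """Coherence networks for several bands from one spectral pass."""
    if epochset.n_epochs < 2:
        raise ValueError("coherence needs at least 2 epochs")
    z, freqs = _epoch_spectra(epochset)
    union = np.unique(
        np.concatenate(
            [_band_bins(freqs, band, epochset.sample_rate / 2.0) for band in bands]
        )
    )
    # cross-spectra only at the bins any band needs
    zf = np.transpose(z[:, :, union], (2, 0, 1))  # (bins, epochs, rois)
    s = np.matmul(np.conjugate(np.transpose(zf, (0, 2, 1))), zf) / epochset.n_epochs
    freqs_u = freqs[union]
    auto = np.real(np.einsum("fii->fi", s))
    if np.any(auto <= 0):
        raise ValueError("constant (zero-variance) channel in epochs")
    labels = roi_labels or [f"roi{i}" for i in range(s.shape[1])]
    out: dict[str, WeightedNetwork] = {}
    for band in bands:
        idx = np.flatnonzero((freqs_u >= band.f_lo) & (freqs_u <= band.f_hi))
        ab = auto[idx]
        denom = np.sqrt(ab[:, :, None] * ab[:, None, :])
        w = (np.abs(s[idx]) / denom).mean(axis=0)
        w = np.clip(0.5 * (w + w.T), 0.0, 1.0)
        np.fill_diagonal(w, 0.0)
        out[band.name] = WeightedNetwork(
            w=w, roi_labels=list(labels), band=band, session=session
        )
    return out


def average_sessions(net1: WeightedNetwork, net2: WeightedNetwork) -> WeightedNetwork:
    """Element-wise mean of the two sessions' networks ("mean coh")."""
    if net1.w.shape != net2.w.shape:
        raise ValueError("session networks have different shapes")
    if net1.roi_labels != net2.roi_labels:
        raise ValueError("session networks have different ROI labels")
    if net1.band is not None and net2.band is not None and net1.band != net2.band:
        raise ValueError("session networks are from different bands")
    return replace(net1, w=0.5 * (net1.w + net2.w), session="mean")
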