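"""Magnitude-squared coherence from segmented multichannel recordings.

The recording model is event-related: each channel is observed in ``L``
equal segments (one per stimulus repetition), and spectra are averaged
across segments.  For channels x, y with segment-averaged cross-spectrum
``f_xy`` and auto-spectra ``f_xx``, ``f_yy``, the coherence at frequency
``lambda`` is

    c(x, y) = |f_xy|^2 / (f_xx f_yy)  in [0, 1].

Estimator choices: per-segment mean removal, a Hann taper, no overlap
(segments are experimentally defined epochs), one-sided spectrum with
bins at ``k * fs / T``.  With exactly ``L`` averaged segments the
analytic null threshold ``1 - p**(1/(L-1))`` applies, which is the
calibration the test suite verifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .model import CoherenceNetwork, ElectrodeLayout

__all__ = [
    "SegmentedRecording",
    "CoherenceSpectrum",
    "segment_coherence",
    "band_coherence",
]


@dataclass(frozen=True)
class SegmentedRecording:
    """Per-channel signals split into L equal segments.

    ``data`` has shape (n_channels, L, T); ``fs`` is the sampling rate in
    Hz; ``p`` is the significance probability carried downstream to the
    coherence threshold.
    """

    labels: tuple[str, ...]
    data: np.ndarray
    fs: float
    p: float = 0.01

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("data must have shape (n_channels, L, T)")
        if data.shape[0] != len(labels):
            raise ValueError(
                f"{len(labels)} labels but {data.shape[0]} channel arrays"
            )
        if data.shape[1] < 2:
            raise ValueError("need L >= 2 segments")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie strictly between 0 and 1")
        data.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_segments(self) -> int:
        return self.data.shape[1]

    @property
    def segment_length(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class CoherenceSpectrum:
    """Per-frequency coherence matrices: ``values[k]`` is the symmetric
    coherence matrix at ``freqs[k]`` (unit diagonal)."""

    labels: tuple[str, ...]
    freqs: np.ndarray  # (n_bins,)
    values: np.ndarray  # (n_bins, n, n)

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.shape[1] != values.shape[2]:
            raise ValueError("values must have shape (n_bins, n, n)")
        if values.shape[0] != freqs.shape[0]:
            raise ValueError("freqs and values disagree on bin count")
        freqs.setflags(write=False)
        values.setflags(write=False)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "values", values)


def segment_coherence(recording: SegmentedRecording) -> CoherenceSpectrum:
    """Coherence matrices per frequency bin, averaged over segments.

    Raises if a channel has zero variance (its auto-spectrum vanishes
    and the coherence is undefined).
    """
    data = recording.data
    n, L, T = data.shape
    variances = data.reshape(n, -1).var(axis=1)
    dead = [recording.labels[i] for i in np.flatnonzero(variances == 0.0)]
    if dead:
        raise ValueError(
            f"zero-variance channel(s): {dead}; coherence undefined"
        )

    segs = data - data.mean(axis=2, keepdims=True)  # per-segment detrend
    window = hann(T, sym=False)
    F = np.fft.rfft(segs * window, axis=2)  # (n, L, nb)

    # segment-averaged cross-spectral matrix S[a, b, k]
    S = np.einsum("alk,blk->abk", F, np.conj(F)) / L
    auto = np.real(np.einsum("aak->ak", S))  # (n, nb)
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(S) ** 2 / denom
    coh = np.where(denom > 0.0, coh, 0.0)
    # numerical slack only: estimates are analytically in [0, 1]
    coh = np.clip(coh, 0.0, 1.0)
    coh = (coh + coh.transpose(1, 0, 2)) / 2.0

    freqs = np.fft.rfftfreq(T, d=1.0 / recording.fs)
    return CoherenceSpectrum(
        labels=recording.labels,
        freqs=freqs,
        values=np.ascontiguousarray(coh.transpose(2, 0, 1)),
    )


def band_coherence(
    spectrum: CoherenceSpectrum,
    band: tuple[float, float],
    theta: float,
    layout: ElectrodeLayout,
) -> CoherenceNetwork:
    """Collapse a coherence spectrum to one network for a frequency band.

    The per-pair coherence is the arithmetic mean of the bin coherences
    with ``lo <= lambda <= hi``; the diagonal is zeroed in network form
    and ``theta`` is attached.  Channel order follows ``layout``.
    """
    lo, hi = float(band[0]), float(band[1])
    if hi < lo:
        raise ValueError(f"band limits out of order: {band}")
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if not mask.any():
        raise ValueError(
            f"band [{lo}, {hi}] Hz contains no estimated frequency bin"
        )
    if set(layout.labels) != set(spectrum.labels):
        raise ValueError("layout labels do not match spectrum channels")
    mat = spectrum.values[mask].mean(axis=0)
    # reorder channels to the layout's ordering
    idx = [spectrum.labels.index(lab) for lab in layout.labels]
    mat = mat[np.ix_(idx, idx)]
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return CoherenceNetwork(layout=layout, coherence=mat, theta=theta)
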