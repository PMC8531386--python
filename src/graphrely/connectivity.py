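"""Epoching and band-resolved functional-connectivity estimation.

Two estimators are provided, computed from the same Welch-style segment
cross-spectra within each epoch:

* weighted phase lag index (wPLI) — the asymmetry of the imaginary
  cross-spectrum distribution, ``|E[Im S_xy]| / E[|Im S_xy|]``; blind to
  zero-lag (volume-conduction-like) coupling;
* magnitude coherence (Coh) — ``|<S_xy>| / sqrt(<S_xx><S_yy>)``; sensitive
  to amplitude covariance and to phase consistency at any lag.

Both lie in [0, 1].  Band values are arithmetic means over the frequency
bins whose centre falls inside the band (half-open ``[low, high)`` so that
adjacent bands never share a bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import get_window

__all__ = [
    "Recording",
    "EpochSet",
    "BandDefinition",
    "ConnectivityStack",
    "SpectralConfig",
    "default_bands",
    "epoch_signal",
    "cross_spectra",
    "wpli",
    "coherence",
    "ConfigurationError",
    "InputError",
    "EstimationError",
]


class ConfigurationError(ValueError):
    """Invalid analysis configuration (bad band edges, spectral settings...)."""


class InputError(ValueError):
    """Invalid input data (too short, inconsistent shapes...)."""


class EstimationError(RuntimeError):
    """Estimation impossible on this input (too few segments, dead channel)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band with half-open bin membership [low, high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    def validate_against(self, sampling_rate: float) -> None:
        if self.high > sampling_rate / 2:
            raise ConfigurationError(
                f"band {self.name!r} upper edge {self.high} Hz exceeds Nyquist "
                f"({sampling_rate / 2} Hz)"
            )


def default_bands(theta_low: float = 4.0) -> list[BandDefinition]:
    """The five analysis bands: theta, alpha-1/2, beta-1/2.

    ``theta_low`` defaults to 4 Hz; pass 5.0 for the narrower theta variant.
    """
    return [
        BandDefinition("theta", theta_low, 8.0),
        BandDefinition("alpha1", 8.0, 10.5),
        BandDefinition("alpha2", 10.5, 13.0),
        BandDefinition("beta1", 13.0, 20.0),
        BandDefinition("beta2", 20.0, 30.0),
    ]


@dataclass
class Recording:
    """One participant-session-condition multichannel time series.

    ``samples`` is a (channels, time) float array in arbitrary amplitude
    units; channel order matches ``channel_labels``.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    participant_id: str = "P01"
    session_id: str = "S1"
    condition: str = "PRE"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InputError("samples must be a 2-D (channels, time) array")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise InputError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise InputError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.participant_id, self.session_id, self.condition)


@dataclass
class EpochSet:
    """Overlapping fixed-length windows cut from one Recording."""

    epochs: np.ndarray  # (n_epochs, channels, samples_per_epoch)
    sampling_rate: float
    epoch_length: float
    overlap: float
    channel_labels: list[str]
    participant_id: str = "P01"
    session_id: str = "S1"
    condition: str = "PRE"

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def span(self) -> float:
        """Seconds of consecutive source data covered by the epochs."""
        step = self.epoch_length - self.overlap
        return (self.n_epochs - 1) * step + self.epoch_length


@dataclass
class ConnectivityStack:
    """Per-epoch symmetric channel x channel connectivity matrices.

    Off-diagonal values lie in [0, 1]; the diagonal is fixed at 0 by
    convention and excluded from every downstream statistic.
    """

    matrices: np.ndarray  # (n_epochs, channels, channels)
    estimator: str  # "wpli" | "coh"
    band: BandDefinition
    channel_labels: list[str]
    participant_id: str = "P01"
    session_id: str = "S1"
    condition: str = "PRE"

    @property
    def n_epochs(self) -> int:
        return self.matrices.shape[0]

    def offdiag_values(self) -> np.ndarray:
        """All upper-triangular off-diagonal values across every epoch."""
        n = self.matrices.shape[1]
        iu = np.triu_indices(n, k=1)
        return self.matrices[:, iu[0], iu[1]].ravel()


@dataclass(frozen=True)
class SpectralConfig:
    """Welch-style within-epoch segmentation parameters.

    Defaults give 1 s Hann segments with 50% overlap, i.e. 15 segments per
    8 s epoch and 1 Hz frequency resolution at 256 Hz.
    """

    segment_length: float = 1.0  # seconds
    segment_overlap: float = 0.5  # fraction of segment_length
    window: str = "hann"
    coherence_squared: bool = False

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ConfigurationError("segment_length must be positive")
        if not (0 <= self.segment_overlap < 1):
            raise ConfigurationError("segment_overlap must be in [0, 1)")


# ---------------------------------------------------------------------------
# epoching


def epoch_signal(
    rec: Recording,
    epoch_length: float = 8.0,
    overlap: float = 4.0,
    max_epochs: int | None = 50,
) -> EpochSet:
    """Cut a recording into overlapping epochs, keeping the first ``max_epochs``.

    Epochs start at multiples of ``epoch_length - overlap`` seconds from the
    start of the recording.  With the defaults (8 s epochs, 4 s overlap,
    first 50 epochs) the retained epochs cover 204 s = 3.4 min of
    consecutive data.
    """
    if not (epoch_length > overlap >= 0):
        raise ConfigurationError("need epoch_length > overlap >= 0")
    fs = rec.sampling_rate
    n_len = int(round(epoch_length * fs))
    step = int(round((epoch_length - overlap) * fs))
    if step <= 0:
        raise ConfigurationError("epoch step rounds to zero samples")
    if rec.n_samples < n_len:
        raise InputError(
            f"recording of {rec.duration:.3f} s is shorter than one "
            f"{epoch_length} s epoch"
        )
    n_avail = (rec.n_samples - n_len) // step + 1
    n_keep = n_avail if max_epochs is None else min(n_avail, max_epochs)
    starts = np.arange(n_keep) * step
    epochs = np.stack([rec.samples[:, s : s + n_len] for s in starts])
    return EpochSet(
        epochs=epochs,
        sampling_rate=fs,
        epoch_length=epoch_length,
        overlap=overlap,
        channel_labels=list(rec.channel_labels),
        participant_id=rec.participant_id,
        session_id=rec.session_id,
        condition=rec.condition,
    )


# ---------------------------------------------------------------------------
# spectral kernel


def _segment_ffts(
    epoch: np.ndarray, sampling_rate: float, config: SpectralConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Tapered segment DFTs of one epoch.

    Returns ``(freqs, Z)`` with ``Z`` of shape (n_segments, n_channels,
    n_freqs).  The estimators below are ratios, so no density scaling is
    applied.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n_ch, n_t = epoch.shape
    nper = int(round(config.segment_length * sampling_rate))
    if nper > n_t:
        raise EstimationError(
            f"segment length {nper} samples exceeds epoch length {n_t}"
        )
    step = max(1, int(round(nper * (1 - config.segment_overlap))))
    starts = np.arange(0, n_t - nper + 1, step)
    if len(starts) < 2:
        raise EstimationError(
            "need at least 2 segments per epoch for cross-spectral estimation"
        )
    win = get_window(config.window, nper)
    segs = np.stack([epoch[:, s : s + nper] for s in starts])  # (S, C, nper)
    Z = np.fft.rfft(segs * win, axis=-1)
    freqs = np.fft.rfftfreq(nper, d=1.0 / sampling_rate)
    return freqs, Z


def cross_spectra(
    epoch: np.ndarray,
    sampling_rate: float,
    segment_length: float = 1.0,
    segment_overlap: float = 0.5,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment complex cross-spectra of one epoch.

    Returns ``(freqs, S)`` where ``S[s, i, j, f] = Z_i(f) conj(Z_j(f))`` for
    segment ``s``.  Auto-spectra sit on the diagonal ``S[s, i, i, f]``.
    Frequency resolution is ``sampling_rate / segment_length_in_samples``.
    """
    cfg = SpectralConfig(segment_length=segment_length,
                         segment_overlap=segment_overlap, window=window)
    freqs, Z = _segment_ffts(epoch, sampling_rate, cfg)
    S = np.einsum("scf,sdf->scdf", Z, np.conj(Z))
    return freqs, S


def _band_bins(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = (freqs >= band.low) & (freqs < band.high)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ConfigurationError(
            f"no frequency bins inside band {band.name!r} "
            f"[{band.low}, {band.high}) at resolution "
            f"{freqs[1] - freqs[0]:.4g} Hz"
        )
    return idx


def _validate_band(band: BandDefinition, sampling_rate: float) -> None:
    band.validate_against(sampling_rate)


def wpli(
    epochs: EpochSet,
    band: BandDefinition,
    config: SpectralConfig | None = None,
) -> ConnectivityStack:
    """Weighted phase lag index per epoch and channel pair.

    Per frequency bin, ``wPLI = |sum_s Im S_xy,s| / sum_s |Im S_xy,s]|``
    over within-epoch segments ``s``; a bin with zero denominator (pure
    zero-lag) is defined as 0.  Band values average the bins inside
    ``[low, high)``.
    """
    config = config or SpectralConfig()
    _validate_band(band, epochs.sampling_rate)
    n_ep, n_ch, _ = epochs.epochs.shape
    out = np.zeros((n_ep, n_ch, n_ch))
    for e in range(n_ep):
        freqs, Z = _segment_ffts(epochs.epochs[e], epochs.sampling_rate, config)
        bins = _band_bins(freqs, band)
        Zb = Z[:, :, bins]  # (S, C, B)
        sxy = np.einsum("scb,sdb->scdb", Zb, np.conj(Zb))  # (S, C, C, B)
        imag = sxy.imag
        num = np.abs(imag.sum(axis=0))
        den = np.abs(imag).sum(axis=0)
        # zero-denominator convention with a relative floor: an imaginary
        # part that is pure roundoff next to the cross-spectrum magnitude
        # (zero-lag coupling) counts as zero
        floor = 1e-12 * np.abs(sxy).sum(axis=0)
        ok = den > floor
        with np.errstate(invalid="ignore", divide="ignore"):
            per_bin = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
        mat = per_bin.mean(axis=-1)
        np.fill_diagonal(mat, 0.0)
        out[e] = 0.5 * (mat + mat.T)  # symmetric by construction; enforce exactly
    np.clip(out, 0.0, 1.0, out=out)
    return ConnectivityStack(
        matrices=out, estimator="wpli", band=band,
        channel_labels=list(epochs.channel_labels),
        participant_id=epochs.participant_id,
        session_id=epochs.session_id, condition=epochs.condition,
    )


def coherence(
    epochs: EpochSet,
    band: BandDefinition,
    config: SpectralConfig | None = None,
) -> ConnectivityStack:
    """Magnitude coherence per epoch and channel pair.

    ``Coh = |<S_xy>_s| / sqrt(<S_xx>_s <S_yy>_s)`` with segment averages,
    then averaged over band bins.  Set ``config.coherence_squared`` for
    magnitude-squared coherence.
    """
    config = config or SpectralConfig()
    _validate_band(band, epochs.sampling_rate)
    n_ep, n_ch, _ = epochs.epochs.shape
    ptp = np.ptp(epochs.epochs, axis=-1)  # (E, C)
    if np.any(ptp.max(axis=0) == 0):
        dead = [epochs.channel_labels[i]
                for i in np.flatnonzero(ptp.max(axis=0) == 0)]
        raise EstimationError(
            f"constant channel(s) {dead}: auto-spectrum is zero, coherence undefined"
        )
    out = np.zeros((n_ep, n_ch, n_ch))
    for e in range(n_ep):
        freqs, Z = _segment_ffts(epochs.epochs[e], epochs.sampling_rate, config)
        bins = _band_bins(freqs, band)
        Zb = Z[:, :, bins]
        Sxy = np.einsum("scb,sdb->cdb", Zb, np.conj(Zb)) / Zb.shape[0]
        auto = np.einsum("ccb->cb", Sxy).real  # auto-spectra: (C, B)
        denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
        if np.any(denom == 0):
            raise EstimationError("zero auto-spectrum inside band")
        c = np.abs(Sxy) / denom
        if config.coherence_squared:
            c = c**2
        mat = c.mean(axis=-1)
        np.fill_diagonal(mat, 0.0)
        out[e] = 0.5 * (mat + mat.T)
    np.clip(out, 0.0, 1.0, out=out)
    return ConnectivityStack(
        matrices=out, estimator="coh", band=band,
        channel_labels=list(epochs.channel_labels),
        participant_id=epochs.participant_id,
        session_id=epochs.session_id, condition=epochs.condition,
    )
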