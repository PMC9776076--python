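"""Band filtering, epoch segmentation, and clean-epoch selection.

A continuous multichannel recording is high-pass filtered to remove DC
drift, notch filtered to remove mains interference, band-pass filtered into
one of six conventional EEG frequency bands, consecutively segmented into
non-overlapping fixed-duration epochs, and reduced to the first *n* epochs
whose peak-to-peak amplitude stays below an artifact threshold on every
channel.

All filters are 4th-order Butterworth designs applied forward-backward
(zero-phase), so epoch boundaries are not shifted by group delay. Filtering
happens on the continuous record *before* segmentation to keep filter edge
artifacts out of the one-second windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class Recording:
    """A labeled multichannel signal block at a fixed sampling rate.

    data is channels x samples; ``labels`` names the rows.
    """

    labels: tuple[str, ...]
    sampling_rate: float
    data: np.ndarray
    stage: int | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[0] != len(self.labels):
            raise ValueError(
                f"data must be (n_channels={len(self.labels)}) x samples, "
                f"got shape {data.shape}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band given by its name and edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")


#: The six conventional EEG bands.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 32.0),
    BandDefinition("low_gamma", 32.0, 50.0),
    BandDefinition("high_gamma", 50.0, 80.0),
)

BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in BANDS}

#: The bands in which visual/cognitive network effects concentrate.
HIGH_FREQUENCY_BANDS: tuple[str, ...] = ("beta", "low_gamma", "high_gamma")


@dataclass(frozen=True)
class EpochSet:
    """Fixed-duration epochs of a recording restricted to one band.

    epochs is epoch x channel x sample. ``n_requested`` and ``shortfall``
    record clean-epoch selection bookkeeping (``shortfall`` is set when
    fewer clean epochs than requested were available).
    """

    epochs: np.ndarray
    labels: tuple[str, ...]
    sampling_rate: float
    band: BandDefinition | None = None
    stage: int | None = None
    duration: float = 1.0
    n_requested: int | None = None
    shortfall: bool = False
    warnings_: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        epochs = np.asarray(self.epochs, dtype=float)
        object.__setattr__(self, "epochs", epochs)
        if epochs.ndim != 3:
            raise ValueError("epochs must be epoch x channel x sample")
        if epochs.shape[1] != len(self.labels):
            raise ValueError("channel count does not match labels")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def _check_cutoff(cutoff: float, fs: float) -> None:
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {fs / 2} Hz")


def highpass_filter(rec: Recording, cutoff: float = 0.53, order: int = 4) -> Recording:
    """Remove DC offset and slow drift with a zero-phase high-pass filter."""
    _check_cutoff(cutoff, rec.sampling_rate)
    sos = signal.butter(order, cutoff, btype="highpass", fs=rec.sampling_rate,
                        output="sos")
    return replace(rec, data=signal.sosfiltfilt(sos, rec.data, axis=-1))


def notch_filter(rec: Recording, low: float = 59.0, high: float = 61.0,
                 order: int = 4) -> Recording:
    """Suppress mains interference with a zero-phase band-stop filter."""
    if not 0 < low < high:
        raise ValueError(f"invalid notch band ({low}, {high})")
    _check_cutoff(high, rec.sampling_rate)
    sos = signal.butter(order, [low, high], btype="bandstop",
                        fs=rec.sampling_rate, output="sos")
    return replace(rec, data=signal.sosfiltfilt(sos, rec.data, axis=-1))


def bandpass_filter(rec: Recording, band: BandDefinition, order: int = 4) -> Recording:
    """Restrict a recording to one frequency band (zero-phase band-pass)."""
    _check_cutoff(band.high, rec.sampling_rate)
    sos = signal.butter(order, [band.low, band.high], btype="bandpass",
                        fs=rec.sampling_rate, output="sos")
    return replace(rec, data=signal.sosfiltfilt(sos, rec.data, axis=-1))


def bandpass_array(x: np.ndarray, band: BandDefinition, fs: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase band-pass on a bare array; same filter as `bandpass_filter`."""
    if band.high >= fs / 2:
        raise ValueError(f"band edge {band.high} Hz >= Nyquist {fs / 2} Hz")
    sos = signal.butter(order, [band.low, band.high], btype="bandpass",
                        fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def segment_epochs(rec: Recording, duration: float = 1.0,
                   band: BandDefinition | None = None) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    The trailing remainder shorter than one epoch is discarded.
    """
    if duration <= 0:
        raise ValueError("epoch duration must be positive")
    samples_per_epoch = int(round(duration * rec.sampling_rate))
    n_epochs = rec.n_samples // samples_per_epoch
    if n_epochs == 0:
        raise ValueError(
            f"recording shorter ({rec.duration:.3f} s) than one epoch "
            f"({duration} s)")
    used = n_epochs * samples_per_epoch
    epochs = rec.data[:, :used].reshape(rec.n_channels, n_epochs,
                                        samples_per_epoch)
    epochs = np.transpose(epochs, (1, 0, 2)).copy()
    return EpochSet(epochs=epochs, labels=rec.labels,
                    sampling_rate=rec.sampling_rate, band=band,
                    stage=rec.stage, duration=duration)


def select_clean_epochs(es: EpochSet, n: int = 50,
                        ptp_limit: float = 100.0) -> EpochSet:
    """Keep the first ``n`` epochs that are clean on every channel.

    An epoch is clean when its per-channel peak-to-peak amplitude is at most
    ``ptp_limit`` on all channels. If fewer than ``n`` epochs qualify, all
    qualifying epochs are returned and the result is flagged (``shortfall``)
    rather than raising: downstream code can decide whether a short stage is
    usable.
    """
    if n < 1:
        raise ValueError("must request at least one epoch")
    ptp = np.ptp(es.epochs, axis=-1)        # epoch x channel
    clean = np.all(ptp <= ptp_limit, axis=1)
    idx = np.flatnonzero(clean)[:n]
    shortfall = idx.size < n
    notes = es.warnings_
    if shortfall:
        msg = (f"only {idx.size} of the requested {n} clean epochs available "
               f"(ptp_limit={ptp_limit})")
        warnings.warn(msg, stacklevel=2)
        notes = notes + (msg,)
    return replace(es, epochs=es.epochs[idx], n_requested=n,
                   shortfall=shortfall, warnings_=notes)


def band_limited_epochs(rec: Recording, band: BandDefinition,
                        duration: float = 1.0, n_epochs: int = 50,
                        ptp_limit: float = 100.0,
                        highpass_cutoff: float = 0.53,
                        notch: tuple[float, float] | None = (59.0, 61.0),
                        ) -> EpochSet:
    """Full preprocessing chain: high-pass, notch, band-pass, segment, select."""
    out = highpass_filter(rec, highpass_cutoff)
    if notch is not None:
        out = notch_filter(out, *notch)
    out = bandpass_filter(out, band)
    es = segment_epochs(out, duration=duration, band=band)
    return select_clean_epochs(es, n=n_epochs, ptp_limit=ptp_limit)
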