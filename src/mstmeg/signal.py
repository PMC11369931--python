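"""Band-pass filtering and analytic-envelope extraction.

Filtering follows the MEG convention of a high-order FIR designed with a
Hann window, applied forward and backward (two-pass) so the net response is
zero-phase with the squared magnitude of the one-pass design.  Epochs are
padded by reflection before filtering to suppress edge transients; the pad
length is truncated (and logged) when an epoch is too short to supply it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import firwin, filtfilt, hilbert

logger = logging.getLogger(__name__)

#: FIR order of the band-pass filter (number of taps minus one).
DEFAULT_FILTER_ORDER = 450
#: Reflection padding, in samples, applied at each epoch edge before filtering.
DEFAULT_PAD_SAMPLES = 2000


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_against(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name!r}: high edge {self.high} Hz is not below "
                f"the Nyquist frequency {fs / 2} Hz"
            )


THETA = BandSpec("theta", 4.0, 8.0)
ALPHA = BandSpec("alpha", 8.0, 13.0)
BETA = BandSpec("beta", 13.0, 30.0)
DEFAULT_BANDS: tuple[BandSpec, ...] = (THETA, ALPHA, BETA)


def band_from_name(name: str) -> BandSpec:
    for band in DEFAULT_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band name {name!r}; known: "
                   f"{[b.name for b in DEFAULT_BANDS]}")


@dataclass
class EpochedTimeSeries:
    """Region x epoch x sample array with sampling-rate metadata.

    The canonical unit consumed by the connectivity stage: ``data[r, e, t]``
    is the signal of region ``r`` in epoch ``e`` at sample ``t``.
    """

    data: np.ndarray
    fs: float
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be region x epoch x sample (3-d), got shape {self.data.shape}"
            )
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 regions")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.region_labels:
            self.region_labels = [f"region_{i:03d}" for i in range(self.n_regions)]
        if len(self.region_labels) != self.n_regions:
            raise ValueError("region_labels length does not match region count")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def design_bandpass(band: BandSpec, fs: float,
                    order: int = DEFAULT_FILTER_ORDER) -> np.ndarray:
    """Hann-window FIR band-pass taps (``order + 1`` of them)."""
    band.validate_against(fs)
    return firwin(order + 1, [band.low, band.high], window="hann",
                  pass_zero=False, fs=fs)


def bandpass_filter(ts: EpochedTimeSeries, band: BandSpec,
                    order: int = DEFAULT_FILTER_ORDER,
                    pad_samples: int = DEFAULT_PAD_SAMPLES) -> EpochedTimeSeries:
    """Zero-phase band-pass filter every region and epoch.

    Two-pass (forward-backward) application of the FIR, so the effective
    magnitude response is the square of the one-pass design and the phase
    response is identically zero.

    Parameters
    ----------
    ts : EpochedTimeSeries
    band : BandSpec
        Pass band; must lie below Nyquist.
    order : int
        FIR order. The epoch must be longer than the order.
    pad_samples : int
        Reflection padding per edge; truncated to the available epoch
        length (minus one) when epochs are short, with a log notice.
    """
    b = design_bandpass(band, ts.fs, order=order)
    n = ts.n_samples
    if n <= order:
        raise ValueError(
            f"epoch length {n} must exceed the filter order {order}"
        )
    padlen = min(pad_samples, n - 1)
    if padlen < pad_samples:
        logger.info(
            "bandpass_filter: padding truncated from %d to %d samples "
            "(epoch length %d)", pad_samples, padlen, n,
        )
    logger.debug(
        "bandpass_filter: band=%s order=%d padlen=%d fs=%g", band.name, order,
        padlen, ts.fs,
    )
    out = filtfilt(b, [1.0], ts.data, axis=-1, padtype="even", padlen=padlen)
    return replace(ts, data=out)


def analytic_envelope(ts: EpochedTimeSeries) -> EpochedTimeSeries:
    """Magnitude of the analytic (Hilbert) signal, per region and epoch.

    The input is assumed band-limited; the result is nonnegative and, for a
    narrow-band carrier with a slowly varying amplitude, recovers that
    amplitude.
    """
    env = np.abs(hilbert(ts.data, axis=-1))
    return replace(ts, data=env)
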