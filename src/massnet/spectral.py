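"""Spectral outcome measures for multichannel epochs, simulated or external.

Every channel (neural mass or virtual electrode) is Fourier-transformed to a
power spectrum; outcome measures are the relative power in standard frequency
bands, the total (absolute broadband, 0.5-48 Hz) power, and the peak
frequency (spectral argmax restricted to 4-13 Hz by default).  Whole-brain
values average the per-channel measures within an iteration; batch values
then average over iterations.  For simulated data the mean pyramidal pulse
density over time and masses ("spike density") is carried along as the
neuronal-activity readout.

The default estimator is a full-epoch periodogram with linear detrend and a
rectangular window, for which the one-sided spectrum sums exactly to the
variance of the detrended signal (Parseval); window and band edges are
configurable.  Band intervals are half-open [low, high) so that a disjoint
band set covering the broadband partitions its power exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BROADBAND",
    "PEAK_RANGE",
    "SpectralSummary",
    "power_spectrum",
    "band_power",
    "relative_band_powers",
    "peak_frequency",
    "whole_brain_summary",
    "summarize_batch",
    "normalized_average_spectrum",
]


class BandDefinition(NamedTuple):
    """Frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

BROADBAND = BandDefinition("broadband", 0.5, 48.0)

#: default search range for the dominant-rhythm peak, Hz (closed interval)
PEAK_RANGE = (4.0, 13.0)

MIN_SAMPLES = 256


def power_spectrum(
    signal: np.ndarray,
    dt: float,
    window: str = "boxcar",
    detrend: str = "linear",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of one channel (or of channels along axis 0).

    Returns (frequencies [Hz], power per bin [signal-units^2]).  With the
    default rectangular window the power bins sum to the variance of the
    detrended signal exactly.
    """
    x = np.asarray(signal, dtype=float)
    if x.shape[0] < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {x.shape[0]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    freqs, power = scipy.signal.periodogram(
        x, fs=1.0 / dt, window=window, detrend=detrend, scaling="spectrum", axis=0
    )
    return freqs, power


def band_power(freqs: np.ndarray, power: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Total power in [low, high), summed over bins (axis 0)."""
    mask = (freqs >= band.low) & (freqs < band.high)
    return power[mask].sum(axis=0)


def relative_band_powers(
    freqs: np.ndarray,
    power: np.ndarray,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    broadband: BandDefinition = BROADBAND,
) -> dict[str, np.ndarray]:
    """Band power divided by broadband power, per band."""
    for b in bands:
        if b.low < broadband.low or b.high > broadband.high:
            raise ValueError(f"band {b.name} [{b.low},{b.high}) outside broadband")
    total = band_power(freqs, power, broadband)
    if np.any(total <= 0):
        raise ValueError("zero broadband power; relative powers undefined")
    return {b.name: band_power(freqs, power, b) / total for b in bands}


def peak_frequency(
    freqs: np.ndarray,
    power: np.ndarray,
    range_low: float = PEAK_RANGE[0],
    range_high: float = PEAK_RANGE[1],
) -> float | np.ndarray:
    """Frequency of maximum power within the closed search range.

    Ties break toward the lower frequency (first argmax).  Requires the
    spectral resolution to be finer than 0.5 Hz.
    """
    mask = (freqs >= range_low) & (freqs <= range_high)
    if not np.any(mask):
        raise ValueError(f"empty peak search range [{range_low}, {range_high}] Hz")
    if freqs.size > 1 and (freqs[1] - freqs[0]) > 0.5:
        raise ValueError("spectral resolution coarser than 0.5 Hz; epoch too short")
    sel = freqs[mask]
    idx = np.argmax(power[mask], axis=0)
    out = sel[idx]
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class SpectralSummary:
    """Whole-brain outcome measures, aggregated over iterations.

    ``rel_power``/``total_power``/``peak_frequency``/``mean_spike_density``
    are iteration means; ``dispersion`` maps each measure name to its
    across-iteration standard deviation (zero for a single iteration);
    ``per_iteration`` holds one row per iteration.
    """

    rel_power: dict[str, float]
    total_power: float
    peak_frequency: float
    mean_spike_density: float | None
    n_iterations: int
    dispersion: dict[str, float]
    per_iteration: pd.DataFrame = field(repr=False)

    def measure(self, name: str) -> float:
        """Scalar mean of a named measure (band name or measure column)."""
        if name in self.rel_power:
            return self.rel_power[name]
        return float(getattr(self, name))


def _iteration_row(
    epochs: np.ndarray,
    dt: float,
    bands: Sequence[BandDefinition],
    broadband: BandDefinition,
    peak_range: tuple[float, float],
    spike_density: float | None,
    window: str,
) -> dict[str, float]:
    """Per-channel measures averaged across channels for one iteration.

    ``epochs``: (samples, channels).
    """
    if epochs.ndim == 1:
        epochs = epochs[:, None]
    if epochs.shape[1] < 1:
        raise ValueError("need at least one channel")
    freqs, power = power_spectrum(epochs, dt, window=window)
    rel = relative_band_powers(freqs, power, bands, broadband)
    row = {name: float(np.mean(vals)) for name, vals in rel.items()}
    row["total_power"] = float(np.mean(band_power(freqs, power, broadband)))
    row["peak_frequency"] = float(np.mean(peak_frequency(freqs, power, *peak_range)))
    if spike_density is not None:
        row["mean_spike_density"] = spike_density
    return row


def _as_epochs_and_density(result) -> tuple[np.ndarray, float, float | None]:
    """Accept a SimulationResult or a (samples, channels) array (+ dt)."""
    if hasattr(result, "meg_like"):
        epochs = np.asarray(result.meg_like, dtype=float).T
        density = float(np.mean(result.pulse_density))
        return epochs, float(result.dt), density
    raise TypeError(
        "expected a SimulationResult; pass plain arrays with an explicit dt "
        "via whole_brain_summary(epochs, dt=...)"
    )


def whole_brain_summary(
    result,
    dt: float | None = None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    broadband: BandDefinition = BROADBAND,
    peak_range: tuple[float, float] = PEAK_RANGE,
    window: str = "boxcar",
) -> SpectralSummary:
    """Outcome measures for one iteration (one run or one epoch matrix).

    ``result`` is a :class:`~massnet.network_sim.SimulationResult`, or a
    (samples, channels) array with ``dt`` given, in which case no spike
    density is reported (external data carry no pulse-density readout).
    """
    if hasattr(result, "meg_like"):
        epochs, dt, density = _as_epochs_and_density(result)
    else:
        if dt is None:
            raise ValueError("dt is required for plain epoch arrays")
        epochs = np.asarray(result, dtype=float)
        density = None
    row = _iteration_row(epochs, dt, bands, broadband, peak_range, density, window)
    return _aggregate_rows([row], bands)


def _aggregate_rows(
    rows: list[dict[str, float]], bands: Sequence[BandDefinition]
) -> SpectralSummary:
    table = pd.DataFrame(rows)
    means = table.mean()
    stds = table.std(ddof=1) if len(rows) > 1 else table.iloc[0] * 0.0
    band_names = [b.name for b in bands]
    return SpectralSummary(
        rel_power={b: float(means[b]) for b in band_names},
        total_power=float(means["total_power"]),
        peak_frequency=float(means["peak_frequency"]),
        mean_spike_density=(
            float(means["mean_spike_density"]) if "mean_spike_density" in table else None
        ),
        n_iterations=len(rows),
        dispersion={c: float(stds[c]) for c in table.columns},
        per_iteration=table,
    )


def summarize_batch(
    results: Iterable,
    dt: float | None = None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    broadband: BandDefinition = BROADBAND,
    peak_range: tuple[float, float] = PEAK_RANGE,
    window: str = "boxcar",
) -> SpectralSummary:
    """Aggregate a Monte-Carlo batch: measures per iteration, then averaged."""
    rows = []
    for result in results:
        if hasattr(result, "meg_like"):
            epochs, this_dt, density = _as_epochs_and_density(result)
        else:
            if dt is None:
                raise ValueError("dt is required for plain epoch arrays")
            epochs, this_dt, density = np.asarray(result, dtype=float), dt, None
        rows.append(
            _iteration_row(epochs, this_dt, bands, broadband, peak_range, density, window)
        )
    if not rows:
        raise ValueError("empty batch")
    return _aggregate_rows(rows, bands)


def normalized_average_spectrum(
    results: Iterable,
    dt: float | None = None,
    window: str = "boxcar",
) -> tuple[np.ndarray, np.ndarray]:
    """Grand-average power spectrum rescaled to unit total power.

    Averages spectra over channels and iterations, then normalises so the
    bins sum to 1.  Scale-invariant: rescaling all signals by a common factor
    leaves the output unchanged.
    """
    accum = None
    count = 0
    freqs = None
    for result in results:
        if hasattr(result, "meg_like"):
            epochs, this_dt, _ = _as_epochs_and_density(result)
        else:
            if dt is None:
                raise ValueError("dt is required for plain epoch arrays")
            epochs, this_dt = np.asarray(result, dtype=float), dt
        if epochs.ndim == 1:
            epochs = epochs[:, None]
        freqs, power = power_spectrum(epochs, this_dt, window=window)
        mean_over_channels = power.mean(axis=1)
        accum = mean_over_channels if accum is None else accum + mean_over_channels
        count += 1
    if count == 0:
        raise ValueError("empty batch")
    avg = accum / count
    total = avg.sum()
    if total <= 0:
        raise ValueError("zero total power; cannot normalise")
    return freqs, avg / total
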