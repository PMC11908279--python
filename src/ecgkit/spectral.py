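"""Power spectra and the two diagnostics that gate harmonization.

Two spectral rules decide what the harmonization pipeline does to a
record:

1. *Low-frequency excess* — the mean log10 power below 1 Hz minus the
   mean log10 power in the 1-30 Hz clinical band. When the excess is
   above one logarithmic unit the record carries baseline wander and the
   1 Hz high-pass stage fires.
2. *Artifact-peak detection* — powerline interference (50/60 Hz and
   harmonics) is flagged when the log-power in a narrow zone around a
   candidate frequency exceeds the local mean by more than ``k_sd``
   standard deviations of the surrounding bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .records import ECGRecord

__all__ = [
    "PowerSpectrum",
    "ArtifactPeak",
    "power_spectrum",
    "lowfreq_excess",
    "detect_artifact_peaks",
    "LOWFREQ_TRIGGER",
]

#: trigger threshold for the high-pass stage, in log10 units
LOWFREQ_TRIGGER = 1.0

# floor applied before log10 so that empty bins stay finite
_LOG_FLOOR = 1e-300


@dataclass
class PowerSpectrum:
    """Per-lead Welch power spectral density estimate.

    ``power`` is ``(n_leads, n_freqs)`` in mV²/Hz; ``freqs`` ascend from
    0 to fs/2.
    """

    freqs: np.ndarray
    power: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.power.shape[1] != self.freqs.size:
            raise ValueError("power columns must match frequency bins")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def n_leads(self) -> int:
        return self.power.shape[0]

    @property
    def log_power(self) -> np.ndarray:
        """log10 power with a tiny floor so all-zero spectra stay finite."""
        return np.log10(np.maximum(self.power, _LOG_FLOOR))

    def pooled_log_power(self) -> np.ndarray:
        """log10 of the lead-averaged power (averaging before the log)."""
        return np.log10(np.maximum(self.power.mean(axis=0), _LOG_FLOOR))


@dataclass
class ArtifactPeak:
    """A detected interference peak in a power spectrum.

    ``lead`` is None when detection pooled all leads. ``harmonic_of`` is
    the base frequency in Hz when the peak is a higher harmonic of a
    candidate powerline frequency, else None.
    """

    center_hz: float
    excess_sd: float
    lead: int | None = None
    harmonic_of: float | None = None


def power_spectrum(
    record: ECGRecord, segment_s: float = 2.0, overlap_frac: float = 0.5
) -> PowerSpectrum:
    """Welch averaged-periodogram PSD per lead (Hann window).

    Frequency resolution is 1/segment_s. Each segment is mean-detrended,
    which keeps the DC component from leaking into sub-1 Hz bins.
    """
    if segment_s <= 0:
        raise ValueError("segment_s must be positive")
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    nperseg = int(round(segment_s * record.fs))
    if nperseg > record.n_samples:
        raise ValueError(
            f"segment of {segment_s} s exceeds record duration "
            f"{record.duration_s:.3g} s"
        )
    freqs, power = signal.welch(
        record.waveform,
        fs=record.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return PowerSpectrum(freqs=freqs, power=power, fs=record.fs)


def lowfreq_excess(
    spectrum: PowerSpectrum,
    low_band: tuple[float, float] = (0.0, 1.0),
    ref_band: tuple[float, float] = (1.0, 30.0),
) -> np.ndarray:
    """Per-lead low-frequency excess in log10 units.

    mean(log10 power) over the open sub-1 Hz band minus mean(log10 power)
    over the 1-30 Hz reference band. Values above ``LOWFREQ_TRIGGER``
    (one logarithmic unit) indicate baseline wander. Invariant to global
    amplitude rescaling of the record (the log-ratio cancels it).
    """
    f = spectrum.freqs
    low = (f > low_band[0]) & (f < low_band[1])
    ref = (f >= ref_band[0]) & (f <= ref_band[1])
    if not low.any():
        raise ValueError(
            f"no frequency bins inside ({low_band[0]}, {low_band[1]}) Hz; "
            "recompute the spectrum with a longer segment_s"
        )
    if not ref.any():
        raise ValueError(
            f"no frequency bins inside [{ref_band[0]}, {ref_band[1]}] Hz"
        )
    lp = spectrum.log_power
    return lp[:, low].mean(axis=1) - lp[:, ref].mean(axis=1)


def detect_artifact_peaks(
    spectrum: PowerSpectrum,
    local_window_hz: float = 5.0,
    exclusion_hz: float = 1.0,
    k_sd: float = 2.0,
    candidate_bases: Sequence[float] = (50.0, 60.0),
    max_harmonics: int = 3,
    pooled: bool = True,
    min_prominence_db: float = 6.0,
) -> list[ArtifactPeak]:
    """Detect powerline peaks at candidate bases and their harmonics.

    For each candidate frequency (base × 1..max_harmonics, below
    Nyquist), the statistic is the mean log10 power over the ±
    ``exclusion_hz`` zone around the candidate, compared against the mean
    + ``k_sd`` × SD of the per-bin log10 power in the surrounding ±
    ``local_window_hz`` window (the zone itself excluded from the
    baseline). Averaging over the zone makes a single noisy bin unlikely
    to trip the threshold, while a genuine tone lifts the zone by orders
    of magnitude.

    A peak must also be at least ``min_prominence_db`` above the local
    mean in absolute terms: single-record spectra are noisy enough that
    purely relative exceedances of 2-4 SD occur on clean input, but
    those sit well under 1 dB, whereas any interference tone worth
    removing stands 20+ dB proud of the floor. Detection runs on the
    lead-averaged spectrum by default (``pooled=True``) or per lead.
    """
    if local_window_hz <= exclusion_hz:
        raise ValueError("local_window_hz must exceed exclusion_hz")
    f = spectrum.freqs
    resolution = f[1] - f[0]
    if local_window_hz <= resolution:
        raise ValueError("local_window_hz must exceed the spectral resolution")
    nyquist = spectrum.fs / 2

    if pooled:
        log_rows: list[tuple[int | None, np.ndarray]] = [
            (None, spectrum.pooled_log_power())
        ]
    else:
        lp = spectrum.log_power
        log_rows = [(i, lp[i]) for i in range(spectrum.n_leads)]

    peaks: list[ArtifactPeak] = []
    for base in candidate_bases:
        for h in range(1, max_harmonics + 1):
            center = base * h
            if center >= nyquist:
                break
            if any(abs(p.center_hz - center) < resolution / 2 and p.lead is None
                   for p in peaks):
                continue  # 50/60 harmonic collision (e.g. 300 Hz)
            dist = np.abs(f - center)
            zone = dist <= exclusion_hz
            window = (dist > exclusion_hz) & (dist <= local_window_hz)
            if window.sum() < 5:
                raise ValueError(
                    f"fewer than 5 baseline bins around {center} Hz; widen "
                    "local_window_hz or use a longer segment_s"
                )
            for lead, lp_row in log_rows:
                stat = lp_row[zone].mean()
                mu = lp_row[window].mean()
                sd = lp_row[window].std(ddof=1)
                if sd <= 0:
                    continue
                excess = (stat - mu) / sd
                prominent = (stat - mu) >= min_prominence_db / 10.0
                if excess > k_sd and prominent:
                    peaks.append(
                        ArtifactPeak(
                            center_hz=float(center),
                            excess_sd=float(excess),
                            lead=lead,
                            harmonic_of=float(base) if h > 1 else None,
                        )
                    )
    return peaks
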