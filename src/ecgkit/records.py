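"""Core waveform container shared by every pipeline stage.

A record is a ``(n_leads, n_samples)`` matrix of voltages in millivolts
plus its sampling rate and lead names. Optional demographics (age, sex)
ride along so downstream audits can group by them. ``meta`` is a free-form
dict; the synthetic generators use it to store exact contamination traces
so tests have a subtraction oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ECGRecord"]


@dataclass
class ECGRecord:
    """A multichannel ECG waveform in physical units.

    Parameters
    ----------
    waveform:
        ``(n_leads, n_samples)`` float array, millivolts.
    fs:
        Sampling rate in Hz.
    lead_names:
        One name per lead (e.g. ``["I", "II", ..., "V6"]``).
    age, sex:
        Optional per-record demographics (years; arbitrary category).
    source_id:
        Identifier of the dataset/record this waveform came from.
    meta:
        Free-form metadata. Generators store injected contamination
        traces here under ``"contaminations"``.
    """

    waveform: np.ndarray
    fs: float
    lead_names: list[str] = field(default_factory=list)
    age: float | None = None
    sex: str | None = None
    source_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.waveform = np.atleast_2d(np.asarray(self.waveform, dtype=float))
        if self.waveform.ndim != 2:
            raise ValueError("waveform must be a (n_leads, n_samples) matrix")
        if self.waveform.shape[0] < 1 or self.waveform.shape[1] < 1:
            raise ValueError("waveform must contain at least one lead and one sample")
        if not np.isfinite(self.waveform).all():
            bad = np.argwhere(~np.isfinite(self.waveform))[0]
            raise ValueError(
                f"waveform contains a non-finite value at lead {bad[0]}, sample {bad[1]}"
            )
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.lead_names:
            self.lead_names = [f"lead{i}" for i in range(self.n_leads)]
        if len(self.lead_names) != self.n_leads:
            raise ValueError(
                f"{len(self.lead_names)} lead names for {self.n_leads} leads"
            )

    @property
    def n_leads(self) -> int:
        return self.waveform.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveform.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self, *, waveform: np.ndarray | None = None) -> "ECGRecord":
        """Deep copy, optionally swapping in a new waveform of the same shape."""
        wf = self.waveform.copy() if waveform is None else np.asarray(waveform, float)
        return ECGRecord(
            waveform=wf,
            fs=self.fs,
            lead_names=list(self.lead_names),
            age=self.age,
            sex=self.sex,
            source_id=self.source_id,
            meta={k: v for k, v in self.meta.items()},
        )
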