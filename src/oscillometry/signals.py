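"""Shared time-series container for oscillometric recordings.

Sign and reference conventions, used everywhere in the package:

* flow is in L/s with inspiration positive;
* volume is in L above functional residual capacity (FRC = 0), i.e. the
  running integral of flow;
* pressure is airway-opening pressure in cmH2O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid


@dataclass
class SignalRecord:
    """Synchronized mouth flow / pressure / volume traces on a uniform grid.

    Parameters
    ----------
    t : array of float
        Time in seconds, strictly increasing, uniform spacing ``1/fs``.
    flow : array of float
        Mouth flow, L/s, inspiration positive.
    pressure : array of float
        Airway-opening pressure, cmH2O.
    volume : array of float
        Lung volume above FRC, L; must equal the cumulative trapezoidal
        integral of ``flow`` within numerical tolerance.
    fs : float
        Sample rate, Hz.
    events : list of (label, time) pairs
        Protocol marks, e.g. ``("di_onset", 300.0)`` and ``("di_end", 304.0)``
        for a deep inspiration.
    """

    t: np.ndarray
    flow: np.ndarray
    pressure: np.ndarray
    volume: np.ndarray
    fs: float
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        self.events = [(str(lbl), float(tm)) for lbl, tm in self.events]

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n > 1 else 0.0

    def event_time(self, label: str):
        """Time of the first event with this label, or None."""
        for lbl, tm in self.events:
            if lbl == label:
                return tm
        return None

    def validate(self, vol_tol: float = 5e-3) -> None:
        """Check array lengths, monotonic time, and volume/flow consistency.

        Raises ``ValueError`` on the first violated invariant.  ``vol_tol``
        is the allowed absolute deviation (L) between the stored volume and
        the trapezoidal integral of flow, scaled by the volume excursion.
        """
        n = self.n
        if not (self.flow.size == self.pressure.size == self.volume.size == n):
            raise ValueError("t, flow, pressure, volume must have equal lengths")
        if n < 2:
            raise ValueError("signal must contain at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("t must be strictly increasing")
        vref = cumulative_trapezoid(self.flow, self.t, initial=0.0) + self.volume[0]
        scale = max(1.0, float(np.max(np.abs(self.volume))))
        if np.max(np.abs(vref - self.volume)) > vol_tol * scale:
            raise ValueError("volume is not the cumulative integral of flow")
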