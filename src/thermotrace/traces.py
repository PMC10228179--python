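"""MST trace container: a time/intensity record through a laser on/off cycle."""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = ["MSTTrace", "ROLES"]

ROLES = ("fluorophore", "particle")


@dataclass
class MSTTrace:
    """One MST recording: fluorescence counts vs time with laser markers.

    ``role`` distinguishes free-fluorophore reference traces (decay only)
    from particle traces (decay times thermophoretic Conc(t)).  At least 20
    samples must fall inside the laser-on window for a fit to be meaningful.
    """

    times: np.ndarray          # s
    intensities: np.ndarray    # counts (arbitrary units)
    laser_on: float            # s
    laser_off: float           # s
    trace_id: str = "trace"
    role: str = "particle"
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.laser_on < self.laser_off:
            raise ValueError("laser_on must precede laser_off")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if self.n_on_samples < 20:
            raise ValueError(
                f"only {self.n_on_samples} samples inside the laser-on "
                "window; at least 20 required")

    @property
    def on_mask(self) -> np.ndarray:
        return (self.times >= self.laser_on) & (self.times <= self.laser_off)

    @property
    def n_on_samples(self) -> int:
        return int(np.count_nonzero(self.on_mask))

    def on_window(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, y) inside the laser-on phase with t re-zeroed at laser-on."""
        m = self.on_mask
        return self.times[m] - self.laser_on, self.intensities[m]

    def baseline(self) -> np.ndarray:
        """Pre-laser intensities (baseline-stability checks)."""
        return self.intensities[self.times < self.laser_on]

    def copy_with(self, **kwargs) -> "MSTTrace":
        data = dict(times=self.times.copy(),
                    intensities=self.intensities.copy(),
                    laser_on=self.laser_on, laser_off=self.laser_off,
                    trace_id=self.trace_id, role=self.role,
                    metadata=dict(self.metadata))
        data.update(kwargs)
        return MSTTrace(**data)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt
        ax = ax or plt.gca()
        ax.plot(self.times, self.intensities, **kwargs)
        ax.axvline(self.laser_on, color="0.6", ls="--", lw=0.8)
        ax.axvline(self.laser_off, color="0.6", ls="--", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("fluorescence (counts)")
        return ax
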