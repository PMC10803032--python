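"""Ca²⁺ trace container shared by the simulator and the synthetic generator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CalciumTraceSet"]


@dataclass(frozen=True)
class CalciumTraceSet:
    """Cells × timepoints matrix of [Ca²⁺]-proxy values.

    ``times`` are the sample times in seconds (strictly increasing);
    ``analysis_window`` is the [t_start, t_end] interval (inclusive) over
    which downstream metrics operate — typically the post-transient
    "second phase" of the recording. ``provenance`` tags the origin:
    ``"simulated"``, ``"experimental"`` or ``"synthetic"``.
    """

    traces: np.ndarray
    times: np.ndarray
    analysis_window: tuple[float, float]
    provenance: str = "simulated"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tr = np.asarray(self.traces, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if tr.ndim != 2:
            raise ValueError("traces must be a (cells, time) matrix")
        if t.ndim != 1 or t.shape[0] != tr.shape[1]:
            raise ValueError("times must match the trace time axis")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        lo, hi = self.analysis_window
        if not (t[0] <= lo < hi <= t[-1] + 1e-9):
            raise ValueError("analysis_window must lie inside the recording")
        mask = (t >= lo) & (t <= hi)
        if not np.all(np.isfinite(tr[:, mask])):
            raise ValueError("traces contain non-finite values inside the analysis window")
        object.__setattr__(self, "traces", tr)
        object.__setattr__(self, "times", t)

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def sampling_interval(self) -> float:
        return float(np.median(np.diff(self.times)))

    def window_slice(self) -> np.ndarray:
        """Trace matrix restricted to the analysis window."""
        lo, hi = self.analysis_window
        mask = (self.times >= lo) & (self.times <= hi)
        return self.traces[:, mask]
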