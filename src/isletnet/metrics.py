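"""Per-cell and pairwise metrics on Ca²⁺ traces.

Covers pixel-level QC (outlier-pixel pruning before a cell trace is
formed), the oscillation duty cycle, the pairwise Pearson correlation
matrix that seeds the functional network, parameter–duty-cycle
correlations, and the glucose-stimulated NAD(P)H response metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from isletnet.islet import CellParameters
from isletnet.traces import CalciumTraceSet

__all__ = [
    "CorrelationMatrix",
    "DutyCycleVector",
    "NadphResponse",
    "EmptyCellError",
    "prune_outlier_pixels",
    "duty_cycle",
    "duty_cycles",
    "pearson_matrix",
    "correlate_params_with_duty",
    "nadph_metric",
]


class EmptyCellError(ValueError):
    """All pixels of a cell were pruned."""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson matrix with unit diagonal.

    Rows/columns of zero-variance (silent) cells are NaN and carry a
    ``valid`` flag of False; such cells are excluded from downstream
    network construction rather than failing the islet.
    """

    R: np.ndarray
    valid: np.ndarray
    analysis_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("R must be square")
        if valid.shape != (R.shape[0],):
            raise ValueError("valid flag length mismatch")
        sub = R[np.ix_(valid, valid)]
        if sub.size and not np.allclose(sub, sub.T, equal_nan=True):
            raise ValueError("R must be symmetric")
        if sub.size and np.nanmax(np.abs(sub)) > 1 + 1e-9:
            raise ValueError("|R| must be ≤ 1")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "valid", valid)

    @property
    def n_cells(self) -> int:
        return self.R.shape[0]


@dataclass(frozen=True)
class DutyCycleVector:
    """Per-cell fraction of time above 50% of the cell's maximum."""

    values: np.ndarray
    silent: np.ndarray
    threshold_fraction: float = 0.5

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError("duty cycles must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "silent", np.asarray(self.silent, dtype=bool))


@dataclass(frozen=True)
class NadphResponse:
    """Mean-centered glucose-stimulated NAD(P)H response per cell."""

    metric: np.ndarray
    raw_delta: np.ndarray


def prune_outlier_pixels(pixel_traces: np.ndarray, k_sd: float = 5.0) -> np.ndarray:
    """Collapse pixel traces to a cell trace after removing outlier pixels.

    A pixel is discarded when the RMS distance of its trace from the
    robust (median) cell trace exceeds ``k_sd`` × the temporal standard
    deviation of that median trace — i.e. its dynamics are not within
    ``k_sd`` SDs of the average dynamics (the QC rule admits a 5–10 SD
    band; 5 is the default). The median reference keeps a lone aberrant
    pixel from dragging the comparison trace toward itself. Returns the
    mean trace of the surviving pixels.
    """
    px = np.asarray(pixel_traces, dtype=float)
    if px.ndim != 2 or px.shape[0] < 1:
        raise ValueError("pixel_traces must be (pixels, time) with ≥1 pixel")
    ref = np.median(px, axis=0)
    rms = np.sqrt(np.mean((px - ref) ** 2, axis=1))
    scale = ref.std()
    if scale == 0 or not np.isfinite(k_sd):
        # no reference dynamics to judge against (or an infinite band): keep all
        keep = np.ones(px.shape[0], dtype=bool)
    else:
        keep = rms <= k_sd * scale
    if not keep.any():
        raise EmptyCellError("all pixels pruned")
    return px[keep].mean(axis=0)


def duty_cycle(trace: np.ndarray, threshold_fraction: float = 0.5) -> tuple[float, bool]:
    """Fraction of samples strictly above ``threshold_fraction`` × max.

    Returns ``(duty, silent)``; a constant trace has no oscillation, is
    flagged silent, and is assigned duty 0.
    """
    tr = np.asarray(trace, dtype=float)
    if tr.ndim != 1 or tr.size == 0:
        raise ValueError("trace must be a nonempty 1-d array")
    if np.ptp(tr) == 0:
        return 0.0, True
    thr = threshold_fraction * tr.max()
    return float(np.mean(tr > thr)), False


def duty_cycles(traces: CalciumTraceSet, threshold_fraction: float = 0.5) -> DutyCycleVector:
    """Per-cell duty cycles over the analysis window."""
    X = traces.window_slice()
    vals = np.empty(X.shape[0])
    silent = np.zeros(X.shape[0], dtype=bool)
    for i, row in enumerate(X):
        vals[i], silent[i] = duty_cycle(row, threshold_fraction)
    return DutyCycleVector(values=vals, silent=silent, threshold_fraction=threshold_fraction)


def pearson_matrix(traces: CalciumTraceSet) -> CorrelationMatrix:
    """Pairwise product-moment correlation over the analysis window.

    Zero-variance traces get NaN rows/columns and ``valid=False``.
    """
    X = traces.window_slice()
    if X.shape[1] < 3:
        raise ValueError("need ≥3 timepoints in the analysis window")
    sd = X.std(axis=1)
    valid = sd > 0
    R = np.full((X.shape[0], X.shape[0]), np.nan)
    if valid.sum() >= 1:
        sub = np.atleast_2d(np.corrcoef(X[valid]))
        sub = np.clip(0.5 * (sub + sub.T), -1.0, 1.0)  # enforce exact symmetry
        np.fill_diagonal(sub, 1.0)
        R[np.ix_(valid, valid)] = sub
    return CorrelationMatrix(R=R, valid=valid, analysis_window=traces.analysis_window)


def correlate_params_with_duty(
    params: CellParameters,
    duty: DutyCycleVector,
    total_conductance: np.ndarray | None = None,
) -> dict[str, float]:
    """Pearson r between duty cycle and each intrinsic parameter.

    ``total_conductance`` (per-cell summed edge conductance) is used for the
    coupling entry when given; otherwise the per-cell coupling parameter is
    used. Returns ``{"k_glyc": r, "g_KATP": r, "g_coup": r}`` for one islet.
    """
    d = duty.values
    if len(d) != params.n_cells or len(d) < 3:
        raise ValueError("need ≥3 aligned cells")
    g = total_conductance if total_conductance is not None else params.g_coup_cell

    def r(x: np.ndarray) -> float:
        if np.std(x) == 0 or np.std(d) == 0:
            return float("nan")
        return float(np.corrcoef(x, d)[0, 1])

    return {"k_glyc": r(params.k_glyc), "g_KATP": r(params.g_KATP), "g_coup": r(np.asarray(g))}


def nadph_metric(intensity_2mM: np.ndarray, intensity_11mM: np.ndarray) -> NadphResponse:
    """Glucose-stimulated NAD(P)H response, centered on the islet mean.

    metric_i = (NADPH_11,i − NADPH_2,i) − mean_j(NADPH_11,j − NADPH_2,j);
    zero means the cell matches the islet-average response. The centering
    removes inter-islet variability, so adding any constant to all cells at
    either glucose level leaves the metric unchanged.
    """
    lo = np.asarray(intensity_2mM, dtype=float)
    hi = np.asarray(intensity_11mM, dtype=float)
    if lo.shape != hi.shape or lo.ndim != 1 or lo.size == 0:
        raise ValueError("both glucose conditions must be present for each cell")
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("intensities must be finite")
    delta = hi - lo
    return NadphResponse(metric=delta - delta.mean(), raw_delta=delta)
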