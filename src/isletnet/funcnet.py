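"""Functional (Ca²⁺-synchronization) network construction.

An edge connects any cell pair whose Pearson correlation meets the
threshold R_th. Per-cell degrees are normalized to the islet's maximum
degree (percent of max), hubs are cells whose normalized degree exceeds
60% (or alternatively the top 10% of cells by degree), and the threshold
itself can be tuned to maximize the power-law character of the degree
distribution subject to 5 ≤ k_avg ≤ 15 — the regime reported for islet
functional networks.

Default thresholds follow the source analyses: 0.9995 for simulated fast
islets, 0.999999999 for simulated slow (IOM) islets, and 0.9 for
experimental-style recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from isletnet.metrics import CorrelationMatrix

__all__ = [
    "DEFAULT_THRESHOLDS",
    "FunctionalNetwork",
    "HubClassification",
    "ThresholdTuningResult",
    "TuningError",
    "threshold_network",
    "tune_threshold",
    "identify_hubs",
    "degree_distribution",
    "power_law_gof",
]

DEFAULT_THRESHOLDS = {
    "simulated_fast": 0.9995,
    "simulated_iom": 0.999999999,
    "experimental": 0.9,
}


class TuningError(RuntimeError):
    """Threshold tuning could not satisfy its constraints."""


@dataclass(frozen=True)
class FunctionalNetwork:
    """Thresholded correlation graph with degree statistics."""

    adjacency: np.ndarray
    R_th: float
    valid: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if not np.array_equal(adj, adj.T) or np.any(np.diag(adj)):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def normalized_degree_pct(self) -> np.ndarray:
        """Degree as percent of the islet's maximum degree (0 if empty)."""
        deg = self.degrees
        mx = deg.max()
        if mx == 0:
            return np.zeros_like(deg, dtype=float)
        return 100.0 * deg / mx

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def k_avg(self) -> float:
        """Mean degree over valid cells."""
        nv = int(self.valid.sum())
        return float(self.degrees[self.valid].mean()) if nv else 0.0

    @property
    def size_normalized_mean_degree(self) -> float:
        """k_avg / n — the islet-size-independent mean degree."""
        return self.k_avg / self.n_cells

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(i.tolist(), j.tolist()))


@dataclass(frozen=True)
class HubClassification:
    """Per-cell hub labels under one of the two published rules."""

    is_hub: np.ndarray
    method: str

    @property
    def hub_fraction(self) -> float:
        return float(np.mean(self.is_hub))


@dataclass(frozen=True)
class ThresholdTuningResult:
    R_th: float
    gof: float
    k_avg: float


def threshold_network(R: CorrelationMatrix, R_th: float) -> FunctionalNetwork:
    """Edges where R_ij ≥ R_th between valid cells."""
    if not (-1 < R_th <= 1):
        raise ValueError("R_th must lie in (−1, 1]")
    M = np.where(np.isnan(R.R), -np.inf, R.R)
    adj = M >= R_th
    np.fill_diagonal(adj, False)
    adj &= R.valid[:, None] & R.valid[None, :]
    return FunctionalNetwork(adjacency=adj, R_th=R_th, valid=R.valid)


def degree_distribution(
    net: FunctionalNetwork, bins: int | np.ndarray = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of normalized degree (percent of islet max).

    Returns ``(counts, bin_edges)`` over (0, 100]; zero-degree cells are
    excluded (they have no edges to distribute). An empty network yields
    all-zero counts.
    """
    if isinstance(bins, int):
        edges = np.linspace(0.0, 100.0, bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    nd = net.normalized_degree_pct
    nd = nd[(nd > 0) & net.valid]
    counts, _ = np.histogram(nd, bins=edges)
    return counts, edges


def power_law_gof(counts: np.ndarray, edges: np.ndarray) -> float:
    """Coefficient of determination of a log-log linear fit to the histogram.

    Degree distributions of islet functional networks look roughly linear
    on a log-log plot; this scores that linearity. Requires ≥3 nonempty
    bins, else −inf.
    """
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = counts > 0
    if mask.sum() < 3:
        return float("-inf")
    x = np.log(centers[mask])
    y = np.log(counts[mask].astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return float("-inf")
    return float(1.0 - np.sum(resid**2) / ss_tot)


def tune_threshold(
    R: CorrelationMatrix,
    k_avg_bounds: tuple[float, float] = (5.0, 15.0),
    bins: int = 10,
    n_grid: int = 200,
) -> ThresholdTuningResult:
    """Choose R_th maximizing power-law goodness of fit under a k_avg bound.

    Candidate thresholds are the quantile grid of off-diagonal correlations
    restricted to the interval where 5 ≤ k_avg ≤ 15 (k_avg is nonincreasing
    in R_th, so the feasible set is an interval). Deterministic: ties are
    broken toward the larger threshold (sparser network).
    """
    if int(R.valid.sum()) < 20:
        raise TuningError("threshold tuning needs a ≥20-cell islet")
    vals = R.R[np.ix_(R.valid, R.valid)]
    iu = np.triu_indices(vals.shape[0], 1)
    rvals = np.unique(vals[iu])
    rvals = rvals[np.isfinite(rvals)]
    if rvals.size < 2:
        raise TuningError("degenerate correlation matrix: all pair correlations equal")

    lo_k, hi_k = k_avg_bounds
    nv = int(R.valid.sum())
    pair_vals = np.sort(vals[iu])
    # k_avg(th) = 2 · #{pairs with R ≥ th} / n_valid, nonincreasing in th
    n_ge = len(pair_vals) - np.searchsorted(pair_vals, rvals, side="left")
    k_avgs = 2.0 * n_ge / nv
    feasible = rvals[(k_avgs >= lo_k) & (k_avgs <= hi_k)]
    if feasible.size == 0:
        raise TuningError(
            f"no threshold achieves k_avg in [{lo_k}, {hi_k}]; "
            f"achievable k_avg range is {k_avgs.min():.3f}–{k_avgs.max():.3f}"
        )
    cand = np.unique(np.quantile(feasible, np.linspace(0, 1, min(n_grid, len(feasible)))))
    best: ThresholdTuningResult | None = None
    for th in cand:
        net = threshold_network(R, float(th))
        if not (lo_k <= net.k_avg <= hi_k):
            continue
        counts, edges = degree_distribution(net, bins)
        gof = power_law_gof(counts, edges)
        if best is None or gof > best.gof or (gof == best.gof and th > best.R_th):
            best = ThresholdTuningResult(R_th=float(th), gof=gof, k_avg=net.k_avg)
    if best is None or not np.isfinite(best.gof):
        raise TuningError("no feasible threshold produced a scorable degree distribution")
    return best


def identify_hubs(net: FunctionalNetwork, method: str = "threshold60") -> HubClassification:
    """Label hub cells.

    ``"threshold60"``: hubs are cells with normalized degree strictly
    greater than 60% of the islet maximum. ``"top10pct"``: exactly
    ⌈0.10 n⌉ cells with the highest degree (ties at the cutoff broken by
    cell index, lowest first, for determinism).
    """
    if method == "threshold60":
        return HubClassification(is_hub=net.normalized_degree_pct > 60.0, method=method)
    if method == "top10pct":
        if net.n_edges == 0:
            raise ValueError("top10pct hub rule is undefined on an empty network")
        n = net.n_cells
        m = int(np.ceil(0.10 * n))
        order = np.lexsort((np.arange(n), -net.degrees))
        is_hub = np.zeros(n, dtype=bool)
        is_hub[order[:m]] = True
        return HubClassification(is_hub=is_hub, method=method)
    raise ValueError(f"unknown hub method {method!r}")
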