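"""Functional ↔ structural ↔ metabolic network comparison.

Three questions are quantified here:

* how often functional (synchronization) and structural (gap-junction) or
  metabolic (glucokinase-similarity) edges coincide, as plain and
  conditional probabilities over cell pairs;
* whether synchronized cell pairs lie on higher-conductance (or more
  metabolically active) routes through the structural network, via
  least-resistance weighted shortest paths stratified by hop distance;
* the metabolic network itself: proximal cell pairs (Euclidean distance
  ≤ 15% of the islet diameter) with similar k_glyc, with the similarity
  cutoff calibrated so Pr(sync|metabolic) matches Pr(sync|gap-junction) —
  the control condition that makes Pr(Met|Sync) and Pr(GJ|Sync) directly
  comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import johnson
from scipy import stats as sps

from isletnet.funcnet import FunctionalNetwork
from isletnet.islet import CellParameters, IsletGeometry, StructuralNetwork

__all__ = [
    "ComparisonStats",
    "MetabolicNetwork",
    "PathAnalysisResult",
    "CalibrationError",
    "comparison_probabilities",
    "build_metabolic_network",
    "weighted_shortest_paths",
    "sync_stratified_path_comparison",
]


class CalibrationError(RuntimeError):
    """Metabolic-network calibration could not reach its target."""


@dataclass(frozen=True)
class ComparisonStats:
    """Edge counts and (conditional) probabilities for one islet.

    Probabilities are relative to the n(n−1)/2 unordered cell pairs;
    conditionals are edge-intersection ratios. Undefined conditionals
    (zero-probability conditioning event) are NaN.
    """

    n: int
    m_sync: int
    m_other: int
    m_both: int

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def pr_sync(self) -> float:
        return self.m_sync / self.n_pairs

    @property
    def pr_other(self) -> float:
        return self.m_other / self.n_pairs

    @property
    def pr_both(self) -> float:
        return self.m_both / self.n_pairs

    @property
    def pr_sync_given_other(self) -> float:
        return self.m_both / self.m_other if self.m_other else float("nan")

    @property
    def pr_other_given_sync(self) -> float:
        return self.m_both / self.m_sync if self.m_sync else float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "m_sync": self.m_sync,
            "m_other": self.m_other,
            "m_both": self.m_both,
            "pr_sync": self.pr_sync,
            "pr_other": self.pr_other,
            "pr_both": self.pr_both,
            "pr_sync_given_other": self.pr_sync_given_other,
            "pr_other_given_sync": self.pr_other_given_sync,
        }


@dataclass(frozen=True)
class MetabolicNetwork:
    """k_glyc-similarity graph over proximal cell pairs."""

    adjacency: np.ndarray
    similarity_cutoff: float
    distance_fraction: float
    calibration: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class PathAnalysisResult:
    """All-pairs least-resistance paths through the structural network.

    ``hops[i, j]`` — number of edges along the chosen path;
    ``cumulative_weight[i, j]`` — sum of per-edge ½-mean weights along it;
    ``total_resistance[i, j]`` — the minimized sum of inverse edge weights;
    ``normalized_weight`` — cumulative weight per hop. Disconnected pairs
    carry hops = −1 and NaN/inf weights.
    """

    hops: np.ndarray
    cumulative_weight: np.ndarray
    total_resistance: np.ndarray
    weight_source: str

    @property
    def normalized_weight(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.hops > 0, self.cumulative_weight / self.hops, np.nan)

    @property
    def disconnected(self) -> np.ndarray:
        return self.hops < 0


def _edge_count(adj: np.ndarray) -> int:
    return int(np.triu(adj, 1).sum())


def comparison_probabilities(func_net: FunctionalNetwork, other: np.ndarray | StructuralNetwork | MetabolicNetwork) -> ComparisonStats:
    """Pair-count probabilities linking the functional net with another graph."""
    other_adj = other if isinstance(other, np.ndarray) else other.adjacency
    other_adj = np.asarray(other_adj, dtype=bool)
    sync = func_net.adjacency
    if other_adj.shape != sync.shape:
        raise ValueError("networks must share the same cell set")
    return ComparisonStats(
        n=func_net.n_cells,
        m_sync=_edge_count(sync),
        m_other=_edge_count(other_adj),
        m_both=_edge_count(sync & other_adj),
    )


def build_metabolic_network(
    params: CellParameters,
    geometry: IsletGeometry,
    func_net: FunctionalNetwork,
    struct_net: StructuralNetwork,
    distance_fraction: float = 0.15,
    tolerance: float = 0.01,
    similarity_cutoff: float | None = None,
) -> MetabolicNetwork:
    """Construct the calibrated glucokinase-similarity network.

    Candidate pairs are those with Euclidean distance ≤ ``distance_fraction``
    × islet diameter. Among candidates, edges are pairs whose |Δk_glyc| lies
    below a cutoff chosen so that Pr(sync|metabolic) matches the islet's
    Pr(sync|gap-junction) within ``tolerance`` (scanning candidate pairs in
    order of increasing |Δk_glyc|; deterministic). Raises
    :class:`CalibrationError` when no cutoff gets within tolerance. An
    explicit ``similarity_cutoff`` skips the calibration.
    """
    n = params.n_cells
    dist = geometry.pairwise_distances()
    diam = geometry.islet_diameter
    iu = np.triu_indices(n, 1)
    candidate = dist[iu] <= distance_fraction * diam
    if not candidate.any():
        raise CalibrationError("no candidate pairs satisfy the distance constraint")

    dk = np.abs(params.k_glyc[iu[0]] - params.k_glyc[iu[1]])
    if similarity_cutoff is not None:
        keep = np.flatnonzero(candidate & (dk <= similarity_cutoff))
        adj = np.zeros((n, n), dtype=bool)
        adj[iu[0][keep], iu[1][keep]] = True
        adj |= adj.T
        return MetabolicNetwork(
            adjacency=adj,
            similarity_cutoff=float(similarity_cutoff),
            distance_fraction=distance_fraction,
            calibration={"mode": "fixed_cutoff", "n_edges": int(len(keep))},
        )

    target = comparison_probabilities(func_net, struct_net).pr_sync_given_other
    if np.isnan(target):
        raise CalibrationError("Pr(sync|GJ) undefined: structural network has no edges")

    sync = func_net.adjacency[iu]
    ci = np.flatnonzero(candidate)
    order = ci[np.argsort(dk[ci], kind="stable")]
    # Pr(sync|Met) after admitting the m most similar candidate pairs
    cum_sync = np.cumsum(sync[order])
    m_range = np.arange(1, len(order) + 1)
    pr = cum_sync / m_range
    err = np.abs(pr - target)
    best = int(np.argmin(err))
    if err[best] > tolerance:
        raise CalibrationError(
            f"calibration target Pr(sync|GJ)={target:.4f} not bracketed; "
            f"achieved Pr(sync|Met) range [{pr.min():.4f}, {pr.max():.4f}]"
        )
    cutoff = float(dk[order[best]])
    keep = order[: best + 1]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[0][keep], iu[1][keep]] = True
    adj |= adj.T
    return MetabolicNetwork(
        adjacency=adj,
        similarity_cutoff=cutoff,
        distance_fraction=distance_fraction,
        calibration={
            "target_pr_sync_given_gj": float(target),
            "achieved_pr_sync_given_met": float(pr[best]),
            "n_candidate_pairs": int(candidate.sum()),
            "n_edges": int(best + 1),
        },
    )


def weighted_shortest_paths(
    struct_net: StructuralNetwork,
    params: CellParameters | None = None,
    weight_source: str = "g_coup",
) -> PathAnalysisResult:
    """All-pairs least-resistance paths (Johnson's algorithm).

    Each edge (i, j) carries weight w_ij = ½(w_i + w_j) — endpoint-mean
    coupling conductance or k_glyc — and resistance 1/w_ij. The chosen path
    minimizes total resistance; reported per pair are its hop count and the
    cumulative (summed) edge weight along it.
    """
    adj = struct_net.adjacency
    n = struct_net.n_cells
    if weight_source == "g_coup":
        if struct_net.edge_conductance is None:
            raise ValueError("structural network lacks edge conductances")
        W = struct_net.edge_conductance
    elif weight_source == "k_glyc":
        if params is None:
            raise ValueError("k_glyc weighting requires cell parameters")
        k = params.k_glyc
        W = 0.5 * (k[:, None] + k[None, :]) * adj
    else:
        raise ValueError(f"unknown weight_source {weight_source!r}")
    if np.any(W[adj] <= 0):
        raise ValueError("edge weights must be strictly positive")

    with np.errstate(divide="ignore"):
        resist = np.where(adj, 1.0 / np.where(adj, W, 1.0), 0.0)
    graph = csr_matrix(resist)
    dist, pred = johnson(graph, directed=False, return_predecessors=True)

    hops = np.full((n, n), -1, dtype=int)
    cumw = np.full((n, n), np.nan)
    np.fill_diagonal(hops, 0)
    np.fill_diagonal(cumw, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j or not np.isfinite(dist[i, j]):
                continue
            h = 0
            w = 0.0
            k = j
            while k != i:
                p = pred[i, k]
                w += W[p, k]
                h += 1
                k = p
            hops[i, j] = h
            cumw[i, j] = w
    return PathAnalysisResult(
        hops=hops, cumulative_weight=cumw, total_resistance=dist, weight_source=weight_source
    )


def sync_stratified_path_comparison(
    islets: list[tuple[PathAnalysisResult, FunctionalNetwork]],
    max_distance: int = 15,
    family_alpha: float = 0.05,
) -> dict:
    """Compare cumulative path weight of synchronized vs non-synchronized
    pairs, stratified by hop distance, paired across islets.

    Returns a dict with a tidy per-islet table (islet, distance, sync_label,
    mean_weight, n_pairs), per-distance normalized group means, and paired
    two-tailed t-tests at the Bonferroni-corrected per-test alpha
    (``family_alpha`` / ``max_distance``).
    """
    from isletnet.stats import bonferroni_alpha

    rows = []
    for idx, (paths, fnet) in enumerate(islets):
        n = fnet.n_cells
        iu = np.triu_indices(n, 1)
        hops = paths.hops[iu]
        w = paths.cumulative_weight[iu]
        sync = fnet.adjacency[iu]
        for d in range(1, max_distance + 1):
            at_d = hops == d
            for label, mask in (("sync", at_d & sync), ("nonsync", at_d & ~sync)):
                if mask.any():
                    rows.append(
                        {
                            "islet": idx,
                            "distance": d,
                            "sync_label": label,
                            "mean_weight": float(w[mask].mean()),
                            "n_pairs": int(mask.sum()),
                        }
                    )
    table = pd.DataFrame(rows)
    alpha = bonferroni_alpha(max_distance, family_alpha)
    tests = []
    excluded = []
    for d in range(1, max_distance + 1):
        sub = table[table["distance"] == d]
        piv = sub.pivot_table(index="islet", columns="sync_label", values="mean_weight")
        if "sync" not in piv or "nonsync" not in piv:
            excluded.append(d)
            continue
        piv = piv.dropna()
        pooled = float(sub["mean_weight"].mean())
        norm_sync = piv["sync"] / pooled
        norm_nonsync = piv["nonsync"] / pooled
        if len(piv) >= 2:
            t, p = sps.ttest_rel(piv["sync"], piv["nonsync"])
            t, p = float(t), float(p)
        else:
            t = p = float("nan")
        tests.append(
            {
                "distance": d,
                "n_islets": int(len(piv)),
                "mean_sync_norm": float(norm_sync.mean()),
                "mean_nonsync_norm": float(norm_nonsync.mean()),
                "t": t,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return {
        "table": table,
        "tests": pd.DataFrame(tests),
        "per_test_alpha": alpha,
        "excluded_distances": excluded,
    }
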