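"""Construction of simulated islets.

An islet is modeled as a compact, roughly spherical cluster of β-cells.
Three ingredients are generated here:

* **geometry** — cell positions packed inside a sphere with a minimum
  separation, so that every interior cell has enough proximal neighbors
  to support the configured gap-junction degree range;
* **structural network** — the gap-junction graph, whose per-cell degree
  is drawn from a rounded truncated normal distribution and whose edges
  connect only proximal cells;
* **heterogeneity** — per-cell intrinsic parameters (glucokinase rate
  ``k_glyc``, maximal K_ATP conductance ``g_KATP``, and the per-cell
  coupling-conductance parameter ``g_coup_cell``).

Two parameter regimes are built in: ``"fast"`` (electrophysiological model
of fast Ca²⁺ oscillations, 1000-cell islets, degrees N(5.25, 1.6) in
[1, 12]) and ``"iom"`` (integrated oscillator model of slow oscillations,
260-cell islets, degrees targeting mean 6.01 in [1, 14]).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "IsletGeometry",
    "CellParameters",
    "StructuralNetwork",
    "IsletModel",
    "PackingConfig",
    "DegreeSpec",
    "HETEROGENEITY_SPECS",
    "DEGREE_SPECS",
    "StructuralConstructionError",
    "build_geometry",
    "build_structural_network",
    "sample_heterogeneity",
    "assign_edge_conductances",
    "build_islet",
]


class StructuralConstructionError(RuntimeError):
    """Raised when a drawn degree sequence cannot be realized geometrically."""


@dataclass(frozen=True)
class PackingConfig:
    """Sphere-packing parameters for cell placement.

    ``min_separation`` is the hard-core distance between cell centers (the
    length unit of the islet); ``packing_fraction`` sets the sphere radius
    via the hard-core volume fraction; ``coupling_cutoff`` is the maximum
    center-to-center distance at which two cells may share a gap junction
    (in units of ``min_separation``).
    """

    min_separation: float = 1.0
    packing_fraction: float = 0.15
    coupling_cutoff: float = 2.35
    max_attempts_per_cell: int = 2000

    def sphere_radius(self, n_cells: int) -> float:
        # packing_fraction = n * (d/2)^3 / R^3  (hard-sphere volume ratio)
        return self.min_separation * (n_cells / (8.0 * self.packing_fraction)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class DegreeSpec:
    """Truncated-normal specification for gap-junction degrees."""

    mean: float
    sd: float
    lo: int = 1
    hi: int = 12

    def __post_init__(self) -> None:
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError(f"degree mean {self.mean} outside bounds [{self.lo}, {self.hi}]")
        if self.sd < 0:
            raise ValueError("degree sd must be nonnegative")


#: Default degree specifications per model regime.
DEGREE_SPECS: Mapping[str, DegreeSpec] = {
    "fast": DegreeSpec(mean=5.25, sd=1.6, lo=1, hi=12),
    "iom": DegreeSpec(mean=6.01, sd=2.66, lo=1, hi=14),
}

#: Per-regime heterogeneity distributions: (mean, sd) of normals for k_glyc
#: and g_KATP, and the gamma shape plus target mean for g_coup_cell.
#: Units: fast — k_glyc s⁻¹, g_KATP pA/mV (≡ nS), g_coup nS;
#: iom — k_glyc µM/ms, g_KATP pS, g_coup pS (normal, not gamma).
HETEROGENEITY_SPECS: Mapping[str, Mapping[str, tuple]] = {
    "fast": {
        "k_glyc": ("normal", 1.26e-4, 3.15e-5),
        "g_KATP": ("normal", 2.31, 0.57),
        "g_coup": ("gamma_rescaled", 4.0, 4.0, 0.12),
    },
    "iom": {
        "k_glyc": ("normal", 0.0037, 0.0015),
        "g_KATP": ("normal", 19700.0, 3940.0),
        "g_coup": ("normal", 1.0, 0.5),
    },
}


@dataclass(frozen=True)
class IsletGeometry:
    """Cell positions of one islet (positions are (n, 3), arbitrary units)."""

    positions: np.ndarray
    coupling_cutoff: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if pos.shape[0] < 2:
            raise ValueError("an islet needs at least 2 cells")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        return squareform(pdist(self.positions))

    @property
    def islet_diameter(self) -> float:
        """Maximum pairwise Euclidean distance between cells."""
        return float(pdist(self.positions).max())


@dataclass(frozen=True)
class CellParameters:
    """Per-cell intrinsic parameters; all strictly positive."""

    k_glyc: np.ndarray
    g_KATP: np.ndarray
    g_coup_cell: np.ndarray
    model_tag: str = "fast"

    def __post_init__(self) -> None:
        for name in ("k_glyc", "g_KATP", "g_coup_cell"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1:
                raise ValueError(f"{name} must be a 1-d vector")
            if not np.all(v > 0):
                raise ValueError(f"{name} must be strictly positive")
            object.__setattr__(self, name, v)
        n = {len(self.k_glyc), len(self.g_KATP), len(self.g_coup_cell)}
        if len(n) != 1:
            raise ValueError("parameter vectors must have equal length")

    @property
    def n_cells(self) -> int:
        return len(self.k_glyc)


@dataclass(frozen=True)
class StructuralNetwork:
    """Gap-junction graph: symmetric adjacency plus edge conductances.

    ``edge_conductance[i, j] = ½ (g_coup_cell_i + g_coup_cell_j)`` for
    adjacent pairs, and each cell's ``total_conductance`` is the sum of its
    incident edge conductances.
    """

    adjacency: np.ndarray
    edge_conductance: np.ndarray | None = None

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj)):
            raise ValueError("adjacency must have zero diagonal")
        object.__setattr__(self, "adjacency", adj)
        if self.edge_conductance is not None:
            ec = np.asarray(self.edge_conductance, dtype=float)
            if ec.shape != adj.shape:
                raise ValueError("edge_conductance shape mismatch")
            object.__setattr__(self, "edge_conductance", ec)

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def total_conductance(self) -> np.ndarray:
        """Per-cell sum of incident edge conductances."""
        if self.edge_conductance is None:
            raise ValueError("edge conductances not assigned")
        return self.edge_conductance.sum(axis=1)

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(i.tolist(), j.tolist()))


@dataclass(frozen=True)
class IsletModel:
    """A fully constructed islet: geometry, structure, and heterogeneity."""

    geometry: IsletGeometry
    structure: StructuralNetwork
    params: CellParameters

    @property
    def n_cells(self) -> int:
        return self.geometry.n_cells


def build_geometry(
    n_cells: int,
    seed: int,
    packing: PackingConfig | None = None,
) -> IsletGeometry:
    """Place ``n_cells`` cells inside a sphere with minimum-separation rejection.

    Deterministic for a fixed seed. Points are drawn uniformly in the sphere
    and accepted only if at least ``min_separation`` away from every accepted
    point (Poisson-disc-like sequential packing).
    """
    if n_cells < 2:
        raise ValueError("n_cells must be ≥ 2")
    packing = packing or PackingConfig()
    rng = np.random.default_rng(seed)
    radius = packing.sphere_radius(n_cells)
    d2 = packing.min_separation**2

    accepted: list[np.ndarray] = []
    pts = np.empty((0, 3))
    tree: cKDTree | None = None
    attempts = 0
    max_attempts = packing.max_attempts_per_cell * n_cells
    while len(accepted) < n_cells:
        if attempts > max_attempts:
            raise StructuralConstructionError(
                f"could not pack {n_cells} cells at packing fraction "
                f"{packing.packing_fraction} after {attempts} attempts"
            )
        # draw a batch of uniform points in the sphere via rejection from the cube
        m = max(64, n_cells - len(accepted))
        cand = rng.uniform(-radius, radius, size=(m, 3))
        cand = cand[np.einsum("ij,ij->i", cand, cand) <= radius**2]
        attempts += m
        for p in cand:
            if len(accepted) >= n_cells:
                break
            if accepted:
                if tree is None or len(accepted) % 128 == 0:
                    pts = np.asarray(accepted)
                    tree = cKDTree(pts)
                # check the (possibly stale) tree, then the tail appended since
                idx = tree.query_ball_point(p, packing.min_separation)
                if idx:
                    continue
                tail = accepted[len(pts):]
                if tail and np.min(np.sum((np.asarray(tail) - p) ** 2, axis=1)) < d2:
                    continue
            accepted.append(p)
    return IsletGeometry(
        positions=np.asarray(accepted),
        coupling_cutoff=packing.coupling_cutoff * packing.min_separation,
    )


def _draw_degree_sequence(n: int, spec: DegreeSpec, rng: np.random.Generator) -> np.ndarray:
    hi = min(spec.hi, n - 1)  # a cell cannot exceed n-1 partners
    deg = np.rint(rng.normal(spec.mean, spec.sd, size=n)).astype(int)
    deg = np.clip(deg, spec.lo, hi)
    # parity repair: redraw single cells until the degree sum is even
    guard = 0
    while deg.sum() % 2 != 0:
        i = int(rng.integers(n))
        deg[i] = int(np.clip(np.rint(rng.normal(spec.mean, spec.sd)), spec.lo, hi))
        guard += 1
        if guard > 10_000:  # pragma: no cover - spec.sd == 0 with odd parity
            deg[i] = int(np.clip(deg[i] + 1, spec.lo, hi))
    return deg


def build_structural_network(
    geometry: IsletGeometry,
    degree_spec: DegreeSpec | None = None,
    seed: int = 0,
    max_relax_passes: int = 30,
    max_restarts: int = 10,
) -> StructuralNetwork:
    """Wire the gap-junction graph to a drawn truncated-normal degree sequence.

    Per-cell target degrees are drawn (round-to-nearest, clamp to bounds,
    single-cell redraws if the sum is odd), then each deficit cell is greedily
    connected to its nearest eligible neighbor within the proximity cutoff.
    If deficits remain, the cutoff is relaxed by 10% steps and residual
    deadlocks are resolved by degree-preserving edge swaps; a geometrically
    infeasible draw triggers a restart with a fresh sequence (up to
    ``max_restarts``). Raises :class:`StructuralConstructionError` if every
    attempt remains infeasible.
    """
    spec = degree_spec or DEGREE_SPECS["fast"]
    rng = np.random.default_rng(seed)
    n = geometry.n_cells
    dist = geometry.pairwise_distances()
    np.fill_diagonal(dist, np.inf)

    last_report = ""
    for _ in range(max_restarts):
        target = _draw_degree_sequence(n, spec, rng)
        adj, cur = _greedy_wire(target, dist, geometry.coupling_cutoff, max_relax_passes)
        if not np.array_equal(cur, target):
            _swap_repair(adj, cur, target, dist)
        if np.array_equal(cur, target):
            return StructuralNetwork(adjacency=adj)
        short = np.flatnonzero(cur != target)
        last_report = (
            f"{len(short)} cells off-target (e.g. cell {short[0]}: "
            f"{cur[short[0]]} vs {target[short[0]]})"
        )
    raise StructuralConstructionError(
        f"degree sequence infeasible after {max_restarts} restarts of "
        f"{max_relax_passes} relaxation passes each; last attempt: {last_report}"
    )


def _greedy_wire(
    target: np.ndarray, dist: np.ndarray, cutoff0: float, max_relax_passes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-neighbor matching of a degree sequence within a cutoff."""
    n = len(target)
    adj = np.zeros((n, n), dtype=bool)
    cur = np.zeros(n, dtype=int)
    cutoff = cutoff0
    for _ in range(max_relax_passes):
        progress = True
        while progress:
            progress = False
            deficit = target - cur
            order = np.argsort(-deficit, kind="stable")
            for i in order:
                if target[i] - cur[i] <= 0:
                    continue
                eligible = (target - cur > 0) & ~adj[i] & (dist[i] <= cutoff)
                eligible[i] = False
                if not eligible.any():
                    continue
                j = int(np.argmin(np.where(eligible, dist[i], np.inf)))
                adj[i, j] = adj[j, i] = True
                cur[i] += 1
                cur[j] += 1
                progress = True
        if np.array_equal(cur, target):
            break
        cutoff *= 1.1
    return adj, cur


def _swap_repair(adj: np.ndarray, cur: np.ndarray, target: np.ndarray, dist: np.ndarray) -> None:
    """Resolve residual deficits via deficit-shifting edge rewires.

    Strategies, in order: (1) connect the deficit cell directly to the
    nearest other deficit cell it is not yet adjacent to (the cutoff no
    longer applies at this stage); (2) a degree-preserving pair swap —
    for deficit cells i, j (possibly i = j with deficit ≥ 2) find an
    existing edge (u, v) disjoint from {i, j} with i–u and j–v absent and
    replace it by (i, u) and (j, v).
    """
    n = len(cur)
    guard = 0
    while not np.array_equal(cur, target) and guard < 10_000:
        guard += 1
        deficits = np.flatnonzero(target - cur > 0)
        if len(deficits) == 0:
            break
        i = int(deficits[0])
        partners = [int(j) for j in deficits if j != i and not adj[i, j]]
        if partners:
            j = min(partners, key=lambda j: dist[i, j])
            adj[i, j] = adj[j, i] = True
            cur[i] += 1
            cur[j] += 1
            continue
        # pair swap: pick j = another deficit cell (adjacent to i) or i itself
        if len(deficits) > 1:
            j = int(deficits[1])
        elif target[i] - cur[i] >= 2:
            j = i
        else:
            return
        eu, ev = np.nonzero(np.triu(adj, 1))
        done = False
        for u, v in zip(eu.tolist(), ev.tolist()):
            if u in (i, j) or v in (i, j):
                continue
            for a, b in ((u, v), (v, u)):
                if not adj[i, a] and not adj[j, b] and not (i == j and a == b):
                    adj[u, v] = adj[v, u] = False
                    adj[i, a] = adj[a, i] = True
                    adj[j, b] = adj[b, j] = True
                    cur[i] += 1
                    cur[j] += 1
                    done = True
                    break
            if done:
                break
        if not done:
            return


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws with nonpositive values resampled (truncation at 0)."""
    if mean <= 0:
        raise ValueError("requested mean must be positive")
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    guard = 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
        guard += 1
        if guard > 1000:  # pragma: no cover
            raise RuntimeError("positive-normal resampling did not converge")
    return out


def sample_heterogeneity(
    n_cells: int,
    model_tag: str = "fast",
    seed: int = 0,
    overrides: Mapping[str, tuple] | None = None,
) -> CellParameters:
    """Draw per-cell intrinsic parameters for the chosen model regime.

    ``overrides`` replaces individual distribution entries of
    :data:`HETEROGENEITY_SPECS` (same tuple format). Normal draws are
    truncated at zero by resampling; the coupling parameter of the fast
    regime is gamma(k=4, θ=4) rescaled multiplicatively so the islet mean
    equals the target (preserving the gamma shape, hence CV = 1/√k = 0.5).
    """
    if model_tag not in HETEROGENEITY_SPECS:
        raise ValueError(f"unknown model_tag {model_tag!r}")
    spec = dict(HETEROGENEITY_SPECS[model_tag])
    if overrides:
        spec.update(overrides)
    rng = np.random.default_rng(seed)

    def draw(entry: tuple) -> np.ndarray:
        kind = entry[0]
        if kind == "normal":
            mean, sd = entry[1], entry[2]
            return _positive_normal(rng, mean, sd, n_cells)
        if kind == "gamma_rescaled":
            shape, scale, target_mean = entry[1], entry[2], entry[3]
            if target_mean <= 0:
                raise ValueError("requested mean must be positive")
            raw = rng.gamma(shape, scale, size=n_cells)
            return raw * (target_mean / raw.mean())
        raise ValueError(f"unknown distribution kind {kind!r}")

    return CellParameters(
        k_glyc=draw(spec["k_glyc"]),
        g_KATP=draw(spec["g_KATP"]),
        g_coup_cell=draw(spec["g_coup"]),
        model_tag=model_tag,
    )


def assign_edge_conductances(net: StructuralNetwork, params: CellParameters) -> StructuralNetwork:
    """Set each edge's conductance to the mean of its endpoint parameters."""
    if net.n_cells != params.n_cells:
        raise ValueError("network and parameters have mismatched cell counts")
    g = params.g_coup_cell
    ec = 0.5 * (g[:, None] + g[None, :]) * net.adjacency
    return replace(net, edge_conductance=ec)


def build_islet(
    n_cells: int,
    model_tag: str = "fast",
    seed: int = 0,
    packing: PackingConfig | None = None,
    degree_spec: DegreeSpec | None = None,
    overrides: Mapping[str, tuple] | None = None,
) -> IsletModel:
    """Convenience constructor: geometry + structure + heterogeneity.

    Sub-stage seeds are derived deterministically from ``seed`` so that the
    same top-level seed always yields the same islet.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    geom = build_geometry(n_cells, seed=sub[0], packing=packing)
    spec = degree_spec or DEGREE_SPECS[model_tag]
    net = build_structural_network(geom, degree_spec=spec, seed=sub[1])
    params = sample_heterogeneity(n_cells, model_tag=model_tag, seed=sub[2], overrides=overrides)
    return IsletModel(geometry=geom, structure=assign_edge_conductances(net, params), params=params)
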