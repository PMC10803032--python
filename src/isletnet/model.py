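"""Reference β-cell bursting model.

The detailed ionic/metabolic kinetics of published β-cell models enter this
package only through the :class:`CellModel` interface, so any single-cell
model can be dropped in. The shipped reference model is a reduced
Morris-Lecar-style relaxation burster with four states per cell:

* ``V`` — membrane potential (mV), fast subsystem with a Ca²⁺-like inward
  current and a delayed-rectifier-like outward current;
* ``n`` — K⁺-channel activation gate;
* ``s`` — slow negative-feedback conductance (stands in for the slow
  metabolic/Ca²⁺-handling drive that paces bursting); its time constant
  sets the oscillation period (fast regime < 2 min, slow regime > 2 min);
* ``c`` — [Ca²⁺] readout, a low-pass sigmoid of ``V``.

Cell heterogeneity enters through two dimensionless ratios relative to a
regime reference point: the glucokinase rate ``k_glyc`` closes the
K_ATP-like leak through a Hill-type openness factor
``o = 1 / (1 + (k_glyc/k_ref)^h)`` (more glycolytic flux → more ATP →
fewer open K_ATP channels → longer active phase), and ``g_KATP`` scales
that leak linearly. The resulting duty cycle is monotone increasing in
``k_glyc`` and monotone decreasing in ``g_KATP`` across the heterogeneity
range, the behavioral contract this model is tuned to.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from isletnet.islet import CellParameters, HETEROGENEITY_SPECS

__all__ = ["BurstingModelConfig", "ReferenceBurstingModel", "reference_bursting_model"]


#: Regime reference points (k_glyc_ref, g_KATP_ref, g_coup_ref) in the
#: native units of each parameter set. Heterogeneous parameters are mapped
#: into model units through these: a cell at the reference point behaves
#: identically in either regime, and coupling-reduction experiments scale
#: model coupling proportionally (g_coup_ref stays fixed at the standard
#: regime mean).
_REGIME_REFS = {
    "fast": (1.26e-4, 2.31, 0.12),
    "iom": (0.0037, 19700.0, 1.0),
}


@dataclass(frozen=True)
class BurstingModelConfig:
    """Fixed kinetic parameters of the reference burster (model units).

    Conductances in nS, potentials in mV, times in s. ``C_m`` is an
    effective capacitance (nS·s) chosen so the fast subsystem evolves on a
    ~0.1 s scale; the model is a plateau burster, not a spike-resolved one.
    """

    g_Ca: float = 3.6
    g_K: float = 10.0
    g_s: float = 4.0
    v_Ca: float = 25.0
    v_K: float = -75.0
    v_m: float = -24.0
    s_m: float = 12.0
    v_n: float = -16.0
    s_n: float = 5.6
    tau_n: float = 0.5
    v_s: float = -36.0
    s_s: float = 5.0
    tau_s: float = 30.0
    v_c: float = -32.0
    s_c: float = 6.0
    tau_c: float = 1.0
    C_m: float = 1.0
    g_KATP_scale: float = 0.3
    #: K_ATP-like leak conductance (nS) of a cell at the regime reference point
    g_KATP_model: float = 2.31
    katp_hill: float = 3.0
    #: reference model coupling conductance (nS) for a cell at g_coup_ref
    g_coup_model: float = 0.12

    def with_period_regime(self, regime: str) -> "BurstingModelConfig":
        """Return a copy configured for ``"fast"`` (<2 min) or ``"slow"``
        (>2 min) oscillation periods via the slow time constant."""
        if regime == "fast":
            return replace(self, tau_s=30.0)
        if regime == "slow":
            return replace(self, tau_s=240.0)
        raise ValueError(f"unknown period regime {regime!r}")


class ReferenceBurstingModel:
    """CellModel implementation binding heterogeneous parameters.

    Exposes the interface the simulator requires: ``state_dimension``,
    ``calcium_index``, ``voltage_index``, ``C_m``, ``initial_state`` and
    ``rhs(t, state, I_coup)`` where ``state`` is a (state_dimension,
    n_cells) array and ``I_coup`` the per-cell coupling current (pA,
    positive outward).
    """

    state_dimension = 4
    voltage_index = 0
    calcium_index = 3

    def __init__(
        self,
        params: CellParameters,
        config: BurstingModelConfig | None = None,
        period_regime: str | None = None,
    ):
        cfg = config or BurstingModelConfig()
        if period_regime is None:
            period_regime = "fast" if params.model_tag == "fast" else "slow"
        cfg = cfg.with_period_regime(period_regime)
        self.config = cfg
        self.params = params
        self.period_regime = period_regime
        k_ref, g_ref, _ = _REGIME_REFS.get(params.model_tag, _REGIME_REFS["fast"])
        x_k = params.k_glyc / k_ref
        x_g = params.g_KATP / g_ref
        openness = 1.0 / (1.0 + x_k**cfg.katp_hill)
        # effective static K_ATP-like leak conductance per cell (nS)
        self._g_katp_eff = cfg.g_KATP_scale * cfg.g_KATP_model * x_g * openness
        self.C_m = cfg.C_m

    @property
    def n_cells(self) -> int:
        return self.params.n_cells

    def coupling_conductance_scale(self) -> float:
        """Factor mapping g_coup_cell units to model nS."""
        _, _, g_ref = _REGIME_REFS.get(self.params.model_tag, _REGIME_REFS["fast"])
        return self.config.g_coup_model / g_ref

    def initial_state(self, rng: np.random.Generator | None = None, jitter: float = 0.0) -> np.ndarray:
        """Deterministic rest-like initial state, optionally jittered in the
        slow variable to desynchronize starting phases."""
        n = self.n_cells
        state = np.zeros((self.state_dimension, n))
        state[0] = -60.0
        state[2] = 0.3
        if jitter > 0:
            if rng is None:
                raise ValueError("jitter requires an rng")
            state[2] += rng.uniform(-jitter, jitter, size=n)
        return state

    def rhs(self, t: float, state: np.ndarray, I_coup: np.ndarray) -> np.ndarray:
        cfg = self.config
        V, n, s, c = state
        m_inf = 1.0 / (1.0 + np.exp((cfg.v_m - V) / cfg.s_m))
        n_inf = 1.0 / (1.0 + np.exp((cfg.v_n - V) / cfg.s_n))
        s_inf = 1.0 / (1.0 + np.exp((cfg.v_s - V) / cfg.s_s))
        c_inf = 1.0 / (1.0 + np.exp((cfg.v_c - V) / cfg.s_c))
        I_ion = (
            cfg.g_Ca * m_inf * (V - cfg.v_Ca)
            + cfg.g_K * n * (V - cfg.v_K)
            + cfg.g_s * s * (V - cfg.v_K)
            + self._g_katp_eff * (V - cfg.v_K)
        )
        out = np.empty_like(state)
        out[0] = -(I_ion + I_coup) / cfg.C_m
        out[1] = (n_inf - n) / cfg.tau_n
        out[2] = (s_inf - s) / cfg.tau_s
        out[3] = (c_inf - c) / cfg.tau_c
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite state derivative")
        return out


def reference_bursting_model(
    params: CellParameters,
    period_regime: str | None = None,
    config: BurstingModelConfig | None = None,
) -> ReferenceBurstingModel:
    """Build the reference burster for a heterogeneous parameter set."""
    return ReferenceBurstingModel(params, config=config, period_regime=period_regime)
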