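"""Reaction-network model of the negative-feedback linearizer circuit.

The model is a mass-action network over eight species:

* ``Dox_int`` — intracellular doxycycline, fed by a zeroth-order influx
  ``f * dox_ext`` from the (infinite) medium and cleared at ``g_dox``;
* ``D_free``, ``D_R1``, ``D_R2`` — promoter copies with zero, one or two
  operator sites occupied by TetR.  Two identical operator sites give the
  statistical factors ``2r`` (first binding) and ``2*k_off`` (loss of the
  doubly bound state);
* ``mRNA`` — the single transcript encoding both TetR and eGFP, produced at
  ``m`` from a free promoter and at ``leak_r1*m`` / ``leak_r2*m`` from the
  bound states (transcriptional leakage);
* ``TetR_free`` — active repressor, sequestered reversibly by Dox;
* ``TetR_Dox`` — the inactive repressor-inducer complex;
* ``eGFP`` — the reporter protein, translated separately from the same mRNA.

Total promoter count ``D_free + D_R1 + D_R2 = copy_number`` is conserved by
every reaction.  Deterministic dynamics integrate the mass-action rate
equations; stochastic dynamics use the direct-method kinetic Monte Carlo
(Gillespie) algorithm on integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar, root

from .params import CircuitParameters, ParameterError

__all__ = [
    "SPECIES",
    "Reaction",
    "ReactionNetwork",
    "SimulationResult",
    "IntegrationError",
    "build_network",
    "simulate_ode",
    "simulate_ssa",
    "find_steady_state",
    "dose_response",
    "copy_number_sweep",
    "promoter_fractions",
    "fit_dox_influx",
    "DoxInfluxFit",
]

SPECIES = ("Dox_int", "D_free", "D_R1", "D_R2", "mRNA", "TetR_free", "TetR_Dox", "eGFP")
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: relative tolerance on d(species)/dt used to declare steady state
STEADY_STATE_TOL = 1e-6


class IntegrationError(RuntimeError):
    """ODE integration failure; carries the last valid time point."""

    def __init__(self, message: str, t_last: float, state_last: np.ndarray | None = None):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``family`` groups the two directions of a reversible binding step under
    one label; irreversible reactions are their own family.
    """

    name: str
    family: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: float


@dataclass
class ReactionNetwork:
    """Executable form of the circuit reaction scheme."""

    species: tuple[str, ...]
    reactions: list[Reaction]
    copy_number: int
    params: CircuitParameters

    # cached arrays, built lazily
    _rates: np.ndarray | None = field(default=None, repr=False)
    _react_idx: np.ndarray | None = field(default=None, repr=False)
    _net: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def families(self) -> tuple[str, ...]:
        """Distinct reaction families, in first-appearance order."""
        seen: dict[str, None] = {}
        for rxn in self.reactions:
            seen.setdefault(rxn.family, None)
        return tuple(seen)

    def initial_state(self) -> np.ndarray:
        """All promoter copies free, every other species absent."""
        x0 = np.zeros(self.n_species)
        x0[_IDX["D_free"]] = self.copy_number
        return x0

    def _build_arrays(self) -> None:
        n_r, n_s = len(self.reactions), self.n_species
        rates = np.empty(n_r)
        react_idx = np.full((n_r, 2), -1, dtype=np.int64)
        net = np.zeros((n_r, n_s), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            rates[j] = rxn.rate
            k = 0
            for name, stoich in rxn.reactants:
                if stoich != 1 or k >= 2:
                    raise ValueError(
                        "network supports at most two distinct unit-stoichiometry reactants"
                    )
                react_idx[j, k] = _IDX[name]
                net[j, _IDX[name]] -= stoich
                k += 1
            for name, stoich in rxn.products:
                net[j, _IDX[name]] += stoich
        self._rates, self._react_idx, self._net = rates, react_idx, net

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rate constants, reactant index pairs (-1 padded), net stoichiometry)."""
        if self._rates is None:
            self._build_arrays()
        return self._rates, self._react_idx, self._net  # type: ignore[return-value]

    def propensities(self, x: np.ndarray) -> np.ndarray:
        """Mass-action propensities at state ``x``."""
        rates, react_idx, _ = self.arrays()
        a = rates.copy()
        for k in range(2):
            idx = react_idx[:, k]
            mask = idx >= 0
            a[mask] *= x[idx[mask]]
        return a

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        """Deterministic rate equations dx/dt = S^T a(x)."""
        _, _, net = self.arrays()
        return self.propensities(x) @ net


@dataclass
class SimulationResult:
    """Trajectories (or a single steady-state point) of all species."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    species: tuple[str, ...]
    copy_number: int
    steady_state: bool

    def trajectory(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def final(self, name: str) -> float:
        return float(self.states[-1, self.species.index(name)])

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    @property
    def promoter_fractions(self) -> tuple[float, float, float] | None:
        """(p_free, p_single, p_double) at the last time point; None if no DNA."""
        if self.copy_number == 0:
            return None
        return promoter_fractions(self, self.copy_number)


def build_network(params: CircuitParameters) -> ReactionNetwork:
    """Assemble the mass-action reaction list from circuit parameters.

    Raises :class:`~linamp.params.ParameterError` for invalid parameters
    (validation happens when ``params`` is constructed; passing a plain
    mapping re-validates here).
    """
    if not isinstance(params, CircuitParameters):
        params = CircuitParameters.from_dict(params)
    p = params
    rxns = [
        Reaction("dox_influx", "dox_influx", (), (("Dox_int", 1),), p.f * p.dox_ext),
        Reaction("dox_clearance", "dox_clearance", (("Dox_int", 1),), (), p.g_dox),
        Reaction(
            "tetr_dox_bind",
            "tetr_dox_sequestration",
            (("TetR_free", 1), ("Dox_int", 1)),
            (("TetR_Dox", 1),),
            p.k_seq_on,
        ),
        Reaction(
            "tetr_dox_release",
            "tetr_dox_sequestration",
            (("TetR_Dox", 1),),
            (("TetR_free", 1), ("Dox_int", 1)),
            p.k_seq_off,
        ),
        # two identical operator sites: statistical factor 2 on first binding
        Reaction(
            "operator_bind_1",
            "operator_binding_1",
            (("D_free", 1), ("TetR_free", 1)),
            (("D_R1", 1),),
            2.0 * p.r,
        ),
        Reaction(
            "operator_unbind_1",
            "operator_binding_1",
            (("D_R1", 1),),
            (("D_free", 1), ("TetR_free", 1)),
            p.k_off,
        ),
        Reaction(
            "operator_bind_2",
            "operator_binding_2",
            (("D_R1", 1), ("TetR_free", 1)),
            (("D_R2", 1),),
            p.r,
        ),
        Reaction(
            "operator_unbind_2",
            "operator_binding_2",
            (("D_R2", 1),),
            (("D_R1", 1), ("TetR_free", 1)),
            2.0 * p.k_off,
        ),
        Reaction(
            "transcription_free", "transcription_free", (("D_free", 1),),
            (("D_free", 1), ("mRNA", 1)), p.m,
        ),
        Reaction(
            "transcription_leak_r1", "transcription_leak_r1", (("D_R1", 1),),
            (("D_R1", 1), ("mRNA", 1)), p.leak_r1 * p.m,
        ),
        Reaction(
            "transcription_leak_r2", "transcription_leak_r2", (("D_R2", 1),),
            (("D_R2", 1), ("mRNA", 1)), p.leak_r2 * p.m,
        ),
        Reaction(
            "translation_tetr", "translation_tetr", (("mRNA", 1),),
            (("mRNA", 1), ("TetR_free", 1)), p.k_tl_tetr,
        ),
        Reaction(
            "translation_gfp", "translation_gfp", (("mRNA", 1),),
            (("mRNA", 1), ("eGFP", 1)), p.k_tl_gfp,
        ),
        Reaction("mrna_decay", "mrna_decay", (("mRNA", 1),), (), p.d_m),
        Reaction("tetr_decay", "tetr_decay", (("TetR_free", 1),), (), p.d_tetr),
        Reaction("gfp_decay", "gfp_decay", (("eGFP", 1),), (), p.d_gfp),
        Reaction("complex_decay", "complex_decay", (("TetR_Dox", 1),), (), p.d_complex),
    ]
    return ReactionNetwork(
        species=SPECIES, reactions=rxns, copy_number=p.copy_number, params=p
    )


def simulate_ode(
    network: ReactionNetwork,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 201,
) -> SimulationResult:
    """Integrate the deterministic rate equations from the initial state.

    Promoter conservation holds to within integration error (the summed
    promoter rows of the stoichiometry matrix are exactly zero).  The result
    is flagged ``steady_state`` when the scaled time-derivative criterion
    ``max |dx/dt| / (1 + |x|) < STEADY_STATE_TOL`` holds at ``t_end``.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        network.rhs,
        (0.0, t_end),
        network.initial_state(),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_last = float(sol.t[-1]) if sol.t.size else 0.0
        x_last = sol.y[:, -1] if sol.t.size else network.initial_state()
        raise IntegrationError(f"ODE integration failed: {sol.message}", t_last, x_last)
    states = sol.y.T
    x_end = states[-1]
    scaled = np.abs(network.rhs(t_end, x_end)) / (1.0 + np.abs(x_end))
    return SimulationResult(
        times=sol.t,
        states=states,
        species=network.species,
        copy_number=network.copy_number,
        steady_state=bool(np.max(scaled) < STEADY_STATE_TOL),
    )


def _reduced_residual(network: ReactionNetwork, y: np.ndarray) -> np.ndarray:
    """Rate-equation residual with D_free eliminated by conservation."""
    i_free = _IDX["D_free"]
    n = network.copy_number
    x = np.empty(network.n_species)
    j = 0
    for i in range(network.n_species):
        if i == i_free:
            continue
        x[i] = y[j]
        j += 1
    x[i_free] = n - x[_IDX["D_R1"]] - x[_IDX["D_R2"]]
    dx = network.rhs(0.0, x)
    return np.delete(dx, i_free)


def find_steady_state(
    network: ReactionNetwork,
    t_max: float = 20000.0,
    polish: bool = True,
) -> np.ndarray:
    """Steady state of the rate equations.

    Integrates in growing time chunks until the derivative criterion of
    :func:`simulate_ode` is met, then (optionally) polishes by root-finding
    on the reduced system in which ``D_free`` is eliminated through promoter
    conservation, so the conserved total is exact by construction.
    """
    t = 200.0
    result = simulate_ode(network, t, n_points=2)
    while not result.steady_state and t < t_max:
        t = min(2.0 * t, t_max)
        result = simulate_ode(network, t, n_points=2)
    x = result.final_state.copy()
    if not polish:
        return x
    i_free = _IDX["D_free"]
    y0 = np.delete(x, i_free)
    sol = root(lambda y: _reduced_residual(network, y), y0, method="hybr", tol=1e-12)
    if sol.success and np.all(sol.x > -1e-9):
        y = np.clip(sol.x, 0.0, None)
        x_polished = np.insert(y, i_free, 0.0)
        x_polished[i_free] = (
            network.copy_number - x_polished[_IDX["D_R1"]] - x_polished[_IDX["D_R2"]]
        )
        if x_polished[i_free] > -1e-9:
            x_polished[i_free] = max(x_polished[i_free], 0.0)
            return x_polished
    return x


# ---------------------------------------------------------------------------
# stochastic simulation (direct-method kinetic Monte Carlo)

def _ssa_core(x0, rates, react_idx, net, sample_times, seed, max_events):
    """Direct-method SSA; records the state at each sample time.

    Written in a form that `numba.njit` can compile; also runs (slowly) as
    plain Python when numba is unavailable.
    """
    np.random.seed(seed)
    n_r = rates.shape[0]
    n_s = x0.shape[0]
    n_t = sample_times.shape[0]
    x = x0.copy()
    out = np.zeros((n_t, n_s))
    a = np.zeros(n_r)
    t = 0.0
    k_sample = 0
    events = 0
    while k_sample < n_t:
        a0 = 0.0
        for j in range(n_r):
            aj = rates[j]
            i1 = react_idx[j, 0]
            if i1 >= 0:
                aj *= x[i1]
                i2 = react_idx[j, 1]
                if i2 >= 0:
                    aj *= x[i2]
            a[j] = aj
            a0 += aj
        if a0 <= 0.0:
            # frozen: hold the state to the end of the recording grid
            while k_sample < n_t:
                out[k_sample] = x
                k_sample += 1
            break
        tau = -np.log(np.random.random()) / a0
        t_next = t + tau
        while k_sample < n_t and sample_times[k_sample] < t_next:
            out[k_sample] = x
            k_sample += 1
        if k_sample >= n_t:
            break
        t = t_next
        u = np.random.random() * a0
        acc = 0.0
        j_fire = n_r - 1
        for j in range(n_r):
            acc += a[j]
            if u <= acc:
                j_fire = j
                break
        for i in range(n_s):
            x[i] += net[j_fire, i]
        events += 1
        if events >= max_events:
            return out, -1
    return out, events


try:  # optional acceleration; identical numerics either way
    from numba import njit as _njit

    _ssa_core_compiled = _njit(cache=True)(_ssa_core)
except ImportError:  # pragma: no cover - numba present in normal installs
    _ssa_core_compiled = _ssa_core


def simulate_ssa(
    network: ReactionNetwork,
    t_end: float,
    seed: int,
    n_samples: int = 101,
    max_events: int = 200_000_000,
) -> SimulationResult:
    """Exact stochastic trajectory of integer counts (direct method).

    Reproducible for a fixed ``seed``.  Promoter conservation holds exactly
    at every event because each reaction's stoichiometry conserves the
    promoter total.  With zero total propensity the trajectory is held
    constant to ``t_end``.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if seed is None:
        raise ValueError("simulate_ssa requires an explicit seed")
    rates, react_idx, net = network.arrays()
    sample_times = np.linspace(0.0, t_end, n_samples)
    x0 = network.initial_state()
    out, events = _ssa_core_compiled(
        x0, rates, react_idx, net, sample_times, int(seed) & 0x7FFFFFFF, max_events
    )
    if events < 0:
        raise RuntimeError(f"SSA exceeded max_events={max_events}")
    return SimulationResult(
        times=sample_times,
        states=out,
        species=network.species,
        copy_number=network.copy_number,
        steady_state=False,
    )


# ---------------------------------------------------------------------------
# derived computations

def promoter_fractions(result: SimulationResult, n: int) -> tuple[float, float, float]:
    """Fractions of free / singly bound / doubly bound promoters at the
    final recorded state.  Undefined (error) for ``n == 0``."""
    if n <= 0:
        raise ValueError("promoter fractions are undefined for copy_number == 0")
    p = (
        result.final("D_free") / n,
        result.final("D_R1") / n,
        result.final("D_R2") / n,
    )
    return p


def _steady_row(params: CircuitParameters) -> dict[str, float]:
    network = build_network(params)
    x = find_steady_state(network)
    n = params.copy_number
    d_free, d_r1, d_r2 = x[_IDX["D_free"]], x[_IDX["D_R1"]], x[_IDX["D_R2"]]
    tetr_free = x[_IDX["TetR_free"]]
    row = {
        "mrna": x[_IDX["mRNA"]],
        "tetr_free": tetr_free,
        "tetr_protein": tetr_free + x[_IDX["TetR_Dox"]] + d_r1 + 2.0 * d_r2,
        "egfp": x[_IDX["eGFP"]],
        "dox_int": x[_IDX["Dox_int"]],
    }
    if n > 0:
        row["p_free"] = d_free / n
        row["p_single"] = d_r1 / n
        row["p_double"] = d_r2 / n
    else:
        row["p_free"] = row["p_single"] = row["p_double"] = float("nan")
    return row


def dose_response(
    params: CircuitParameters, dox_grid: Sequence[float]
) -> pd.DataFrame:
    """Steady-state expression versus external Dox concentration.

    One deterministic steady state per dose.  Columns: ``dox``, ``mrna``,
    ``tetr_free``, ``tetr_protein`` (free + sequestered + operator-bound),
    ``egfp`` and promoter-state fractions.
    """
    dox_grid = list(dox_grid)
    if any(d < 0 for d in dox_grid):
        raise ValueError("dox_grid values must be >= 0")
    rows = []
    for d in dox_grid:
        try:
            row = _steady_row(params.replace(dox_ext=float(d)))
        except IntegrationError as err:
            raise IntegrationError(
                f"integration failed at dox={d}: {err}", err.t_last, err.state_last
            ) from err
        row["dox"] = float(d)
        rows.append(row)
    cols = ["dox", "mrna", "tetr_free", "tetr_protein", "egfp", "dox_int",
            "p_free", "p_single", "p_double"]
    return pd.DataFrame(rows)[cols]


def copy_number_sweep(
    params: CircuitParameters, n_values: Iterable[int], dox: float
) -> pd.DataFrame:
    """Steady-state expression and promoter occupancy versus DNA copy number
    at a fixed Dox dose.  Emulates amplification of the integrated circuit."""
    n_values = list(n_values)
    if any((not float(n).is_integer()) or n <= 0 for n in n_values):
        raise ValueError("n_values must be positive integers")
    rows = []
    for n in n_values:
        row = _steady_row(params.replace(copy_number=int(n), dox_ext=float(dox)))
        row["n"] = int(n)
        rows.append(row)
    cols = ["n", "mrna", "tetr_free", "tetr_protein", "egfp",
            "p_free", "p_single", "p_double"]
    return pd.DataFrame(rows)[cols]


@dataclass
class DoxInfluxFit:
    """Result of the one-parameter Dox-influx fit (plus output scale)."""

    f: float
    scale: float
    sse: float
    converged: bool
    n_doses: int
    message: str = ""


def fit_dox_influx(
    params0: CircuitParameters,
    observed: pd.DataFrame,
    f_bounds: tuple[float, float] | None = None,
    rel_resid_tol: float = 0.05,
) -> DoxInfluxFit:
    """Fit the Dox cell-entry rate ``f`` (and an arbitrary-units scale) to an
    observed eGFP dose response.

    ``observed`` needs columns ``dox`` and ``egfp`` with at least three
    distinct doses.  For each trial ``f`` the simulated steady-state curve is
    computed and the scale minimizing the sum of squared residuals is solved
    in closed form; the outer one-dimensional search over ``log f`` uses
    bounded scalar minimization (deterministic).  A fit is flagged
    non-converged when the optimizer fails or the residual is large
    relative to the observed dose-to-dose variation
    (``SSE > rel_resid_tol^2 * sum((obs - mean)^2)``), so data that carry
    no dose response at all — which the self-repressed wild-type model
    cannot produce — come back flagged.
    """
    if not {"dox", "egfp"} <= set(observed.columns):
        raise ValueError("observed must have columns 'dox' and 'egfp'")
    doses = np.asarray(observed["dox"], dtype=float)
    y_obs = np.asarray(observed["egfp"], dtype=float)
    if len(np.unique(doses)) < 3:
        raise ValueError("need at least 3 distinct doses")
    if f_bounds is None:
        f_bounds = (params0.f / 10.0, params0.f * 10.0)

    cache: dict[float, tuple[float, float]] = {}

    def sse_of_logf(logf: float) -> float:
        fval = float(np.exp(logf))
        curve = dose_response(params0.replace(f=fval), doses)["egfp"].to_numpy()
        denom = float(curve @ curve)
        scale = float(curve @ y_obs) / denom if denom > 0 else 0.0
        resid = y_obs - scale * curve
        sse = float(resid @ resid)
        cache[fval] = (scale, sse)
        return sse

    opt = minimize_scalar(
        sse_of_logf,
        bounds=(np.log(f_bounds[0]), np.log(f_bounds[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    f_hat = float(np.exp(opt.x))
    scale, sse = cache.get(f_hat, (float("nan"), float(opt.fun)))
    if not np.isfinite(scale):
        sse = sse_of_logf(opt.x)
        scale, sse = cache[f_hat]
    sst = float(((y_obs - y_obs.mean()) ** 2).sum())
    converged = bool(opt.success) and sst > 0 and sse <= rel_resid_tol**2 * sst
    return DoxInfluxFit(
        f=f_hat,
        scale=scale,
        sse=sse,
        converged=converged,
        n_doses=len(np.unique(doses)),
        message=str(getattr(opt, "message", "")),
    )
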