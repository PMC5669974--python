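"""The 21-node EGFR/IGF1R--MAPK--PI3K/mTOR signaling ODE model.

Each protein node carries a conserved total abundance (normalized to 1.0)
split between an active and an inactive form; only the active fraction
``a`` is integrated and the inactive fraction is ``1 - a`` by construction,
so the conservation law holds structurally.  Enzymatic (de)activation edges
follow Michaelis-Menten kinetics in the substrate's convertible fraction:

    activation by source S:   k * a_S * (1 - a) / (K + 1 - a)
    inhibition by source S:   k * a_S * a / (K + a)

Non-enzymatic couplings use the mass-action law (the same expressions
without the saturating denominator).  Every dynamic node additionally
relaxes through a basal first-order deactivation ``-d * a``; receptor
nodes are driven by a constant extracellular stimulus through the same
saturating activation form, and constitutively active phosphatase nodes
are held at a constant activity.  These functional forms keep every state
inside [0, 1] for any positive parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

ACTIVATING = "activating"
INHIBITING = "inhibiting"
MICHAELIS_MENTEN = "michaelis_menten"
MASS_ACTION = "mass_action"

ROLES = ("input-receptor", "kinase", "phosphatase", "effector")


class ModelConfigError(ValueError):
    """The model definition is inconsistent (dangling edge, duplicate node...)."""


class SimulationError(RuntimeError):
    """The integrator failed to produce a valid trajectory."""


@dataclass(frozen=True)
class ProteinNode:
    name: str
    role: str = "kinase"
    total: float = 1.0
    initial_active: float = 0.0
    constant: bool = False  # constitutively active, no dynamics

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ModelConfigError(f"{self.name}: unknown role {self.role!r}")
        if not 0.0 <= self.initial_active <= self.total:
            raise ModelConfigError(f"{self.name}: initial_active outside [0,total]")


@dataclass(frozen=True)
class Interaction:
    source: str
    target: str
    sign: str
    law: str = MICHAELIS_MENTEN
    k_nominal: float = 1.0
    K_nominal: float = 0.5

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATING, INHIBITING):
            raise ModelConfigError(f"bad sign {self.sign!r}")
        if self.law not in (MICHAELIS_MENTEN, MASS_ACTION):
            raise ModelConfigError(f"bad law {self.law!r}")
        if self.k_nominal <= 0 or (self.law == MICHAELIS_MENTEN and self.K_nominal <= 0):
            raise ModelConfigError(f"{self.source}->{self.target}: rates must be > 0")


@dataclass(frozen=True)
class Drive:
    """Constant receptor stimulus acting through the saturating activation form."""

    node: str
    strength: float = 0.5
    K: float = 0.5


@dataclass(frozen=True)
class BasalActivation:
    """Constant mass-action activation (for input nodes without a ligand)."""

    node: str
    rate: float = 0.1


@dataclass
class PathwayModel:
    nodes: list[ProteinNode]
    interactions: list[Interaction]
    drives: list[Drive] = field(default_factory=list)
    basal_activations: list[BasalActivation] = field(default_factory=list)
    decay_nominal: dict[str, float] = field(default_factory=dict)

    # filled by _finalize
    node_index: dict[str, int] = field(default_factory=dict, init=False)
    parameter_names: list[str] = field(default_factory=list, init=False)
    nominal: np.ndarray = field(default=None, init=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ModelConfigError(f"duplicate nodes: {sorted(dupes)}")
        self.node_index = {n.name: i for i, n in enumerate(self.nodes)}
        for e in self.interactions:
            for endpoint in (e.source, e.target):
                if endpoint not in self.node_index:
                    raise ModelConfigError(f"edge references undeclared node {endpoint!r}")
            if self._node(e.target).constant:
                raise ModelConfigError(f"edge targets constant node {e.target!r}")
        for d in self.drives:
            if d.node not in self.node_index:
                raise ModelConfigError(f"drive on undeclared node {d.node!r}")
        for b in self.basal_activations:
            if b.node not in self.node_index:
                raise ModelConfigError(f"basal activation on undeclared node {b.node!r}")
        self._finalize()

    def _node(self, name: str) -> ProteinNode:
        return self.nodes[self.node_index[name]]

    @property
    def dynamic_nodes(self) -> list[ProteinNode]:
        return [n for n in self.nodes if not n.constant]

    def _finalize(self) -> None:
        """Assign the canonical parameter ordering and nominal values.

        Order: per edge (k, then K for Michaelis-Menten edges) in declaration
        order; basal decay per dynamic node in node order; per drive
        (strength, half-saturation); basal activation rates.
        """
        names: list[str] = []
        nominal: list[float] = []
        for e in self.interactions:
            names.append(f"k_{e.source}_{e.target}")
            nominal.append(e.k_nominal)
            if e.law == MICHAELIS_MENTEN:
                names.append(f"K_{e.source}_{e.target}")
                nominal.append(e.K_nominal)
        for n in self.dynamic_nodes:
            names.append(f"d_{n.name}")
            nominal.append(self.decay_nominal.get(n.name, 0.1))
        for d in self.drives:
            names.append(f"s_{d.node}")
            nominal.append(d.strength)
            names.append(f"Ks_{d.node}")
            nominal.append(d.K)
        for b in self.basal_activations:
            names.append(f"b_{b.node}")
            nominal.append(b.rate)
        if len(set(names)) != len(names):
            raise ModelConfigError("duplicate parameter names (parallel edges?)")
        self.parameter_names = names
        self.nominal = np.asarray(nominal, dtype=float)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def initial_state(self) -> np.ndarray:
        return np.array(
            [n.total if n.constant else n.initial_active for n in self.nodes]
        )

    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]


# --- construction from a YAML/dict definition ------------------------------

def build_model(config: Mapping) -> PathwayModel:
    """Build a :class:`PathwayModel` from a parsed model-definition mapping."""
    try:
        node_defs = config["nodes"]
        edge_defs = config.get("edges", [])
    except (KeyError, TypeError) as exc:
        raise ModelConfigError(f"bad model definition: {exc}") from exc
    nodes = [
        ProteinNode(
            name=d["name"],
            role=d.get("role", "kinase"),
            initial_active=float(d.get("initial_active", 0.0)),
            constant=bool(d.get("constant", False)),
        )
        for d in node_defs
    ]
    edges = [
        Interaction(
            source=d["source"],
            target=d["target"],
            sign=d["sign"],
            law=d.get("law", MICHAELIS_MENTEN),
            k_nominal=float(d.get("k", 1.0)),
            K_nominal=float(d.get("K", 0.5)),
        )
        for d in edge_defs
    ]
    drives = [
        Drive(node=d["node"], strength=float(d.get("strength", 0.5)), K=float(d.get("K", 0.5)))
        for d in config.get("drives", [])
    ]
    basal = [
        BasalActivation(node=d["node"], rate=float(d.get("rate", 0.1)))
        for d in config.get("basal_activations", [])
    ]
    decay = config.get("decay", {})
    decay_nominal = {k: float(v) for k, v in decay.get("overrides", {}).items()}
    default_decay = float(decay.get("default", 0.1))
    model = PathwayModel(
        nodes=nodes,
        interactions=edges,
        drives=drives,
        basal_activations=basal,
        decay_nominal={
            **{n.name: default_decay for n in nodes if not n.constant},
            **decay_nominal,
        },
    )
    return model


def load_model(path: str | Path) -> PathwayModel:
    with open(path, "r", encoding="utf-8") as fh:
        return build_model(yaml.safe_load(fh))


def build_default_model() -> PathwayModel:
    """The default 21-node EGFR/IGF1R-MAPK-PI3K/mTOR network."""
    text = resources.files("rppacra.data").joinpath("model_default.yaml").read_text("utf-8")
    return build_model(yaml.safe_load(text))


# --- ODE assembly -----------------------------------------------------------

def _compiled_arrays(model: PathwayModel):
    pidx = {name: i for i, name in enumerate(model.parameter_names)}
    n_edges = len(model.interactions)
    e_src = np.empty(n_edges, dtype=np.int64)
    e_tgt = np.empty(n_edges, dtype=np.int64)
    e_sign = np.empty(n_edges, dtype=np.int64)
    e_k = np.empty(n_edges, dtype=np.int64)
    e_K = np.empty(n_edges, dtype=np.int64)
    for j, e in enumerate(model.interactions):
        e_src[j] = model.node_index[e.source]
        e_tgt[j] = model.node_index[e.target]
        e_sign[j] = 1 if e.sign == ACTIVATING else -1
        e_k[j] = pidx[f"k_{e.source}_{e.target}"]
        e_K[j] = pidx.get(f"K_{e.source}_{e.target}", -1)
    dyn = model.dynamic_nodes
    dec_node = np.array([model.node_index[n.name] for n in dyn], dtype=np.int64)
    dec_idx = np.array([pidx[f"d_{n.name}"] for n in dyn], dtype=np.int64)
    drv_node = np.array([model.node_index[d.node] for d in model.drives], dtype=np.int64)
    drv_s = np.array([pidx[f"s_{d.node}"] for d in model.drives], dtype=np.int64)
    drv_K = np.array([pidx[f"Ks_{d.node}"] for d in model.drives], dtype=np.int64)
    bas_node = np.array(
        [model.node_index[b.node] for b in model.basal_activations], dtype=np.int64
    )
    bas_idx = np.array([pidx[f"b_{b.node}"] for b in model.basal_activations], dtype=np.int64)
    totals = np.array([n.total for n in model.nodes])
    return (e_src, e_tgt, e_sign, e_k, e_K, dec_node, dec_idx,
            drv_node, drv_s, drv_K, bas_node, bas_idx, totals)


def _rhs_python(y, theta, arrs):
    (e_src, e_tgt, e_sign, e_k, e_K, dec_node, dec_idx,
     drv_node, drv_s, drv_K, bas_node, bas_idx, totals) = arrs
    dy = np.zeros_like(y)
    for j in range(e_src.shape[0]):
        a_src = y[e_src[j]]
        tgt = e_tgt[j]
        k = theta[e_k[j]]
        if e_sign[j] > 0:
            sub = totals[tgt] - y[tgt]
        else:
            sub = y[tgt]
        if e_K[j] >= 0:
            flux = k * a_src * sub / (theta[e_K[j]] + sub)
        else:
            flux = k * a_src * sub
        dy[tgt] += e_sign[j] * flux
    for j in range(dec_node.shape[0]):
        dy[dec_node[j]] -= theta[dec_idx[j]] * y[dec_node[j]]
    for j in range(drv_node.shape[0]):
        node = drv_node[j]
        sub = totals[node] - y[node]
        dy[node] += theta[drv_s[j]] * sub / (theta[drv_K[j]] + sub)
    for j in range(bas_node.shape[0]):
        node = bas_node[j]
        dy[node] += theta[bas_idx[j]] * (totals[node] - y[node])
    return dy


def _rhs_numba_body(y, theta, e_src, e_tgt, e_sign, e_k, e_K, dec_node, dec_idx,
                    drv_node, drv_s, drv_K, bas_node, bas_idx, totals):
    dy = np.zeros_like(y)
    for j in range(e_src.shape[0]):
        a_src = y[e_src[j]]
        tgt = e_tgt[j]
        k = theta[e_k[j]]
        if e_sign[j] > 0:
            sub = totals[tgt] - y[tgt]
        else:
            sub = y[tgt]
        if e_K[j] >= 0:
            flux = k * a_src * sub / (theta[e_K[j]] + sub)
        else:
            flux = k * a_src * sub
        dy[tgt] += e_sign[j] * flux
    for j in range(dec_node.shape[0]):
        dy[dec_node[j]] -= theta[dec_idx[j]] * y[dec_node[j]]
    for j in range(drv_node.shape[0]):
        node = drv_node[j]
        sub = totals[node] - y[node]
        dy[node] += theta[drv_s[j]] * sub / (theta[drv_K[j]] + sub)
    for j in range(bas_node.shape[0]):
        node = bas_node[j]
        dy[node] += theta[bas_idx[j]] * (totals[node] - y[node])
    return dy


def _jac_numba_body(y, theta, e_src, e_tgt, e_sign, e_k, e_K, dec_node, dec_idx,
                    drv_node, drv_s, drv_K, bas_node, bas_idx, totals):
    n = y.shape[0]
    J = np.zeros((n, n))
    for j in range(e_src.shape[0]):
        src = e_src[j]
        tgt = e_tgt[j]
        a_src = y[src]
        k = theta[e_k[j]]
        if e_sign[j] > 0:
            sub = totals[tgt] - y[tgt]
        else:
            sub = y[tgt]
        if e_K[j] >= 0:
            K = theta[e_K[j]]
            g = sub / (K + sub)
            gp = K / ((K + sub) * (K + sub))
        else:
            g = sub
            gp = 1.0
        J[tgt, src] += e_sign[j] * k * g
        # d(sub)/d(a_tgt) is -1 for activation and +1 for inhibition, which
        # combined with the edge sign always drains the diagonal
        J[tgt, tgt] -= k * a_src * gp
    for j in range(dec_node.shape[0]):
        J[dec_node[j], dec_node[j]] -= theta[dec_idx[j]]
    for j in range(drv_node.shape[0]):
        node = drv_node[j]
        sub = totals[node] - y[node]
        K = theta[drv_K[j]]
        J[node, node] -= theta[drv_s[j]] * K / ((K + sub) * (K + sub))
    for j in range(bas_node.shape[0]):
        J[bas_node[j], bas_node[j]] -= theta[bas_idx[j]]
    return J


try:  # jit-compile the generic right-hand side when numba is available
    import numba as _nb

    _rhs_compiled = _nb.njit(cache=False)(_rhs_numba_body)
    _jac_compiled = _nb.njit(cache=False)(_jac_numba_body)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is part of the supported stack
    _rhs_compiled = None
    _jac_compiled = None
    HAVE_NUMBA = False


def assemble_odes(model: PathwayModel) -> Callable[[float, np.ndarray, np.ndarray], np.ndarray]:
    """Return ``f(t, y, theta) -> dy/dt`` over the active-fraction state vector.

    Constant (constitutively active) nodes have zero derivative; the
    inactive fraction is never integrated (conservation is structural).
    """
    arrs = _compiled_arrays(model)
    if _rhs_compiled is not None:
        def rhs(t, y, theta, _arrs=arrs):
            return _rhs_compiled(y, theta, *_arrs)
        def jac(t, y, theta, _arrs=arrs):
            return _jac_compiled(y, theta, *_arrs)
    else:
        def rhs(t, y, theta, _arrs=arrs):
            return _rhs_python(y, theta, _arrs)
        jac = None
    rhs.jacobian = jac  # consumed by simulate(); finite differences otherwise
    return rhs


# --- simulation -------------------------------------------------------------

@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray            # shape (n_times, n_nodes), active fractions
    node_names: list[str]
    success: bool = True
    message: str = ""

    def state_of(self, node: str) -> np.ndarray:
        try:
            j = self.node_names.index(node)
        except ValueError as exc:
            raise KeyError(f"unknown node {node!r}") from exc
        return self.states[:, j]

    def conservation_residual(self, totals: Sequence[float] | None = None) -> float:
        """Max |active + inactive - total| over nodes and times.

        Inactive fractions are defined as total - active, so the residual is
        identically zero up to floating-point rounding; kept as an explicit
        check of the structural conservation law.
        """
        tot = np.ones(self.states.shape[1]) if totals is None else np.asarray(totals)
        inactive = tot[None, :] - self.states
        return float(np.max(np.abs(self.states + inactive - tot[None, :])))


DEFAULT_HORIZON = 100.0
DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9
_BOUND_TOL = 1e-6


def simulate(
    model: PathwayModel,
    theta: np.ndarray,
    horizon: float = DEFAULT_HORIZON,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_grid: int = 201,
    rhs: Callable | None = None,
) -> Trajectory:
    """Integrate the model with a stiff-capable solver (LSODA).

    Failures (non-convergence, out-of-bound states beyond numerical
    tolerance) are reported on the returned trajectory, never silently
    replaced by defaults.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (model.n_parameters,):
        raise ValueError(
            f"theta has shape {theta.shape}, expected ({model.n_parameters},)"
        )
    if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
        raise ValueError("theta must be strictly positive and finite")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if rhs is None:
        rhs = assemble_odes(model)
    t_eval = np.linspace(0.0, horizon, n_grid)
    y0 = model.initial_state()
    jac = getattr(rhs, "jacobian", None)
    sol = solve_ivp(
        rhs, (0.0, horizon), y0, method="LSODA", t_eval=t_eval,
        args=(theta,), rtol=rtol, atol=atol, jac=jac,
    )
    if not sol.success:
        return Trajectory(
            times=t_eval, states=np.full((n_grid, len(y0)), np.nan),
            node_names=model.node_names(), success=False, message=sol.message,
        )
    states = sol.y.T
    totals = np.array([n.total for n in model.nodes])
    if np.min(states) < -_BOUND_TOL or np.max(states - totals[None, :]) > _BOUND_TOL:
        return Trajectory(
            times=sol.t, states=states, node_names=model.node_names(),
            success=False, message="state left [0, total] beyond tolerance",
        )
    return Trajectory(times=sol.t, states=states, node_names=model.node_names())


def evaluation_auc(traj: Trajectory, node: str) -> float:
    """Evaluation function: area under the active-fraction curve over [0, T]."""
    if not traj.success:
        raise SimulationError(f"trajectory failed: {traj.message}")
    return float(np.trapezoid(traj.state_of(node), traj.times))


def trajectory_to_frame(traj: Trajectory):
    """Tidy (time, node, active_fraction) table for CSV export."""
    import pandas as pd

    records = [
        (t, name, traj.states[i, j])
        for i, t in enumerate(traj.times)
        for j, name in enumerate(traj.node_names)
    ]
    return pd.DataFrame(records, columns=["time", "node", "active_fraction"])
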