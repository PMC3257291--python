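"""Reaction-network data model: species, parameters, reactions, stoichiometry.

A :class:`ReactionNetwork` is the central object of the package.  It holds
species (molecule counts, dimensionless), strictly positive parameters and
reactions whose rate laws are arithmetic expressions over species and
parameter identifiers (operators ``+ - * / ^``, parentheses, numeric
literals, and a built-in ``hill(x, K, h) = 1/(1+(x/K)^h)`` term).  Rate laws
are parsed once into sympy expressions, so both evaluation and
differentiation are exact.

Boundary species have fixed amounts: they may appear in rate expressions but
carry no row in the stoichiometry matrix and no dynamics.

:func:`stoichiometric_decomposition` factors the stoichiometry matrix
``N = L @ N_R`` into a full-row-rank reduced matrix over an independent
species subset plus a link matrix, and extracts the conservation relations
(e.g. total promoter copy number) with their totals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import sympy as sp
from sympy.parsing.sympy_parser import parse_expr

from .errors import EvaluationError, SchemaError

__all__ = [
    "Species",
    "Parameter",
    "Reaction",
    "ReactionNetwork",
    "NetworkStructure",
    "build_network",
    "stoichiometric_decomposition",
    "evaluate_rates",
    "rate_derivatives",
]


def _hill(x, K, h):
    """Built-in inhibitory Hill term 1 / (1 + (x/K)^h)."""
    return 1 / (1 + (x / K) ** h)


#: sympy node types the rate-law grammar may produce after parsing.
_ALLOWED_NODES = (
    sp.Add,
    sp.Mul,
    sp.Pow,
    sp.Symbol,
    sp.Integer,
    sp.Float,
    sp.Rational,
)


def _parse_rate(text: str, symbols: Mapping[str, sp.Symbol], where: str) -> sp.Expr:
    local = dict(symbols)
    local["hill"] = _hill
    try:
        expr = parse_expr(text.replace("^", "**"), local_dict=local)
    except Exception as exc:  # sympy raises a zoo of exception types
        raise SchemaError(f"{where}: cannot parse rate expression {text!r}: {exc}") from exc
    for node in sp.preorder_traversal(expr):
        if not isinstance(node, _ALLOWED_NODES):
            raise SchemaError(
                f"{where}: unsupported construct {type(node).__name__} in rate "
                f"expression {text!r}; allowed: + - * / ^, numbers, identifiers, hill()"
            )
    for sym in expr.free_symbols:
        if str(sym) not in symbols:
            raise SchemaError(f"{where}: undeclared identifier {sym!r} in rate expression {text!r}")
    return expr


@dataclass(frozen=True)
class Species:
    id: str
    initial_amount: float = 0.0
    is_boundary: bool = False

    def __post_init__(self):
        if not self.id or not self.id.isidentifier():
            raise SchemaError(f"invalid species id {self.id!r}")
        if not np.isfinite(self.initial_amount) or self.initial_amount < 0:
            raise SchemaError(f"species {self.id!r}: initial amount must be >= 0")


@dataclass(frozen=True)
class Parameter:
    id: str
    value: float

    def __post_init__(self):
        if not self.id or not self.id.isidentifier():
            raise SchemaError(f"invalid parameter id {self.id!r}")
        if not np.isfinite(self.value) or self.value <= 0:
            # positivity is required for scaled (log-derivative) control coefficients
            raise SchemaError(f"parameter {self.id!r}: value must be > 0, got {self.value}")


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, int]
    rate_expression: str

    def __post_init__(self):
        if not self.id:
            raise SchemaError("reaction with empty id")
        if not self.stoichiometry:
            raise SchemaError(f"reaction {self.id!r}: empty stoichiometry")
        for sid, coeff in self.stoichiometry.items():
            if int(coeff) != coeff:
                raise SchemaError(f"reaction {self.id!r}: non-integer stoichiometry for {sid!r}")


@dataclass
class ReactionNetwork:
    """A validated reaction network.

    ``kind`` is ``"markov-jump"`` (propensities define a jump process; the
    diffusion matrix follows from the stoichiometry and stationary fluxes) or
    ``"langevin"`` (the model carries an explicit constant diffusion matrix
    over its dynamic species).
    """

    species: Sequence[Species]
    parameters: Sequence[Parameter]
    reactions: Sequence[Reaction]
    kind: str = "markov-jump"
    diffusion: np.ndarray | None = None
    name: str = "model"

    def __post_init__(self):
        if self.kind not in ("markov-jump", "langevin"):
            raise SchemaError(f"unknown network kind {self.kind!r}")
        if not self.species or not self.reactions:
            raise SchemaError("a network needs at least one species and one reaction")
        ids = [s.id for s in self.species] + [p.id for p in self.parameters]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise SchemaError(f"duplicate ids: {sorted(dup)}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise SchemaError("duplicate reaction ids")
        known = set(ids)
        for r in self.reactions:
            for sid in r.stoichiometry:
                if sid not in {s.id for s in self.species}:
                    raise SchemaError(f"reaction {r.id!r}: unknown species {sid!r}")
                if sid in {s.id for s in self.species if s.is_boundary}:
                    raise SchemaError(
                        f"reaction {r.id!r}: boundary species {sid!r} cannot change"
                    )
        symbols = {i: sp.Symbol(i) for i in known}
        self._symbols = symbols
        self._rate_exprs = [
            _parse_rate(r.rate_expression, symbols, f"reaction {r.id!r}") for r in self.reactions
        ]
        if self.kind == "langevin":
            n = len(self.dynamic_species)
            if self.diffusion is None:
                raise SchemaError("langevin network requires an explicit diffusion matrix")
            D = np.asarray(self.diffusion, dtype=float)
            if D.shape != (n, n) or not np.allclose(D, D.T):
                raise SchemaError("diffusion matrix must be symmetric over dynamic species")
            self.diffusion = D

    # -- orderings -----------------------------------------------------
    @cached_property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @cached_property
    def dynamic_species(self) -> list[str]:
        return [s.id for s in self.species if not s.is_boundary]

    @cached_property
    def parameter_ids(self) -> list[str]:
        return [p.id for p in self.parameters]

    @cached_property
    def parameter_values(self) -> np.ndarray:
        return np.array([p.value for p in self.parameters], dtype=float)

    @cached_property
    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    @cached_property
    def stoichiometry_matrix(self) -> np.ndarray:
        """Integer stoichiometry matrix, dynamic species x reactions."""
        dyn = self.dynamic_species
        N = np.zeros((len(dyn), len(self.reactions)), dtype=int)
        index = {sid: i for i, sid in enumerate(dyn)}
        for j, r in enumerate(self.reactions):
            for sid, coeff in r.stoichiometry.items():
                N[index[sid], j] = int(coeff)
        return N

    # -- compiled rate laws --------------------------------------------
    @cached_property
    def _args(self) -> list[sp.Symbol]:
        return [self._symbols[i] for i in self.species_ids + self.parameter_ids]

    @cached_property
    def _rate_fn(self):
        return sp.lambdify(self._args, sp.Matrix(self._rate_exprs), "numpy")

    @cached_property
    def _dvdx_fn(self):
        xs = [self._symbols[i] for i in self.dynamic_species]
        J = sp.Matrix(self._rate_exprs).jacobian(xs)
        return sp.lambdify(self._args, J, "numpy")

    @cached_property
    def _dvdp_fn(self):
        ps = [self._symbols[i] for i in self.parameter_ids]
        J = sp.Matrix(self._rate_exprs).jacobian(ps)
        return sp.lambdify(self._args, J, "numpy")

    @cached_property
    def _d2v_fns(self):
        """Second derivatives d2v/(dx dx) and d2v/(dx dp), one matrix per x."""
        xs = [self._symbols[i] for i in self.dynamic_species]
        ps = [self._symbols[i] for i in self.parameter_ids]
        V = sp.Matrix(self._rate_exprs)
        dvdx = V.jacobian(xs)
        dxx = [sp.lambdify(self._args, dvdx.diff(x), "numpy") for x in xs]
        dvdp = V.jacobian(ps)
        dpx = [sp.lambdify(self._args, dvdp.diff(x), "numpy") for x in xs]
        return dxx, dpx

    def _call_args(self, state, params):
        return [*np.asarray(state, dtype=float), *np.asarray(params, dtype=float)]

    def rates(self, state, params=None) -> np.ndarray:
        """Evaluate all reaction rates at ``state`` (all-species order)."""
        params = self.parameter_values if params is None else params
        v = np.asarray(self._rate_fn(*self._call_args(state, params)), dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            bad = self.reactions[int(np.flatnonzero(~np.isfinite(v))[0])].id
            raise EvaluationError(f"reaction {bad!r}: non-finite rate at state {state}")
        if np.any(v < 0):
            bad = self.reactions[int(np.flatnonzero(v < 0)[0])].id
            raise EvaluationError(f"reaction {bad!r}: negative rate at state {state}")
        return v

    def rate_jacobian_x(self, state, params=None) -> np.ndarray:
        """dv/dx, reactions x dynamic species."""
        params = self.parameter_values if params is None else params
        return np.asarray(self._dvdx_fn(*self._call_args(state, params)), dtype=float)

    def rate_jacobian_p(self, state, params=None) -> np.ndarray:
        """dv/dp, reactions x parameters."""
        params = self.parameter_values if params is None else params
        return np.asarray(self._dvdp_fn(*self._call_args(state, params)), dtype=float)

    def rate_hessians(self, state, params=None):
        """Per dynamic species k: (d2v/dx dx_k, d2v/dp dx_k)."""
        params = self.parameter_values if params is None else params
        args = self._call_args(state, params)
        dxx, dpx = self._d2v_fns
        Hxx = [np.asarray(f(*args), dtype=float) for f in dxx]
        Hpx = [np.asarray(f(*args), dtype=float) for f in dpx]
        return Hxx, Hpx

    def with_parameters(self, values: Mapping[str, float] | np.ndarray) -> "ReactionNetwork":
        """Copy of the network with replaced parameter values."""
        if isinstance(values, Mapping):
            new = [Parameter(p.id, float(values.get(p.id, p.value))) for p in self.parameters]
        else:
            vals = np.asarray(values, dtype=float)
            if vals.shape != (len(self.parameters),):
                raise SchemaError("parameter vector has wrong length")
            new = [Parameter(p.id, float(v)) for p, v in zip(self.parameters, vals)]
        return ReactionNetwork(
            species=self.species,
            parameters=new,
            reactions=self.reactions,
            kind=self.kind,
            diffusion=self.diffusion,
            name=self.name,
        )

    def model_hash(self) -> str:
        h = hashlib.sha256()
        for s in self.species:
            h.update(f"S:{s.id}:{s.initial_amount}:{s.is_boundary};".encode())
        for p in self.parameters:
            h.update(f"P:{p.id}:{p.value};".encode())
        for r in self.reactions:
            stoich = ",".join(f"{k}:{v}" for k, v in sorted(r.stoichiometry.items()))
            h.update(f"R:{r.id}:{stoich}:{r.rate_expression};".encode())
        h.update(self.kind.encode())
        return h.hexdigest()[:16]


@dataclass
class NetworkStructure:
    """Stoichiometric decomposition N = L @ N_R with conservation relations.

    ``independent`` lists the indices (into the dynamic-species ordering) of
    the independent species, chosen as the first maximal linearly independent
    row set of N in declaration order.  Each conservation relation is a
    coefficient vector ``g`` over dynamic species with ``g @ N = 0``, paired
    with its total ``g @ x0``.
    """

    N: np.ndarray
    N_R: np.ndarray
    L: np.ndarray
    independent: list[int]
    conservation: list[tuple[np.ndarray, float]] = field(default_factory=list)
    dynamic_ids: list[str] = field(default_factory=list)

    @property
    def n_independent(self) -> int:
        return len(self.independent)

    def reduce_state(self, x_dyn: np.ndarray) -> np.ndarray:
        """Extract independent-species coordinates from a dynamic-species vector."""
        return np.asarray(x_dyn, dtype=float)[self.independent]

    def lift_covariance(self, C_ind: np.ndarray) -> np.ndarray:
        return self.L @ C_ind @ self.L.T


def build_network(spec) -> ReactionNetwork:
    """Build a validated :class:`ReactionNetwork` from a structured description.

    ``spec`` may already be a :class:`ReactionNetwork` (returned unchanged
    after validation), a mapping with keys ``species``, ``parameters``,
    ``reactions`` (see the native schema in :mod:`stocan.schema`), or a path /
    text handled by :func:`stocan.schema.load_model`.
    """
    if isinstance(spec, ReactionNetwork):
        return spec
    if isinstance(spec, Mapping):
        return _network_from_dict(spec)
    from . import schema

    return schema.load_model(spec)


def _network_from_dict(d: Mapping) -> ReactionNetwork:
    species = []
    for s in d.get("species", []):
        if isinstance(s, Species):
            species.append(s)
        else:
            species.append(
                Species(
                    id=s["id"],
                    initial_amount=float(s.get("initial_amount", 0.0)),
                    is_boundary=bool(s.get("is_boundary", False)),
                )
            )
    params = [
        p if isinstance(p, Parameter) else Parameter(p["id"], float(p["value"]))
        for p in d.get("parameters", [])
    ]
    reactions = []
    for r in d.get("reactions", []):
        if isinstance(r, Reaction):
            reactions.append(r)
        else:
            reactions.append(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: int(v) for k, v in r["stoichiometry"].items()},
                    rate_expression=r["rate"] if "rate" in r else r["rate_expression"],
                )
            )
    return ReactionNetwork(
        species=species,
        parameters=params,
        reactions=reactions,
        kind=d.get("kind", "markov-jump"),
        diffusion=None if d.get("diffusion") is None else np.asarray(d["diffusion"], float),
        name=d.get("name", "model"),
    )


def stoichiometric_decomposition(net: ReactionNetwork) -> NetworkStructure:
    """Factor N = L @ N_R and extract conservation relations (exact arithmetic).

    The independent species are chosen by a deterministic greedy scan of the
    rows of N in declaration order, so the decomposition is reproducible.
    """
    N = net.stoichiometry_matrix
    n_dyn = N.shape[0]
    M = sp.Matrix(N.tolist())

    independent: list[int] = []
    basis = sp.zeros(0, N.shape[1])
    for i in range(n_dyn):
        cand = basis.col_join(M.row(i))
        if cand.rank() > basis.rank():
            basis = cand
            independent.append(i)

    N_R = N[independent, :]
    # L solves N = L @ N_R exactly; row i of L solves N_R^T l = N_i^T
    NRt = sp.Matrix(N_R.tolist()).T
    L = sp.zeros(n_dyn, len(independent))
    for i in range(n_dyn):
        sol = NRt.solve_least_squares(M.row(i).T) if independent else sp.zeros(0, 1)
        if independent:
            # exact solve: N_R^T has full column rank, least squares is exact here
            resid = NRt * sol - M.row(i).T
            if any(r != 0 for r in resid):
                raise SchemaError("internal: link-matrix solve failed")  # pragma: no cover
            L[i, :] = sol.T
    L_np = np.array(L.tolist(), dtype=float)
    assert np.array_equal(L_np @ N_R, N)

    x0 = net.initial_state[[net.species_ids.index(s) for s in net.dynamic_species]]
    conservation: list[tuple[np.ndarray, float]] = []
    indep_set = set(independent)
    for i in range(n_dyn):
        if i in indep_set:
            continue
        g = np.zeros(n_dyn)
        g[i] = 1.0
        g[independent] -= L_np[i, :]
        conservation.append((g, float(g @ x0)))

    return NetworkStructure(
        N=N,
        N_R=N_R,
        L=L_np,
        independent=independent,
        conservation=conservation,
        dynamic_ids=list(net.dynamic_species),
    )


def evaluate_rates(net: ReactionNetwork, state, params=None) -> np.ndarray:
    """Evaluate all reaction rates at ``state`` (all-species declaration order)."""
    return net.rates(state, params)


def rate_derivatives(net, state, params=None, method: str = "symbolic"):
    """Partial derivatives (dv/dx over dynamic species, dv/dp).

    ``method="symbolic"`` differentiates the parsed rate laws exactly;
    ``method="fd"`` uses central finite differences with relative step 1e-6
    (used as a cross-check of the symbolic path).
    """
    params = net.parameter_values if params is None else np.asarray(params, float)
    state = np.asarray(state, dtype=float)
    if method == "symbolic":
        dvdx = net.rate_jacobian_x(state, params)
        dvdp = net.rate_jacobian_p(state, params)
    elif method == "fd":
        rel = 1e-6
        dyn_idx = [net.species_ids.index(s) for s in net.dynamic_species]
        dvdx = np.zeros((len(net.reactions), len(dyn_idx)))
        for col, i in enumerate(dyn_idx):
            h = rel * max(1.0, abs(state[i]))
            up, dn = state.copy(), state.copy()
            up[i] += h
            dn[i] -= h
            dvdx[:, col] = (net.rates(up, params) - net.rates(dn, params)) / (2 * h)
        dvdp = np.zeros((len(net.reactions), len(params)))
        for j in range(len(params)):
            h = rel * abs(params[j])
            up, dn = params.copy(), params.copy()
            up[j] += h
            dn[j] -= h
            dvdp[:, j] = (net.rates(state, up) - net.rates(state, dn)) / (2 * h)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not (np.all(np.isfinite(dvdx)) and np.all(np.isfinite(dvdp))):
        raise EvaluationError("non-finite rate derivative")
    return dvdx, dvdp
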