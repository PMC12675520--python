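"""Kinetic schemes for ligand-gated channels.

Builds continuous-time Markov generators (Q-matrices) for a homotrimeric
receptor in which each subunit carries two binary coordinates — agonist
occupancy of the inter-subunit pocket it heads, and a rotated/unrotated
conformation — together with declaratively configured arbitrary schemes.

Geometry convention: pocket ``i`` is framed by subunit ``i`` (its A-side,
carrying the strong ``RB`` coupling) and subunit ``i+1 mod 3`` (its B-side,
weak ``BR`` coupling).  All couplings act multiplicatively on rates;
off-rate factors are derived as on-factor / equilibrium-factor so that
every cycle in the state graph satisfies microscopic reversibility by
construction.

Units: concentrations in uM, rates in 1/s (association rates in uM^-1 s^-1),
currents in pA.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Callable, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TrimerParams",
    "SubunitConfig",
    "KineticScheme",
    "enumerate_trimer_states",
    "build_trimer_generator",
    "lump_by_symmetry",
    "trimer_scheme",
    "scheme_from_config",
    "conductance_vector",
    "stationary_distribution",
]


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimerParams:
    """Kinetic parameters of the trimeric binding/rotation scheme.

    Rates: ``b_on`` (association, uM^-1 s^-1), ``b_off`` (dissociation, s^-1),
    ``r_on`` / ``r_off`` (subunit rotation / unrotation, s^-1).

    Dimensionless allosteric coupling factors: ``RB``/``BR`` act on
    equilibria, ``RB_bon``/``BR_bon`` on binding on-rates, ``RB_ron``/
    ``BR_ron`` on rotation on-rates.  ``RB*`` factors couple a pocket to its
    A-side subunit, ``BR*`` to its B-side subunit.  Off-rate factors are the
    derived quotients (e.g. ``RB_boff = RB_bon / RB``), which closes every
    thermodynamic cycle exactly.

    Fields may be scalars or equal-length arrays (a batch of parameter
    vectors); all derived quantities broadcast.
    """

    b_on: float | np.ndarray
    b_off: float | np.ndarray
    r_on: float | np.ndarray
    r_off: float | np.ndarray
    RB: float | np.ndarray = 1.0
    BR: float | np.ndarray = 1.0
    RB_bon: float | np.ndarray = 1.0
    BR_bon: float | np.ndarray = 1.0
    RB_ron: float | np.ndarray = 1.0
    BR_ron: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"TrimerParams.{name} must be strictly positive and finite")

    # derived off-rate coupling factors (thermodynamic closure)
    @property
    def RB_boff(self):
        return np.asarray(self.RB_bon) / np.asarray(self.RB)

    @property
    def BR_boff(self):
        return np.asarray(self.BR_bon) / np.asarray(self.BR)

    @property
    def RB_roff(self):
        return np.asarray(self.RB_ron) / np.asarray(self.RB)

    @property
    def BR_roff(self):
        return np.asarray(self.BR_ron) / np.asarray(self.BR)

    def symmetrized(self) -> "TrimerParams":
        """Return the symmetric counterpart (B-side couplings := A-side)."""
        return replace(self, BR=self.RB, BR_bon=self.RB_bon, BR_ron=self.RB_ron)


@dataclass(frozen=True)
class SubunitConfig:
    """One micro-configuration of the trimer: per-subunit occupancy and rotation."""

    bound: tuple[bool, bool, bool]
    rotated: tuple[bool, bool, bool]

    def shifted(self, k: int = 1) -> "SubunitConfig":
        """Cyclic shift of the subunit ring by ``k`` positions."""
        k = k % 3
        return SubunitConfig(
            bound=tuple(self.bound[(i + k) % 3] for i in range(3)),
            rotated=tuple(self.rotated[(i + k) % 3] for i in range(3)),
        )

    def canonical(self) -> "SubunitConfig":
        return min((self.shifted(k) for k in range(3)), key=lambda s: (s.bound, s.rotated))

    @property
    def n_bound(self) -> int:
        return sum(self.bound)

    @property
    def n_rotated(self) -> int:
        return sum(self.rotated)

    def label(self) -> str:
        return "".join(
            ("B" if b else "-") + ("R" if r else "-") for b, r in zip(self.bound, self.rotated)
        )


# --------------------------------------------------------------------------
# state enumeration under cyclic symmetry
# --------------------------------------------------------------------------

def enumerate_trimer_states(flags_per_subunit: int) -> list[tuple[tuple[int, int, int], int]]:
    """Enumerate cyclic-rotation equivalence classes of per-subunit flag words.

    Each subunit carries ``flags_per_subunit`` binary flags, i.e. a word in
    ``{0 .. 2**flags - 1}``; the trimer state is a triple of words and two
    states are equivalent if a cyclic shift of the ring maps one to the
    other.  Returns ``(representative, orbit_size)`` pairs where the
    representative is the lexicographically smallest rotation.  Orbit sizes
    are 1 (all-equal triples) or 3; their sum is ``(2**flags)**3``.
    """
    if flags_per_subunit < 0:
        raise ValueError("flags_per_subunit must be >= 0")
    n_words = 2 ** flags_per_subunit
    seen: dict[tuple[int, int, int], int] = {}
    for trip in product(range(n_words), repeat=3):
        rots = [tuple(trip[(i + k) % 3] for i in range(3)) for k in range(3)]
        rep = min(rots)
        if rep not in seen:
            seen[rep] = len(set(rots))
    return sorted(seen.items())


def _trimer_states() -> list[SubunitConfig]:
    """All 64 micro-states, indexed by bound bits 0..2 then rotated bits 0..2."""
    states = []
    for code in range(64):
        bound = tuple(bool((code >> i) & 1) for i in range(3))
        rotated = tuple(bool((code >> (i + 3)) & 1) for i in range(3))
        states.append(SubunitConfig(bound=bound, rotated=rotated))
    return states


def _state_index(cfg: SubunitConfig) -> int:
    code = 0
    for i in range(3):
        code |= int(cfg.bound[i]) << i
        code |= int(cfg.rotated[i]) << (i + 3)
    return code


# --------------------------------------------------------------------------
# trimer generator
# --------------------------------------------------------------------------

def build_trimer_generator(
    params: TrimerParams, asymmetric: bool, c: float
) -> np.ndarray:
    """Rate matrix over the 64 micro-states at agonist concentration ``c`` (uM).

    Binding at pocket ``i``: ``b_on*c`` times ``RB_bon`` if subunit ``i`` is
    rotated and ``BR_bon`` if subunit ``i+1`` is; unbinding uses the derived
    off-factors.  Rotation of subunit ``j``: ``r_on`` times ``RB_ron`` if
    pocket ``j`` is bound and ``BR_ron`` if pocket ``j-1`` is; unrotation
    uses the derived off-factors.  With ``asymmetric=False`` every B-side
    factor is replaced by its A-side value.

    If the parameter fields are arrays of length K the result has shape
    ``(K, 64, 64)``; scalars give ``(64, 64)``.
    """
    if not np.isfinite(c) or c < 0:
        raise ValueError(f"concentration must be finite and >= 0, got {c!r}")
    p = params if asymmetric else params.symmetrized()

    batch = np.broadcast(np.asarray(p.b_on, dtype=float)).shape
    scalar = batch == ()

    def arr(x):
        return np.asarray(x, dtype=float)

    shape = (64, 64) if scalar else (arr(p.b_on).shape[0], 64, 64)
    Q = np.zeros(shape)
    states = _trimer_states()

    def add(i: int, j: int, rate) -> None:
        if scalar:
            Q[i, j] += rate
        else:
            Q[..., i, j] += rate

    one = 1.0
    for s_idx, s in enumerate(states):
        for i in range(3):  # pocket index
            a_rot = s.rotated[i]            # A-side subunit i
            b_rot = s.rotated[(i + 1) % 3]  # B-side subunit i+1
            if not s.bound[i]:
                rate = arr(p.b_on) * c
                rate = rate * (arr(p.RB_bon) if a_rot else one)
                rate = rate * (arr(p.BR_bon) if b_rot else one)
                tgt = replace(s, bound=tuple(b or (k == i) for k, b in enumerate(s.bound)))
                add(s_idx, _state_index(tgt), rate)
            else:
                rate = arr(p.b_off)
                rate = rate * (p.RB_boff if a_rot else one)
                rate = rate * (p.BR_boff if b_rot else one)
                tgt = replace(s, bound=tuple(b and (k != i) for k, b in enumerate(s.bound)))
                add(s_idx, _state_index(tgt), rate)
        for j in range(3):  # subunit index
            own = s.bound[j]             # pocket j couples to its A-side subunit j
            left = s.bound[(j - 1) % 3]  # pocket j-1 couples to its B-side subunit j
            if not s.rotated[j]:
                rate = arr(p.r_on)
                rate = rate * (arr(p.RB_ron) if own else one)
                rate = rate * (arr(p.BR_ron) if left else one)
                tgt = replace(s, rotated=tuple(r or (k == j) for k, r in enumerate(s.rotated)))
                add(s_idx, _state_index(tgt), rate)
            else:
                rate = arr(p.r_off)
                rate = rate * (p.RB_roff if own else one)
                rate = rate * (p.BR_roff if left else one)
                tgt = replace(s, rotated=tuple(r and (k != j) for k, r in enumerate(s.rotated)))
                add(s_idx, _state_index(tgt), rate)

    if scalar:
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices(64)] = -Q.sum(axis=1)
    else:
        idx = np.arange(64)
        Q[..., idx, idx] = 0.0
        Q[..., idx, idx] = -Q.sum(axis=-1)
    return Q


def _cyclic_permutation() -> np.ndarray:
    """Index permutation of the 64 states under a one-step subunit shift."""
    perm = np.empty(64, dtype=int)
    for s_idx, s in enumerate(_trimer_states()):
        perm[s_idx] = _state_index(s.shifted(1))
    return perm


def trimer_orbit_map() -> tuple[np.ndarray, list[SubunitConfig]]:
    """Map each of the 64 micro-states to its cyclic orbit (24 classes).

    Returns ``(orbit_of_state, representatives)`` with representatives
    ordered by canonical state code.
    """
    states = _trimer_states()
    reps: dict[int, int] = {}
    orbit = np.empty(64, dtype=int)
    rep_states: list[SubunitConfig] = []
    for s_idx, s in enumerate(states):
        canon = _state_index(s.canonical())
        if canon not in reps:
            reps[canon] = len(reps)
            rep_states.append(states[canon])
        orbit[s_idx] = reps[canon]
    return orbit, rep_states


def lump_by_symmetry(Q64: np.ndarray, orbit_map: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Aggregate a cyclic-invariant generator over its symmetry orbits.

    The lumped rate from class ``u`` to class ``v`` is the total rate from
    any representative of ``u`` into all members of ``v`` (strong
    lumpability, exact for generators invariant under the cyclic subunit
    permutation).  Raises ``ValueError`` if the invariance check fails.
    """
    Q64 = np.asarray(Q64)
    perm = _cyclic_permutation()
    scale = max(np.abs(Q64).max(), 1.0)
    dev = np.abs(Q64[..., perm, :][..., :, perm] - Q64).max()
    if dev > tol * scale:
        raise ValueError(
            f"generator is not invariant under the cyclic subunit permutation "
            f"(max deviation {dev:.3e})"
        )
    n_cls = int(orbit_map.max()) + 1
    # representative of each class = first state mapping to it
    reps = np.array([np.nonzero(orbit_map == u)[0][0] for u in range(n_cls)])
    agg = np.zeros((64, n_cls))
    agg[np.arange(64), orbit_map] = 1.0
    return Q64[..., reps, :] @ agg


# --------------------------------------------------------------------------
# scheme container
# --------------------------------------------------------------------------

@dataclass
class KineticScheme:
    """A kinetic scheme: labelled states, a generator builder, conductance classes.

    ``generator(c)`` returns the rate matrix at agonist concentration ``c``
    (uM); when the underlying parameters are arrays of length K it returns a
    ``(K, S, S)`` stack.  ``conductance_class[s]`` is the number of rotated
    subunits for trimer schemes, or a user-assigned class for declarative
    schemes.
    """

    state_labels: list[str]
    conductance_class: np.ndarray
    generator: Callable[[float], np.ndarray]
    n_bound: np.ndarray | None = None
    n_rotated: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    _rebuild: Callable[[dict], "KineticScheme"] | None = None

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def with_params(self, updates: dict) -> "KineticScheme":
        """Return a copy with (possibly array-valued) parameter updates."""
        if self._rebuild is None:
            raise ValueError("this scheme does not support parameter rebinding")
        new = dict(self.params)
        new.update(updates)
        return self._rebuild(new)


def trimer_scheme(
    params: TrimerParams, asymmetric: bool = True, lumped: bool = True
) -> KineticScheme:
    """The trimeric binding/rotation scheme (64 micro-states or 24 symmetry classes)."""
    orbit, reps = trimer_orbit_map()
    if lumped:
        labels = [s.label() for s in reps]
        n_b = np.array([s.n_bound for s in reps])
        n_r = np.array([s.n_rotated for s in reps])
    else:
        sts = _trimer_states()
        labels = [s.label() for s in sts]
        n_b = np.array([s.n_bound for s in sts])
        n_r = np.array([s.n_rotated for s in sts])

    def gen(c: float, _p=params) -> np.ndarray:
        Q = build_trimer_generator(_p, asymmetric, c)
        return lump_by_symmetry(Q, orbit) if lumped else Q

    def rebuild(d: dict) -> KineticScheme:
        return trimer_scheme(TrimerParams(**d), asymmetric=asymmetric, lumped=lumped)

    return KineticScheme(
        state_labels=labels,
        conductance_class=n_r.copy(),
        generator=gen,
        n_bound=n_b,
        n_rotated=n_r,
        params={f.name: getattr(params, f.name) for f in params.__dataclass_fields__.values()}
        if hasattr(params, "__dataclass_fields__")
        else {},
        _rebuild=rebuild,
    )



# --------------------------------------------------------------------------
# declarative schemes
# --------------------------------------------------------------------------

_ALLOWED_NODES = (
    ast.Expression, ast.BinOp, ast.UnaryOp, ast.Name, ast.Constant,
    ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow, ast.USub, ast.UAdd, ast.Load,
)


def _compile_rate(expr: str, known: set[str]) -> Callable[[dict], np.ndarray]:
    """Compile a rate expression over named parameters (safe arithmetic only)."""
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as e:
        raise ValueError(f"invalid rate expression {expr!r}: {e}") from None
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ValueError(f"disallowed construct {type(node).__name__!r} in rate {expr!r}")
        if isinstance(node, ast.Name) and node.id not in known:
            raise ValueError(f"unknown parameter symbol {node.id!r} in rate {expr!r}")
    code = compile(tree, "<rate>", "eval")
    return lambda env: eval(code, {"__builtins__": {}}, env)  # noqa: S307 - AST-validated


def scheme_from_config(config: str | dict, params: dict | None = None) -> KineticScheme:
    """Build a :class:`KineticScheme` from a declarative TOML description.

    The configuration declares state labels, per-state conductance classes,
    parameter names (with optional default values), and edges::

        [scheme]
        states = ["C", "O"]
        classes = [0, 3]

        [scheme.params]
        k_on = 10.0
        k_off = 100.0

        [[scheme.edge]]
        from = "C"
        to = "O"
        rate = "k_on"
        conc = true       # multiply by agonist concentration

    Undeclared transitions have rate zero.  ``params`` overrides the
    defaults; values may be scalars or length-K arrays (batched generator).
    """
    if isinstance(config, str):
        import tomllib

        cfg = tomllib.loads(config)
    else:
        cfg = config
    sc = cfg.get("scheme", cfg)
    labels = list(sc["states"])
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate state label(s): {dup}")
    classes = np.asarray(sc.get("classes", [0] * len(labels)), dtype=int)
    if len(classes) != len(labels):
        raise ValueError("classes must have one entry per state")
    defaults = dict(sc.get("params", {}))
    values = dict(defaults)
    if params:
        unknown = set(params) - set(defaults)
        if unknown:
            raise ValueError(f"unknown parameter symbol(s): {sorted(unknown)}")
        values.update(params)
    index = {lab: i for i, lab in enumerate(labels)}
    edges = []
    for e in sc.get("edge", []):
        for key in ("from", "to"):
            if e[key] not in index:
                raise ValueError(f"edge references unknown state {e[key]!r}")
        fn = _compile_rate(str(e["rate"]), set(defaults))
        edges.append((index[e["from"]], index[e["to"]], fn, bool(e.get("conc", False))))

    def gen(c: float, _edges=edges, _vals=values, _S=len(labels)) -> np.ndarray:
        if not np.isfinite(c) or c < 0:
            raise ValueError(f"concentration must be finite and >= 0, got {c!r}")
        env = {k: np.asarray(v, dtype=float) for k, v in _vals.items()}
        batch = np.broadcast_shapes(*(v.shape for v in env.values())) if env else ()
        shape = batch + (_S, _S)
        Q = np.zeros(shape)
        for i, j, fn, conc in _edges:
            r = np.asarray(fn(env), dtype=float)
            if conc:
                r = r * c
            Q[..., i, j] += np.broadcast_to(r, batch) if batch else float(r)
        idx = np.arange(_S)
        Q[..., idx, idx] = 0.0
        Q[..., idx, idx] = -Q.sum(axis=-1)
        return Q

    def rebuild(d: dict) -> KineticScheme:
        return scheme_from_config(cfg, params=d)

    return KineticScheme(
        state_labels=labels,
        conductance_class=classes,
        generator=gen,
        params=values,
        _rebuild=rebuild,
    )


# --------------------------------------------------------------------------
# conductance and stationary analysis
# --------------------------------------------------------------------------

def conductance_vector(scheme: KineticScheme, obs) -> np.ndarray:
    """Per-state unitary current (pA) from the rotational conductance ladder.

    ``g(3) = gamma``, ``g(2) = gamma*R_gamma``, ``g(1) = gamma*R_gamma**2``,
    ``g(0) = gamma*rho_leak``: a one-parameter geometric interpolation
    between the fully rotated conductance and a separate closed-channel
    leak.  Parameter fields of ``obs`` may be arrays (batched).
    """
    cls = np.asarray(scheme.conductance_class)
    if cls.min() < 0 or cls.max() > 3:
        raise ValueError("conductance classes must lie in {0,1,2,3}")
    gamma = np.asarray(obs.gamma, dtype=float)
    rg = np.asarray(obs.R_gamma, dtype=float)
    leak = np.asarray(obs.rho_leak, dtype=float)
    batch = np.broadcast_shapes(gamma.shape, rg.shape, leak.shape)
    g = np.empty(batch + cls.shape)
    for n in range(4):
        mask = cls == n
        val = gamma * leak if n == 0 else gamma * rg ** (3 - n)
        g[..., mask] = np.broadcast_to(val, batch)[..., None] if batch else val
    return g


def stationary_distribution(Q: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Stationary probability vector of a generator with a unique closed class.

    Solves ``pi Q = 0`` with ``sum(pi) = 1``.  Transient states (e.g. bound
    states at zero agonist, an absorbing limit) carry zero mass.  If the
    rate graph has more than one closed communicating class the stationary
    law is not unique and a ``ValueError`` identifies the blocks.
    """
    Q = np.asarray(Q, dtype=float)
    S = Q.shape[0]
    adj = (Q > tol).astype(int)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    closed = []
    for k in range(n_comp):
        members = np.nonzero(labels == k)[0]
        outside = np.setdiff1d(np.arange(S), members)
        if len(outside) == 0 or Q[np.ix_(members, outside)].max(initial=0.0) <= tol:
            closed.append(members)
    if len(closed) != 1:
        blocks = [list(map(int, c)) for c in closed]
        raise ValueError(
            f"generator is reducible with {len(closed)} closed classes: {blocks}"
        )
    members = closed[0]
    Qc = Q[np.ix_(members, members)]
    # re-close the diagonal within the class (outgoing rates are ~0 anyway)
    Qc = Qc.copy()
    np.fill_diagonal(Qc, 0.0)
    np.fill_diagonal(Qc, -Qc.sum(axis=1))
    A = np.vstack([Qc.T, np.ones(len(members))])
    b = np.zeros(len(members) + 1)
    b[-1] = 1.0
    pic, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.zeros(S)
    pi[members] = np.clip(pic, 0.0, None)
    return pi / pi.sum()
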