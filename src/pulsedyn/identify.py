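"""Sparse identification of the stress->smoking system by l1 relaxation.

The system is a Wiener-type cascade: a linear time-invariant system driven by
minute-level stress probabilities, followed by a sign nonlinearity that emits
a smoking minute whenever the latent response reaches the threshold (1 by
convention).  The impulse response is a sparse combination of pole atoms
``alpha_p p^k``; each chunk additionally carries free natural-response
coefficients absorbing its unknown initial conditions.  Identification
minimizes ``sum_p t_p`` subject to, for every chunk ``l`` and minute ``k``::

    y_l(k) = ((sum_p C_p alpha_p p^.) * u_l)(k) + sum_p C_p^{N,l} alpha_p p^k
    y_l(k) >= 1 + eps   where s_l(k) = 1
    y_l(k) <= 1 - eps   where s_l(k) = 0
    |C_p| <= t_p,  |C_p^{N,l}| <= t_p  (shared bound across chunks)
    C_p = conj(C_{p*}),  C_p^{N,l} = conj(C_{p*}^{N,l})

The shared bound couples sparsity across chunks: a pole is either active for
the participant (its input and every natural coefficient may use it) or it is
off everywhere.

Conjugate pairs are re-parameterized by real (a, b) so the program is real;
the modulus bounds ``sqrt(a^2 + b^2) <= t`` are the only non-polyhedral
constraints and are handled by a cutting-plane outer approximation (an
initial regular polygon of supporting half-planes, refined with a facet at
``arg(C)`` whenever a solved coefficient escapes its bound) so the whole
program is solved as a sequence of linear programs (HiGHS).  The refinement
terminates at the second-order-cone optimum up to solver tolerance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .atoms import AtomDictionary, PoleGrid, convolve
from .errors import (
    InfeasibleModelError,
    InternalConsistencyError,
    ParameterError,
)
from .preprocess import ChunkedDataset

__all__ = [
    "IdentifiedModel",
    "ResponseDecomposition",
    "identify_model",
    "predict",
    "impulse_response",
]

_IMAG_TOL = 1e-9
_SUPPORT_RTOL = 1e-6


def _solve_lp(c, A_ub, b_ub, bounds, options):
    """Solve an LP with HiGHS, falling back across methods on numerical trouble.

    The l1 programs here are heavily degenerate, so individual HiGHS methods
    occasionally stall or report numerical difficulties on particular
    instances; the optimal *value* is unique regardless of which optimal
    vertex a method returns.  Try the default simplex first, then interior
    point, then dual simplex without presolve.
    """
    options = dict(options)
    options.setdefault("time_limit", 20.0)
    attempts = [
        ("highs", options),
        (
            "highs-ipm",
            {
                "presolve": options.get("presolve", True),
                "time_limit": options["time_limit"],
            },
        ),
        ("highs-ds", {**options, "presolve": False}),
    ]
    res = None
    for method, opts in attempts:
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method=method, options=opts)
        if res.status in (0, 2):
            return res
    return res


@dataclass(frozen=True)
class ResponseDecomposition:
    """Causal, intrinsic and total responses of the identified system on one input."""

    chunk_id: int | None
    y_cause: np.ndarray
    y_intrinsic: np.ndarray
    y_system: np.ndarray
    smoking_pred: np.ndarray


@dataclass
class IdentifiedModel:
    """Result of the l1-relaxed identification program for one participant.

    ``input_coeffs`` and each entry of ``natural_coeffs`` are complex arrays
    aligned with ``grid.poles`` and conjugate-symmetric; ``bounds`` holds the
    per-pole shared bound ``t_p`` and ``objective`` its grid-wide sum.
    """

    grid: PoleGrid
    dictionary: AtomDictionary
    input_coeffs: np.ndarray
    natural_coeffs: dict[int, np.ndarray]
    epsilon: float
    threshold: float
    bounds: np.ndarray
    objective: float
    support: tuple[int, ...]
    solver_status: str
    solver_info: dict = field(default_factory=dict)
    training_data: ChunkedDataset | None = None

    @classmethod
    def zero(
        cls,
        grid: PoleGrid,
        N_l: float,
        epsilon: float = 1e-5,
        threshold: float = 1.0,
    ) -> "IdentifiedModel":
        """The all-zero model (empty support); predicts no smoking anywhere."""
        n = len(grid)
        return cls(
            grid=grid,
            dictionary=AtomDictionary(grid, N_l),
            input_coeffs=np.zeros(n, dtype=complex),
            natural_coeffs={},
            epsilon=epsilon,
            threshold=threshold,
            bounds=np.zeros(n),
            objective=0.0,
            support=(),
            solver_status="optimal",
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "grid": json.loads(self.grid.to_json()),
                "N_l": self.dictionary.N_l,
                "epsilon": self.epsilon,
                "threshold": self.threshold,
                "input_coeffs": [[c.real, c.imag] for c in self.input_coeffs],
                "natural_coeffs": {
                    str(cid): [[c.real, c.imag] for c in arr]
                    for cid, arr in self.natural_coeffs.items()
                },
                "bounds": list(map(float, self.bounds)),
                "objective": self.objective,
                "support": list(self.support),
                "solver_status": self.solver_status,
                "solver_info": self.solver_info,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "IdentifiedModel":
        obj = json.loads(text)
        grid = PoleGrid.from_json(json.dumps(obj["grid"]))
        return cls(
            grid=grid,
            dictionary=AtomDictionary(grid, obj["N_l"]),
            input_coeffs=np.array([complex(re, im) for re, im in obj["input_coeffs"]]),
            natural_coeffs={
                int(cid): np.array([complex(re, im) for re, im in arr])
                for cid, arr in obj["natural_coeffs"].items()
            },
            epsilon=obj["epsilon"],
            threshold=obj["threshold"],
            bounds=np.array(obj["bounds"]),
            objective=obj["objective"],
            support=tuple(obj["support"]),
            solver_status=obj["solver_status"],
            solver_info=obj.get("solver_info", {}),
        )


# ---------------------------------------------------------------------------
# Real re-parameterization of the conjugate-symmetric coefficient space


class _CoefficientSpace:
    """Real coordinates for conjugate-symmetric per-pole coefficients.

    A real pole contributes one real coordinate ``c``; a conjugate pair
    ``(p, p*)`` contributes two, ``(a, b)`` with ``C_p = a + ib``, and the
    pairwise real trajectory ``2 alpha (a Re p^k - b Im p^k)``.
    """

    def __init__(self, dictionary: AtomDictionary):
        self.dictionary = dictionary
        self.grid = dictionary.grid
        self.real_idx, self.pairs = self.grid.partition()
        self.nR = len(self.real_idx)
        self.nP = len(self.pairs)
        self.width = self.nR + 2 * self.nP  # real coordinates per slot
        self.n_groups = self.nR + self.nP
        # objective weight of each group's bound: every grid pole counts once
        self.group_weights = np.concatenate(
            [np.ones(self.nR), 2.0 * np.ones(self.nP)]
        )

    def trajectories(self, length: int) -> np.ndarray:
        """Real basis trajectories, shape (length, width)."""
        k = np.arange(length)
        cols = np.empty((length, self.width))
        a = self.dictionary.alpha
        poles = self.grid.poles
        for j, i in enumerate(self.real_idx):
            cols[:, j] = a[i] * np.power(poles[i].real, k)
        for q, (iu, _) in enumerate(self.pairs):
            pk = np.power(poles[iu], k)
            cols[:, self.nR + 2 * q] = 2.0 * a[iu] * pk.real
            cols[:, self.nR + 2 * q + 1] = -2.0 * a[iu] * pk.imag
        return cols

    def convolved(self, u: np.ndarray) -> np.ndarray:
        """Basis trajectories convolved with input u, shape (len(u), width)."""
        traj = self.trajectories(len(u))
        out = np.empty_like(traj)
        for j in range(self.width):
            out[:, j] = convolve(traj[:, j], u).real
        return out

    def to_complex(self, x: np.ndarray) -> np.ndarray:
        """Map one slot's real coordinates to per-pole complex coefficients."""
        c = np.zeros(len(self.grid), dtype=complex)
        for j, i in enumerate(self.real_idx):
            c[i] = x[j]
        for q, (iu, idn) in enumerate(self.pairs):
            val = complex(x[self.nR + 2 * q], x[self.nR + 2 * q + 1])
            c[iu] = val
            c[idn] = np.conj(val)
        return c


# ---------------------------------------------------------------------------
# The identification LP with cutting-plane modulus bounds


def identify_model(
    data: ChunkedDataset,
    grid: PoleGrid,
    epsilon: float = 1e-5,
    threshold: float = 1.0,
    solver_opts: dict | None = None,
) -> IdentifiedModel:
    """Solve the l1-relaxed sparse identification program over all chunks.

    Parameters
    ----------
    data
        Gap-free chunked dataset of one participant.
    grid
        Conjugate-closed candidate pole grid.
    epsilon
        Separation margin between the latent response and the threshold;
        keeps the feasible set well posed.
    threshold
        The sign-nonlinearity threshold (1 by convention; rescaling it
        rescales the solution inversely).
    solver_opts
        Optional dict with ``init_facets`` (polygon size, default 16),
        ``max_refine`` (cutting-plane rounds, default 50) and
        ``feasibility_tol``.
    """
    if data.N_ch < 1:
        raise ParameterError("dataset must contain at least one chunk")
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    opts = dict(solver_opts or {})
    m0 = int(opts.pop("init_facets", 16))
    max_refine = int(opts.pop("max_refine", 50))
    feas_tol = float(opts.pop("feasibility_tol", min(1e-9, epsilon * threshold / 100.0)))

    space = _CoefficientSpace(AtomDictionary(grid, data.N_l))
    chunks = list(data.chunks)
    L = len(chunks)
    W = space.width
    n_coef = W * (1 + L)  # input slot + one natural slot per chunk
    n_var = n_coef + space.n_groups
    t_off = n_coef

    def slot_off(slot: int) -> int:
        # slot 0 = input coefficients, slot 1..L = natural coefficients of chunk slot-1
        return W * slot

    # -- output constraints (fixed across refinement rounds)
    out_rows, out_rhs = [], []
    for li, ch in enumerate(chunks):
        conv_basis = space.convolved(ch.u)
        nat_basis = space.trajectories(ch.length)
        block = sp.lil_matrix((ch.length, n_var))
        block[:, slot_off(0) : slot_off(0) + W] = conv_basis
        block[:, slot_off(1 + li) : slot_off(1 + li) + W] = nat_basis
        block = block.tocsr()
        sgn = np.where(ch.s == 1, -1.0, 1.0)
        out_rows.append(sp.diags(sgn) @ block)
        out_rhs.append(
            np.where(
                ch.s == 1,
                -threshold * (1.0 + epsilon),
                threshold * (1.0 - epsilon),
            )
        )
    A_out = sp.vstack(out_rows, format="csr")
    b_out = np.concatenate(out_rhs)

    # -- modulus bounds; facet angles per (pair, slot), refined iteratively
    base_angles = 2.0 * np.pi * np.arange(m0) / m0
    facets: dict[tuple[int, int], list[float]] = {
        (q, slot): list(base_angles) for q in range(space.nP) for slot in range(1 + L)
    }

    def build_bound_rows():
        rows_i, cols_i, vals = [], [], []
        rhs_len = 0
        for slot in range(1 + L):
            off = slot_off(slot)
            for j in range(space.nR):
                tg = t_off + j
                for sign in (1.0, -1.0):
                    rows_i += [rhs_len, rhs_len]
                    cols_i += [off + j, tg]
                    vals += [sign, -1.0]
                    rhs_len += 1
            for q in range(space.nP):
                tg = t_off + space.nR + q
                ai = off + space.nR + 2 * q
                for phi in facets[(q, slot)]:
                    rows_i += [rhs_len, rhs_len, rhs_len]
                    cols_i += [ai, ai + 1, tg]
                    vals += [np.cos(phi), np.sin(phi), -1.0]
                    rhs_len += 1
        A = sp.coo_matrix((vals, (rows_i, cols_i)), shape=(rhs_len, n_var)).tocsr()
        return A, np.zeros(rhs_len)

    c_obj = np.zeros(n_var)
    c_obj[t_off:] = space.group_weights
    bounds = [(None, None)] * n_coef + [(0.0, None)] * space.n_groups
    lp_options = {
        "presolve": True,
        "primal_feasibility_tolerance": max(feas_tol, 1e-10),
        "dual_feasibility_tolerance": max(feas_tol, 1e-10),
    }
    lp_options.update(opts)

    res = None
    n_rounds = 0
    for n_rounds in range(1, max_refine + 1):
        A_bnd, b_bnd = build_bound_rows()
        res = _solve_lp(
            c_obj,
            sp.vstack([A_out, A_bnd], format="csr"),
            np.concatenate([b_out, b_bnd]),
            bounds,
            lp_options,
        )
        if res.status == 2:
            raise InfeasibleModelError(
                "identification program infeasible on this pole grid; "
                "try a denser grid or a larger r_max"
            )
        if res.status != 0:
            break
        # cut: add a supporting half-plane wherever a modulus escapes its bound
        x = res.x
        new_cut = False
        for (q, slot), angles in facets.items():
            off = slot_off(slot) + space.nR + 2 * q
            a, b = x[off], x[off + 1]
            t = x[t_off + space.nR + q]
            mod = float(np.hypot(a, b))
            if mod > t * (1.0 + 1e-9) + 1e-12:
                angles.append(float(np.arctan2(b, a)))
                new_cut = True
        if not new_cut:
            break

    if res is None or res.x is None:
        raise InfeasibleModelError(f"solver failed: {getattr(res, 'message', 'no result')}")
    status = "optimal" if res.status == 0 else "inaccurate"
    if status == "inaccurate":
        warnings.warn(
            f"identification solver did not reach optimality: {res.message}",
            stacklevel=2,
        )

    x = res.x
    input_coeffs = space.to_complex(x[slot_off(0) : slot_off(0) + W])
    natural = {
        ch.chunk_id: space.to_complex(x[slot_off(1 + li) : slot_off(1 + li) + W])
        for li, ch in enumerate(chunks)
    }
    t_groups = x[t_off:]
    per_pole_t = np.zeros(len(grid))
    for j, i in enumerate(space.real_idx):
        per_pole_t[i] = t_groups[j]
    for q, (iu, idn) in enumerate(space.pairs):
        per_pole_t[iu] = per_pole_t[idn] = t_groups[space.nR + q]
    objective = float(c_obj @ x)
    tol = _SUPPORT_RTOL * max(1.0, objective)
    support = tuple(int(i) for i in np.flatnonzero(per_pole_t > tol))

    return IdentifiedModel(
        grid=grid,
        dictionary=space.dictionary,
        input_coeffs=input_coeffs,
        natural_coeffs=natural,
        epsilon=epsilon,
        threshold=threshold,
        bounds=per_pole_t,
        objective=objective,
        support=support,
        solver_status=status,
        solver_info={
            "solver": "scipy.optimize.linprog/highs",
            "cutting_plane_rounds": n_rounds,
            "init_facets": m0,
            "feasibility_tolerance": lp_options["primal_feasibility_tolerance"],
            "message": str(res.message),
        },
        training_data=data,
    )


# ---------------------------------------------------------------------------
# Response assembly and prediction


def _real_cast(values: np.ndarray, what: str) -> np.ndarray:
    imag = float(np.max(np.abs(values.imag))) if values.size else 0.0
    if imag > _IMAG_TOL:
        raise InternalConsistencyError(
            f"{what} has imaginary magnitude {imag:.2e} > {_IMAG_TOL}; "
            "conjugate symmetry is broken"
        )
    return values.real.copy()


def impulse_response(model: IdentifiedModel, length: int) -> np.ndarray:
    """Assemble the real input impulse response ``h(k) = sum_p C_p alpha_p p^k``."""
    if length < 1:
        raise ParameterError("length must be >= 1")
    k = np.arange(length)
    h = np.zeros(length, dtype=complex)
    for c, a, p in zip(model.input_coeffs, model.dictionary.alpha, model.grid.poles):
        if c != 0:
            h += c * a * np.power(p, k)
    return _real_cast(h, "assembled impulse response")


def _natural_response(model: IdentifiedModel, coeffs: np.ndarray, length: int) -> np.ndarray:
    k = np.arange(length)
    y = np.zeros(length, dtype=complex)
    for c, a, p in zip(coeffs, model.dictionary.alpha, model.grid.poles):
        if c != 0:
            y += c * a * np.power(p, k)
    return _real_cast(y, "natural response")


def predict(
    model: IdentifiedModel,
    chunk_id: int | None = None,
    u: np.ndarray | None = None,
    natural_coeffs: np.ndarray | None = None,
) -> ResponseDecomposition:
    """Compute the response decomposition and thresholded smoking prediction.

    Either pass a ``chunk_id`` present in the model's training data, or an
    explicit input ``u`` (with optional per-pole natural coefficients for
    that stretch).  A minute smokes exactly when ``y_system`` reaches the
    threshold.
    """
    if chunk_id is not None:
        if model.training_data is None:
            raise KeyError("model carries no training data; pass u explicitly")
        chunk = model.training_data.chunk(chunk_id)  # KeyError if unknown
        u = chunk.u
        natural_coeffs = model.natural_coeffs.get(
            chunk_id, np.zeros(len(model.grid), dtype=complex)
        )
    if u is None:
        raise ParameterError("either chunk_id or u must be supplied")
    u = np.asarray(u, dtype=float)
    n = u.size
    h = impulse_response(model, n)
    y_cause = convolve(h, u).real
    if natural_coeffs is None:
        natural_coeffs = np.zeros(len(model.grid), dtype=complex)
    y_intr = _natural_response(model, np.asarray(natural_coeffs, dtype=complex), n)
    y_system = y_cause + y_intr
    pred = (y_system >= model.threshold).astype(np.int8)
    return ResponseDecomposition(
        chunk_id=chunk_id,
        y_cause=y_cause,
        y_intrinsic=y_intr,
        y_system=y_system,
        smoking_pred=pred,
    )
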