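"""Hold-out validation: freeze poles and input coefficients, refit natural terms.

Chunks are split whole into modeling and validation sides at a 2:1 minute
ratio.  After identifying a model on the modeling side, its poles and input
coefficients are frozen; on each validation chunk only the natural-response
coefficients (restricted to the identified support) are refit by minimizing
the total absolute slack ``sum_k |delta(k)|`` needed to satisfy the
threshold constraints.  A small total slack means the frozen dynamics carry
over to unseen chunks; the validity threshold is a user choice that scales
with the number of validation minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import CannotSplitError, ParameterError
from .identify import IdentifiedModel, _CoefficientSpace, _solve_lp, impulse_response
from .atoms import convolve
from .preprocess import Chunk, ChunkedDataset

__all__ = ["ValidationReport", "split_chunks", "validate_model", "label_agreement"]


@dataclass(frozen=True)
class ValidationReport:
    """Slack profile of a frozen model on validation chunks."""

    delta: dict[tuple[int, int], float]  # (chunk_id, minute offset) -> slack
    total_l1: float
    threshold: float
    valid: bool
    refit_natural_coeffs: dict[int, np.ndarray]
    n_minutes: int
    solver_status: str

    @property
    def slack_per_minute(self) -> float:
        return self.total_l1 / self.n_minutes if self.n_minutes else 0.0


def split_chunks(
    data: ChunkedDataset, ratio: float = 2.0 / 3.0, seed: int = 0
) -> tuple[ChunkedDataset, ChunkedDataset]:
    """Assign whole chunks to modeling/validation sides near a minute ratio.

    Chunks are shuffled with the given seed and assigned greedily: a chunk
    goes to the modeling side whenever that moves its minute total closer to
    ``ratio`` of all minutes.  Both sides are guaranteed nonempty.
    """
    if data.N_ch < 2:
        raise CannotSplitError("need at least 2 chunks to split")
    if not (0.0 < ratio < 1.0):
        raise ParameterError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(data.N_ch)
    target = ratio * data.total_minutes
    modeling: list[Chunk] = []
    validation: list[Chunk] = []
    mod_minutes = 0
    for idx in order:
        ch = data.chunks[idx]
        if abs(mod_minutes + ch.length - target) <= abs(mod_minutes - target):
            modeling.append(ch)
            mod_minutes += ch.length
        else:
            validation.append(ch)
    if not validation:
        validation.append(modeling.pop())
    if not modeling:
        modeling.append(validation.pop())
    key = lambda c: c.chunk_id
    return (
        ChunkedDataset(data.participant_id, tuple(sorted(modeling, key=key))),
        ChunkedDataset(data.participant_id, tuple(sorted(validation, key=key))),
    )


def validate_model(
    model: IdentifiedModel,
    validation: ChunkedDataset,
    threshold: float,
    epsilon: float | None = None,
    refit_poles: set[int] | None = None,
) -> ValidationReport:
    """Refit natural coefficients on validation chunks, minimizing total slack.

    Solves ``min sum_k |delta(k)|`` over per-chunk natural coefficients on
    the model's support poles, subject to ``y(k) + delta(k)`` satisfying the
    margin constraints, where ``y`` combines the frozen input response with
    the refit natural terms.  The program is always feasible (slack is
    unconstrained).  ``threshold`` is the validity bound on the total slack.
    ``refit_poles`` overrides the pole set allowed for the refit (default:
    the model's identified support).
    """
    if validation.N_ch < 1:
        raise ParameterError("validation dataset must be nonempty")
    eps = model.epsilon if epsilon is None else float(epsilon)
    tau = model.threshold

    space = _CoefficientSpace(model.dictionary)
    support = set(model.support) if refit_poles is None else set(refit_poles)
    # real coordinates allowed for the refit: those of groups meeting the support
    allowed = [j for j, i in enumerate(space.real_idx) if i in support]
    for q, (iu, idn) in enumerate(space.pairs):
        if iu in support or idn in support:
            allowed.extend([space.nR + 2 * q, space.nR + 2 * q + 1])
    n_nat = len(allowed)

    chunks = list(validation.chunks)
    L = len(chunks)
    N = sum(c.length for c in chunks)
    # variables: [natural coords (n_nat per chunk), delta+, delta-]
    n_var = n_nat * L + 2 * N

    rows, rhs = [], []
    row0 = 0
    for li, ch in enumerate(chunks):
        y_frozen = convolve(impulse_response(model, ch.length), ch.u).real
        nat_basis = space.trajectories(ch.length)[:, allowed] if n_nat else None
        block = sp.lil_matrix((ch.length, n_var))
        if n_nat:
            block[:, li * n_nat : (li + 1) * n_nat] = nat_basis
        dp0 = n_nat * L + row0
        dm0 = n_nat * L + N + row0
        for k in range(ch.length):
            block[k, dp0 + k] = 1.0
            block[k, dm0 + k] = -1.0
        block = block.tocsr()
        sgn = np.where(ch.s == 1, -1.0, 1.0)
        margin = np.where(ch.s == 1, tau * (1.0 + eps), tau * (1.0 - eps))
        # s=1: -(nat + d) <= y_frozen - tau(1+eps);  s=0: nat + d <= tau(1-eps) - y_frozen
        rows.append(sp.diags(sgn) @ block)
        rhs.append(sgn * (margin - y_frozen))
        row0 += ch.length
    A_ub = sp.vstack(rows, format="csr")
    b_ub = np.concatenate(rhs)

    c_obj = np.zeros(n_var)
    c_obj[n_nat * L :] = 1.0
    bounds = [(None, None)] * (n_nat * L) + [(0.0, None)] * (2 * N)
    res = _solve_lp(
        c_obj,
        A_ub,
        b_ub,
        bounds,
        {
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-10,
        },
    )
    status = "optimal" if res.status == 0 else "inaccurate"

    x = res.x
    refit: dict[int, np.ndarray] = {}
    delta: dict[tuple[int, int], float] = {}
    row0 = 0
    for li, ch in enumerate(chunks):
        coords = np.zeros(space.width)
        if n_nat:
            coords[allowed] = x[li * n_nat : (li + 1) * n_nat]
        refit[ch.chunk_id] = space.to_complex(coords)
        dplus = x[n_nat * L + row0 : n_nat * L + row0 + ch.length]
        dminus = x[n_nat * L + N + row0 : n_nat * L + N + row0 + ch.length]
        for k in range(ch.length):
            delta[(ch.chunk_id, k)] = float(dplus[k] - dminus[k])
        row0 += ch.length
    total = float(res.fun)
    return ValidationReport(
        delta=delta,
        total_l1=total,
        threshold=float(threshold),
        valid=bool(total <= threshold),
        refit_natural_coeffs=refit,
        n_minutes=N,
        solver_status=status,
    )


def label_agreement(
    model: IdentifiedModel,
    data: ChunkedDataset,
    natural_coeffs: dict[int, np.ndarray] | None = None,
) -> float:
    """Fraction of minutes whose thresholded prediction matches observed smoking.

    ``natural_coeffs`` maps chunk_id to per-pole natural coefficients (e.g.
    the model's own training coefficients, or a validation refit); missing
    chunks use zero natural response.
    """
    from .identify import predict

    coeffs = natural_coeffs if natural_coeffs is not None else model.natural_coeffs
    hits = 0
    total = 0
    for ch in data.chunks:
        nat = coeffs.get(ch.chunk_id)
        dec = predict(model, u=ch.u, natural_coeffs=nat)
        hits += int(np.sum(dec.smoking_pred == ch.s))
        total += ch.length
    return hits / total if total else float("nan")
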