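"""Pole grids, atomic dictionaries and convolution machinery.

The impulse response of a discrete-time linear time-invariant system is
represented as a sparse combination of *atoms*: scaled pole trajectories
``alpha_p * p**k`` with the pole ``p`` strictly inside the unit disc.  Complex
poles come in conjugate pairs so that assembled responses are real.  The
per-pole scaling factor

    alpha_p = (1 - |p|**2) / (1 - |p|**(N_l + 2))

normalizes atoms by the average chunk length ``N_l`` so that slow (large
``|p|``) and fast (small ``|p|``) modes compete on an even footing in the
sparsity-inducing objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "PoleGrid",
    "AtomDictionary",
    "build_pole_grid",
    "scaling_factor",
    "atom_trajectory",
    "convolve",
]

_DEDUP_DECIMALS = 12


@dataclass(frozen=True)
class PoleGrid:
    """A conjugate-closed set of candidate poles inside the unit disc.

    Parameters
    ----------
    poles
        Complex array of candidate poles, each with ``|p| < 1``.  The set is
        closed under complex conjugation and contains no duplicates.
    seed
        Seed used for random subsampling, if any (recorded for provenance).
    params
        Construction parameters (grid counts, ``r_max``), for provenance.
    """

    poles: np.ndarray
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        poles = np.asarray(self.poles, dtype=complex)
        object.__setattr__(self, "poles", poles)
        if poles.size and np.max(np.abs(poles)) >= 1.0:
            raise ParameterError("all poles must satisfy |p| < 1")
        keys = set(map(_pole_key, poles))
        if len(keys) != poles.size:
            raise ParameterError("pole grid contains duplicates")
        for p in poles:
            if _pole_key(np.conj(p)) not in keys:
                raise ParameterError(f"grid not closed under conjugation: {p}")

    def __len__(self) -> int:
        return self.poles.size

    @property
    def conjugate_pairing(self) -> dict[int, int]:
        """Map each non-real pole's index to the index of its conjugate."""
        index = {_pole_key(p): i for i, p in enumerate(self.poles)}
        return {
            i: index[_pole_key(np.conj(p))]
            for i, p in enumerate(self.poles)
            if abs(p.imag) > 0.0
        }

    def partition(self) -> tuple[list[int], list[tuple[int, int]]]:
        """Split indices into real poles and (upper, lower) conjugate pairs.

        Each non-real pole appears in exactly one pair with its upper-half
        representative first; real poles are listed by index.
        """
        real = [i for i, p in enumerate(self.poles) if abs(p.imag) == 0.0]
        pairing = self.conjugate_pairing
        pairs = [
            (i, pairing[i])
            for i, p in enumerate(self.poles)
            if p.imag > 0.0
        ]
        return real, pairs

    def to_json(self) -> str:
        return json.dumps(
            {
                "poles": [[p.real, p.imag] for p in self.poles],
                "seed": self.seed,
                "params": self.params,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PoleGrid":
        obj = json.loads(text)
        poles = np.array([complex(re, im) for re, im in obj["poles"]])
        return cls(poles=poles, seed=obj.get("seed"), params=obj.get("params", {}))


def _pole_key(p: complex) -> tuple[float, float]:
    return (round(float(np.real(p)), _DEDUP_DECIMALS), round(float(np.imag(p)), _DEDUP_DECIMALS))


def build_pole_grid(
    n_radii: int,
    n_angles: int,
    r_max: float = 0.98,
    subsample: int | None = None,
    seed: int | None = None,
) -> PoleGrid:
    """Build a uniform polar grid of candidate poles, closed under conjugation.

    Radii are equally spaced in ``(0, r_max]`` (``r_max * i / n_radii``), plus
    the origin; angles are equally spaced starting at 0 with step
    ``pi / n_angles`` (the upper half-plane; conjugates are added for every
    non-real pole).  With ``subsample`` set, conjugate-closed units (a real
    pole, or a pole together with its conjugate) are drawn uniformly without
    replacement, in seeded order, until at least ``subsample`` poles are
    retained; the origin is always kept.
    """
    if n_radii < 1 or n_angles < 1:
        raise ParameterError("n_radii and n_angles must be >= 1")
    if not (0.0 < r_max < 1.0):
        raise ParameterError("r_max must lie strictly inside (0, 1)")

    radii = r_max * np.arange(1, n_radii + 1) / n_radii
    angles = np.pi * np.arange(n_angles) / n_angles

    seen: dict[tuple[float, float], complex] = {}

    def _add(p: complex) -> None:
        seen.setdefault(_pole_key(p), p)

    _add(0.0 + 0.0j)
    snap = 10 ** (-_DEDUP_DECIMALS)
    for r in radii:
        for th in angles:
            p = r * np.exp(1j * th)
            # snap floating residue of cos/sin at axis angles to exact zero
            p = complex(
                0.0 if abs(p.real) < snap else p.real,
                0.0 if abs(p.imag) < snap else p.imag,
            )
            _add(p)
            _add(np.conj(p))

    poles = np.array(sorted(seen.values(), key=lambda p: (abs(p), np.angle(p))))

    if subsample is not None:
        if subsample < 1:
            raise ParameterError("subsample must be >= 1")
        units: list[list[complex]] = [[0.0 + 0.0j]]
        for p in poles:
            if p == 0:
                continue
            if p.imag > 0:
                units.append([p, np.conj(p)])
            elif p.imag == 0:
                units.append([p])
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(units) - 1) + 1  # origin (unit 0) always kept
        kept: list[complex] = list(units[0])
        for idx in order:
            if len(kept) >= subsample:
                break
            kept.extend(units[idx])
        poles = np.array(sorted(kept, key=lambda p: (abs(p), np.angle(p))))

    return PoleGrid(
        poles=poles,
        seed=seed,
        params={
            "n_radii": n_radii,
            "n_angles": n_angles,
            "r_max": r_max,
            "subsample": subsample,
        },
    )


def scaling_factor(p: complex, N_l: float) -> float:
    """Per-pole atom normalization ``(1 - |p|^2) / (1 - |p|^(N_l + 2))``.

    Depends on ``|p|`` only; equals 1 at the origin and decreases toward 0 as
    ``|p| -> 1`` for ``N_l >= 1``.  ``N_l`` is the mean retained chunk length
    (minutes) and may be non-integer.
    """
    mag = float(np.abs(p))
    if mag >= 1.0:
        raise ParameterError("scaling_factor requires |p| < 1")
    if N_l < 0:
        raise ParameterError("N_l must be nonnegative")
    if mag == 0.0:
        return 1.0
    return (1.0 - mag**2) / (1.0 - mag ** (N_l + 2.0))


@dataclass(frozen=True)
class AtomDictionary:
    """A pole grid together with its scaling factors for a given ``N_l``."""

    grid: PoleGrid
    N_l: float
    alpha: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        alpha = np.array([scaling_factor(p, self.N_l) for p in self.grid.poles])
        object.__setattr__(self, "alpha", alpha)


def atom_trajectory(p: complex, alpha: float, length: int) -> np.ndarray:
    """Evaluate the atom ``alpha * p**k`` for ``k = 0..length-1`` (with 0**0 = 1)."""
    if length < 1:
        raise ParameterError("length must be >= 1")
    return alpha * np.power(complex(p), np.arange(length))


def convolve(h: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Causal convolution ``y(k) = sum_{t=0..k} h(t) u(k-t)`` truncated to ``len(u)``.

    The impulse response is zero-padded or truncated to the input length: a
    chunk starts at rest, and its convolution never reaches beyond the chunk.
    """
    u = np.asarray(u)
    if u.size == 0:
        raise ParameterError("input vector u must be nonempty")
    h = np.asarray(h)[: u.size]
    return np.convolve(h, u)[: u.size]
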