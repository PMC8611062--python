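"""Synthetic minute-level stress/smoking data from known ground-truth models.

The generator emulates the statistical structure of minute-level sensor
markers: a low stress baseline with noise, episodic elevations toward 1
arriving as a Poisson process, and missing-data gaps of mixed duration (some
short enough to interpolate, some not) that fragment the record into chunks.
Smoking is generated by driving a known pole-atom model with the stress
series and thresholding at 1, so identification, prediction and validation
can be tested end to end against a known answer.

Minutes whose latent response falls within ``epsilon_gen`` of the threshold
are degenerate for identification (the feasible set collapses); the
generator rejects such draws and regenerates the noise, so every emitted
dataset is strictly separable with margin ``epsilon_gen``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atoms import AtomDictionary, PoleGrid, build_pole_grid, convolve, scaling_factor
from .errors import GenerationError, ParameterError
from .identify import identify_model
from .preprocess import (
    Chunk,
    ChunkedDataset,
    MinuteSeries,
    interpolate_short_gaps,
    make_chunks,
)
from .validate import label_agreement, split_chunks, validate_model

__all__ = [
    "SyntheticSpec",
    "SyntheticResult",
    "default_recovery_grid",
    "default_spec",
    "generate_stress_input",
    "simulate_ground_truth",
    "to_raw_tables",
    "recovery_experiment",
]


def default_recovery_grid() -> PoleGrid:
    """The default candidate grid for recovery experiments (~90 poles)."""
    return build_pole_grid(n_radii=6, n_angles=8, r_max=0.98)


def _default_true_poles() -> tuple[complex, ...]:
    # on the default recovery grid: radius index 3 (real) and 4 at angle pi/8
    r3 = 0.98 * 3 / 6
    r4 = 0.98 * 4 / 6
    p = r4 * np.exp(1j * (np.pi * 1 / 8))
    return (complex(r3), complex(p), complex(np.conj(p)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth model and input/gap processes for one synthetic participant.

    Defaults emulate a typical participant record: ~12 h of minute samples
    (n_minutes=720), about one stress episode per hour lasting 5-15 min with
    stress near 0.95, a quiet baseline near 0.08, and per-minute gap onsets
    that fragment the record into chunks of a few tens of minutes.
    """

    true_poles: tuple[complex, ...] = field(default_factory=_default_true_poles)
    true_input_coeffs: tuple[complex, ...] = (
        1.3 + 0.0j,
        0.15 - 0.05j,
        0.15 + 0.05j,
    )
    true_natural: str | float = "zero"  # "zero" or a per-chunk coefficient
    episode_rate_per_hour: float = 1.0
    episode_duration_minutes: tuple[int, int] = (5, 15)
    episode_level: float = 0.95
    baseline_level: float = 0.08
    noise_sd: float = 0.03
    short_gap_prob: float = 0.02
    long_gap_prob: float = 0.02
    long_gap_minutes: tuple[int, int] = (3, 15)
    n_minutes: int = 720
    epsilon_gen: float = 1e-4
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        poles = np.array(self.true_poles, dtype=complex)
        if poles.size and np.max(np.abs(poles)) >= 1.0:
            raise ParameterError("true poles must satisfy |p| < 1")
        coeffs = np.array(self.true_input_coeffs, dtype=complex)
        if coeffs.shape != poles.shape:
            raise ParameterError("one input coefficient per true pole required")
        # conjugate symmetry of the true model
        for p, c in zip(poles, coeffs):
            match = [
                c2
                for p2, c2 in zip(poles, coeffs)
                if abs(p2 - np.conj(p)) < 1e-12
            ]
            if not match or abs(match[0] - np.conj(c)) > 1e-12:
                raise ParameterError("true model must be conjugate-symmetric")


@dataclass(frozen=True)
class SyntheticResult:
    """A generated dataset together with its generating truth."""

    series: MinuteSeries
    dataset: ChunkedDataset
    truth: dict


def _generate_stress(spec: SyntheticSpec, attempt: int) -> MinuteSeries:
    if spec.n_minutes < 1:
        raise ParameterError("n_minutes must be positive")
    rng = np.random.default_rng([spec.seed, attempt])
    n = spec.n_minutes

    level = np.full(n, spec.baseline_level)
    p_start = spec.episode_rate_per_hour / 60.0
    lo, hi = spec.episode_duration_minutes
    m = 0
    while m < n:
        if rng.random() < p_start:
            dur = int(rng.integers(lo, hi + 1))
            level[m : m + dur] = spec.episode_level
            m += dur
        else:
            m += 1

    stress = np.clip(level + rng.normal(0.0, spec.noise_sd, size=n), 0.0, 1.0)

    m = 0
    while m < n:
        r = rng.random()
        if r < spec.short_gap_prob:
            dur = int(rng.integers(1, 3))  # 1 or 2 minutes: interpolable
            stress[m : m + dur] = np.nan
            m += dur
        elif r < spec.short_gap_prob + spec.long_gap_prob:
            glo, ghi = spec.long_gap_minutes
            dur = int(rng.integers(glo, ghi + 1))
            stress[m : m + dur] = np.nan
            m += dur
        else:
            m += 1

    return MinuteSeries(
        participant_id=f"synth-{spec.seed}",
        minute_index=np.arange(n, dtype=np.int64),
        stress=stress,
        smoking=np.zeros(n, dtype=np.int8),
    )


def generate_stress_input(spec: SyntheticSpec) -> MinuteSeries:
    """Seeded, reproducible stress input with episodes and missing gaps."""
    return _generate_stress(spec, attempt=0)


def _true_impulse(spec: SyntheticSpec, N_l: float, length: int) -> np.ndarray:
    k = np.arange(length)
    h = np.zeros(length, dtype=complex)
    for p, c in zip(spec.true_poles, spec.true_input_coeffs):
        h += c * scaling_factor(p, N_l) * np.power(p, k)
    return h.real


def _true_natural(spec: SyntheticSpec, N_l: float, length: int) -> np.ndarray:
    if spec.true_natural == "zero":
        return np.zeros(length)
    coeff = float(spec.true_natural)
    # decaying intrinsic term on the slowest real true pole
    reals = [p.real for p in spec.true_poles if abs(p.imag) < 1e-12]
    if not reals:
        raise ParameterError("constant natural rule needs a real true pole")
    p = max(reals, key=abs)
    return coeff * scaling_factor(p, N_l) * np.power(p, np.arange(length))


def simulate_ground_truth(
    spec: SyntheticSpec, stress: MinuteSeries | None = None
) -> SyntheticResult:
    """Generate a chunked dataset whose smoking labels come from the true model.

    The stress series is interpolated and chunked exactly as the
    preprocessing pipeline would do it, the true model's latent response is
    computed per chunk, and smoking is its thresholded output.  Draws whose
    response approaches the threshold closer than ``epsilon_gen`` on any
    minute are rejected and the noise regenerated (bounded retries), so the
    emitted dataset is strictly separable.
    """
    supplied = stress is not None
    attempts = 1 if supplied else spec.max_retries
    last_margin = np.inf
    for attempt in range(attempts):
        series = stress if supplied else _generate_stress(spec, attempt)
        interp = interpolate_short_gaps(series.copy())
        dataset = make_chunks(interp, min_length=5)
        N_l = dataset.N_l

        ok = True
        labeled: list[Chunk] = []
        truth_y: dict[int, np.ndarray] = {}
        margin = np.inf
        for ch in dataset.chunks:
            h = _true_impulse(spec, N_l, ch.length)
            y = convolve(h, ch.u).real + _true_natural(spec, N_l, ch.length)
            margin = min(margin, float(np.min(np.abs(y - 1.0))))
            if margin < spec.epsilon_gen:
                ok = False
                break
            s = (y >= 1.0).astype(np.int8)
            labeled.append(Chunk(ch.chunk_id, ch.start_minute, ch.u, s))
            truth_y[ch.chunk_id] = y
        last_margin = margin
        if not ok:
            continue

        out_series = interp.copy()
        for ch in labeled:
            i0 = int(np.searchsorted(out_series.minute_index, ch.start_minute))
            out_series.smoking[i0 : i0 + ch.length] = ch.s
        out = ChunkedDataset(dataset.participant_id, tuple(labeled))
        truth = {
            "poles": list(spec.true_poles),
            "input_coeffs": list(spec.true_input_coeffs),
            "natural_rule": spec.true_natural,
            "N_l": N_l,
            "y_system": truth_y,
            "attempt": attempt,
        }
        return SyntheticResult(series=out_series, dataset=out, truth=truth)

    raise GenerationError(
        f"could not achieve threshold margin {spec.epsilon_gen:g} after "
        f"{attempts} attempts (closest approach {last_margin:.2e}); "
        "lower epsilon_gen or change the true model / input process"
    )


# ---------------------------------------------------------------------------
# Export in the raw-table dialect consumed by the preprocessing pipeline


def to_raw_tables(
    result: SyntheticResult, t0_epoch: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit stress.csv / puffs.csv tables that round-trip through preprocessing.

    Each smoking run becomes one puff episode with four puffs in every
    smoking minute, which the 5-min/4-puff episode delimiter reproduces
    exactly.
    """
    series = result.series
    stress_rows = []
    for m, v in zip(series.minute_index, series.stress):
        if not np.isnan(v):
            stress_rows.append(
                {
                    "participant_id": series.participant_id,
                    "timestamp_unix_s": t0_epoch + int(m) * 60,
                    "stress_probability": float(v),
                }
            )
    puff_rows = []
    for ch in result.dataset.chunks:
        m = 0
        while m < ch.length:
            if ch.s[m] == 1:
                j = m
                while j < ch.length and ch.s[j] == 1:
                    j += 1
                start_minute = ch.start_minute + m
                for mm in range(start_minute, ch.start_minute + j):
                    for sec in (0, 10, 20, 25):
                        puff_rows.append(
                            {
                                "participant_id": series.participant_id,
                                "episode_start_unix_s": t0_epoch + start_minute * 60,
                                "puff_unix_s": t0_epoch + mm * 60 + sec,
                            }
                        )
                m = j
            else:
                m += 1
    return pd.DataFrame(stress_rows), pd.DataFrame(puff_rows)


# ---------------------------------------------------------------------------
# Recovery experiments


def true_pulse(
    spec: SyntheticSpec, N_l: float, pulse_minutes: int = 10, horizon: int = 30
) -> np.ndarray:
    """Pulse response of the ground-truth model (for comparison with fits)."""
    u = np.zeros(horizon)
    u[:pulse_minutes] = 1.0
    return convolve(_true_impulse(spec, N_l, horizon), u).real


def recovery_experiment(
    spec: SyntheticSpec,
    grid: PoleGrid | None = None,
    n_seeds: int = 10,
    epsilon: float = 1e-5,
    split_ratio: float = 2.0 / 3.0,
) -> dict:
    """Generate, split 2:1, identify, and score recovery over several seeds.

    For each seed: training minute-agreement of the identified model,
    held-out total slack after the natural-coefficient refit, held-out
    minute-agreement using the refit coefficients, and the normalized inner
    product between the true and identified 10-minute pulse responses.
    Seeds run from ``spec.seed`` to ``spec.seed + n_seeds - 1``.
    """
    if n_seeds < 1:
        raise ParameterError("n_seeds must be >= 1")
    if grid is None:
        grid = default_recovery_grid()
    per_seed = []
    for s in range(spec.seed, spec.seed + n_seeds):
        sp = replace(spec, seed=s)
        result = simulate_ground_truth(sp)
        modeling, validation = split_chunks(result.dataset, ratio=split_ratio, seed=s)
        model = identify_model(modeling, grid, epsilon=epsilon)
        train_agree = label_agreement(model, modeling)
        report = validate_model(model, validation, threshold=float("inf"), epsilon=epsilon)
        heldout_agree = label_agreement(model, validation, report.refit_natural_coeffs)
        y_true = true_pulse(sp, result.dataset.N_l)
        from .simulate import pulse_response

        y_fit = pulse_response(model).y_cause
        denom = float(np.linalg.norm(y_true) * np.linalg.norm(y_fit))
        cosine = float(y_true @ y_fit / denom) if denom > 0 else float("nan")
        per_seed.append(
            {
                "seed": s,
                "n_chunks": result.dataset.N_ch,
                "total_minutes": result.dataset.total_minutes,
                "solver_status": model.solver_status,
                "training_agreement": train_agree,
                "heldout_total_l1": report.total_l1,
                "heldout_agreement": heldout_agree,
                "pulse_cosine": cosine,
            }
        )
    med = lambda key: float(np.median([r[key] for r in per_seed]))
    return {
        "per_seed": per_seed,
        "median_training_agreement": med("training_agreement"),
        "median_heldout_agreement": med("heldout_agreement"),
        "median_heldout_total_l1": med("heldout_total_l1"),
        "median_pulse_cosine": med("pulse_cosine"),
    }
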