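"""Grid search and beam search over docking parameterizations.

Grid search evaluates a predefined Cartesian grid of parameter values
once.  Beam search iterates: at each step it keeps only the top fraction
of candidates, recenters and shrinks every numeric range around the best
value seen (finer resolution in the promising neighborhood), and fans
each retained candidate out into freshly perturbed matching-sphere
variants — by default 10 new sphere sets per candidate in the first step,
rising to 50 in the final step.  At a comparable evaluation budget the
progressive refinement concentrates samples near the optimum, which is
what lets beam search beat a one-shot grid.

Every evaluation is recorded in a history (one row per candidate:
parameterization, step, criterion value, status); candidates are
deduplicated by parameterization id, so the history length is exactly the
evaluation budget spent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from screenopt.dag import Parameterization
from screenopt.spheres import SphereSet, perturb_spheres

__all__ = [
    "SpherePerturbationSpec",
    "SearchSpace",
    "BeamState",
    "EvaluationRecord",
    "grid_search",
    "refine_ranges",
    "beam_search",
    "early_stop",
    "flatten_sequence",
    "run_sequence",
    "MAX_SEQUENCE_DEPTH",
]

MAX_SEQUENCE_DEPTH = 3

FAILED = "failed"


@dataclass(frozen=True)
class SpherePerturbationSpec:
    """Matching-sphere perturbation settings: ball radius and per-step counts."""

    radius: float = 0.4
    counts_per_step: tuple[int, ...] = (10, 25, 50)

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("perturbation radius must be >= 0")
        if len(self.counts_per_step) < 1:
            raise ValueError("counts_per_step must have length >= 1")
        object.__setattr__(self, "counts_per_step", tuple(int(c) for c in self.counts_per_step))

    def count_at(self, step: int) -> int:
        """Perturbed sphere sets per candidate at a given step (last count persists)."""
        return self.counts_per_step[min(step, len(self.counts_per_step) - 1)]


@dataclass(frozen=True)
class NumericRange:
    low: float
    high: float
    n_points: int

    def pool(self) -> np.ndarray:
        if self.n_points == 1:
            return np.array([(self.low + self.high) / 2.0])
        return np.linspace(self.low, self.high, self.n_points)

    @property
    def resolution(self) -> float:
        if self.n_points == 1:
            return self.high - self.low
        return (self.high - self.low) / (self.n_points - 1)


@dataclass(frozen=True)
class SearchSpace:
    """Numeric ranges, categorical pools and the sphere-perturbation spec."""

    numeric: dict[str, NumericRange] = field(default_factory=dict)
    categorical: dict[str, tuple] = field(default_factory=dict)
    base_spheres: SphereSet | None = None
    perturbation: SpherePerturbationSpec | None = None

    def __post_init__(self) -> None:
        for name, pool in self.categorical.items():
            if len(pool) == 0:
                raise ValueError(f"categorical parameter {name!r}: empty pool")
            object.__setattr__(self, "categorical",
                               {k: tuple(v) for k, v in self.categorical.items()})

    def grid(self, sphere_set: SphereSet | None = None) -> list[Parameterization]:
        """Cartesian product of all pools, bound to one sphere set."""
        import itertools

        names = sorted(self.numeric) + sorted(self.categorical)
        pools = [self.numeric[n].pool().tolist() for n in sorted(self.numeric)] + [
            list(self.categorical[n]) for n in sorted(self.categorical)
        ]
        spheres = sphere_set if sphere_set is not None else self.base_spheres
        if not names:
            return [Parameterization(bindings={}, sphere_set=spheres)]
        return [
            Parameterization(bindings=dict(zip(names, combo)), sphere_set=spheres)
            for combo in itertools.product(*pools)
        ]


@dataclass(frozen=True)
class EvaluationRecord:
    parameterization: Parameterization
    step: int
    value: float | None
    status: str  # "ok" | "failed: ..."

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class BeamState:
    """State carried between beam steps: retained candidates and current ranges."""

    step_index: int
    retained: list[tuple[Parameterization, float]]  # sorted descending by value
    ranges: dict[str, NumericRange]
    original: dict[str, NumericRange]


def _rank(records: list[EvaluationRecord]) -> list[tuple[Parameterization, float]]:
    ok = [(r.parameterization, r.value) for r in records if r.ok]
    # descending by criterion; ties broken by parameterization id for determinism
    return sorted(ok, key=lambda t: (-t[1], t[0].id))


def _evaluate_batch(candidates, evaluate, step, history, seen, executor=None):
    """Evaluate candidates not yet seen (id-level dedup), append to history."""
    fresh = []
    for c in candidates:
        if c.id not in seen:
            seen.add(c.id)
            fresh.append(c)

    def _one(cand):
        try:
            return EvaluationRecord(cand, step, float(evaluate(cand)), "ok")
        except Exception as exc:  # noqa: BLE001 — failures become sentinel records
            return EvaluationRecord(cand, step, None, f"{FAILED}: {exc}")

    if executor is not None:
        records = executor.map(_one, fresh)
    else:
        records = [_one(c) for c in fresh]
    history.extend(records)
    return records


def grid_search(space: SearchSpace, evaluate, executor=None, history=None):
    """Evaluate every Cartesian combination once; return candidates ranked descending.

    ``evaluate(parameterization) -> float`` is the criterion (higher is
    better).  A failing evaluation is recorded with a "failed" sentinel in
    the history and excluded from the ranking.  Pass ``history`` (a list)
    to capture per-candidate records.
    """
    history = history if history is not None else []
    records = _evaluate_batch(space.grid(), evaluate, 0, history, set(), executor)
    return _rank(records)


def refine_ranges(state: BeamState, zoom_factor: float = 2.0) -> dict[str, NumericRange]:
    """Shrink every numeric range around the best retained candidate.

    The new range is centered on the best value with width = previous
    width / zoom_factor, clipped to the original bounds (so the best value
    always stays inside), at the same pool cardinality — i.e. finer
    resolution in the neighborhood of the current optimum.
    """
    if not state.retained:
        raise ValueError("cannot refine ranges with no retained candidates")
    best = state.retained[0][0]
    out = {}
    for name, rng in state.ranges.items():
        center = float(best.bindings[name])
        width = (rng.high - rng.low) / zoom_factor
        orig = state.original[name]
        low = max(orig.low, center - width / 2.0)
        high = min(orig.high, center + width / 2.0)
        if high < low:
            low = high = center
        out[name] = NumericRange(low=low, high=high, n_points=rng.n_points)
    return out


def early_stop(best_per_step: list[float], patience: int = 2, min_delta: float = 0.0) -> bool:
    """True iff the running best improved by < min_delta for `patience` consecutive steps."""
    if patience < 1:
        raise ValueError("patience must be >= 1")
    if not best_per_step:
        raise ValueError("history must be non-empty")
    running = best_per_step[0]
    stalls = 0
    for value in best_per_step[1:]:
        improvement = value - running
        # no strict improvement always counts as a stall, even at min_delta = 0
        if improvement <= 0 or improvement < min_delta:
            stalls += 1
        else:
            stalls = 0
        running = max(running, value)
    return stalls >= patience


def beam_search(
    space: SearchSpace,
    evaluate,
    top_fraction: float = 0.2,
    n_steps: int = 3,
    zoom_factor: float = 2.0,
    max_beam_width: int | None = 5,
    early_stopping: dict | None = None,
    executor=None,
    seed: int = 0,
    seen: set | None = None,
):
    """Iterative top-fraction search with range refinement and sphere perturbation.

    Step 0 evaluates the initial grid (crossed with the base sphere set
    and, if a perturbation spec is present, with ``counts_per_step[0]``
    freshly perturbed sphere sets).  Each later step k evaluates the
    refined grid at the best sphere set plus, for every retained
    candidate, ``counts_per_step[k]`` perturbed variants of that
    candidate's own sphere set at its bindings; retained candidates stay
    in the ranking without re-evaluation.  ``early_stopping`` is an
    optional ``{"patience": int, "min_delta": float}``.

    Returns ``(ranked, history)``: the final descending ranking of all
    successful candidates and the full evaluation history.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")

    history: list[EvaluationRecord] = []
    seen = seen if seen is not None else set()
    perturb = space.perturbation
    rng_seed = np.random.default_rng(seed)

    # --- step 0: initial grid x {base sphere set + first perturbation round}
    sphere_sets = [space.base_spheres]
    if perturb is not None and space.base_spheres is not None and perturb.radius > 0:
        sphere_sets += perturb_spheres(
            space.base_spheres, perturb.radius, perturb.count_at(0),
            seed=int(rng_seed.integers(2**31)),
        )
    candidates = [c for s in sphere_sets for c in space.grid(sphere_set=s)]
    _evaluate_batch(candidates, evaluate, 0, history, seen, executor)

    original = dict(space.numeric)
    state = BeamState(step_index=0, retained=[], ranges=dict(space.numeric), original=original)
    best_per_step: list[float] = []

    ranked = _rank(history)
    for step in range(n_steps):
        if not ranked:
            raise RuntimeError(f"all candidates failed by step {step}; aborting beam search")
        evaluated_this_step = sum(1 for r in history if r.step == step)
        n_keep = max(1, math.ceil(top_fraction * evaluated_this_step))
        if max_beam_width is not None:
            n_keep = min(n_keep, max_beam_width)
        state = BeamState(step_index=step, retained=ranked[:n_keep],
                          ranges=state.ranges, original=original)
        best_per_step.append(ranked[0][1])

        if early_stopping is not None and early_stop(
            best_per_step,
            patience=early_stopping.get("patience", 2),
            min_delta=early_stopping.get("min_delta", 0.0),
        ):
            break
        if step == n_steps - 1:
            break

        # --- step k+1 candidates
        state = BeamState(step_index=step + 1, retained=state.retained,
                          ranges=refine_ranges(state, zoom_factor), original=original)
        best_param, _ = state.retained[0]
        refined_space = replace(space, numeric=state.ranges)
        candidates = refined_space.grid(sphere_set=best_param.sphere_set)
        if perturb is not None and perturb.radius > 0:
            count = perturb.count_at(step + 1)
            for cand, _val in state.retained:
                if cand.sphere_set is None:
                    continue
                for variant in perturb_spheres(
                    cand.sphere_set, perturb.radius, count,
                    seed=int(rng_seed.integers(2**31)),
                ):
                    candidates.append(cand.with_spheres(variant))
        _evaluate_batch(candidates, evaluate, step + 1, history, seen, executor)
        ranked = _rank(history)

    return _rank(history), history


def flatten_sequence(node, depth: int = 1) -> list[dict]:
    """Expand a (possibly nested) step-sequence declaration into flat phases.

    A node is either a phase dict (beam settings: n_steps, top_fraction,
    criterion, ...) or ``{"sequence": [...], "iterate": k}`` embedding a
    child sequence repeated ``k`` times.  Nesting deeper than
    ``MAX_SEQUENCE_DEPTH`` (3) is a validation error.
    """
    if depth > MAX_SEQUENCE_DEPTH:
        raise ValueError(
            f"step-sequence nesting is limited to depth {MAX_SEQUENCE_DEPTH}"
        )
    if isinstance(node, list):
        return [p for child in node for p in flatten_sequence(child, depth)]
    if not isinstance(node, dict):
        raise ValueError(f"sequence node must be a mapping or list, got {type(node)}")
    if "sequence" in node:
        iterate = int(node.get("iterate", 1))
        if iterate < 1:
            raise ValueError("sequence iterate count must be >= 1")
        inner = flatten_sequence(node["sequence"], depth + 1)
        return inner * iterate
    return [dict(node)]


def run_sequence(
    space: SearchSpace,
    make_evaluate,
    sequence,
    zoom_factor: float = 2.0,
    executor=None,
    seed: int = 0,
):
    """Run a (nested) sequence of beam-search phases, carrying state forward.

    ``make_evaluate(criterion_name)`` returns the evaluation callable for a
    phase (phases may score with different criteria, e.g. a cheap one first
    and the full enrichment score later).  Each phase after the first
    starts from ranges refined around the previous phase's best candidate
    and from that candidate's sphere set.  Returns ``(ranked, history)``
    over all phases, with phase-global step numbers.
    """
    phases = flatten_sequence(sequence)
    if not phases:
        raise ValueError("empty step sequence")
    history: list[EvaluationRecord] = []
    ranked: list = []
    current = space
    step_offset = 0
    for k, phase in enumerate(phases):
        evaluate = make_evaluate(phase.get("criterion", "normalized_logauc"))
        es = phase.get("early_stopping")
        phase_ranked, phase_history = beam_search(
            current,
            evaluate,
            top_fraction=float(phase.get("top_fraction", 0.2)),
            n_steps=int(phase.get("n_steps", 1)),
            zoom_factor=float(phase.get("zoom_factor", zoom_factor)),
            max_beam_width=phase.get("max_beam_width", 5),
            early_stopping=es,
            executor=executor,
            seed=(seed + 7919 * k) % 2**31,
        )
        history.extend(
            EvaluationRecord(r.parameterization, r.step + step_offset, r.value, r.status)
            for r in phase_history
        )
        step_offset += 1 + max(r.step for r in phase_history)
        ranked = phase_ranked
        if k < len(phases) - 1:
            best = phase_ranked[0][0]
            state = BeamState(
                step_index=0,
                retained=phase_ranked[:1],
                ranges=dict(current.numeric),
                original=dict(space.numeric),
            )
            current = replace(
                current,
                numeric=refine_ranges(state, zoom_factor),
                base_spheres=best.sphere_set or current.base_spheres,
            )
    # phases are independent searches: a candidate re-visited by a later
    # phase keeps only its first record, so ids stay unique in reports
    deduped: list[EvaluationRecord] = []
    seen_ids: set[str] = set()
    for r in history:
        if r.parameterization.id not in seen_ids:
            seen_ids.add(r.parameterization.id)
            deduped.append(r)
    return _rank(deduped), deduped
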