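"""End-to-end pipeline: one call builds, evaluates and optimizes docking models.

``run_pipeline(config, dataset, out_dir)`` wires everything together:
load + validate the config, derive the candidate DAG from the inputs,
search the parameter space (grid or beam) with the configured backend,
compute the Bonferroni-corrected significance threshold from the
empirical null conditioned on the dataset's positive count, and persist
the artifacts:

    out_dir/
      results.csv             one row per evaluated parameterization
      effective-config.yaml   config with every default materialized
      report.html             plot suite (ROC, histogram, violins, ...)
      best_retrodock_jobs/    top-k candidates: score tables + dockfiles
      working/                every candidate's dockfiles, indexed by id
      screenopt.log           run log

Seeding: one master seed from the config; every candidate's docking seed
is a stable hash of (master seed, parameterization id), so serial and
parallel runs — and reruns — produce bit-identical results.csv.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from screenopt.config import load_config, parameter_pool, save_config
from screenopt.dag import Parameterization, build_dag, enumerate_parameterizations
from screenopt.dataset import RetrospectiveDataset, read_dataset
from screenopt.enrichment import get_criterion
from screenopt.executor import LocalExecutor
from screenopt.nullstats import SignificanceConfig, significance_threshold, simulate_null
from screenopt.oracle import OracleBackend, OracleConfig
from screenopt.search import (
    NumericRange,
    SearchSpace,
    SpherePerturbationSpec,
    beam_search,
    grid_search,
    run_sequence,
)
from screenopt.spheres import Sphere, SphereSet, read_sph, write_sph

__all__ = ["run_pipeline", "PipelineResult", "BeamPipeline", "candidate_seed",
           "build_search_space", "make_backend", "default_sphere_set"]

log = logging.getLogger("screenopt")


def candidate_seed(master_seed: int, parameterization_id: str) -> int:
    """Stable per-candidate seed below 2**31, independent of evaluation order."""
    digest = hashlib.sha256(f"{master_seed}:{parameterization_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def default_sphere_set(seed: int = 0, n: int = 10, extent: float = 5.0) -> SphereSet:
    """Deterministic fallback matching-sphere set in a cube of half-width `extent` Å."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-extent, extent, size=(n, 3))
    spheres = tuple(
        Sphere(index=i + 1, x=float(c[0]), y=float(c[1]), z=float(c[2]), radius=0.7)
        for i, c in enumerate(coords)
    )
    return SphereSet(spheres=spheres, provenance=f"default(seed={seed})")


def build_search_space(cfg: dict, base_spheres: SphereSet | None) -> SearchSpace:
    """Translate the config's parameter specs into a SearchSpace."""
    numeric: dict[str, NumericRange] = {}
    categorical: dict[str, tuple] = {}
    for name, spec in cfg["parameters"].items():
        kind, pool = parameter_pool(name, spec)
        if kind == "categorical":
            categorical[name] = tuple(pool)
        else:
            numeric[name] = NumericRange(low=float(min(pool)), high=float(max(pool)),
                                         n_points=len(pool))
    pert_cfg = cfg["matching_spheres_perturbation"]
    perturbation = (
        SpherePerturbationSpec(radius=pert_cfg["radius"],
                               counts_per_step=tuple(pert_cfg["counts_per_step"]))
        if pert_cfg.get("enabled", True)
        else None
    )
    return SearchSpace(numeric=numeric, categorical=categorical,
                       base_spheres=base_spheres, perturbation=perturbation)


def make_backend(cfg: dict, space: SearchSpace, base_spheres: SphereSet | None):
    """Instantiate the configured backend (synthetic oracle by default).

    If the oracle's hidden optimum is not pinned in the config it is drawn
    from the master seed uniformly within each numeric parameter's bounds;
    unset hotspots default to the base matching-sphere centers.
    """
    name = cfg["backend"]["name"]
    if name != "oracle":
        from screenopt.oracle import get_backend

        return get_backend(name)
    ocfg = cfg["backend"]["oracle"]
    rng = np.random.default_rng(cfg["seed"])
    theta_opt = ocfg.get("theta_opt")
    if theta_opt is None:
        theta_opt = {
            name: float(rng.uniform(r.low, r.high)) for name, r in sorted(space.numeric.items())
        }
    hotspots = ocfg.get("hotspots")
    if hotspots is None:
        hotspots = tuple(map(tuple, base_spheres.centers())) if base_spheres else ()
    else:
        hotspots = tuple(tuple(map(float, h)) for h in hotspots)
    return OracleBackend(
        OracleConfig(
            theta_opt={k: float(v) for k, v in theta_opt.items()},
            sigma=float(ocfg["sigma"]),
            signal=float(ocfg["signal"]),
            noise_sd=float(ocfg["noise_sd"]),
            charge_offset=float(ocfg["charge_offset"]),
            hotspots=hotspots,
            bounds={n: (r.low, r.high) for n, r in space.numeric.items()},
            seed=cfg["seed"],
        )
    )


class BeamPipeline:
    """Search + evaluation bundle used by cross-validation.

    Wraps a backend, a search space and beam settings so that
    :func:`screenopt.crossval.compare_first_last` can run the same search
    on every training fold and score any resulting model on a test fold.
    """

    def __init__(self, backend, space: SearchSpace, criterion: str = "normalized_logauc",
                 **beam_kwargs):
        self.backend = backend
        self.space = space
        self.criterion = get_criterion(criterion)
        self.beam_kwargs = beam_kwargs

    def evaluate(self, parameterization: Parameterization, dataset: RetrospectiveDataset,
                 seed: int) -> float:
        result = self.backend.dock(parameterization, dataset,
                                   candidate_seed(seed, parameterization.id))
        return float(self.criterion(result.scored_classes()))

    def search(self, dataset: RetrospectiveDataset, seed: int):
        return beam_search(
            self.space,
            lambda p: self.evaluate(p, dataset, seed),
            seed=seed,
            **self.beam_kwargs,
        )


@dataclass
class PipelineResult:
    out_dir: Path
    results: pd.DataFrame
    threshold: float | None
    best: Parameterization
    best_value: float
    n_evaluated: int


def _results_table(history, criterion_name: str, summaries: dict) -> pd.DataFrame:
    param_names = sorted({k for r in history for k in r.parameterization.bindings})
    rows = []
    for r in history:
        p = r.parameterization
        row = {"id": p.id, "step": r.step}
        for name in param_names:
            row[name] = p.bindings.get(name)
        row["sphere_provenance"] = p.sphere_provenance
        row["criterion"] = criterion_name
        row["criterion_value"] = r.value
        row["status"] = r.status
        mean_pos, mean_neg = summaries.get(p.id, (None, None))
        row["mean_score_pos"] = mean_pos
        row["mean_score_neg"] = mean_neg
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["step", "id"], kind="mergesort").reset_index(drop=True)


def run_pipeline(
    config: str | Path | dict | None,
    dataset: str | Path | RetrospectiveDataset,
    out_dir: str | Path,
) -> PipelineResult:
    """Run the full optimization pipeline and persist all artifacts.

    ``config`` is a YAML path, a dict, or None for all defaults;
    ``dataset`` a dataset file path or an in-memory dataset.  Reruns with
    an unchanged config and dataset reproduce results.csv bit-identically.
    """
    t0 = time.time()
    cfg = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "screenopt.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        if not isinstance(dataset, RetrospectiveDataset):
            dataset = read_dataset(dataset)
        master_seed = int(cfg["seed"])
        run_id = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        log.info("run %s: %d positives, %d negatives (ratio %.1f)",
                 run_id, len(dataset.positives), len(dataset.negatives), dataset.ratio)

        sphere_file = cfg["paths"]["sphere_file"]
        base_spheres = read_sph(sphere_file) if sphere_file else default_sphere_set(master_seed)
        space = build_search_space(cfg, base_spheres)
        backend = make_backend(cfg, space, base_spheres)
        criterion = get_criterion(cfg["criterion"])

        # candidate DAG from config + roots; its enumeration is the initial grid
        dag = build_dag(
            {"parameters": {n: r.pool().tolist() for n, r in space.numeric.items()}
             | {n: list(v) for n, v in space.categorical.items()}},
            roots={"receptor": dataset.receptor_ref, "ligand": dataset.ligand_ref},
        )
        n_initial = len(enumerate_parameterizations(dag))
        assert n_initial == len(space.grid()), "DAG enumeration must match the search grid"
        log.info("blaster DAG hash %s; %d initial parameterizations",
                 dag.structure_hash()[:12], n_initial)

        summaries: dict[str, tuple] = {}

        def make_evaluate(criterion_name: str):
            crit = get_criterion(criterion_name)

            def evaluate(p: Parameterization) -> float:
                result = backend.dock(p, dataset, candidate_seed(master_seed, p.id))
                t = result.table
                summaries[p.id] = (
                    float(t.loc[t["label"] == "positive", "total_score"].mean()),
                    float(t.loc[t["label"] == "negative", "total_score"].mean()),
                )
                return float(crit(result.scored_classes()))

            return evaluate

        evaluate = make_evaluate(cfg["criterion"])

        executor = LocalExecutor(workers=int(cfg["executor"]["workers"]),
                                 retries=int(cfg["executor"]["retries"]))
        s = cfg["search"]
        if s["mode"] == "grid":
            history: list = []
            ranked = grid_search(space, evaluate, executor=executor, history=history)
        elif s.get("sequence"):
            ranked, history = run_sequence(
                space,
                make_evaluate,
                s["sequence"],
                zoom_factor=float(s["zoom_factor"]),
                executor=executor,
                seed=master_seed,
            )
        else:
            es = s["early_stopping"]
            ranked, history = beam_search(
                space,
                evaluate,
                top_fraction=float(s["top_fraction"]),
                n_steps=int(s["n_steps"]),
                zoom_factor=float(s["zoom_factor"]),
                max_beam_width=int(s["max_beam_width"]),
                early_stopping=(
                    {"patience": int(es["patience"]), "min_delta": float(es["min_delta"])}
                    if es.get("enabled")
                    else None
                ),
                executor=executor,
                seed=master_seed,
            )
        if not ranked:
            raise RuntimeError("no candidate evaluated successfully")
        best, best_value = ranked[0]
        log.info("search done: %d evaluations, best %s = %.4f",
                 len(history), cfg["criterion"], best_value)

        results = _results_table(history, cfg["criterion"], summaries)
        results.to_csv(out_dir / "results.csv", index=False)
        save_config(cfg, out_dir / "effective-config.yaml")

        # working/: every candidate's dockfiles
        working = out_dir / "working"
        for r in history:
            p = r.parameterization
            d = working / p.id
            d.mkdir(parents=True, exist_ok=True)
            (d / "dockfiles.txt").write_text(
                json.dumps({"bindings": p.bindings, "spheres": p.sphere_provenance},
                           sort_keys=True, default=str) + "\n"
            )
            if p.sphere_set is not None:
                write_sph(p.sphere_set, d / "matching_spheres.sph")

        # best_retrodock_jobs/: top-k score tables + dockfiles
        top_k = int(cfg["report"]["top_k"])
        best_dir = out_dir / "best_retrodock_jobs"
        for rank, (p, value) in enumerate(ranked[:top_k], start=1):
            d = best_dir / f"rank_{rank}"
            d.mkdir(parents=True, exist_ok=True)
            result = backend.dock(p, dataset, candidate_seed(master_seed, p.id))
            result.table.to_csv(d / "scores.csv", index=False)
            (d / "dockfiles.txt").write_text(
                json.dumps({"id": p.id, "bindings": p.bindings, "criterion_value": value,
                            "spheres": p.sphere_provenance}, sort_keys=True, default=str) + "\n"
            )

        # significance threshold conditioned on this dataset's positive count
        sig = cfg["significance"]
        n_models = int(results["status"].eq("ok").sum())
        threshold = None
        try:
            null = simulate_null(
                n_pos=len(dataset.positives),
                ratio=dataset.ratio,
                reps=int(sig["null_reps"]),
                seed=master_seed,
                cache_dir=out_dir / "null_cache",
            )
            threshold = significance_threshold(
                null, SignificanceConfig(p_value=float(sig["p_value"]), n_tests=n_models)
            )
            log.info("significance threshold (p=%g, %d tests): %.4f",
                     sig["p_value"], n_models, threshold)
        except ValueError as exc:
            log.warning("significance threshold unavailable: %s", exc)

        from screenopt.report import render_report

        best_scores = pd.read_csv(best_dir / "rank_1" / "scores.csv")
        render_report(out_dir / "report.html", results, best_scores, threshold,
                      criterion_name=cfg["criterion"])
        log.info("finished in %.1f s; artifacts in %s", time.time() - t0, out_dir)
        return PipelineResult(out_dir=out_dir, results=results, threshold=threshold,
                              best=best, best_value=best_value, n_evaluated=len(history))
    finally:
        log.removeHandler(handler)
        handler.close()
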