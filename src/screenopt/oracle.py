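"""Pluggable docking-backend contract and the synthetic docking oracle.

A *docking model* is a parameterization (numeric tunables plus a matching
sphere set) combined with a docking engine.  The engine side is abstracted
behind :class:`DockingBackend`: given a parameterization, a retrospective
dataset and a seed, a backend returns one score (and its energy-term
breakdown) per molecule, deterministically.

The shipped backend is a synthetic oracle whose class separation depends
on how close the tested parameters sit to a hidden optimum theta*:

    total_score(m) = -signal * 1[m positive] * affinity(m) * g(theta) * h(spheres)
                     + noise_sd * eps(m)

with g(theta) = exp(-||theta - theta*||^2 / (2 sigma^2)) a Gaussian kernel
over the numeric parameters and h the fraction of matching spheres lying
within 1.5 Å of a hotspot.  Scores follow the energy convention (lower is
better), so positives separate from negatives exactly when the model is
near the optimum — which is what lets the search, significance and
cross-validation machinery be exercised end to end without a physical
docking engine.

The numeric knobs mirror the tunables that matter most in real docking
models: the electrostatic and ligand-desolvation thin-sphere radii
(low-dielectric / desolvation boundary thickness) and matching-sphere
placement.  Pose-sampling controls (match_goal, bump limits, chemical
matching) are exposed as categorical parameters that scale the score
noise, since their real effect is on sampling reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from screenopt.dataset import RetrospectiveDataset
from screenopt.enrichment import ScoredClasses

__all__ = [
    "DockingResultSet",
    "DockingBackend",
    "OracleConfig",
    "OracleBackend",
    "Dock38Stub",
    "get_backend",
    "BACKENDS",
]

HOTSPOT_CAPTURE_RADIUS = 1.5  # Å: sphere counts as placed if within this of a hotspot

#: Categorical pose-sampling controls and the noise multiplier each value applies.
CATEGORICAL_NOISE_SCALES: dict[str, dict[str, float]] = {
    "match_goal": {"low": 1.5, "default": 1.0, "high": 0.7},
    "bump_maximum": {"strict": 0.8, "default": 1.0, "loose": 1.3},
    "bump_rigid": {"strict": 0.8, "default": 1.0, "loose": 1.3},
    "chemical_matching": {"on": 0.8, "off": 1.0},
}


@dataclass(frozen=True)
class DockingResultSet:
    """Per-molecule docking scores with energy-term breakdown.

    ``table`` has one row per molecule: id, label, net_charge,
    total_score, electrostatic, vdw, ligand_desolvation.  The three energy
    terms sum to the total score (the predicted binding free energy)
    within 1e-9 by contract.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        term_sum = t["electrostatic"] + t["vdw"] + t["ligand_desolvation"]
        if not np.allclose(term_sum, t["total_score"], atol=1e-9):
            raise ValueError("energy terms must sum to total_score within 1e-9")

    def scored_classes(self) -> ScoredClasses:
        pos = self.table.loc[self.table["label"] == "positive", "total_score"]
        neg = self.table.loc[self.table["label"] == "negative", "total_score"]
        return ScoredClasses(scores_pos=pos.to_numpy(), scores_neg=neg.to_numpy())


class DockingBackend:
    """Contract every docking engine adapter implements."""

    name = "abstract"

    def schema(self) -> dict[str, dict]:
        """Parameter schema: name -> {'type': 'numeric', 'bounds': (lo, hi)} or
        {'type': 'categorical', 'values': [...]}."""
        raise NotImplementedError

    def dock(self, parameterization, dataset: RetrospectiveDataset, seed: int) -> DockingResultSet:
        """Score every molecule; identical inputs + seed give identical results."""
        raise NotImplementedError


@dataclass(frozen=True)
class OracleConfig:
    """Hidden truth of the synthetic oracle.

    theta_opt: hidden optimum per numeric parameter (same units as the
    parameter, here Å for thin-sphere radii).  sigma: kernel width of the
    enrichment peak around the optimum.  signal: score separation (in
    score units, "kcal/mol"-like) between classes at the optimum.
    noise_sd: per-molecule score noise.  hotspots: 3D points the matching
    spheres should cover; the signal scales with the covered fraction.
    charge_offset: per-unit-charge shift added to the electrostatic term,
    used to emulate charge bias in reports.
    """

    theta_opt: dict[str, float]
    sigma: float = 1.0
    signal: float = 5.0
    noise_sd: float = 1.0
    hotspots: tuple[tuple[float, float, float], ...] = ()
    charge_offset: float = 0.0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


class OracleBackend(DockingBackend):
    """Synthetic engine: class separation peaks at the hidden optimum."""

    name = "oracle"

    def __init__(self, config: OracleConfig):
        self.config = config
        # fixed random convex split of the score into energy terms
        self._term_weights = np.random.default_rng(config.seed).dirichlet((1.0, 1.0, 1.0))

    def schema(self) -> dict[str, dict]:
        out: dict[str, dict] = {}
        for name in sorted(self.config.theta_opt):
            lo, hi = self.config.bounds.get(name, (-np.inf, np.inf))
            out[name] = {"type": "numeric", "bounds": (lo, hi)}
        for name, scales in CATEGORICAL_NOISE_SCALES.items():
            out[name] = {"type": "categorical", "values": sorted(scales)}
        return out

    def _kernel(self, bindings: dict) -> float:
        sq = 0.0
        for name, opt in self.config.theta_opt.items():
            if name not in bindings:
                raise KeyError(f"parameterization does not bind oracle parameter {name!r}")
            sq += (float(bindings[name]) - opt) ** 2
        return float(np.exp(-sq / (2.0 * self.config.sigma**2)))

    def _sphere_coverage(self, sphere_set) -> float:
        hotspots = np.asarray(self.config.hotspots, dtype=float)
        if sphere_set is None or hotspots.size == 0 or len(sphere_set) == 0:
            return 1.0
        centers = sphere_set.centers()
        d = np.linalg.norm(centers[:, None, :] - hotspots[None, :, :], axis=2)
        return float(np.mean(d.min(axis=1) <= HOTSPOT_CAPTURE_RADIUS))

    def _noise_scale(self, bindings: dict) -> float:
        scale = 1.0
        for name, scales in CATEGORICAL_NOISE_SCALES.items():
            if name in bindings:
                value = str(bindings[name])
                if value not in scales:
                    raise KeyError(f"unknown {name} value {value!r}")
                scale *= scales[value]
        return scale

    def dock(self, parameterization, dataset: RetrospectiveDataset, seed: int) -> DockingResultSet:
        cfg = self.config
        g = self._kernel(parameterization.bindings)
        h = self._sphere_coverage(parameterization.sphere_set)
        noise_sd = cfg.noise_sd * self._noise_scale(parameterization.bindings)
        rng = np.random.default_rng(seed)

        labels = np.array([m.label for m in dataset.molecules])
        affinity = np.array([m.latent_affinity for m in dataset.molecules])
        charges = np.array([m.net_charge for m in dataset.molecules])
        is_pos = labels == "positive"

        base = -cfg.signal * is_pos * affinity * g * h + noise_sd * rng.standard_normal(labels.size)
        w_es, w_vdw, w_des = self._term_weights
        es_offset = cfg.charge_offset * charges
        table = pd.DataFrame(
            {
                "id": [m.id for m in dataset.molecules],
                "label": labels,
                "net_charge": charges,
                "total_score": base + es_offset,
                "electrostatic": w_es * base + es_offset,
                "vdw": w_vdw * base,
                "ligand_desolvation": w_des * base,
            }
        )
        return DockingResultSet(table=table)


class Dock38Stub(DockingBackend):
    """Adapter stub for a user-supplied physical docking executable.

    Documents the integration surface only: a real adapter would write the
    parameterization's dockfiles, invoke the executable per molecule batch,
    and parse score tables back into a :class:`DockingResultSet`.  Untested
    and raises on use.
    """

    name = "dock38"

    def __init__(self, executable: str = "dock64"):
        self.executable = executable

    def schema(self) -> dict[str, dict]:
        raise NotImplementedError("dock38 adapter is a documented stub; supply your own")

    def dock(self, parameterization, dataset, seed):
        raise NotImplementedError("dock38 adapter is a documented stub; supply your own")


BACKENDS = {"oracle": OracleBackend, "dock38": Dock38Stub}


def get_backend(name: str, *args, **kwargs) -> DockingBackend:
    """Instantiate a registered backend by name ('oracle' or 'dock38')."""
    try:
        cls = BACKENDS[name]
    except KeyError:
        raise KeyError(f"unknown backend {name!r}; available: {sorted(BACKENDS)}") from None
    return cls(*args, **kwargs)
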