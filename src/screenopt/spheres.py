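"""Matching-sphere sets: .sph dialect I/O and stochastic perturbation.

Matching spheres are 3D hotspot points in the binding pocket used to
orient ligands during pose sampling; their number and placement strongly
affect docking performance, which makes them a search axis.  New candidate
sphere files are derived from existing ones by displacing each sphere with
an independent draw from the uniform distribution over a ball of a given
radius (default 0.4 Å) centered at the origin.

The file dialect follows DOCK sphere-cluster files: a single ``cluster``
header line carrying the sphere count, then one fixed-column record per
sphere (index, x, y, z, radius).  Extra trailing columns present in real
DOCK files (surface point, critical cluster, chemical color) are read and
preserved verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Sphere", "SphereSet", "read_sph", "write_sph", "perturb_spheres", "sample_in_ball"]


@dataclass(frozen=True)
class Sphere:
    """One matching sphere: 1-based index, center (Å) and radius (Å)."""

    index: int
    x: float
    y: float
    z: float
    radius: float
    extra: str = ""  # trailing DOCK columns, preserved verbatim

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"sphere {self.index}: radius must be > 0")
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError(f"sphere {self.index}: coordinates must be finite")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class SphereSet:
    """Ordered sphere list plus a provenance string recording perturbation lineage."""

    spheres: tuple[Sphere, ...]
    provenance: str = "base"

    def __post_init__(self) -> None:
        object.__setattr__(self, "spheres", tuple(self.spheres))
        indices = [s.index for s in self.spheres]
        if len(indices) != len(set(indices)):
            raise ValueError("sphere indices must be unique")

    def __len__(self) -> int:
        return len(self.spheres)

    def centers(self) -> np.ndarray:
        """(n, 3) array of sphere centers in file order."""
        if not self.spheres:
            return np.empty((0, 3))
        return np.vstack([s.center for s in self.spheres])


_HEADER = "cluster     1   number of spheres in cluster {count:5d}"


def read_sph(path: str | Path) -> SphereSet:
    """Parse a .sph file: one cluster header then fixed-column sphere records.

    Record columns: index (5), x/y/z (10 each, 5 decimals), radius (8,
    3 decimals); anything beyond column 43 is kept verbatim in
    ``Sphere.extra``.  Header/record count mismatch and malformed numeric
    fields are hard errors (the latter reported with the line number).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_i = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("cluster"):
            header_i = i
            break
    if header_i is None:
        raise ValueError(f"{path}: no 'cluster' header line found")
    try:
        count = int(lines[header_i].split()[-1])
    except ValueError:
        raise ValueError(f"{path}: malformed sphere count in header line {header_i + 1}")
    spheres = []
    for offset, line in enumerate(lines[header_i + 1 :], start=header_i + 2):
        if not line.strip():
            continue
        if line.lstrip().startswith("cluster"):
            break
        try:
            sph = Sphere(
                index=int(line[0:5]),
                x=float(line[5:15]),
                y=float(line[15:25]),
                z=float(line[25:35]),
                radius=float(line[35:43]),
                extra=line[43:].rstrip("\n"),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed sphere record at line {offset}: {exc}")
        spheres.append(sph)
    if len(spheres) != count:
        raise ValueError(
            f"{path}: header declares {count} spheres but {len(spheres)} records found"
        )
    return SphereSet(spheres=tuple(spheres), provenance=f"file:{path.name}")


def write_sph(sphere_set: SphereSet, path: str | Path) -> None:
    """Write a SphereSet in the .sph dialect read by :func:`read_sph`.

    Coordinates print with 5 decimals and radii with 3, so a round trip is
    exact to that printed precision.
    """
    path = Path(path)
    lines = [_HEADER.format(count=len(sphere_set))]
    for s in sphere_set.spheres:
        lines.append(f"{s.index:5d}{s.x:10.5f}{s.y:10.5f}{s.z:10.5f}{s.radius:8.3f}{s.extra}")
    path.write_text("\n".join(lines) + "\n")


def sample_in_ball(rng: np.random.Generator, radius: float, n: int) -> np.ndarray:
    """Draw ``n`` points uniformly from the 3-ball of the given radius.

    Uses a normalized Gaussian direction scaled by ``radius * U**(1/3)``,
    which is exact (the cube of norm/radius is Uniform(0,1)) and needs no
    rejection loop.
    """
    if radius == 0.0:
        return np.zeros((n, 3))
    direction = rng.normal(size=(n, 3))
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    # a zero Gaussian vector has probability 0; guard anyway
    norms[norms == 0] = 1.0
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return direction / norms * r[:, None]


def perturb_spheres(
    sphere_set: SphereSet,
    radius: float,
    count: int,
    seed: int,
    mode: str = "per_sphere",
) -> list[SphereSet]:
    """Generate ``count`` perturbed copies of a sphere set.

    Each output set displaces spheres by draws from the uniform
    distribution over a ball of ``radius`` Å centered at the origin, so no
    sphere moves farther than ``radius`` from its source position; sphere
    radii, indices and order are unchanged.  ``mode='per_sphere'``
    (default) draws an independent displacement per sphere, adding pose
    sampling diversity; ``mode='rigid'`` applies one shared displacement
    per output set.  Deterministic under a fixed seed.
    """
    if radius < 0:
        raise ValueError("perturbation radius must be >= 0")
    if count < 1:
        raise ValueError("count must be >= 1")
    if mode not in ("per_sphere", "rigid"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = len(sphere_set)
    out = []
    for k in range(count):
        if mode == "per_sphere":
            disp = sample_in_ball(rng, radius, n)
        else:
            disp = np.repeat(sample_in_ball(rng, radius, 1), n, axis=0)
        spheres = tuple(
            replace(s, x=s.x + d[0], y=s.y + d[1], z=s.z + d[2])
            for s, d in zip(sphere_set.spheres, disp)
        )
        out.append(
            SphereSet(
                spheres=spheres,
                provenance=f"{sphere_set.provenance}|perturb(r={radius},seed={seed},k={k})",
            )
        )
    return out
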