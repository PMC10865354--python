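"""Read, perturb and write DOCK-style matching-sphere files.

Matching spheres are the binding-pocket hotspots used to orient ligand
poses.  The optimizer explores their placement by drawing displacements
uniformly from a 0.4 Å ball for every sphere, generating many candidate
sphere files per step.
"""

import numpy as np

from screenopt import perturb_spheres, read_sph, write_sph
from screenopt.pipeline import default_sphere_set

base = default_sphere_set(seed=0, n=10)
write_sph(base, "matching_spheres.sph")
base = read_sph("matching_spheres.sph")  # round trip through the .sph dialect

variants = perturb_spheres(base, radius=0.4, count=10, seed=1)
displacements = np.array(
    [np.linalg.norm(v.centers() - base.centers(), axis=1) for v in variants]
)
print(f"spheres per set: {len(base)}; perturbed variants: {len(variants)}")
print(f"max displacement: {displacements.max():.4f} A (hard bound 0.4)")
print(f"mean displacement: {displacements.mean():.4f} A")
print(f"lineage of first variant: {variants[0].provenance}")
# Every sphere moves independently but never farther than the ball radius;
# the provenance string records the perturbation lineage for results.csv.
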