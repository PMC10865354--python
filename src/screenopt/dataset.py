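"""Retrospective dataset types, tabular I/O and the synthetic generator.

A retrospective dataset pairs positive-class molecules (known ligands)
with negative-class molecules (property-matched decoys).  Each molecule
carries an integer net charge and a fixed-length binary fingerprint; the
synthetic generator additionally plants a latent binding affinity that
the oracle backend turns into a graded docking signal.

The on-disk format is a headered tab-separated file with columns
``id, label, net_charge, fingerprint`` — fingerprints serialized as 0/1
strings so no chemistry toolkit is needed to read or write datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MoleculeRecord",
    "RetrospectiveDataset",
    "read_dataset",
    "write_dataset",
    "generate_dataset",
]

POSITIVE = "positive"
NEGATIVE = "negative"
_LABELS = {POSITIVE, NEGATIVE}


@dataclass(frozen=True)
class MoleculeRecord:
    """One labeled molecule: binary class, net charge and bit fingerprint."""

    id: str
    label: str
    net_charge: int
    fingerprint: np.ndarray
    latent_affinity: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r} for molecule {self.id!r}")
        fp = np.asarray(self.fingerprint, dtype=np.uint8)
        if fp.ndim != 1 or not np.isin(fp, (0, 1)).all():
            raise ValueError(f"fingerprint of {self.id!r} must be a 1-D 0/1 vector")
        object.__setattr__(self, "fingerprint", fp)

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


@dataclass
class RetrospectiveDataset:
    """Labeled molecules plus opaque receptor/ligand structure references."""

    molecules: list[MoleculeRecord]
    receptor_ref: str = "receptor.pdb"
    ligand_ref: str = "ligand.pdb"

    def __post_init__(self) -> None:
        ids = [m.id for m in self.molecules]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate molecule ids: {dup[:5]}")
        lengths = {m.fingerprint.size for m in self.molecules}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent fingerprint lengths: {sorted(lengths)}")
        if not self.positives:
            raise ValueError("dataset must contain at least one positive molecule")

    @property
    def positives(self) -> list[MoleculeRecord]:
        return [m for m in self.molecules if m.is_positive]

    @property
    def negatives(self) -> list[MoleculeRecord]:
        return [m for m in self.molecules if not m.is_positive]

    @property
    def ratio(self) -> float:
        """Negatives per positive."""
        return len(self.negatives) / len(self.positives)

    @property
    def fp_len(self) -> int:
        return self.molecules[0].fingerprint.size

    def subset(self, ids: set[str]) -> "RetrospectiveDataset":
        """New dataset restricted to the given molecule ids (order preserved)."""
        return RetrospectiveDataset(
            molecules=[m for m in self.molecules if m.id in ids],
            receptor_ref=self.receptor_ref,
            ligand_ref=self.ligand_ref,
        )

    def fingerprint_matrix(self, which: str = POSITIVE) -> np.ndarray:
        mols = self.positives if which == POSITIVE else self.negatives
        return np.vstack([m.fingerprint for m in mols])


def read_dataset(path: str | Path) -> RetrospectiveDataset:
    """Read a tab-separated dataset file with columns id, label, net_charge, fingerprint.

    Fingerprints may be 0/1 strings or hex strings prefixed ``0x`` (decoded
    MSB-first).  Duplicate ids, unknown labels and inconsistent fingerprint
    lengths are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "label", "net_charge", "fingerprint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset file missing columns: {sorted(missing)}")
    has_affinity = "latent_affinity" in df.columns
    molecules = []
    for row in df.itertuples(index=False):
        fp_str = row.fingerprint.strip()
        if fp_str.startswith("0x"):
            nbits = 4 * (len(fp_str) - 2)
            value = int(fp_str, 16)
            fp = np.array([(value >> (nbits - 1 - i)) & 1 for i in range(nbits)], dtype=np.uint8)
        else:
            if set(fp_str) - {"0", "1"}:
                raise ValueError(f"malformed fingerprint for molecule {row.id!r}")
            fp = np.frombuffer(fp_str.encode(), dtype=np.uint8) - ord("0")
        molecules.append(
            MoleculeRecord(
                id=str(row.id),
                label=str(row.label),
                net_charge=int(row.net_charge),
                fingerprint=fp,
                latent_affinity=float(row.latent_affinity) if has_affinity else 0.0,
            )
        )
    return RetrospectiveDataset(molecules=molecules)


def write_dataset(dataset: RetrospectiveDataset, path: str | Path) -> None:
    """Write a dataset to the tab-separated format read by :func:`read_dataset`."""
    rows = [
        {
            "id": m.id,
            "label": m.label,
            "net_charge": m.net_charge,
            "fingerprint": "".join(map(str, m.fingerprint.tolist())),
            "latent_affinity": repr(m.latent_affinity),
        }
        for m in dataset.molecules
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _sample_prototypes(
    rng: np.random.Generator, n_clusters: int, fp_len: int, min_dist: float
) -> np.ndarray:
    """Random bit-vector prototypes with pairwise Tanimoto distance > min_dist.

    Prototypes are resampled until the separation holds, which guarantees
    the planted clustering is the unique complete-linkage solution at the
    clustering cutoff (min_dist includes a safety margin above it).
    """
    from screenopt.crossval import tanimoto_distance

    for _ in range(1000):
        protos = (rng.random((n_clusters, fp_len)) < 0.3).astype(np.uint8)
        ok = all(p.any() for p in protos) and all(
            tanimoto_distance(protos[i], protos[j]) > min_dist
            for i in range(n_clusters)
            for j in range(i + 1, n_clusters)
        )
        if ok:
            return protos
    raise RuntimeError(
        f"could not place {n_clusters} prototypes at pairwise distance > {min_dist}; "
        "increase fp_len"
    )


def generate_dataset(
    n_pos: int,
    ratio: float = 50.0,
    n_clusters: int = 2,
    fp_len: int = 256,
    seed: int = 0,
    flip_fraction: float = 0.04,
    prototype_margin: float = 0.1,
    cluster_cutoff: float = 0.6,
) -> RetrospectiveDataset:
    """Generate a synthetic retrospective dataset with planted fingerprint clusters.

    Produces exactly ``n_pos`` positives and ``round(ratio * n_pos)``
    negatives (default ratio 50 negatives per positive, the shape used for
    null-distribution work).  Positive fingerprints are noisy copies of
    ``n_clusters`` well-separated prototypes: members flip a small fixed
    fraction of prototype bits, keeping within-cluster Tanimoto distance
    below ``cluster_cutoff`` while prototypes sit farther than
    ``cluster_cutoff + prototype_margin`` apart, so complete-linkage
    clustering at the cutoff recovers the planted partition.  Net charges
    are uniform on {-2,...,+2}.  Positives receive a latent affinity
    (mean 3, unit variance, floored at 0.1); negatives get affinity 0.

    Deterministic and bit-exactly reproducible for a fixed seed.
    """
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if not 1 <= n_clusters <= n_pos:
        raise ValueError(f"n_clusters must be in [1, n_pos={n_pos}]")
    rng = np.random.default_rng(seed)
    n_neg = int(round(ratio * n_pos))

    protos = _sample_prototypes(rng, n_clusters, fp_len, cluster_cutoff + prototype_margin)
    # round-robin assignment guarantees every cluster is non-empty
    assignment = np.arange(n_pos) % n_clusters
    n_flip = max(1, int(round(flip_fraction * fp_len)))

    molecules: list[MoleculeRecord] = []
    for i in range(n_pos):
        fp = protos[assignment[i]].copy()
        flip_idx = rng.choice(fp_len, size=n_flip, replace=False)
        fp[flip_idx] ^= 1
        molecules.append(
            MoleculeRecord(
                id=f"pos_{i:05d}",
                label=POSITIVE,
                net_charge=int(rng.integers(-2, 3)),
                fingerprint=fp,
                latent_affinity=float(max(0.1, rng.normal(3.0, 1.0))),
            )
        )
    for j in range(n_neg):
        fp = (rng.random(fp_len) < 0.3).astype(np.uint8)
        molecules.append(
            MoleculeRecord(
                id=f"neg_{j:05d}",
                label=NEGATIVE,
                net_charge=int(rng.integers(-2, 3)),
                fingerprint=fp,
                latent_affinity=0.0,
            )
        )
    return RetrospectiveDataset(molecules=molecules)
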