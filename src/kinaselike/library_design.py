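"""Focused-library construction and fingerprint diversity.

A focused library is built by pooling source libraries, removing duplicate
structures and known actives, and keeping the top-N compounds by KLS
(N = 10,000 by default).  Diversity of a compound set is the mean Tanimoto
distance (1 - similarity) over all unordered pairs of Morgan circular
fingerprints of radius 3 / 2048 bits (the ECFP_6-equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import LibraryTable, MoleculeRecord
from .errors import ConfigurationError, SchemaError

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)


@dataclass
class FocusedLibrary:
    """Members ordered by non-increasing KLS, with construction provenance."""

    members: pd.DataFrame  # columns: id, kls (+ any carried columns)
    n_requested: int
    provenance: list[str]
    n_duplicates_removed: int = 0
    n_actives_removed: int = 0

    def __len__(self) -> int:
        return len(self.members)

    @property
    def ids(self) -> list[str]:
        return self.members["id"].tolist()

    @property
    def mean_kls(self) -> float:
        return float(self.members["kls"].mean())


def _structure_key(smiles: str, key: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if key == "smiles":
        return Chem.MolToSmiles(mol)
    if key == "inchikey":
        return Chem.MolToInchiKey(mol)
    raise ConfigurationError(f"unknown structure key {key!r}")


def pool_and_dedupe(
    libraries: Sequence[LibraryTable],
    exclude_actives: Iterable[str] = (),
    key: str = "smiles",
) -> LibraryTable:
    """Pool libraries, keep one row per unique structure, drop known actives.

    Each table must carry a ``smiles`` column for identity hashing; the key
    is the canonical SMILES (default) or InChIKey.  The first occurrence of
    each structure wins, so membership is order-independent but provenance
    follows pool order.  Removal counts are attached to the result frame's
    ``attrs``.
    """
    if not libraries:
        raise ConfigurationError("no libraries to pool")
    frames = []
    for lib in libraries:
        if "smiles" not in lib.df.columns:
            raise SchemaError(
                f"library {lib.name!r} lacks a 'smiles' column needed for dedup"
            )
        df = lib.df.copy()
        df["_source"] = lib.name
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    pooled["_key"] = [_structure_key(s, key) for s in pooled["smiles"]]

    active_keys = {
        k for k in (_structure_key(s, key) for s in exclude_actives) if k is not None
    }
    is_active = pooled["_key"].isin(active_keys)
    n_actives_removed = int(is_active.sum())
    pooled = pooled[~is_active]
    is_dupe = pooled["_key"].duplicated()
    n_duplicates_removed = int(is_dupe.sum())
    pooled = pooled[~is_dupe].drop(columns=["_key"]).reset_index(drop=True)
    # pooled ids may collide across sources even for distinct structures
    if pooled["id"].duplicated().any():
        pooled["id"] = pooled["_source"].str.cat(pooled["id"].astype(str), sep=":")
    pooled = pooled.drop(columns=["_source"])
    result = LibraryTable(pooled, name="+".join(lib.name for lib in libraries))
    result.df.attrs["n_duplicates_removed"] = n_duplicates_removed
    result.df.attrs["n_actives_removed"] = n_actives_removed
    return result


def build_focused_library(pool: LibraryTable, n: int = 10_000) -> FocusedLibrary:
    """Top-n rows of a scored pool by KLS descending.

    Ties at the cutoff break by stable input order.  If the pool is smaller
    than n, all rows are returned (with a warning attached via provenance).
    """
    if n <= 0:
        raise ConfigurationError(f"n must be positive, got {n}")
    if not pool.scored:
        raise SchemaError("pool must be scored before selection")
    scores = pool.df["kls"].to_numpy(dtype=float)
    order = np.argsort(-scores, kind="stable")
    taken = order[: min(n, len(scores))]
    members = pool.df.iloc[taken].reset_index(drop=True)
    prov = [pool.name]
    if len(scores) < n:
        prov.append(f"pool smaller than requested ({len(scores)} < {n})")
    return FocusedLibrary(
        members=members,
        n_requested=n,
        provenance=prov,
        n_duplicates_removed=pool.df.attrs.get("n_duplicates_removed", 0),
        n_actives_removed=pool.df.attrs.get("n_actives_removed", 0),
    )


def random_subset(pool: LibraryTable, n: int, rng_seed: int) -> FocusedLibrary:
    """Uniform sample of n pool rows without replacement (the 'random set'
    baseline a focused library is compared against)."""
    if n <= 0:
        raise ConfigurationError(f"n must be positive, got {n}")
    if n > len(pool):
        raise ConfigurationError(f"cannot sample {n} from a pool of {len(pool)}")
    rng = np.random.default_rng(rng_seed)
    picked = rng.choice(len(pool), size=n, replace=False)
    members = pool.df.iloc[np.sort(picked)].reset_index(drop=True)
    return FocusedLibrary(
        members=members, n_requested=n, provenance=[pool.name, f"random seed={rng_seed}"]
    )


def average_pairwise_distance(molecules: Sequence[MoleculeRecord | Chem.Mol | str]) -> float:
    """Mean Tanimoto distance (1 - similarity) over all unordered pairs,
    using Morgan fingerprints of radius 3 folded to 2048 bits."""
    mols = []
    for m in molecules:
        if isinstance(m, MoleculeRecord):
            mol = m.mol
        elif isinstance(m, str):
            mol = Chem.MolFromSmiles(m)
        else:
            mol = m
        if mol is None:
            raise ConfigurationError("unparseable structure in diversity set")
        mols.append(mol)
    if len(mols) < 2:
        raise ConfigurationError("diversity needs at least 2 molecules")
    fps = [_MORGAN.GetFingerprint(m) for m in mols]
    total, n_pairs = 0.0, 0
    for i in range(len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
        total += sum(1.0 - s for s in sims)
        n_pairs += len(sims)
    return total / n_pairs
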