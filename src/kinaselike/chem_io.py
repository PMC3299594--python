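"""Molecular and tabular I/O plus structure preprocessing.

Reads SMILES line files, SDF (V2000) and CSV-with-SMILES into
:class:`MoleculeRecord` objects, and applies the preprocessing pipeline used
before descriptor calculation: desalting to the largest organic fragment,
charge neutralization, metal exclusion, and a 100-700 Da molecular-weight
window.  Filtering never deletes records; it flags them with an
``excluded_reason`` so the record count is conserved end to end.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .constants import (
    DESCRIPTOR_NAMES,
    MAX_WEIGHT,
    MIN_WEIGHT,
    ORGANIC_ELEMENTS,
)
from .errors import ConfigurationError, SchemaError

RDLogger.DisableLog("rdApp.*")


class ExclusionReason(str, enum.Enum):
    UNPARSEABLE = "unparseable"
    METAL = "metal"
    WEIGHT_OUT_OF_RANGE = "weight_out_of_range"
    EMPTY_AFTER_DESALTING = "empty_after_desalting"


@dataclass
class MoleculeRecord:
    """One input molecule with its preprocessing fate.

    ``mol`` is the RDKit molecular graph (None only when unparseable);
    ``excluded_reason`` is set by parsing or :func:`preprocess` and a record
    carrying it must never reach descriptor computation.
    """

    id: str
    mol: Chem.Mol | None
    source: str = ""
    excluded_reason: ExclusionReason | None = None

    @property
    def excluded(self) -> bool:
        return self.excluded_reason is not None

    @property
    def smiles(self) -> str | None:
        return Chem.MolToSmiles(self.mol) if self.mol is not None else None


@dataclass
class LibraryTable:
    """An ordered descriptor table for one library.

    Wraps a DataFrame with an ``id`` column, the nine canonical descriptor
    columns, and optionally ``kls`` (and ``smiles`` when structures are
    carried along for dedup/diversity).  Input row order is preserved and
    ids are unique.
    """

    df: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        if "id" not in self.df.columns:
            raise SchemaError(f"library table {self.name!r} lacks an 'id' column")
        if self.df["id"].duplicated().any():
            dupes = self.df["id"][self.df["id"].duplicated()].iloc[0]
            raise SchemaError(
                f"duplicate id {dupes!r} in library table {self.name!r}"
            )
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def scored(self) -> bool:
        return "kls" in self.df.columns

    def descriptor_frame(self) -> pd.DataFrame:
        missing = [c for c in DESCRIPTOR_NAMES if c not in self.df.columns]
        if missing:
            raise SchemaError(
                f"library table {self.name!r} is missing descriptor "
                f"column(s): {', '.join(missing)}"
            )
        return self.df[list(DESCRIPTOR_NAMES)]


_UNCHARGER = rdMolStandardize.Uncharger()


def _parse_smiles_lines(path: Path) -> list[MoleculeRecord]:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{i + 1}"
            mol = Chem.MolFromSmiles(smiles)
            reason = ExclusionReason.UNPARSEABLE if mol is None else None
            records.append(
                MoleculeRecord(mol_id, mol, source=str(path), excluded_reason=reason)
            )
    return records


def _parse_sdf(path: Path) -> list[MoleculeRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            records.append(
                MoleculeRecord(
                    f"mol{i + 1}", None, source=str(path),
                    excluded_reason=ExclusionReason.UNPARSEABLE,
                )
            )
        else:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            records.append(
                MoleculeRecord(name.strip() or f"mol{i + 1}", mol, source=str(path))
            )
    return records


def _parse_csv(path: Path, smiles_column: str, id_column: str | None) -> list[MoleculeRecord]:
    df = pd.read_csv(path, dtype=str)
    if smiles_column not in df.columns:
        raise ConfigurationError(
            f"CSV {path} has no column {smiles_column!r} "
            f"(columns: {', '.join(df.columns)})"
        )
    if id_column is not None and id_column not in df.columns:
        raise ConfigurationError(f"CSV {path} has no id column {id_column!r}")
    records = []
    for i, row in df.iterrows():
        mol = Chem.MolFromSmiles(str(row[smiles_column]))
        mol_id = str(row[id_column]) if id_column is not None else f"mol{i + 1}"
        reason = ExclusionReason.UNPARSEABLE if mol is None else None
        records.append(
            MoleculeRecord(mol_id, mol, source=str(path), excluded_reason=reason)
        )
    return records


def read_molecules(
    path: str | Path,
    format: str | None = None,
    *,
    smiles_column: str = "smiles",
    id_column: str | None = None,
) -> list[MoleculeRecord]:
    """Read molecules from a SMILES line file, SDF or CSV.

    One record is returned per input entry, in input order; entries that
    fail to parse come back flagged ``unparseable`` rather than raising.
    ``format`` is inferred from the file extension when not given.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read molecule file: {path}")
    if format is None:
        format = {".smi": "smiles", ".smiles": "smiles", ".txt": "smiles",
                  ".sdf": "sdf", ".sd": "sdf", ".csv": "csv"}.get(path.suffix.lower())
        if format is None:
            raise ConfigurationError(
                f"cannot infer molecule format from suffix {path.suffix!r}; "
                "pass format='smiles'|'sdf'|'csv'"
            )
    if format == "smiles":
        return _parse_smiles_lines(path)
    if format == "sdf":
        return _parse_sdf(path)
    if format == "csv":
        return _parse_csv(path, smiles_column, id_column)
    raise ConfigurationError(f"unknown molecule format {format!r}")


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    """Largest fragment by heavy-atom count; ties broken by molecular
    weight, then canonical-SMILES order. Returns None if no fragment has
    a heavy atom."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    best = None
    best_key = None
    for frag in frags:
        n_heavy = frag.GetNumHeavyAtoms()
        if n_heavy == 0:
            continue
        try:
            Chem.SanitizeMol(frag)
        except Exception:
            continue
        key = (n_heavy, Descriptors.MolWt(frag), Chem.MolToSmiles(frag))
        if best_key is None or key > best_key:
            best, best_key = frag, key
    return best


def _contains_metal(mol: Chem.Mol) -> bool:
    return any(a.GetSymbol() not in ORGANIC_ELEMENTS for a in mol.GetAtoms())


def preprocess(
    records: Iterable[MoleculeRecord],
    min_weight: float = MIN_WEIGHT,
    max_weight: float = MAX_WEIGHT,
) -> list[MoleculeRecord]:
    """Standardize structures and flag exclusions before descriptor work.

    Per record: desalt to the largest organic fragment, neutralize simple
    charged groups (carboxylates, protonated amines), flag metal-containing
    structures, and flag molecular weights strictly outside the inclusive
    [min_weight, max_weight] window.  Records already excluded pass through
    unchanged, so the operation is idempotent and conserves record count.
    """
    out: list[MoleculeRecord] = []
    for rec in records:
        if rec.excluded or rec.mol is None:
            if rec.excluded_reason is None:
                rec = replace(rec, excluded_reason=ExclusionReason.UNPARSEABLE)
            out.append(rec)
            continue
        frag = _largest_organic_fragment(rec.mol)
        if frag is None:
            out.append(replace(rec, excluded_reason=ExclusionReason.EMPTY_AFTER_DESALTING))
            continue
        if _contains_metal(frag):
            out.append(replace(rec, mol=frag, excluded_reason=ExclusionReason.METAL))
            continue
        frag = _UNCHARGER.uncharge(frag)
        wt = Descriptors.MolWt(frag)
        if wt < min_weight or wt > max_weight:
            out.append(
                replace(rec, mol=frag, excluded_reason=ExclusionReason.WEIGHT_OUT_OF_RANGE)
            )
            continue
        out.append(replace(rec, mol=frag, excluded_reason=None))
    return out


def read_descriptor_table(path: str | Path, name: str = "") -> LibraryTable:
    """Read an id + nine-descriptor (optionally kls, smiles) CSV."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read table: {path}")
    df = pd.read_csv(path)
    return LibraryTable(df, name=name or path.stem)


def write_scored_table(table: LibraryTable, path: str | Path) -> None:
    """Write a scored table as CSV: id, the nine canonical descriptor
    columns, kls (and smiles when present). Round-trips losslessly with
    :func:`read_descriptor_table`."""
    table.descriptor_frame()  # validates descriptor columns
    if not table.scored:
        raise SchemaError(f"table {table.name!r} has no 'kls' column to write")
    cols = ["id", *DESCRIPTOR_NAMES, "kls"]
    if "smiles" in table.df.columns:
        cols.append("smiles")
    table.df[cols].to_csv(path, index=False)


def write_exclusion_report(
    records: Sequence[MoleculeRecord], path: str | Path
) -> int:
    """Write (id, excluded_reason) rows for all flagged records; returns
    the number of exclusions written."""
    excluded = [r for r in records if r.excluded]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "excluded_reason"])
        for rec in excluded:
            writer.writerow([rec.id, rec.excluded_reason.value])
    return len(excluded)
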