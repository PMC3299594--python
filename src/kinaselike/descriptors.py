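"""The nine physicochemical descriptors underlying the kinase-likeness score.

Canonical order: Wt, RB, HBA, HBD, SlogP, TPSA, Rings, nN, nO.

Primitive property calculators come from RDKit (average-isotope molecular
weight, Wildman-Crippen SlogP, Ertl TPSA with S/P contributions, SSSR ring
count).  The rotatable-bond count is implemented here from its defining
rule — a bond counts if it (a) has bond order 1, (b) is not in a ring and
(c) has at least two heavy neighbours at each end — which differs from
RDKit's SMARTS definition (RDKit additionally excludes amide bonds).

One descriptor implementation must serve both profile fitting and scoring;
mixing descriptor sources between the two is a consistency error the caller
is responsible for avoiding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chem_io import LibraryTable, MoleculeRecord
from .constants import DESCRIPTOR_NAMES
from .errors import ContractViolationError

# Acceptor exclusions for the default (strict) HBA rule: pyrrole-type
# aromatic N-H, and amide/sulfonamide-type N bonded to C=O or S=O.
_PYRROLE_N = Chem.MolFromSmarts("[nH]")
_AMIDE_N = Chem.MolFromSmarts("[NX3][CX3]=[OX1]")
_SULFONAMIDE_N = Chem.MolFromSmarts("[NX3][SX4](=[OX1])")


@dataclass(frozen=True)
class DescriptorVector:
    """The nine descriptors of one compound, in canonical order."""

    Wt: float
    RB: int
    HBA: int
    HBD: int
    SlogP: float
    TPSA: float
    Rings: int
    nN: int
    nO: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in DESCRIPTOR_NAMES], dtype=float)

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "DescriptorVector":
        return cls(**{name: values[name] for name in DESCRIPTOR_NAMES})


def count_rotatable_bonds(mol: Chem.Mol) -> int:
    """Count bonds that are single, acyclic, and whose two endpoints each
    have at least two heavy-atom neighbours (terminal bonds excluded)."""
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        if a.GetDegree() >= 2 and b.GetDegree() >= 2:
            n += 1
    return n


def count_hb_donors(mol: Chem.Mol) -> int:
    """Lipinski-style donor count: heavy N or O atoms bearing >= 1 hydrogen."""
    return sum(
        1
        for atom in mol.GetAtoms()
        if atom.GetAtomicNum() in (7, 8) and atom.GetTotalNumHs() > 0
    )


def count_hb_acceptors(mol: Chem.Mol, strict: bool = True) -> int:
    """Acceptor count over N and O atoms.

    With ``strict=True`` (default) pyrrole-type N-H nitrogens and amide /
    sulfonamide nitrogens are excluded, since their lone pairs are
    delocalized and they accept poorly.  With ``strict=False`` every N and O
    counts (plain Lipinski rule).
    """
    candidates = {
        a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)
    }
    if strict:
        excluded: set[int] = set()
        for patt in (_PYRROLE_N, _AMIDE_N, _SULFONAMIDE_N):
            for match in mol.GetSubstructMatches(patt):
                excluded.add(match[0])
        candidates -= excluded
    return len(candidates)


def compute_descriptors(
    record: MoleculeRecord | Chem.Mol, *, strict_hba: bool = True
) -> DescriptorVector:
    """Compute the nine canonical descriptors for a preprocessed molecule.

    Raises ContractViolationError for a record flagged by preprocessing.
    Deterministic and invariant to atom ordering.
    """
    if isinstance(record, MoleculeRecord):
        if record.excluded:
            raise ContractViolationError(
                f"record {record.id!r} was excluded "
                f"({record.excluded_reason.value}) and cannot be scored"
            )
        mol = record.mol
    else:
        mol = record
    if mol is None:
        raise ContractViolationError("record has no parsed structure")
    return DescriptorVector(
        Wt=Descriptors.MolWt(mol),
        RB=count_rotatable_bonds(mol),
        HBA=count_hb_acceptors(mol, strict=strict_hba),
        HBD=count_hb_donors(mol),
        SlogP=Crippen.MolLogP(mol),
        TPSA=rdMolDescriptors.CalcTPSA(mol, includeSandP=True),
        Rings=rdMolDescriptors.CalcNumRings(mol),
        nN=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7),
        nO=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8),
    )


def descriptor_table(
    records: Iterable[MoleculeRecord],
    name: str = "",
    *,
    keep_smiles: bool = False,
    strict_hba: bool = True,
) -> LibraryTable:
    """Batch descriptor computation over non-excluded records.

    Excluded records are silently dropped (they are reported separately via
    the exclusion report); surviving rows keep input order.
    """
    rows = []
    for rec in records:
        if rec.excluded:
            continue
        vec = compute_descriptors(rec, strict_hba=strict_hba)
        row = {"id": rec.id, **{k: getattr(vec, k) for k in DESCRIPTOR_NAMES}}
        if keep_smiles:
            row["smiles"] = rec.smiles
        rows.append(row)
    df = pd.DataFrame(rows, columns=["id", *DESCRIPTOR_NAMES] + (["smiles"] if keep_smiles else []))
    return LibraryTable(df, name=name)
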