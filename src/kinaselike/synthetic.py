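"""Synthetic descriptor tables and hand-verifiable structure fixtures.

Real screening libraries (hundreds of thousands of structures) cannot ship
with the package, but their published per-descriptor summary statistics
can.  :func:`generate_descriptor_table` draws descriptor tables from
per-descriptor normal marginals — optionally coupled through a target
correlation matrix via a Gaussian copula-style multivariate normal — and
post-processes them the way real descriptor tables look: count descriptors
rounded to non-negative integers and molecular weight truncated to the
100-700 Da preprocessing window.

``TABLE1_MARGINALS`` carries the published means/SDs and sizes of the five
studied libraries (KBD kinase actives, NCI, NPD, MLSMR, WDI), so every
evaluation protocol in the package can be exercised at realistic parameter
settings without downloading anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import LibraryTable, MoleculeRecord, preprocess, read_molecules
from .constants import COUNT_DESCRIPTORS, DESCRIPTOR_NAMES, MAX_WEIGHT, MIN_WEIGHT
from .errors import ConfigurationError, SchemaError
from .scoring import CorrelationMatrix

# Published per-library descriptor means/SDs, canonical descriptor order:
# (Wt, RB, HBA, HBD, SlogP, TPSA, Rings, nN, nO).
TABLE1_MARGINALS: dict[str, dict] = {
    "KBD": {
        "n": 22615,
        "mean": {"Wt": 411, "RB": 6.1, "HBA": 3.7, "HBD": 1.9, "SlogP": 3.4,
                 "TPSA": 89, "Rings": 4.0, "nN": 4.3, "nO": 2.4},
        "sd": {"Wt": 96, "RB": 3.3, "HBA": 1.6, "HBD": 1.3, "SlogP": 1.8,
               "TPSA": 33, "Rings": 1.2, "nN": 1.8, "nO": 1.9},
    },
    "NCI": {
        "n": 264554,
        "mean": {"Wt": 305, "RB": 4.6, "HBA": 2.8, "HBD": 1.1, "SlogP": 2.0,
                 "TPSA": 72, "Rings": 2.5, "nN": 2.0, "nO": 3.0},
        "sd": {"Wt": 91, "RB": 3.2, "HBA": 1.9, "HBD": 1.3, "SlogP": 2.3,
               "TPSA": 42, "Rings": 1.4, "nN": 1.8, "nO": 2.1},
    },
    "NPD": {
        "n": 103668,
        "mean": {"Wt": 375, "RB": 5.3, "HBA": 3.2, "HBD": 1.1, "SlogP": 2.6,
                 "TPSA": 78, "Rings": 3.6, "nN": 2.1, "nO": 3.8},
        "sd": {"Wt": 86, "RB": 3.0, "HBA": 1.6, "HBD": 1.1, "SlogP": 2.0,
               "TPSA": 34, "Rings": 1.3, "nN": 1.6, "nO": 1.9},
    },
    "MLSMR": {
        "n": 343605,
        "mean": {"Wt": 362, "RB": 6.1, "HBA": 3.4, "HBD": 1.0, "SlogP": 2.8,
                 "TPSA": 77, "Rings": 3.0, "nN": 2.9, "nO": 3.0},
        "sd": {"Wt": 78, "RB": 2.6, "HBA": 1.5, "HBD": 0.9, "SlogP": 1.4,
               "TPSA": 28, "Rings": 1.0, "nN": 1.4, "nO": 1.7},
    },
    "WDI": {
        "n": 61368,
        "mean": {"Wt": 379, "RB": 5.9, "HBA": 3.6, "HBD": 1.7, "SlogP": 2.2,
                 "TPSA": 89, "Rings": 3.1, "nN": 1.9, "nO": 4.2},
        "sd": {"Wt": 138, "RB": 4.3, "HBA": 2.7, "HBD": 1.8, "SlogP": 2.7,
               "TPSA": 54, "Rings": 1.7, "nN": 1.9, "nO": 3.2},
    },
}


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic descriptor table.

    ``means``/``sds`` are per-descriptor normal marginals (canonical names);
    ``correlation`` optionally couples them; count descriptors are rounded
    to non-negative integers after sampling unless ``integer_rounding`` is
    disabled.
    """

    means: dict[str, float]
    sds: dict[str, float]
    n: int
    rng_seed: int
    correlation: CorrelationMatrix | None = None
    integer_rounding: bool = True
    label: str = "synthetic"

    @classmethod
    def from_table1(
        cls,
        library: str,
        n: int | None = None,
        rng_seed: int = 0,
        correlation: CorrelationMatrix | None = None,
        integer_rounding: bool = True,
    ) -> "GeneratorSpec":
        if library not in TABLE1_MARGINALS:
            raise ConfigurationError(
                f"unknown library {library!r}; choose from "
                f"{sorted(TABLE1_MARGINALS)}"
            )
        entry = TABLE1_MARGINALS[library]
        return cls(
            means=dict(entry["mean"]),
            sds=dict(entry["sd"]),
            n=n if n is not None else entry["n"],
            rng_seed=rng_seed,
            correlation=correlation,
            integer_rounding=integer_rounding,
            label=f"synthetic-{library}",
        )


def _psd_repair(corr: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to 0 and renormalize to unit diagonal.

    A symmetric matrix assembled from 2-decimal published entries is not
    guaranteed positive semi-definite; the repair is the nearest-PSD
    projection followed by rescaling back to a correlation matrix.
    """
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= -1e-10:
        return corr
    vals = np.clip(vals, 0.0, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def generate_descriptor_table(spec: GeneratorSpec) -> LibraryTable:
    """Draw a synthetic descriptor table from a GeneratorSpec.

    Samples n rows from N(mu, Sigma) where Sigma is diagonal (independent
    marginals) or induced from the target correlation matrix via Cholesky
    factorization (after PSD repair).  Count descriptors are rounded to the
    nearest non-negative integer; Wt is truncated to [100, 700] to mirror
    the preprocessing weight window.  Deterministic for a given seed.
    """
    missing = [d for d in DESCRIPTOR_NAMES if d not in spec.means or d not in spec.sds]
    if missing:
        raise SchemaError(f"generator spec missing marginals for {missing}")
    if spec.n <= 0:
        raise ConfigurationError(f"n must be positive, got {spec.n}")
    mu = np.array([spec.means[d] for d in DESCRIPTOR_NAMES], dtype=float)
    sd = np.array([spec.sds[d] for d in DESCRIPTOR_NAMES], dtype=float)
    if (sd <= 0).any():
        raise ConfigurationError("all marginal sds must be positive")

    rng = np.random.default_rng(spec.rng_seed)
    z = rng.standard_normal((spec.n, len(DESCRIPTOR_NAMES)))
    if spec.correlation is not None:
        corr = _psd_repair(spec.correlation.values)
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise SchemaError("target correlation matrix is not PSD")
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(DESCRIPTOR_NAMES)))
        z = z @ chol.T
    x = mu + sd * z

    df = pd.DataFrame(x, columns=list(DESCRIPTOR_NAMES))
    if spec.integer_rounding:
        for name in DESCRIPTOR_NAMES:
            if name in COUNT_DESCRIPTORS:
                df[name] = np.maximum(np.rint(df[name]), 0).astype(int)
    df["Wt"] = df["Wt"].clip(MIN_WEIGHT, MAX_WEIGHT)
    df.insert(0, "id", [f"{spec.label}-{i + 1}" for i in range(spec.n)])
    return LibraryTable(df, name=spec.label)


# (name, SMILES, expected preprocessing fate) for the hand-verifiable set.
_FIXTURE_SMILES: tuple[tuple[str, str, str], ...] = (
    ("benzene", "c1ccccc1", "weight_out_of_range"),  # 78 Da, below window
    ("pyridine", "c1ccncc1", "weight_out_of_range"),
    ("ethanol", "CCO", "weight_out_of_range"),
    ("n_butane", "CCCC", "weight_out_of_range"),
    ("cyclohexane", "C1CCCCC1", "weight_out_of_range"),
    ("methane", "C", "weight_out_of_range"),
    ("sodium_acetate", "CC(=O)[O-].[Na+]", "desalted"),  # acetate kept, still < 100 Da
    ("tetraethyllead", "CC[Pb](CC)(CC)CC", "metal"),
    ("hexacontane", "C" * 60, "weight_out_of_range"),  # ~844 Da, above window
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "kept"),
    ("sunitinib",
     "CCN(CC)CCNC(=O)c1c(C)[nH]c(/C=C2\\C(=O)Nc3ccc(F)cc32)c1C",
     "kept"),
    ("imatinib",
     "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1",
     "kept"),
)


def fixture_molecules() -> dict[str, MoleculeRecord]:
    """A named set of small, hand-countable molecules plus edge cases
    (salt, metal complex, out-of-window weights, two kinase drugs).

    Returned records are raw (pre-preprocessing); run them through
    :func:`kinaselike.chem_io.preprocess` to observe their documented fates.
    """
    from rdkit import Chem

    records = {}
    for name, smi, _fate in _FIXTURE_SMILES:
        records[name] = MoleculeRecord(name, Chem.MolFromSmiles(smi), source="fixture")
    return records


def fixture_expected_fates() -> dict[str, str]:
    """Documented preprocessing fate per fixture molecule: 'kept', 'metal',
    'weight_out_of_range' or 'desalted' (salt stripped, then weight rule
    applies to the surviving fragment)."""
    return {name: fate for name, smi, fate in _FIXTURE_SMILES}
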