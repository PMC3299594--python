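"""Canonical descriptor ordering and shared numeric constants.

Every table, profile, correlation matrix and score in this package indexes
the nine physicochemical descriptors in one fixed order.  Mixing orders is
a schema error, never a silent reindex.
"""

from __future__ import annotations

#: Canonical descriptor order: molecular weight, rotatable bonds,
#: H-bond acceptors, H-bond donors, Wildman-Crippen logP, topological polar
#: surface area, ring count, nitrogen count, oxygen count.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "Wt", "RB", "HBA", "HBD", "SlogP", "TPSA", "Rings", "nN", "nO",
)

N_DESCRIPTORS = len(DESCRIPTOR_NAMES)

#: Descriptors that are non-negative integer counts.
COUNT_DESCRIPTORS: frozenset[str] = frozenset(
    {"RB", "HBA", "HBD", "Rings", "nN", "nO"}
)

#: Number of unordered descriptor pairs, the normalizer of the
#: correlation-matrix library score (9 * 8 / 2).
N_PAIRS = N_DESCRIPTORS * (N_DESCRIPTORS - 1) // 2

#: Standard-normal 90th-percentile quantile, used to derive P10/P90 clamps
#: from (mean, sd) when empirical percentiles are not supplied.
Z90 = 1.2815515655446004

#: Elements regarded as organic for preprocessing; any other element marks
#: a structure as metal-containing and excludes it.
ORGANIC_ELEMENTS: frozenset[str] = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

#: Default molecular-weight window (daltons), inclusive at both ends.
MIN_WEIGHT = 100.0
MAX_WEIGHT = 700.0
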