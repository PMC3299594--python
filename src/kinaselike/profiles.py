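"""Per-descriptor Gaussian parameters (mu, sigma) and P10/P90 clamps.

A :class:`KinaseProfile` holds, for each of the nine descriptors, the mean
and standard deviation of a training population of kinase actives plus the
10th/90th percentile window used to zero out far-outlying descriptor
contributions.  Profiles are fitted from descriptor tables or loaded from
JSON; the published reference profile (22,615 ChEMBL kinase actives) ships
with the package.

When a profile source supplies only (mean, sd) — as the published summary
table does — the clamps default to the normal quantiles
``p10 = mu - 1.28155 sigma`` and ``p90 = mu + 1.28155 sigma`` (the training
distributions are approximately normal), floored at 0 for count
descriptors.  Exact empirical percentiles override this when present.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_io import LibraryTable
from .constants import COUNT_DESCRIPTORS, DESCRIPTOR_NAMES, Z90
from .errors import DegenerateProfileError, SchemaError

PROFILE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class DescriptorStats:
    """mu, sigma and the P10-P90 clamp window for one descriptor."""

    mean: float
    sd: float
    p10: float
    p90: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.mean, self.sd, self.p10, self.p90]).all():
            raise SchemaError("descriptor statistics must be finite")
        if self.sd <= 0:
            raise SchemaError(f"sd must be positive, got {self.sd}")


def _default_clamps(name: str, mean: float, sd: float) -> tuple[float, float]:
    p10 = mean - Z90 * sd
    p90 = mean + Z90 * sd
    if name in COUNT_DESCRIPTORS:
        p10 = max(p10, 0.0)
    return p10, p90


@dataclass(frozen=True)
class KinaseProfile:
    """Nine DescriptorStats in canonical order, with training provenance."""

    stats: dict[str, DescriptorStats]
    n_train: int
    label: str = ""

    def __post_init__(self) -> None:
        if tuple(self.stats) != DESCRIPTOR_NAMES:
            raise SchemaError(
                "profile must define exactly the nine canonical descriptors "
                f"in order {DESCRIPTOR_NAMES}, got {tuple(self.stats)}"
            )
        for name, st in self.stats.items():
            if not (st.p10 <= st.mean <= st.p90):
                warnings.warn(
                    f"profile {self.label!r}: mean of {name} lies outside "
                    f"its [p10, p90] window", stacklevel=2,
                )

    def __getattr__(self, name: str) -> DescriptorStats:
        if name in DESCRIPTOR_NAMES:
            return self.stats[name]
        raise AttributeError(name)

    def means(self) -> np.ndarray:
        return np.array([self.stats[n].mean for n in DESCRIPTOR_NAMES])

    def sds(self) -> np.ndarray:
        return np.array([self.stats[n].sd for n in DESCRIPTOR_NAMES])

    def p10s(self) -> np.ndarray:
        return np.array([self.stats[n].p10 for n in DESCRIPTOR_NAMES])

    def p90s(self) -> np.ndarray:
        return np.array([self.stats[n].p90 for n in DESCRIPTOR_NAMES])


def fit_profile(table: LibraryTable | pd.DataFrame, label: str = "") -> KinaseProfile:
    """Fit a profile from a descriptor table.

    mean = arithmetic mean, sd = sample standard deviation (n-1 denominator),
    p10/p90 = empirical percentiles with linear interpolation between order
    statistics.  A constant column makes the Gaussian term undefined and
    raises DegenerateProfileError.
    """
    df = table.descriptor_frame() if isinstance(table, LibraryTable) else table[list(DESCRIPTOR_NAMES)]
    if len(df) < 2:
        raise DegenerateProfileError("profile fitting needs at least 2 rows")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise SchemaError("descriptor table contains non-finite values")
    stats = {}
    for name in DESCRIPTOR_NAMES:
        col = df[name].to_numpy(dtype=float)
        sd = float(np.std(col, ddof=1))
        if sd == 0.0:
            raise DegenerateProfileError(
                f"descriptor {name!r} is constant; profile is degenerate"
            )
        stats[name] = DescriptorStats(
            mean=float(np.mean(col)),
            sd=sd,
            p10=float(np.percentile(col, 10)),
            p90=float(np.percentile(col, 90)),
        )
    return KinaseProfile(stats=stats, n_train=len(df), label=label)


def serialize_profile(profile: KinaseProfile) -> dict:
    """Profile -> JSON-ready dict (schema-versioned, lossless)."""
    return {
        "schema_version": PROFILE_SCHEMA_VERSION,
        "label": profile.label,
        "n_train": profile.n_train,
        "stats": {
            name: {"mean": st.mean, "sd": st.sd, "p10": st.p10, "p90": st.p90}
            for name, st in profile.stats.items()
        },
    }


def deserialize_profile(doc: dict) -> KinaseProfile:
    """JSON dict -> profile. p10/p90 may be omitted (or null) per descriptor,
    in which case the normal-quantile defaults are derived."""
    if not isinstance(doc, dict) or "stats" not in doc:
        raise SchemaError("profile document lacks a 'stats' section")
    version = doc.get("schema_version", PROFILE_SCHEMA_VERSION)
    if version != PROFILE_SCHEMA_VERSION:
        raise SchemaError(f"unsupported profile schema version {version!r}")
    stats = {}
    for name in DESCRIPTOR_NAMES:
        if name not in doc["stats"]:
            raise SchemaError(f"profile document is missing descriptor {name!r}")
        entry = doc["stats"][name]
        try:
            mean, sd = float(entry["mean"]), float(entry["sd"])
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"bad mean/sd for descriptor {name!r}") from exc
        p10, p90 = entry.get("p10"), entry.get("p90")
        if p10 is None or p90 is None:
            d10, d90 = _default_clamps(name, mean, sd)
            p10 = d10 if p10 is None else float(p10)
            p90 = d90 if p90 is None else float(p90)
        stats[name] = DescriptorStats(mean=mean, sd=sd, p10=float(p10), p90=float(p90))
    return KinaseProfile(
        stats=stats,
        n_train=int(doc.get("n_train", 0)),
        label=str(doc.get("label", "")),
    )


def save_profile(profile: KinaseProfile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(serialize_profile(profile), indent=2))


def load_profile(path: str | Path) -> KinaseProfile:
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read profile: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed profile JSON in {path}: {exc}") from exc
    return deserialize_profile(doc)


def kbd_reference_profile() -> KinaseProfile:
    """The built-in reference profile of 22,615 known kinase actives.

    Means and standard deviations are the published summary statistics of
    the kinase binding database (KBD); P10/P90 clamps are the derived
    normal quantiles since the empirical percentiles were not published.
    """
    doc = json.loads(
        resources.files("kinaselike.data").joinpath("kbd_table1.json").read_text()
    )
    return deserialize_profile(doc)
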