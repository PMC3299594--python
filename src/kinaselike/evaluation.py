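"""Seeded-ROC evaluation of library kinase-likeness, plus the statistical
comparisons used alongside it.

The seeding protocol: draw a small fraction (default 1%) of known kinase
actives, spike them into a candidate library, rank the union by KLS
descending, and measure the ROC AUC with the spiked actives as positives.
Repeat (default 10x) and summarize.  An AUC near 0.5 means the score cannot
tell the library from the actives — the library is kinase-like; an AUC near
1 means the library occupies a different region of property space.

AUC is the Mann-Whitney rank statistic, P(score_pos > score_neg) + 1/2
P(tie), so it is independent of which ROC axis convention is drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .chem_io import LibraryTable
from .constants import DESCRIPTOR_NAMES
from .errors import ConfigurationError, DegenerateProfileError, UndefinedAUCError

__all__ = [
    "SeedingResult",
    "roc_auc",
    "seeding_experiment",
    "compare_descriptor_distributions",
    "compare_auc_distributions",
    "ks_compare_kls",
]


@dataclass
class SeedingResult:
    """Per-repeat AUCs and summaries from one seeding experiment."""

    per_repeat_auc: list[float]
    mean_auc: float
    min_auc: float
    max_auc: float
    n_repeats: int
    seed_fraction: float
    n_seeded: int
    rng_seed: int
    curves: list[tuple[np.ndarray, np.ndarray]] | None = None

    def summary(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "min_auc": self.min_auc,
            "max_auc": self.max_auc,
            "n_repeats": self.n_repeats,
            "seed_fraction": self.seed_fraction,
            "n_seeded": self.n_seeded,
            "rng_seed": self.rng_seed,
        }


def roc_auc(scores, labels) -> float:
    """ROC AUC with half-credit for ties (the Mann-Whitney convention).

    ``labels`` are binary with 1 = positive. Raises UndefinedAUCError when
    only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ConfigurationError("scores and labels must have equal length")
    classes = np.unique(labels)
    if classes.size != 2:
        raise UndefinedAUCError(
            f"AUC needs both classes present, got labels {classes.tolist()}"
        )
    return float(roc_auc_score(labels, scores))


def seeding_experiment(
    library: LibraryTable,
    actives: LibraryTable,
    fraction: float = 0.01,
    n_repeats: int = 10,
    rng_seed: int = 0,
    keep_curves: bool = False,
) -> SeedingResult:
    """Spike-in ROC evaluation of a scored library against scored actives.

    Per repeat, ceil(fraction * |actives|) actives are sampled without
    replacement, labelled positive against the whole library (labelled
    negative), and the union is ranked by KLS.  Per-repeat RNG streams are
    spawned from one master seed, so results are reproducible and repeats
    are independent.
    """
    if not (0 < fraction <= 1):
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    if len(actives) == 0:
        raise ConfigurationError("actives table is empty")
    if not library.scored or not actives.scored:
        raise ConfigurationError("both tables must carry a 'kls' column")
    n_seed = math.ceil(fraction * len(actives))
    if n_seed == 0:
        raise ConfigurationError("fraction yields zero seeded actives")

    lib_scores = library.df["kls"].to_numpy(dtype=float)
    act_scores = actives.df["kls"].to_numpy(dtype=float)
    streams = np.random.SeedSequence(rng_seed).spawn(n_repeats)
    aucs: list[float] = []
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        picked = rng.choice(len(act_scores), size=n_seed, replace=False)
        scores = np.concatenate([act_scores[picked], lib_scores])
        labels = np.concatenate(
            [np.ones(n_seed, dtype=int), np.zeros(len(lib_scores), dtype=int)]
        )
        aucs.append(roc_auc(scores, labels))
        if keep_curves:
            fpr, tpr, _ = roc_curve(labels, scores)
            curves.append((fpr, tpr))
    return SeedingResult(
        per_repeat_auc=aucs,
        mean_auc=float(np.mean(aucs)),
        min_auc=float(np.min(aucs)),
        max_auc=float(np.max(aucs)),
        n_repeats=n_repeats,
        seed_fraction=fraction,
        n_seeded=n_seed,
        rng_seed=rng_seed,
        curves=curves if keep_curves else None,
    )


def compare_descriptor_distributions(
    table_a: LibraryTable, table_b: LibraryTable
) -> pd.Series:
    """Two-sided two-sample Student's t-test per descriptor column.

    Returns a Series of p-values indexed by descriptor name.  A column that
    is constant in both tables has an undefined t statistic and raises for
    that descriptor only (reported, not silently NaN).
    """
    pvals = {}
    a = table_a.descriptor_frame()
    b = table_b.descriptor_frame()
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("each table needs at least 2 rows")
    for name in DESCRIPTOR_NAMES:
        x, y = a[name].to_numpy(dtype=float), b[name].to_numpy(dtype=float)
        if np.std(x) == 0 and np.std(y) == 0 and x.mean() == y.mean():
            raise DegenerateProfileError(
                f"descriptor {name!r} is constant in both tables; "
                "t-test undefined"
            )
        t = stats.ttest_ind(x, y, equal_var=True)
        pvals[name] = float(t.pvalue)
    return pd.Series(pvals)


def compare_auc_distributions(aucs_a, aucs_b) -> float:
    """Two-sided two-sample Student's t-test on per-repeat AUC lists."""
    a, b = np.asarray(aucs_a, dtype=float), np.asarray(aucs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("need at least 2 AUC values per group")
    if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def ks_compare_kls(kls_a, kls_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of two KLS distributions.

    Returns (k statistic, asymptotic p-value) where k = sup |ECDF_A - ECDF_B|.
    """
    a, b = np.asarray(kls_a, dtype=float), np.asarray(kls_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("KS test needs non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
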