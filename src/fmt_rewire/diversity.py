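"""Alpha-diversity estimators and two-group comparison.

Indices reported: observed richness, bias-corrected Chao1, ACE (Chao & Lee),
Shannon entropy in nats, and the Simpson index in its *dominance* form
D = sum(p_i^2). The dominance form is used because lower diversity pairs
with a *higher* Simpson value in dysbiotic communities; the complement 1-D
is exposed as well. Computation delegates to scikit-bio's alpha-diversity
implementations.

Group comparison uses the two-sided Mann-Whitney U test, exact for small
tie-free samples and normal-approximated with tie correction otherwise.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import alpha as _alpha

from .containers import FeatureTable

DEFAULT_RARE_CUTOFF = 10
DEFAULT_LIBRARY_SIZE = 50_000


def _as_counts(v) -> np.ndarray:
    a = np.asarray(v)
    if a.ndim != 1:
        raise ValueError("count vector must be one-dimensional")
    if (a < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(a, np.round(a)):
        raise ValueError("counts must be integers")
    if a.sum() == 0:
        raise ValueError("all-zero count vector")
    return np.round(a).astype(np.int64)


def observed_richness(v) -> int:
    """Number of features with count > 0."""
    return int(_alpha.sobs(_as_counts(v)))


def chao1(v) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    return float(_alpha.chao1(_as_counts(v), bias_corrected=True))


def ace(v, rare_cutoff: int = DEFAULT_RARE_CUTOFF) -> float:
    """ACE richness (Chao & Lee), rare class = counts <= ``rare_cutoff``.

    When the sample-coverage estimate is zero (every rare individual is a
    singleton) the estimator is undefined and the bias-corrected Chao1 value
    is returned instead.
    """
    counts = _as_counts(v)
    rare = counts[(counts > 0) & (counts <= rare_cutoff)]
    if rare.size and (rare == 1).all():
        return chao1(counts)
    return float(_alpha.ace(counts, rare_threshold=rare_cutoff))


def shannon(v) -> float:
    """Shannon entropy -sum(p ln p) in nats."""
    return float(_alpha.shannon(_as_counts(v), base=np.e))


def simpson(v) -> float:
    """Simpson dominance D = sum(p_i^2); 1 is a single-feature community."""
    return float(_alpha.dominance(_as_counts(v)))


def simpson_complement(v) -> float:
    """Gini-Simpson diversity 1 - D."""
    return 1.0 - simpson(v)


def compare_diversity(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for two groups of index values.

    Returns ``(U statistic for A-vs-B, p-value)``; p is from exhaustive
    enumeration when both groups have <= 8 tie-free values, otherwise from
    the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    if a.size <= 8 and b.size <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def relative_to_counts(table: FeatureTable, library_size: int = DEFAULT_LIBRARY_SIZE) -> pd.DataFrame:
    """Pseudo-count rescaling of a relative-abundance table.

    Diversity indices are defined on counts; when only relative abundances
    exist, each sample is rescaled by a nominal library size and rounded.
    Features whose abundance falls below 0.5/library_size therefore drop to
    zero, emulating finite sequencing depth.
    """
    if table.feature_class != "taxon":
        raise ValueError("pseudo-count rescaling applies to taxon tables")
    return (table.values * library_size).round().astype(np.int64)


def diversity_table(counts: pd.DataFrame, rare_cutoff: int = DEFAULT_RARE_CUTOFF) -> pd.DataFrame:
    """Per-sample diversity summary (rows = samples).

    Columns: observed, chao1, ace, shannon, simpson_D.
    """
    rows = {}
    for sid, v in counts.iterrows():
        c = v.to_numpy()
        rows[sid] = {
            "observed": observed_richness(c),
            "chao1": chao1(c),
            "ace": ace(c, rare_cutoff),
            "shannon": shannon(c),
            "simpson_D": simpson(c),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def mannwhitney_exact_p(a, b) -> float:
    """Brute-force two-sided Mann-Whitney p by enumerating all labelings.

    Reference implementation for small groups (C(nA+nB, nA) labelings);
    intended for validation, not production use.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na = a.size

    def u_stat(x, y):
        # mid-rank U via pairwise comparison (tie-aware)
        gt = (x[:, None] > y[None, :]).sum()
        eq = (x[:, None] == y[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_stat(a, b)
    mu = na * b.size / 2.0
    d_obs = abs(u_obs - mu)
    total = 0
    hits = 0
    for pick in combinations(range(pooled.size), na):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(pick)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / total
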