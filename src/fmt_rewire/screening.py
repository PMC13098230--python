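"""Three-criterion screen for FMT-response-associated features.

A feature (taxon or metabolite) is called response-associated when it

1. is differentially abundant between patient baselines and donors
   (Benjamini-Hochberg q < alpha),
2. shifts to donor levels in responders post-treatment (non-significant vs
   donors AND the responder-post group mean lies on the donor side of the
   baseline mean), and
3. persists at baseline levels in non-responders post-treatment
   (non-significant vs baseline).

Criterion (2)'s directionality guard exists because non-significance alone
is also satisfied by high-variance features; criterion (3) follows the
literal "persistence" reading (non-significance vs baseline), with a
stricter still-different-from-donor variant available via
``crit3_vs_donor=True``.

Default tests: Mann-Whitney for taxa (compositional, zero-inflated),
Welch t-test on log-transformed values for metabolites. FDR is controlled
within feature class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable, SampleMetadata

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_PREVALENCE = 0.6

_LOG_FLOOR = 1e-12


@dataclass
class ScreenResult:
    """Per-feature screening statistics and criterion flags.

    ``table`` columns: p_baseline_vs_donor, q_baseline_vs_donor,
    p_resp_post_vs_donor, p_nonresp_post_vs_baseline, crit1, crit2, crit3,
    selected, direction.
    """

    table: pd.DataFrame
    feature_class: str
    alpha: float
    crit3_vacuous: bool = False

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature_id")


def differential_abundance(
    table: FeatureTable,
    group_a,
    group_b,
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Per-feature two-sided test between two disjoint sample groups.

    ``test`` is ``mannwhitney`` or ``ttest`` (Welch, on log-transformed
    values). Features constant across both groups get p = 1 and are flagged
    in the ``constant`` column.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("sample groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if test not in ("mannwhitney", "ttest"):
        raise ValueError(f"unknown test {test!r}")

    a = table.values.loc[group_a].to_numpy(dtype=float)
    b = table.values.loc[group_b].to_numpy(dtype=float)
    if test == "ttest":
        a = np.log(a + _LOG_FLOOR)
        b = np.log(b + _LOG_FLOOR)

    stats_out = np.empty(table.n_features)
    pvals = np.ones(table.n_features)
    constant = np.zeros(table.n_features, dtype=bool)
    for j in range(table.n_features):
        x, y = a[:, j], b[:, j]
        if np.ptp(np.concatenate([x, y])) == 0:
            constant[j] = True
            stats_out[j] = np.nan
            continue
        if test == "mannwhitney":
            both_small = len(x) <= 8 and len(y) <= 8
            ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            method = "exact" if both_small and not ties else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        else:
            res = stats.ttest_ind(x, y, equal_var=False)
        stats_out[j] = res.statistic
        pvals[j] = res.pvalue
    return pd.DataFrame(
        {"statistic": stats_out, "p": pvals, "constant": constant},
        index=table.feature_ids,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1, in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def prevalence_filter(
    table: FeatureTable, min_prevalence: float = DEFAULT_MIN_PREVALENCE
) -> FeatureTable:
    """Keep features with a nonzero value in >= ``min_prevalence`` of samples."""
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    prev = (table.values > 0).mean(axis=0)
    keep = prev[prev >= min_prevalence].index
    return FeatureTable(table.values[list(keep)], table.feature_class)


def screen_response_features(
    table: FeatureTable,
    meta: SampleMetadata,
    alpha: float = DEFAULT_ALPHA,
    test: str | None = None,
    crit3_vs_donor: bool = False,
) -> ScreenResult:
    """Apply the three-criterion response screen to one feature table.

    ``test`` defaults to Mann-Whitney for taxa and a log-scale t-test for
    metabolites/clinical tables. If the cohort has no non-responders,
    criterion (3) is vacuously true and the result is flagged.
    """
    if test is None:
        test = "mannwhitney" if table.feature_class == "taxon" else "ttest"
    donors = meta.donor_samples()
    baseline = meta.baseline_samples()
    resp_post = meta.post_samples("R")
    nonresp_post = meta.post_samples("NR")
    for name, grp in (("donor", donors), ("baseline", baseline), ("responder-post", resp_post)):
        if len(grp) < 2:
            raise ValueError(f"stratum {name!r} has fewer than 2 samples")

    d1 = differential_abundance(table, baseline, donors, test=test)
    q1 = bh_adjust(d1["p"].to_numpy())
    d2 = differential_abundance(table, resp_post, donors, test=test)

    crit3_vacuous = len(nonresp_post) < 2
    if crit3_vacuous:
        p3 = np.ones(table.n_features)
    else:
        p3 = differential_abundance(table, nonresp_post, baseline, test=test)["p"].to_numpy()

    vals = table.values
    mean_donor = vals.loc[donors].mean(axis=0).to_numpy()
    mean_base = vals.loc[baseline].mean(axis=0).to_numpy()
    mean_resp = vals.loc[resp_post].mean(axis=0).to_numpy()
    med_diff = (
        vals.loc[baseline].median(axis=0) - vals.loc[donors].median(axis=0)
    ).to_numpy()

    crit1 = q1 < alpha
    # donor side: responder-post mean moved from the baseline mean toward the
    # donor mean (overshoot beyond the donor mean still counts)
    toward_donor = (mean_resp - mean_base) * (mean_donor - mean_base) > 0
    crit2 = (d2["p"].to_numpy() >= alpha) & toward_donor
    if crit3_vs_donor and not crit3_vacuous:
        p3_eff = differential_abundance(table, nonresp_post, donors, test=test)["p"].to_numpy()
        crit3 = p3_eff < alpha  # still significantly different from donors
    else:
        crit3 = p3 >= alpha

    out = pd.DataFrame(
        {
            "p_baseline_vs_donor": d1["p"].to_numpy(),
            "q_baseline_vs_donor": q1,
            "p_resp_post_vs_donor": d2["p"].to_numpy(),
            "p_nonresp_post_vs_baseline": p3,
            "crit1": crit1,
            "crit2": crit2,
            "crit3": crit3,
            "selected": crit1 & crit2 & crit3,
            "direction": np.where(med_diff >= 0, "enriched_baseline", "depleted_baseline"),
            "constant": d1["constant"].to_numpy(),
        },
        index=table.feature_ids,
    )
    return ScreenResult(out, table.feature_class, alpha, crit3_vacuous)
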