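"""Cross-assay comparison of dominance measures.

Two complementary views: (1) Pearson correlation matrices of final
dominance scores (Elo or David's) across assays, computed per animal
group/strain with pairwise-complete observations; (2) for dyads whose
hierarchy is stable in two assays, whether the same animal is dominant
in both (maintained) or the direction flips (reversed) — the signature
used to show that one assay can measure something different from the
others in a given strain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from domsuite.errors import ValidationError
from domsuite.ranking import DyadStatus, Stability
from domsuite.records_io import Assay


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r matrix over assays with matching p-values and n."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def score_correlation_matrix(
    panel: pd.DataFrame,
    group: str | None = None,
    group_col: str = "group",
    min_n: int = 3,
) -> CorrelationMatrix:
    """Pearson correlations of per-animal scores across assays.

    ``panel`` is long-format: columns animal, assay, score, and optionally
    a group column for stratification. Each animal appears at most once
    per assay; missing animals are handled pairwise-complete. Entries with
    fewer than ``min_n`` complete pairs are NaN (flagged via the n
    matrix), never silently computed.
    """
    required = {"animal", "assay", "score"}
    if not required <= set(panel.columns):
        raise ValidationError(f"panel must have columns {sorted(required)}")
    if group is not None:
        panel = panel[panel[group_col] == group]
    dup = panel.duplicated(subset=["animal", "assay"])
    if dup.any():
        raise ValidationError("an animal appears more than once in one assay")
    wide = panel.pivot(index="animal", columns="assay", values="score")
    assays = list(wide.columns)
    r = pd.DataFrame(np.eye(len(assays)), index=assays, columns=assays)
    p = pd.DataFrame(np.zeros((len(assays), len(assays))), index=assays, columns=assays)
    n = pd.DataFrame(0, index=assays, columns=assays)
    for a in assays:
        n.loc[a, a] = wide[a].notna().sum()
    for a1, a2 in itertools.combinations(assays, 2):
        pair = wide[[a1, a2]].dropna()
        n.loc[a1, a2] = n.loc[a2, a1] = len(pair)
        if len(pair) < min_n:
            r.loc[a1, a2] = r.loc[a2, a1] = np.nan
            p.loc[a1, a2] = p.loc[a2, a1] = np.nan
            continue
        res = stats.pearsonr(pair[a1], pair[a2])
        r.loc[a1, a2] = r.loc[a2, a1] = res.statistic
        p.loc[a1, a2] = p.loc[a2, a1] = res.pvalue
    return CorrelationMatrix(r=r, p=p, n=n)


def holm_bonferroni(pvals: pd.Series) -> pd.Series:
    """Holm–Bonferroni adjustment (delegated to statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    mask = pvals.notna()
    adj = pvals.copy()
    if mask.any():
        adj[mask] = multipletests(pvals[mask], method="holm")[1]
    return adj


@dataclass
class ReversalSummary:
    """Maintained vs reversed counts over dyads stable in both assays."""

    assay_1: Assay
    assay_2: Assay
    maintained: int
    reversed: int
    maintained_pairs: list[tuple[str, str]]
    reversed_pairs: list[tuple[str, str]]
    excluded: int  # dyads stable in at most one assay

    @property
    def stable_in_both(self) -> int:
        return self.maintained + self.reversed


def rank_reversals(
    stability_1: list[DyadStatus], stability_2: list[DyadStatus]
) -> ReversalSummary:
    """Compare dominance direction across two assays for stable dyads.

    A dyad counts only if classified stable in both assays; it is
    maintained iff the same animal is dominant in both, reversed
    otherwise. Dyads stable in one or neither assay are excluded (counted
    separately), never folded into either bucket.
    """
    a1 = {frozenset((d.id_a, d.id_b)): d for d in stability_1}
    a2 = {frozenset((d.id_a, d.id_b)): d for d in stability_2}
    assay_1 = stability_1[0].assay if stability_1 else None
    assay_2 = stability_2[0].assay if stability_2 else None
    maintained, rev = [], []
    excluded = 0
    for pair in sorted(set(a1) | set(a2), key=sorted):
        d1, d2 = a1.get(pair), a2.get(pair)
        if (
            d1 is None
            or d2 is None
            or d1.status is not Stability.STABLE
            or d2.status is not Stability.STABLE
        ):
            excluded += 1
            continue
        key = tuple(sorted(pair))
        if d1.dominant_id == d2.dominant_id:
            maintained.append(key)
        else:
            rev.append(key)
    return ReversalSummary(
        assay_1=assay_1,
        assay_2=assay_2,
        maintained=len(maintained),
        reversed=len(rev),
        maintained_pairs=maintained,
        reversed_pairs=rev,
        excluded=excluded,
    )


def reversal_fisher_test(s_group1: ReversalSummary, s_group2: ReversalSummary) -> float:
    """Fisher's exact p-value comparing reversal proportions of two groups
    (plumbing over scipy)."""
    table = [
        [s_group1.maintained, s_group1.reversed],
        [s_group2.maintained, s_group2.reversed],
    ]
    return float(stats.fisher_exact(table).pvalue)
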