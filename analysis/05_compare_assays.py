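"""Compare dominance measures across assays within each cohort.

Builds per-cohort score panels from 02, computes Pearson correlation
matrices of Elo (and David's) scores across assays, and counts
maintained vs reversed relative ranks among dyads stable in both assays
of each pair. In the straight cohort every assay should correlate
positively with every other; in the tube-inverted cohort the tube row
should be negative and tube-involving pairs should reverse.

Writes results/elo_corr_<cohort>.csv, david_corr_<cohort>.csv,
reversals_<cohort>.csv.
"""

import itertools
from pathlib import Path

import pandas as pd

from domsuite.cross_assay import rank_reversals, score_correlation_matrix
from domsuite.ranking import DyadStatus, Stability, classify_dyad_stability, dyads, group_matches
from domsuite.records_io import Assay, read_matches

OUT = Path("results")

for cohort in ("c57", "cd1"):
    elo = pd.read_csv(OUT / f"elo_{cohort}.csv")
    panel = elo.rename(columns={"elo": "score"})[["animal", "assay", "score"]]
    corr = score_correlation_matrix(panel)
    corr.r.to_csv(OUT / f"elo_corr_{cohort}.csv")

    david = pd.read_csv(OUT / f"david_{cohort}.csv")
    dpanel = david.rename(columns={"ds": "score"})[["animal", "assay", "score"]]
    dcorr = score_correlation_matrix(dpanel)
    dcorr.r.to_csv(OUT / f"david_corr_{cohort}.csv")

    matches = read_matches(OUT / f"matches_{cohort}.csv")
    statuses: dict[Assay, list[DyadStatus]] = {}
    for (assay, _), grp in group_matches(matches).items():
        for _, dyad_matches in dyads(grp).items():
            statuses.setdefault(assay, []).append(
                classify_dyad_stability(dyad_matches, assay)
            )
    rows = []
    for a1, a2 in itertools.combinations(sorted(statuses, key=lambda a: a.value), 2):
        s = rank_reversals(statuses[a1], statuses[a2])
        rows.append(
            {"assay_1": a1.value, "assay_2": a2.value, "maintained": s.maintained,
             "reversed": s.reversed, "excluded": s.excluded}
        )
    rev = pd.DataFrame(rows)
    rev.to_csv(OUT / f"reversals_{cohort}.csv", index=False)

    print(f"\n== {cohort} ==")
    print("Elo correlation matrix across assays:")
    print(corr.r.round(3).to_string())
    tube_pairs = rev[(rev["assay_1"] == "tube") | (rev["assay_2"] == "tube")]
    frac = tube_pairs["reversed"].sum() / max(
        (tube_pairs["reversed"] + tube_pairs["maintained"]).sum(), 1
    )
    print(f"reversal fraction in tube-involving stable pairs: {frac:.2f}")
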