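"""Score every cage in every assay: Elo, David's score, DCI, stability.

Reads the cohort match tables from 01, writes per-animal score panels,
per-cage DCI values and per-dyad stability classifications, and prints a
summary. Elo and David's scores should agree on cage orderings; the
reward-competition assay (fewer trials, many ties) is expected to show
the weakest directional consistency.
"""

from pathlib import Path

import pandas as pd

from domsuite.pipeline import score_all
from domsuite.records_io import read_matches

OUT = Path("results")

for cohort in ("c57", "cd1"):
    matches = read_matches(OUT / f"matches_{cohort}.csv")
    elo, david, dci_table, stability, _ = score_all(matches)
    elo["cohort"] = cohort
    elo.to_csv(OUT / f"elo_{cohort}.csv", index=False)
    david.to_csv(OUT / f"david_{cohort}.csv", index=False)
    dci_table.to_csv(OUT / f"dci_{cohort}.csv", index=False)
    stability.to_csv(OUT / f"stability_{cohort}.csv", index=False)

    print(f"\n== {cohort} ==")
    print("mean DCI by assay:")
    print(dci_table.groupby("assay")["dci"].mean().round(3).to_string())
    frac_stable = (
        stability.groupby("assay")["status"]
        .apply(lambda s: (s == "stable").mean())
        .round(3)
    )
    print("fraction of dyads stable by assay:")
    print(frac_stable.to_string())
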