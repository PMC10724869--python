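"""Image-quality robustness of the male/female index differences.

For each of the five image-quality metrics, selects the 80 lowest and 80
highest subjects per sex (35 for EFC, whose female distribution is much
tighter), then runs the ROI-paired male-vs-female t-test within each
subsample for every (index, measure).  An index whose difference survives
at both quality extremes is a robust marker.
"""

from pathlib import Path

import pandas as pd

from asymkit.indices import INDEX_KINDS, IndexTable
from asymkit.io import MEASURES, read_participants, read_quality, write_table
from asymkit.robustness import classify_outcome, robustness_ttests

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "robustness"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    meta = read_participants(ROOT / "cohort" / "participants.tsv")
    quality = read_quality(ROOT / "cohort" / "iqm.tsv", meta)
    tables = [
        IndexTable(kind, measure,
                   pd.read_csv(ROOT / "indices" / f"index_{kind}_{measure}.csv",
                               index_col=0))
        for measure in MEASURES for kind in INDEX_KINDS
    ]
    report = robustness_ttests(tables, meta, quality, n_per_level=80,
                               overrides={"EFC": 35}, mismatch_tol=1.0)
    verdicts = classify_outcome(report)
    write_table(report, OUT / "report.csv", index_label="row")
    write_table(verdicts, OUT / "verdicts.csv", index_label="row")

    tier_grid = report.pivot_table(index=["index", "measure"],
                                   columns=["metric", "level"], values="tier",
                                   aggfunc="first")
    print(tier_grid.to_string())
    frac = report.groupby("index")["p_value"].apply(lambda p: (p < 0.05).mean())
    print("\nfraction of significant t-tests per index:")
    print((frac * 100).round(1).to_string())
    print(f"\nverdict counts:\n{verdicts.groupby(['index', 'verdict']).size().to_string()}")


if __name__ == "__main__":
    main()
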