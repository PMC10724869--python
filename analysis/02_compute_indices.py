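"""Compute the three asymmetry indices for every subject and measure.

Reads the simulated cohort's long morphometry tables back through the
validating reader (exercising the same path real FreeSurfer exports would
take) and writes one subjects-by-34 CSV per (index, measure) pair, twelve
tables in all, plus a QC summary of undefined entries.
"""

from pathlib import Path

import pandas as pd

from asymkit.indices import compute_index_tables
from asymkit.io import MEASURES, read_morphometry, write_table

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "indices"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    qc_rows = []
    for measure in MEASURES:
        morph = read_morphometry(ROOT / "cohort" / f"morphometry_{measure}_long.csv",
                                 measure)
        for kind, table in compute_index_tables(morph).items():
            write_table(table.values, OUT / f"index_{kind}_{measure}.csv")
            qc_rows.append({"index": kind, "measure": measure, **table.qc})
    qc = pd.DataFrame(qc_rows)
    write_table(qc, OUT / "index_qc.csv", index_label="row")
    print(qc.to_string(index=False))
    print(f"\nwrote {len(qc)} index tables to {OUT}; "
          f"{qc.n_undefined.sum()} undefined entries in total")


if __name__ == "__main__":
    main()
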