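#!/usr/bin/env python
"""Map the selected CoMSIA model back onto the lattice as contour grids.

Refits the best field combination found by 03_fit_models.py, computes the
coeff*stddev map for each of its fields, thresholds at the 80%/20% levels,
exports OpenDX grids under scratch/contours/ and writes a per-field
summary (thresholds, contour point counts, strongest hotspots) under
results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from fieldqsar import chem_io, contours, field_engine, qsar_stats

ROOT = Path(__file__).resolve().parent.parent
SHORT = {"S": "CoMSIA_S", "E": "CoMSIA_E", "H": "CoMSIA_H",
         "D": "CoMSIA_D", "A": "CoMSIA_A"}


def main() -> int:
    search_path = ROOT / "results" / "03_comsia_search.csv"
    if not search_path.exists():
        sys.exit("run 03_fit_models.py first")
    best_label = pd.read_csv(search_path).iloc[0]["fields"]
    kinds = [SHORT[s] for s in best_label.split("+")]

    blocks = field_engine.load_field_blocks(ROOT / "scratch" / "fields.npz")
    table = chem_io.read_activities(
        ROOT / "scratch" / "synthetic" / "activities.csv"
    ).set_index("id")
    ids = blocks[0].mol_ids
    y = np.array([table.loc[i, "pIC50"] for i in ids])
    split = np.array([table.loc[i, "split"] for i in ids])

    chosen = [b for b in blocks if b.field_kind in kinds]
    M = qsar_stats.assemble_matrix(chosen, y, split_labels=split)
    opn, _ = qsar_stats.select_opn(M, 10)
    model = qsar_stats.pls_fit(M, opn)

    out = ROOT / "scratch" / "contours"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for kind in kinds:
        cmap = contours.contour_levels(
            contours.stdev_coeff_map(model, M, kind), 0.80, 0.20
        )
        contours.export_grid(cmap, str(out / f"{kind}.dx"))
        hot = int(np.argmax(np.abs(cmap.values)))
        rows.append(
            {
                "field": kind,
                "favored_threshold": float(cmap.favored_threshold),
                "disfavored_threshold": float(cmap.disfavored_threshold),
                "favored_points": int(cmap.favored_mask.sum()),
                "disfavored_points": int(cmap.disfavored_mask.sum()),
                "strongest_point_index": hot,
                "strongest_value": float(cmap.values[hot]),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(ROOT / "results" / "04_contour_summary.csv", index=False)
    print(f"best subset {best_label} refit at OPN={opn}")
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3e}"))
    print("\nOpenDX grids -> scratch/contours/; "
          "summary -> results/04_contour_summary.csv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
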