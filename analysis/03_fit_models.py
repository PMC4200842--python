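#!/usr/bin/env python
"""Fit the CoMFA model and search all 31 CoMSIA field combinations.

Loads the field container from 02_fields.py and the activity table from
01_simulate.py, fits the steric+electrostatic CoMFA model, then evaluates
every non-empty subset of the five CoMSIA fields with LOO-selected
component counts, ranking by Q².  Writes the ranked table and the selected
model's statistics under results/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from fieldqsar import chem_io, field_engine, qsar_stats

ROOT = Path(__file__).resolve().parent.parent


def main() -> int:
    fields_path = ROOT / "scratch" / "fields.npz"
    acts_path = ROOT / "scratch" / "synthetic" / "activities.csv"
    if not fields_path.exists() or not acts_path.exists():
        sys.exit("run 01_simulate.py and 02_fields.py first")
    blocks = field_engine.load_field_blocks(fields_path)
    table = chem_io.read_activities(acts_path).set_index("id")
    ids = blocks[0].mol_ids
    y = np.array([table.loc[i, "pIC50"] for i in ids])
    split = np.array([table.loc[i, "split"] for i in ids])

    comfa = [b for b in blocks if b.field_kind in field_engine.COMFA_KINDS]
    M = qsar_stats.assemble_matrix(comfa, y, split_labels=split)
    opn, _ = qsar_stats.select_opn(M, 10)
    comfa_stats = qsar_stats.final_stats(qsar_stats.pls_fit(M, opn), M)
    print(f"CoMFA S+E: OPN={comfa_stats.opn}  Q2={comfa_stats.q2:.3f}  "
          f"R2_ncv={comfa_stats.r2_ncv:.3f}  SEE={comfa_stats.see:.3f}")

    comsia = [b for b in blocks if b.field_kind in field_engine.COMSIA_KINDS]
    ranked, fitted = qsar_stats.model_search(
        comsia, y, split_labels=split, max_components=10
    )
    best_label = ranked.iloc[0]["fields"]
    _m, _M, best = fitted[best_label]
    print(f"\n31 CoMSIA combinations evaluated; best subset: {best_label}")
    print(ranked.head(10).to_string(index=False,
                                    float_format=lambda v: f"{v:.3f}"))
    print(f"\nselected model: Q2={best.q2:.3f}  R2_ncv={best.r2_ncv:.3f}  "
          f"R2_pred={best.r2_pred:.3f}  SEE={best.see:.3f}  OPN={best.opn}")
    print("contributions: "
          + ", ".join(f"{k.split('_')[-1]}={100 * v:.1f}%"
                      for k, v in best.contributions.items()))

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    ranked.to_csv(results / "03_comsia_search.csv", index=False)
    report = {
        "CoMFA:S+E": comfa_stats.as_dict(),
        f"CoMSIA:{best_label}": best.as_dict(),
        "n_subsets": int(len(ranked)),
    }
    (results / "03_model_stats.json").write_text(json.dumps(report, indent=1,
                                                            sort_keys=True))
    print("\nranked table -> results/03_comsia_search.csv; "
          "stats -> results/03_model_stats.json")
    return 0


if __name__ == "__main__":
    sys.exit(main())
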