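"""Summarize stacked-richness diversity deficits per scenario and horizon.

Reads the algorithm-averaged percent-species-loss maps written by
04_range_contractions.py (rerunning the pipeline if they are absent) and
prints, per scenario and horizon, the median percent species loss over
unmasked 1° cells under full dispersal — the assemblage-level view of the
hosing impact.  Writes a tidy summary table under results/deficits/.
"""

import numpy as np
import pandas as pd

from amocrange import io as aio, run_pipeline

from study_config import RESULTS, STUDY_DIR, study_config

OUT = RESULTS / "deficits"


def load_or_compute() -> dict[tuple, np.ndarray]:
    maps = {}
    expected = [
        (scen, horizon, disp)
        for scen in ("RCP85", "A", "B", "C", "D")
        for horizon in (2030, 2070)
        for disp in ("full", "none")
    ]
    paths = {
        key: STUDY_DIR / f"deficit_{key[0]}_{key[1]}_{key[2]}_ENSEMBLE.tif"
        for key in expected
    }
    if all(p.exists() for p in paths.values()):
        for key, p in paths.items():
            arr, _, _ = aio.read_raster(p)
            maps[key] = arr.astype(float)
        return maps
    res = run_pipeline(study_config())
    return {
        (scen, horizon, disp): d.percent_loss
        for (scen, horizon, alg, disp), d in res.deficits.items()
        if alg == "ENSEMBLE"
    }


def main() -> None:
    maps = load_or_compute()
    rows = []
    for (scen, horizon, disp), arr in maps.items():
        vals = arr[np.isfinite(arr)]
        rows.append(
            {"scenario": scen, "horizon": horizon, "dispersal": disp,
             "n_cells": vals.size,
             "median_percent_loss": float(np.median(vals)),
             "p90_percent_loss": float(np.percentile(vals, 90)),
             "max_percent_loss": float(vals.max())}
        )
    df = pd.DataFrame(rows).sort_values(["dispersal", "horizon", "scenario"])
    aio.write_table(df, OUT / "deficit_summary.csv")
    full = df[(df.dispersal == "full")]
    print("median percent species loss per 1° cell (full dispersal):")
    print(
        full.pivot_table(index="horizon", columns="scenario",
                         values="median_percent_loss")[["RCP85", "A", "B", "C", "D"]]
        .round(1)
        .to_string()
    )
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
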