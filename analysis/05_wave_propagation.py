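"""Radial wave-front fit and short-circuit cell detection.

Simulates a focal-activation wave (20 um/s) across a 20 x 20 tissue with
five planted short-circuit cells activating 5 s ahead of the front, fits
the distance-vs-time front and flags outlier cells at 3x the residual SD.
Writes results/wave_table.csv and results/wave_fit.json.
"""

from pathlib import Path

import numpy as np

from endonet import io as enio
from endonet.simulate import SimulationParams, simulate_uncaging
from endonet.tissue import build_hex_lattice
from endonet.wave import analyze_wave

SEED = 21
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tissue = build_hex_lattice(20, 20, seed=SEED)
    site = tissue.centroids.mean(axis=0)
    dist = np.linalg.norm(tissue.centroids - site, axis=1)
    planted = np.argsort(dist)[-5:]

    df = simulate_uncaging(tissue, site, wave_speed=20.0,
                           shortcut_cells=planted, shortcut_advance=5.0,
                           params=SimulationParams(seed=SEED))
    res = analyze_wave(df, k_sd=3.0)

    res.table.to_csv(OUT / "wave_table.csv", index=False)
    flagged = res.table.loc[res.table["shortcut"], "cell_id"].tolist()
    enio.write_json({
        "slope_um_s": res.fit.slope,
        "intercept_um": res.fit.intercept,
        "residual_sd_um": res.fit.residual_sd,
        "distance_threshold_um": res.distance_threshold,
        "k_sd": res.k_sd,
        "flagged_cells": flagged,
        "planted_cells": sorted(int(c) for c in planted),
    }, OUT / "wave_fit.json")
    print(f"front speed {res.fit.slope:.2f} um/s, "
          f"flagged {flagged} (planted {sorted(int(c) for c in planted)})")


if __name__ == "__main__":
    main()
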