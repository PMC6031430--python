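"""Trial-aligned phenotyping of the simulated line.

Rebuilds the behavior map (same seed as 02), forms per-fly per-cycle
on/off densities and the chi contrast, runs the double Sidak-corrected
Wilcoxon significance analysis, extracts significant regions, and traces
entropy and region-occupancy time courses across the stimulus cycle.
Writes curves and the summary under results/phenotype/.
"""

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from optomap import opto_phenotyping as op
from optomap import synthetic_arena as sa
from optomap import workflows as wf

OUT = Path(__file__).resolve().parent.parent / "results" / "phenotype"
SEED = 11
TARGET = 3


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    res = wf.run_line_analysis(sa.activated_config(target_state=TARGET),
                               seed=SEED, n_cycles=10, train_size=1200,
                               resolution=24, entropy_resolution=24,
                               max_iter=500)
    phen = res.phenotype
    sig = phen.significance
    print(f"analysis in {time.time() - t0:.0f} s")
    print(f"mean-density entropy H = {sig.H:.2f} bits -> m = {sig.m} "
          f"effective comparisons, alpha' = {sig.alpha_corrected:.2e}")
    print(f"significant activated cells: {int(sig.mask.sum())} "
          f"({phen.regions.n_components} connected region(s))")

    territory = wf.state_territory_mask(res.bmap, res.sessions, TARGET)
    jac = wf.jaccard(sig.mask_image(), territory)
    print(f"overlap with the activated state's watershed territory: "
          f"Jaccard = {jac:.2f}")

    ce, cc = phen.entropy_exp, phen.entropy_ctrl
    t_min = ce.phases_s[np.nanargmin(ce.H)]
    drop = float(-np.nanmin(ce.baseline_subtracted))
    print(f"experimental entropy minimum at t = {t_min:.2f} s "
          f"(LED on at 0 s, off at 15 s), drop {drop:.2f} bits below baseline;"
          f" control curve stays within +-"
          f"{np.nanmax(np.abs(cc.baseline_subtracted)):.2f} bits")

    exp_tracks = [t for t in res.bmap.tracks if t.role == "experimental"]
    tc = op.region_timecourse(exp_tracks, territory, res.schedule,
                              res.bmap.grid, window=3.0, step=0.5)
    peak = tc.phases_s[np.nanargmax(tc.mean)]
    print(f"activated-region occupancy peaks at t = {peak:.1f} s "
          f"(mean {np.nanmax(tc.mean):.2f})")

    pd.DataFrame({"phase_s": ce.phases_s, "H_exp": ce.H, "H_ctrl": cc.H,
                  "dH_exp": ce.baseline_subtracted,
                  "dH_ctrl": cc.baseline_subtracted}).to_csv(
        OUT / "entropy_curves.csv", index=False)
    pd.DataFrame({"phase_s": tc.phases_s, "occupancy_mean": tc.mean,
                  "occupancy_sd": tc.sd}).to_csv(
        OUT / "region_timecourse.csv", index=False)
    (OUT / "phenotype_summary.json").write_text(json.dumps({
        "seed": SEED, "H_bits": sig.H, "m": sig.m,
        "alpha_corrected": sig.alpha_corrected,
        "n_significant_cells": int(sig.mask.sum()),
        "n_significant_regions": phen.regions.n_components,
        "jaccard_with_territory": jac,
        "entropy_min_phase_s": float(t_min),
        "entropy_drop_bits": drop,
        "occupancy_peak_phase_s": float(peak),
    }, indent=1))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    sys.exit(main())
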