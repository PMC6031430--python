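"""Build the 2D behavior space for the simulated line.

Runs the feature and embedding stages — per-frame normalized Morlet
mode-frequency spectra, KL-divergence distances, hierarchical importance
subsampling to a training set, t-SNE minimization, out-of-sample
re-embedding of every frame — then lays the analysis grid over the map,
estimates the overall density and carves it into watershed regions.
Writes the embedded coordinates, density and region labels under
results/map/.
"""

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from optomap import synthetic_arena as sa
from optomap import workflows as wf

OUT = Path(__file__).resolve().parent.parent / "results" / "map"
SEED = 11

# problem sizes for this worked example (reduced from the full screen)
N_CYCLES = 10
STRIDE = 5
TRAIN_SIZE = 1200
RESOLUTION = 48


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    schedule = sa.make_led_schedule(100, N_CYCLES, 15, 45)
    config = sa.activated_config(target_state=3)
    sessions = wf.simulate_line_features(config, schedule, seed=SEED,
                                         stride=STRIDE)
    bmap = wf.build_behavior_map(sessions, SEED + 1, quota=200,
                                 train_size=TRAIN_SIZE, max_iter=500,
                                 resolution=RESOLUTION)
    print(f"embedded {bmap.embedded_fraction:.1%} of {sum(len(s.frames) for s in sessions):,} "
          f"strided frames into a {RESOLUTION}x{RESOLUTION} map "
          f"({time.time() - t0:.0f} s)")
    print(f"watershed found {bmap.regions.n_regions} regions; "
          f"training set {len(bmap.training.features)} exemplars")

    # who owns which region, by ground-truth plurality vote
    ownership = wf.region_state_ownership(bmap, sessions, config.n_states)
    for rid, state in sorted(ownership.items()):
        cells = int((bmap.regions.labels == rid).sum())
        print(f"  region {rid}: {cells:4d} cells, plurality latent state {state}")

    rows = []
    for s, t in zip(sessions, bmap.tracks):
        rows.append(pd.DataFrame({"fly": t.fly_id, "role": t.role,
                                  "frame": t.frames,
                                  "x": t.coords[:, 0], "y": t.coords[:, 1]}))
    pd.concat(rows).to_csv(OUT / "embedded_points.csv.gz", index=False)
    np.savetxt(OUT / "region_labels.csv", bmap.regions.labels, fmt="%d",
               delimiter=",")
    (OUT / "map_summary.json").write_text(json.dumps({
        "seed": SEED, "n_cycles": N_CYCLES, "stride": STRIDE,
        "train_size": TRAIN_SIZE, "resolution": RESOLUTION,
        "embedded_fraction": bmap.embedded_fraction,
        "n_regions": int(bmap.regions.n_regions),
        "region_state_ownership": {str(k): int(v) for k, v in ownership.items()},
        "tsne_cost": bmap.embedding.cost,
    }, indent=1))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    sys.exit(main())
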