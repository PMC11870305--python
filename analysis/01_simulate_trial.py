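"""Generate the reference synthetic trial and climate tables.

Emulates the motivating three-site clonal trial: 32 clones planted in
2009 at a single-tree-plot site with six blocks (LY), and two two-tree
plot sites with five (NY) and four (TS) blocks; height and volume
recorded at ages 1-5, DBH at ages 1-9; ~85% survival.  Writes the trial
and climate CSVs plus the realised ground-truth effect draws.
"""

import sys
from pathlib import Path

import yaml

from clonetrial.synthetic_trial import (
    SimulationParams,
    TrialDesign,
    default_climate_profiles,
    simulate_climate,
    simulate_trial,
)
from clonetrial.trial_io import write_climate_csv, write_trial_csv

OUT = Path("results/data")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    design = TrialDesign.reference(n_clones=32, ages=range(1, 10))
    params = SimulationParams.reference(seed=SEED)
    data, truth = simulate_trial(design, params)
    write_trial_csv(data, OUT / "trial.csv")
    for kind, frame in truth.items():
        frame.to_csv(OUT / f"truth_{kind}.csv", index=False)
    climate = simulate_climate(
        design.site_ids, range(2010, 2015), default_climate_profiles(),
        seed=SEED + 1,
    )
    write_climate_csv(climate, OUT / "climate.csv")
    with open(OUT / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {"seed": SEED, "n_clones": 32, "sites": design.site_ids,
             "blocks": design.blocks_per_site,
             "ramets": design.ramets_per_plot,
             "survival_rate": params.survival_rate},
            fh,
        )
    n_trees = data[["site", "block", "clone", "ramet"]].drop_duplicates()
    print(f"simulated {len(data)} measurements on {len(n_trees)} trees "
          f"at {data['site'].nunique()} sites -> {OUT}/trial.csv")


if __name__ == "__main__":
    main()
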