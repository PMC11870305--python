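"""BLUP-GGE selection: which clones are high-yielding and stable?

Builds the genotype x environment table of per-site clone BLUPs for each
target trait, fits the environment-centered SVD, and reports the four
biplot views: environment discrimination/representativeness,
which-won-where sector winners, mean vs stability, and the
ideal-genotype ranking that drives the final selection.
"""

import json
from pathlib import Path

import pandas as pd

from clonetrial import gge_biplot as gge
from clonetrial.trial_io import read_trial_csv
from clonetrial.variance_components import blup_table, fit_single_site

DATA = Path("results/data")
OUT = Path("results/gge")
TARGETS = [("height", 5), ("dbh", 9), ("volume", 5)]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    data = read_trial_csv(DATA / "trial.csv")
    sites = sorted(data["site"].unique())

    selections = {}
    for trait, age in TARGETS:
        tab = blup_table(
            [fit_single_site(data, trait, age, s) for s in sites]
        )
        gem = gge.build_ge_matrix(tab, trait, age)
        model = gge.fit_gge(gem, scaling="env_sd", svp="genotype_focused")
        www = gge.which_won_where(model)
        ms = gge.mean_vs_stability(model)
        dr = gge.discrimination_representativeness(model)
        rk = gge.rank_genotypes(model)

        gge.coordinates_table(model).to_csv(
            OUT / f"coords_{trait}{age}.csv", index=False
        )
        ms.merge(rk, on="genotype").to_csv(
            OUT / f"views_{trait}{age}.csv", index=False
        )
        dr.to_csv(OUT / f"environments_{trait}{age}.csv", index=False)

        best = rk.iloc[0]["genotype"]
        selections[f"{trait}@{age}"] = {
            "selected_clone": best,
            "per_site_winners": www["winners"],
            "pct_explained": [round(float(p), 1)
                              for p in model.pct_explained[:2]],
        }
        print(f"{trait} (age {age}): PC1+PC2 explain "
              f"{model.pct_explained[:2].sum():.0f}% of G+GE; "
              f"winners by site {www['winners']}; "
              f"closest to ideal genotype: {best}")

    (OUT / "selections.json").write_text(
        json.dumps(selections, indent=2, sort_keys=True) + "\n"
    )


if __name__ == "__main__":
    main()
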