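"""Mixed-model fits: how much of the growth variation is genetic?

Fits the single-site clone model at each site, the multi-site model with
clone and clone-by-site terms, and the all-random decomposition whose
proportions answer the site / clone / G-by-E attribution question.
Requires 01_simulate_trial.py to have produced results/data/.
"""

from pathlib import Path

import pandas as pd

from clonetrial.trial_io import read_trial_csv
from clonetrial.variance_components import (
    blup_table,
    components_table,
    fit_all_random,
    fit_multi_site,
    fit_single_site,
    variance_proportions,
)

DATA = Path("results/data")
OUT = Path("results/variance")
TARGETS = [("height", 5), ("dbh", 9), ("volume", 5)]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    data = read_trial_csv(DATA / "trial.csv")
    sites = sorted(data["site"].unique())

    fits = []
    prop_rows = []
    for trait, age in TARGETS:
        for s in sites:
            fits.append(fit_single_site(data, trait, age, s))
        fits.append(fit_multi_site(data, trait, age))
        props = variance_proportions(fit_all_random(data, trait, age))
        prop_rows.append({"trait": trait, "age": age, **props})

    comp = components_table(fits)
    comp.to_csv(OUT / "components.csv", index=False)
    blup_table(fits).to_csv(OUT / "blups.csv", index=False)
    props = pd.DataFrame(prop_rows)
    props.to_csv(OUT / "proportions.csv", index=False)

    print(comp.to_string(index=False))
    print("\nvariance shares (all-random decomposition):")
    print(props.round(3).to_string(index=False))
    gxe = props.set_index("trait")["site_clone"]
    print(f"\nG-by-E share ranges {gxe.min():.1%}..{gxe.max():.1%}; "
          "site-specific clone choice matters whenever it is non-trivial.")


if __name__ == "__main__":
    main()
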