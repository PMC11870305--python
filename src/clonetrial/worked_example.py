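"""Published worked-example inputs for the genetic-gain formula.

Reference values from a published multi-site *Catalpa bungei* clonal
trial: for each target trait (5-year height, 9-year DBH, 5-year volume)
and each site (plus the across-site combined analysis), the selected
clone, its mean, the population mean, the mean-basis repeatability, and
the gain the source reports.  Volume means are in m^3 (the source prints
a cm^3 unit header, which is not plausible at these magnitudes).

These rows are *inputs*: `replay_gains` recomputes the gain column from
the printed means and repeatabilities through
:func:`clonetrial.genetic_parameters.genetic_gain`.  Because the inputs
are rounded to print precision, the recomputed gains carry a propagated
rounding uncertainty, returned per row as ``tolerance_pct``.
"""

from __future__ import annotations

import pandas as pd

from .genetic_parameters import genetic_gain

# trait, age, site, clone, selected mean, population mean, repeatability,
# reported gain (%)
REFERENCE_GAINS = [
    ("height", 5, "LY", "16-04", 9.01, 8.63, 0.31, 1.36),
    ("height", 5, "NY", "22-01", 7.96, 7.40, 0.67, 5.11),
    ("height", 5, "TS", "20-06", 9.34, 8.18, 0.73, 10.43),
    ("height", 5, "ALL", "22-03", 8.51, 8.07, 0.49, 2.70),
    ("dbh", 9, "LY", "19-01", 15.03, 13.35, 0.49, 6.12),
    ("dbh", 9, "NY", "19-01", 14.55, 12.37, 0.79, 13.94),
    ("dbh", 9, "TS", "22-05", 12.64, 10.44, 0.41, 8.56),
    ("dbh", 9, "ALL", "1-1", 13.09, 12.06, 0.72, 6.22),
    ("volume", 5, "LY", "19-01", 0.0460, 0.0350, 0.58, 18.13),
    ("volume", 5, "NY", "19-01", 0.0366, 0.0260, 0.52, 21.46),
    ("volume", 5, "TS", "22-05", 0.0374, 0.0233, 0.49, 29.84),
    ("volume", 5, "ALL", "22-03", 0.0362, 0.0271, 0.36, 12.11),
]

# Half-ULP of the printed precision for each input column.
_MEAN_HALF_ULP = {"height": 0.005, "dbh": 0.005, "volume": 0.00005}
_R_HALF_ULP = 0.005


def _rounding_tolerance(trait, sel, pop, rep):
    """First-order propagation of print-rounding into the gain (%).

    gain = 100 (sel - pop) R / pop; partials with respect to the three
    rounded inputs give the worst-case half-ULP error band.
    """
    dm = _MEAN_HALF_ULP[trait]
    d_sel = 100.0 * rep / pop * dm
    d_pop = 100.0 * rep * sel / pop**2 * dm
    d_rep = 100.0 * (sel - pop) / pop * _R_HALF_ULP
    return d_sel + d_pop + d_rep


def replay_gains() -> pd.DataFrame:
    """Recompute each reference gain from its printed inputs.

    Columns: trait, age, site, clone, sel_mean, pop_mean, repeatability,
    gain_pct (recomputed), reported_gain_pct, tolerance_pct (propagated
    print-rounding band).
    """
    rows = []
    for trait, age, site, clone, sel, pop, rep, reported in REFERENCE_GAINS:
        rows.append(
            {
                "trait": trait,
                "age": age,
                "site": site,
                "clone": clone,
                "sel_mean": sel,
                "pop_mean": pop,
                "repeatability": rep,
                "gain_pct": genetic_gain(sel, pop, rep),
                "reported_gain_pct": reported,
                "tolerance_pct": _rounding_tolerance(trait, sel, pop, rep),
            }
        )
    return pd.DataFrame(rows)
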