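"""Carbocation-cascade flux profiles of the cultivar x stage groups.

Groups each cultivar x stage cell's mean sesquiterpene output by the
cation intermediate its compounds require (farnesyl / humulyl /
germacradienyl / nerolidyl-bisabolyl) and reports the flux percentages
and the humulyl (1,11-closure) range across groups.
"""

from pathlib import Path

import pandas as pd

from vitiflora.cascades import (
    compute_flux,
    flux_range,
    load_default_cascade_map,
)
from vitiflora.cli import run_pipeline
from vitiflora.volatiles import ConcentrationTable

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "synthetic"


def main() -> None:
    if not (OUT / "concentrations.csv").exists():
        run_pipeline({}, ["simulate", "quantify"], OUT, seed=11)
    run_pipeline({}, ["flux"], OUT, seed=11)

    conc = ConcentrationTable(wide=pd.read_csv(OUT / "concentrations.csv",
                                               index_col=0))
    profiles = compute_flux(conc, load_default_cascade_map(), by_group=True)
    for p in profiles:
        pct = ", ".join(
            f"{k} {v:.1f}%" for k, v in p.percentages.items() if v > 0
        )
        print(f"{p.label}: total {p.total:.1f} µg/g FW | {pct}")
    lo, hi = flux_range(profiles, "humulyl")
    print(f"humulyl (1,11-closure) flux across groups: "
          f"{lo:.1f}% - {hi:.1f}%")


if __name__ == "__main__":
    main()
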