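"""Riverine import fluxes for the two river scenarios.

Recomputes the per-element POM/DOM/DIM boundary imports from the gauge inputs
(flow, sediment, organic and nutrient concentrations, plume area) and reports
the derived sediment concentrations.  The closed-form particulate-carbon flux
for the large-river scenario comes out near 8.7e3 g m-2 y-1, roughly a factor
1e3 below the corresponding published table entry - the discrepancy is
reported here rather than silently absorbed.  Writes
results/river_imports.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _regions import MIDDLE_RIVER, NORTH_RIVER, RESULTS

from stoichnet import river_imports

PUBLISHED_POM_C = 8_671_358.0  # g m-2 y-1 as printed for the turbid-river summer


def main(seed: int = 1) -> None:
    frames = []
    for name, scen in [("middle", MIDDLE_RIVER), ("north", NORTH_RIVER)]:
        table = river_imports(scen).reset_index()
        table.insert(0, "river", name)
        frames.append(table)
        print(f"{name}: sediment {scen.sediment_concentration_g_l:.3f} g/L, "
              f"POM-C {table.loc[0, 'C']:.1f} g m-2 y-1")
    out = pd.concat(frames, ignore_index=True)
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "river_imports.csv", index=False)

    pom_c = out.loc[(out.river == "middle") & (out["pool"] == "POM"), "C"].item()
    print(f"\npublished table entry / closed-form flux = "
          f"{PUBLISHED_POM_C / pom_c:.0f} (a ~1e3 unit discrepancy in the "
          "published import table; the closed form is used throughout)")


if __name__ == "__main__":
    main()
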