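"""Nutrient limitation of nodes and flows in the three subsystems.

Ascendency sensitivities per node and element, the limiting element of every
node (with the classical Liebig cross-check), the percentage summary across
regions, and the ranked limiting flows.  Writes results/node_sensitivities.csv,
results/limitation.csv, results/limitation_summary.csv and
results/limiting_flows.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _regions import RESULTS, region_configs

from stoichnet import classify_limitation, flow_sensitivities, liebig_classical
from stoichnet.io import read_native


def main(seed: int = 1) -> None:
    sens_rows, limit_rows, summary_rows, flow_rows = [], [], [], []
    for region in region_configs(seed):
        multi = read_native(RESULTS / "networks" / region)
        report = classify_limitation(multi)
        classical = liebig_classical(multi)
        agreement = (report.limitation["limiting_element"]
                     == classical["limiting_element"]).mean()

        sens = report.node_sens.reset_index()
        sens.insert(0, "region", region)
        sens_rows.append(sens)
        lim = report.limitation.reset_index()
        lim.insert(0, "region", region)
        limit_rows.append(lim)
        summary_rows.append({"region": region, **report.summary,
                             "liebig_agreement": agreement})

        flows = flow_sensitivities(multi).head(25)
        flows.insert(0, "region", region)
        flow_rows.append(flows)

        top = flows.iloc[0]
        print(f"{region}: limited by "
              + ", ".join(f"{s}: {p:.0f}%" for s, p in report.summary.items())
              + f"; Liebig cross-check agreement {agreement:.0%}; "
              f"top limiting flow {top.element} "
              f"{top.source_name} -> {top.recipient_name}")

    pd.concat(sens_rows).to_csv(RESULTS / "node_sensitivities.csv", index=False)
    pd.concat(limit_rows).to_csv(RESULTS / "limitation.csv", index=False)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(RESULTS / "limitation_summary.csv", index=False)
    pd.concat(flow_rows).to_csv(RESULTS / "limiting_flows.csv", index=False)

    if (summary["P"] > 50).all():
        print("\nP limits the majority of nodes in every region.")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
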