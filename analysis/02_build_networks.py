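"""Mass-balance the carbon webs, add the DIC pool, derive and balance N and P.

Reads results/webs/<region>/; writes the balanced three-element bundles to
results/networks/<region>/ together with the layered-balancer convergence
traces.
"""

import sys
from pathlib import Path

import yaml

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _regions import RESULTS, region_configs

from stoichnet import (
    BalancerConfig,
    InorganicPoolSpec,
    add_inorganic_pool,
    solve_mass_balance,
    validate,
)
from stoichnet.io import read_ecopath_csvs, write_native
from stoichnet.multinutrient import derive_multinetwork
from stoichnet.balancer import balance_multinetwork


def main(seed: int = 1) -> None:
    cfg_bal = BalancerConfig(tolerance=1e-6)
    for region in region_configs(seed):
        web_dir = RESULTS / "webs" / region
        inputs = read_ecopath_csvs(web_dir)
        truths = yaml.safe_load((web_dir / "web.yaml").read_text())

        solved = solve_mass_balance(inputs)
        assert solved.balanced, f"{region}: EE > 1 for {solved.ee_violations}"
        carbon = add_inorganic_pool(
            solved.network,
            InorganicPoolSpec(biomass_c=truths["dic_pool_biomass_c"]),
        )
        multi = derive_multinetwork(carbon)
        pre = {el.symbol: validate(multi[el]).max_abs_imbalance
               for el in multi.elements}
        balanced, traces = balance_multinetwork(multi, cfg_bal)

        out = RESULTS / "networks" / region
        write_native(balanced, out)
        for el, trace in traces.items():
            trace.to_csv(out / f"trace_{el.symbol}.csv")
        post = {el.symbol: validate(balanced[el]).max_abs_imbalance
                for el in balanced.elements}
        print(f"{region}: worst node imbalance "
              + ", ".join(f"{s}: {pre[s]:.3g} -> {post[s]:.2g}" for s in pre)
              + f" ({max(t.iterations for t in traces.values())} outer iterations)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
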