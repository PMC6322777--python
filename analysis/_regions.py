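"""Shared study design for the analysis scripts: three shelf subsystems.

Three synthetic subsystems emulate a nutrient-poor subtropical shelf whose
middle and northern regions receive river outflow: a southern eddy-influenced
web with no riverine input ("south"), a middle web forced by a large turbid
river ("middle"), and a northern web forced by a smaller river ("north").
River forcing follows the published gauge inputs (flows, sediment
concentration/yield, plume areas); the food webs themselves are synthetic.
"""

from pathlib import Path

from stoichnet import RiverScenario, SyntheticWebConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

#: large turbid river: 429 m^3/s summer flow, 4.28 g/L sediment, 561 km^2 plume
MIDDLE_RIVER = RiverScenario(
    plume_area_m2=5.61e8,
    flow_rate_m3_s=429.0,
    sediment_conc_g_l=4.28,
    poc_fraction_of_tss=0.084,
    doc_conc_mg_l=6.0,
    din_conc_mg_l=0.5,
    dip_conc_mg_l=0.05,
)

#: smaller river: 6.8e5 t/y sediment yield over 1.6e12 L/y annual flow
NORTH_RIVER = RiverScenario(
    plume_area_m2=5.61e8,
    annual_flow_l=1.6e12,
    sediment_yield_t_y=6.8e5,
    poc_fraction_of_tss=0.084,
    doc_conc_mg_l=6.0,
    din_conc_mg_l=0.5,
    dip_conc_mg_l=0.05,
)


def region_configs(seed: int = 1) -> dict[str, SyntheticWebConfig]:
    return {
        "south": SyntheticWebConfig(seed=seed),
        "middle": SyntheticWebConfig(seed=seed + 1, river_scenario=MIDDLE_RIVER),
        "north": SyntheticWebConfig(seed=seed + 2, river_scenario=NORTH_RIVER),
    }
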