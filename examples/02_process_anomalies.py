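"""Process anomalies relative to the air/deep-gas mixing lines.

For each field sample, the deviation of a diagnostic species from the
two-end-member mixing curve flags a secondary process: N2/CO2 excess from
O2 consumption in the soil air, CH4 depletion from microbial methane
oxidation.
"""

import mofette as m

profiles = m.datasets.load_gas_profiles()
pair = m.default_pair(m.datasets.load_bubbling_pool())

print(f"{'site':>4} {'depth':>5}  flags")
for obs in profiles:
    if obs.site == "BP":
        continue
    fl = m.classify_sample(obs, pair, threshold=0.05)
    names = [
        n for n, v in [
            ("N2_excess", fl.n2_excess),
            ("CO2_excess", fl.co2_excess),
            ("CH4_depletion", fl.ch4_depletion),
            ("O2_depletion", fl.o2_depletion),
        ] if v
    ]
    print(f"{obs.site:>4} {obs.depth_cm:5.0f}  {', '.join(names) or '-'}")

# CH4 depletion at deep site 6 and at site 8 marks methane oxidation: the
# observed CH4 sits far below the concentration the air-deep mixture
# predicts at the sample's N2 content.
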