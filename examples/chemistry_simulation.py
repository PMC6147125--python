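"""Simulate the 30-day food-web chemistry at both temperatures.

Integrates the kinetic model (polymer hydrolysis -> acetate/propionate/
H2 -> CH4, each conversion Monod-limited and gated by its Gibbs free
energy) and prints the sampled-day trajectories next to the
concentration anchors the presets are calibrated to.
"""

from paddyweb import synth

for name, preset in synth.PRESETS.items():
    chem = synth.simulate_chemistry(preset())
    one = chem[chem["replicate"] == 1]
    print(f"--- {name}")
    print(one[["day", "acetate_mM", "propionate_mM", "pH2_kPa", "pCH4_kPa"]]
          .round(3).to_string(index=False))
    print(f"max acetate: {one['acetate_mM'].max():.2f} mM | "
          f"CH4 at day 30: {one.loc[one['day'] == 30, 'pCH4_kPa'].iloc[0]:.1f} kPa")
    print()

print("Calibration anchors: mesophilic acetate peak 8.4 mM (day 5) and day-30")
print("CH4 48.5 kPa; thermophilic acetate peak 17.7 mM (day 16). The mesophilic")
print("peak is early because acetoclastic methanogens consume acetate as soon")
print("as they are established; the thermophilic peak is late because acetate")
print("waits for syntrophic oxidizers to become active.")
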