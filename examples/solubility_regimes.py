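"""Van't Hoff solubility curve and nucleation-regime classification.

Uses the reference fit for phloroglucinol in water
(S0 = 7e7 wt%, dH_sol = 42,460 J/mol) to decide, for each mass
concentration, whether a cooling droplet stays dissolved, crosses the
solubility curve mid-ramp (precipitating ice-nucleating crystals), or
is supersaturated from the start.
"""

from icespec import PHLOROGLUCINOL_FIT, classify_regime, solubility_at, wt_to_concentration

s25 = solubility_at(PHLOROGLUCINOL_FIT, 298.15)
print(
    f"solubility at 25 degC: {s25:.2f} wt% = "
    f"{wt_to_concentration(s25):.1f} mg/mL"
)

freezing_range = (0.0, -22.5)  # ramp start to pure-water background
for conc in (1.0, 5.0, 10.0, 50.0):
    cls = classify_regime(conc, freezing_range, PHLOROGLUCINOL_FIT)
    note = ""
    if cls.crossing_temperature is not None:
        note = f" (crosses solubility at {cls.crossing_temperature:.2f} degC)"
    print(f"{conc:5.1f} mg/mL: {cls.regime}{note}")
print(
    "-> concentrations >= 5 mg/mL meet the solubility curve within the "
    "freezing range: cooling precipitates crystals that nucleate ice; "
    "dilute solutions rely on dissolved aggregates"
)
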