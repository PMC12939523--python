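"""Reference inventory data shipped with the package.

``CU_INVENTORY`` is the published cradle-to-gate life cycle inventory for
producing one color unit (CU) of phycocyanin and applying its waste stream
as a soil biostimulant: 26 flows normalised to 1 CU delivered at factory
gate. The two elementary CO2 rows are removals (cultivation biofixation and
soil carbon sequestration) and carry ``direction_sign = -1`` while keeping
their printed positive amounts.

``DRAGEE_RECIPE`` is the ingredient/packaging inventory of a 100 g bag of
mixed-colour chocolate dragees. Its emission factors are NOT published —
``DRAGEE_EMISSION_FACTORS`` is a synthetic, illustrative factor set so the
product pipeline is runnable end to end; product footprints computed from
it are demonstrations, not reproductions.

``STAGE_INTENSITIES`` are the pre-characterised climate intensities of the
three life-cycle stages (kg CO2-eq per CU): cultivation 0.15, extraction
4.83, and the biostimulant sequestration credit 1602.48 (a removal).
"""

from __future__ import annotations

# flow_name, amount, unit, compartment, direction_sign, stage, data_source, comment
CU_INVENTORY: list[tuple] = [
    ("Aluminum, cast alloy [GLO]", 0.00434, "kg", "technosphere", 1, "cultivation", "EcoInvent 3.9", "For bioreactor production"),
    ("Battery, Li-ion [GLO]", 0.00011, "kg", "technosphere", 1, "application", "EcoInvent 3.9", "For drone production"),
    ("Cable [GLO]", 1.83251e-05, "kg", "technosphere", 1, "application", "EcoInvent 3.9", "For drone production"),
    ("CO_2", 0.40179, "kg", "elementary", -1, "cultivation", "Elementary flow", "For cultivation"),
    ("CO_2", 1.60248, "t", "elementary", -1, "application", "Elementary flow", "Carbon sequestration"),
    ("Diesel [GLO]", 8.13974, "MJ", "technosphere", 1, "application", "EcoInvent 3.9", "For drone operation"),
    ("Electricity, high voltage [IS]", 1.76167, "MJ", "technosphere", 1, "extraction", "EcoInvent 3.9", "Used in multiple processes"),
    ("Electricity, medium voltage [IS]", 118.38543, "MJ", "technosphere", 1, "extraction", "EcoInvent 3.9", "Used in multiple processes"),
    ("Electronics, for control units [RER]", 0.00641, "kg", "technosphere", 1, "extraction", "EcoInvent 3.9", "Used in multiple processes"),
    ("Glass-fiber-reinforced plastic, polyamide [RER]", 0.00594, "kg", "technosphere", 1, "extraction", "EcoInvent 3.9", "Used in multiple processes"),
    ("Iron sulfate [GLO]", 2.23214e-05, "kg", "technosphere", 1, "cultivation", "EcoInvent 3.9", "Nutrients"),
    ("Land occupation", 0.00320, "m2·a", "elementary", 1, "cultivation", "Elementary flow", "For cultivation"),
    ("Light-Emitting Diode (LED) [GLO]", 0.00538, "kg", "technosphere", 1, "cultivation", "EcoInvent 3.9", "For bioreactor production"),
    ("Nitrogen fertilizer, as N [GLO]", 0.01116, "kg", "technosphere", 1, "cultivation", "EcoInvent 3.9", "Nutrients"),
    ("Nylon 6-6 [RoW]", 2.19901e-06, "kg", "technosphere", 1, "application", "EcoInvent 3.9", "For drone production"),
    ("Polyethylene, high density [GLO]", 0.00011, "kg", "technosphere", 1, "extraction", "EcoInvent 3.9", "Used in multiple processes"),
    ("Polypropylene [GLO]", 0.00014, "kg", "technosphere", 1, "cultivation", "EcoInvent 3.9", "For bioreactor production"),
    ("Polyvinylchloride [GLO]", 0.00141, "kg", "technosphere", 1, "cultivation", "EcoInvent 3.9", "For bioreactor production"),
    ("Silicone, at plant [GLO]", 0.00012, "kg", "technosphere", 1, "cultivation", "EcoInvent 3.9", "For bioreactor production"),
    ("Sodium phosphate [RoW]", 0.00893, "kg", "technosphere", 1, "cultivation", "EcoInvent 3.9", "Nutrients"),
    ("Steel, chromium steel 18/8 [GLO]", 0.00242, "kg", "technosphere", 1, "cultivation", "EcoInvent 3.9", "For bioreactor production"),
    ("Steel, unalloyed [RER]", 0.00155, "kg", "technosphere", 1, "cultivation", "EcoInvent 3.9", "For bioreactor production"),
    ("Tap water [IS]", 37.29687, "kg", "technosphere", 1, "cultivation", "EcoInvent 3.9", "Used in multiple processes"),
    ("Transport, freight, lorry 16-32 ton [GLO]", 6.96354e-05, "t·km", "technosphere", 1, "application", "EcoInvent 3.9", "Used in multiple processes"),
    ("Transport, freight, lorry 3.5-7.5 ton [GLO]", 1.75961, "t·km", "technosphere", 1, "application", "EcoInvent 3.9", "Used in multiple processes"),
    ("Transport, freight, transoceanic ship [GLO]", 0.00443, "t·km", "technosphere", 1, "application", "EcoInvent 3.9", "Used in multiple processes"),
]

# Stage-level climate intensities, kg CO2-eq per CU. The sequestration row
# is a removal (sign -1); its magnitude is the published credited flow.
STAGE_INTENSITIES: list[tuple] = [
    ("cultivation", 0.15, 1),
    ("extraction", 4.83, 1),
    ("sequestration", 1602.48, -1),
]

# ingredient, mass kg per 100 g bag, phase {raw, packaging}, comment
DRAGEE_RECIPE: list[tuple] = [
    ("Milk chocolate", 0.067, "raw", "Used in multiple processes"),
    ("Sugar, from sugarcane", 0.027, "raw", "Used in multiple processes"),
    ("Corn glucose syrup", 0.004, "raw", "Used in yellow dragee"),
    ("Turmeric", 0.0001, "raw", "Proxy for curcumin (E100)"),
    ("Potato starch", 0.0015, "raw", "Proxy for gum arabic (E414) and tapioca starch"),
    ("Spirulina, dried", 0.0001, "raw", "Proxy for Synthetic Blue No 1 (E133)"),
    ("Sugarcane processing", 0.0001, "raw", "Proxy for caramel colour (E150a)"),
    ("Boiling, industrial", 0.0001, "raw", "Proxy for caramel colour (E150a) production"),
    ("Beetroot juice", 0.0001, "raw", "Proxy for anthocyanins (E163)"),
    ("Carrot juice", 0.0001, "raw", "Proxy for beta-carotene (E160a)"),
    ("PET granulate", 0.005, "packaging", "Packaging"),
    ("Polypropylene granulate", 0.004, "packaging", "Packaging"),
    ("Plastic film extrusion", 0.010, "packaging", "Packaging"),
    ("LDPE granulate", 0.001, "packaging", "Packaging"),
]

# SYNTHETIC emission factors, kg CO2-eq per kg. Illustrative orders of
# magnitude only — the real background-database factors are licensed data
# and are deliberately not reproduced here.
DRAGEE_EMISSION_FACTORS: dict[str, float] = {
    "Milk chocolate": 10.0,
    "Sugar, from sugarcane": 0.9,
    "Corn glucose syrup": 1.4,
    "Turmeric": 3.0,
    "Potato starch": 1.1,
    "Spirulina, dried": 9.0,
    "Sugarcane processing": 0.8,
    "Boiling, industrial": 0.5,
    "Beetroot juice": 1.2,
    "Carrot juice": 1.2,
    "PET granulate": 2.6,
    "Polypropylene granulate": 1.8,
    "Plastic film extrusion": 0.6,
    "LDPE granulate": 2.0,
}
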