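"""Physical constants, unit conversions and bilayer-geometry defaults.

All unit conversions used by the vesicle-geometry model live here so the
nm/mL/mM bookkeeping is auditable in one place.
"""

from __future__ import annotations

#: Avogadro's number, molecules per mole (value used throughout the model).
AVOGADRO = 6.02e23

#: nm^3 per litre: 1 L = 1e-3 m^3 = 1e24 nm^3.
NM3_PER_LITRE = 1e24

#: Convert mM (mmol/L) to mol/L.
MM_TO_MOLAR = 1e-3

#: Convert mL to L.
ML_TO_LITRE = 1e-3

#: DPPC bilayer membrane thickness, nm.
DEFAULT_MEMBRANE_THICKNESS_NM = 4.8

#: Molecular area per lipid in a DPPC/cholesterol (1:1) monolayer, nm^2.
DEFAULT_AREA_PER_LIPID_NM2 = 0.43

# Default lipid mixture: DPPC / cholesterol / DHSG / PEG(5000)-DSPE at a
# molar ratio of 5 : 5 : 1 : 0.066.  Molar masses in g/mol; the PEG-lipid
# mass is the nominal mPEG5000 conjugate mass and is overridable wherever a
# LipidComposition is accepted.
DEFAULT_COMPOSITION = (
    ("DPPC", 5.0, 734.04),
    ("cholesterol", 5.0, 386.65),
    ("DHSG", 1.0, 696.0),
    ("PEG-DSPE", 0.066, 5801.0),
)

#: Calcein concentration of the aqueous feed, mM.
DEFAULT_CALCEIN_STOCK_MM = 1.0

#: Ultrafiltration washes until the outer aqueous phase is diluted this much.
DEFAULT_CARRYOVER_DILUTION = 1000.0
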