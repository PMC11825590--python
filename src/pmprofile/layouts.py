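"""A complete synthetic PM-M1..M8 layout for tests, examples and simulation.

The commercial Biolog plate maps are proprietary and are deliberately not
reproduced.  :func:`builtin_layout` instead generates a synthetic
stand-in with the structural features the analysis relies on:

* every named (plate, well, compound) anchor used elsewhere in the
  package (PM-M8 D06 LH, D11 LH-RH, C08 Calcitriol, E06 HCG, E09 ACTH,
  F12 TRH, G10 TNF-alpha; PM-M7 F03 FGF-1(aFGF), G01 IL-1beta, H04 IL-6,
  H07 IL-8; PM-M2 H02 Glu-Trp, H07 Gln-Gly; PM-M4 F05 Trp-Tyr);
* exactly 30 glycine-containing and 27 tyrosine-containing wells across
  the amino-acid/dipeptide plates, so compound-cluster queries have a
  known denominator;
* PM-M5 filled with ionic compounds in four-well increasing-concentration
  series;
* per-plate categories matching the PM-M series (carbon sources on M1,
  amino acids/dipeptides on M2-M4, ions on M5, hormones and metabolic
  effectors on M6-M8), with synthetic filler compounds elsewhere.

IL-6 and IL-8 carry no plate in the source figure captions; they are
placed on PM-M7 alongside the other cytokines by assumption.
"""

from __future__ import annotations

from .plates import (
    N_COLUMNS,
    PLATE_IDS,
    ROWS,
    CompoundAnnotation,
    PlateLayout,
    WellAddress,
)

__all__ = ["builtin_layout", "GLYCINE_WELL_COUNT", "TYROSINE_WELL_COUNT"]

#: wells whose compound name contains "gly" / "tyr" in the builtin layout
GLYCINE_WELL_COUNT = 30
TYROSINE_WELL_COUNT = 27

_M1_NAMED = {
    "A02": "Pectin",
    "A03": "Adenosine",
    "A04": "Pyruvic acid",
    "A05": "D-Glucose",
    "A06": "D-Fructose",
    "A07": "Maltose",
    "A08": "Sucrose",
    "A09": "D-Mannose",
    "A10": "Lactose",
    "A11": "Inosine",
    "A12": "Dextrin",
    "B01": "D-Galactose",
    "B02": "D-Ribose",
    "B03": "D-Xylose",
    "B04": "Citric acid",
    "B05": "Succinic acid",
    "B06": "L-Malic acid",
    "B07": "Acetic acid",
    "B08": "D-Sorbitol",
}

_M2_AMINO = {
    "A02": "L-Alanine",
    "A03": "L-Arginine",
    "A04": "L-Asparagine",
    "A05": "L-Aspartic acid",
    "A06": "L-Cysteine",
    "A07": "L-Glutamic acid",
    "A08": "L-Glutamine",
    "A09": "Glycine",
    "A10": "L-Histidine",
    "A11": "L-Isoleucine",
    "A12": "L-Leucine",
    "B01": "L-Lysine",
    "B02": "L-Methionine",
    "B03": "L-Phenylalanine",
    "B04": "L-Proline",
    "B05": "L-Serine",
    "B06": "L-Threonine",
    "B07": "L-Tryptophan",
    "B08": "L-Tyrosine",
}

_M2_DIPEPTIDES = {
    "B09": "Ile-Gln",
    "B10": "Ser-Gln",
    "C01": "Gly-Ala",
    "C02": "Gly-Arg",
    "C03": "Gly-Asn",
    "C04": "Gly-Asp",
    "C05": "Gly-Glu",
    "C06": "Gly-His",
    "C07": "Gly-Ile",
    "C08": "Gly-Leu",
    "H02": "Glu-Trp",
    "H07": "Gln-Gly",
}

_M3_DIPEPTIDES = {
    "B01": "Gly-Lys",
    "B02": "Gly-Met",
    "B03": "Gly-Phe",
    "B04": "Gly-Pro",
    "B05": "Gly-Ser",
    "B06": "Gly-Thr",
    "B07": "Gly-Trp",
    "B08": "Gly-Tyr",
    "B09": "Gly-Val",
    "B10": "Ala-Gly",
    "B11": "Arg-Gly",
    "B12": "Asn-Gly",
    "C01": "Tyr-Ala",
    "C02": "Tyr-Arg",
    "C03": "Tyr-Asn",
}

_M4_DIPEPTIDES = {
    "B01": "Asp-Gly",
    "B02": "Glu-Gly",
    "B03": "His-Gly",
    "B04": "Ile-Gly",
    "B05": "Leu-Gly",
    "B06": "Lys-Gly",
    "B07": "Met-Gly",
    "B08": "Phe-Gly",
    "C01": "Tyr-Asp",
    "C02": "Tyr-Glu",
    "C03": "Tyr-Gln",
    "C04": "Tyr-His",
    "C05": "Tyr-Ile",
    "C06": "Tyr-Leu",
    "C07": "Tyr-Lys",
    "C08": "Tyr-Met",
    "C09": "Tyr-Phe",
    "C10": "Tyr-Pro",
    "C11": "Tyr-Ser",
    "C12": "Tyr-Thr",
    "D01": "Tyr-Trp",
    "D02": "Tyr-Val",
    "D03": "Ala-Tyr",
    "D04": "Arg-Tyr",
    "D05": "Asn-Tyr",
    "D06": "Asp-Tyr",
    "D07": "Glu-Tyr",
    "D08": "Gln-Tyr",
    "D09": "His-Tyr",
    "F05": "Trp-Tyr",
}

_M5_IONS = [
    "Sodium chloride",
    "Potassium chloride",
    "Calcium chloride",
    "Magnesium chloride",
    "Zinc chloride",
    "Ferric chloride",
    "Copper(II) sulfate",
    "Manganese chloride",
    "Sodium phosphate",
    "Potassium phosphate",
    "Sodium sulfate",
    "Ammonium chloride",
    "Sodium selenite",
    "Sodium nitrate",
    "Lithium chloride",
    "Cobalt chloride",
    "Nickel chloride",
    "Sodium bicarbonate",
    "Sodium citrate",
    "Potassium bromide",
    "Sodium fluoride",
    "Chromium chloride",
    "Sodium molybdate",
    "Aluminum sulfate",
]

_M6_NAMED = {
    "A02": "Insulin",
    "A03": "Glucagon",
    "A04": "Leptin",
    "A05": "Melatonin",
    "A06": "Cortisol",
    "A07": "Estradiol",
    "A08": "Progesterone",
    "A09": "Testosterone",
    "A10": "Aldosterone",
    "A11": "Somatostatin",
    "A12": "Oxytocin",
}

_M7_NAMED = {
    "A02": "EGF",
    "A03": "IGF-1",
    "A04": "NGF",
    "A05": "PDGF-BB",
    "F03": "FGF-1(aFGF)",
    "G01": "IL-1beta",
    "H04": "IL-6",
    "H05": "IL-2",
    "H07": "IL-8",
}

_M8_NAMED = {
    "C08": "Calcitriol",
    "D06": "Luteinizing Hormone (LH)",
    "D11": "Luteinizing Hormone Releasing Hormone (LH-RH)",
    "E06": "Chorionic Gonadotropin Human (HCG)",
    "E09": "Adrenocorticotrophic Hormone Human (ACTH)",
    "F12": "Thyrotropin Releasing Hormone Acetate Salt (TRH)",
}


def _wells(plate: str) -> list[str]:
    return [f"{r}{c:02d}" for r in ROWS for c in range(1, N_COLUMNS + 1)]


def builtin_layout() -> PlateLayout:
    """Build the full 8-plate, 768-well synthetic layout."""
    entries: dict[WellAddress, CompoundAnnotation] = {}

    def put(plate: str, well: str, name: str, category: str, sid: str | None = None, rank: int | None = None):
        entries[WellAddress(plate, well)] = CompoundAnnotation(name, category, sid, rank)

    def fill(plate: str, named: dict[str, tuple[str, str]], filler_prefix: str, filler_cat: str):
        put(plate, "A01", "Negative Control", "other")
        for well, (name, cat) in named.items():
            put(plate, well, name, cat)
        suffix = plate.split("-")[1]
        for well in _wells(plate):
            if WellAddress(plate, well) not in entries:
                put(plate, well, f"{filler_prefix} {suffix}-{well}", filler_cat)

    fill("PM-M1", {w: (n, "carbon_source") for w, n in _M1_NAMED.items()}, "Carbon source", "carbon_source")

    m2 = {w: (n, "amino_acid") for w, n in _M2_AMINO.items()}
    m2.update({w: (n, "dipeptide") for w, n in _M2_DIPEPTIDES.items()})
    fill("PM-M2", m2, "Dipeptide", "dipeptide")
    fill("PM-M3", {w: (n, "dipeptide") for w, n in _M3_DIPEPTIDES.items()}, "Dipeptide", "dipeptide")
    fill("PM-M4", {w: (n, "dipeptide") for w, n in _M4_DIPEPTIDES.items()}, "Dipeptide", "dipeptide")

    # PM-M5: ions in increasing-concentration series (the last series has 3 wells)
    put("PM-M5", "A01", "Negative Control", "other")
    free = [w for w in _wells("PM-M5") if w != "A01"]
    pos = 0
    for i, ion in enumerate(_M5_IONS, start=1):
        length = min(4, len(free) - pos)
        if length == 0:
            break
        for rank in range(1, length + 1):
            put("PM-M5", free[pos], ion, "ion", f"M5-S{i:02d}", rank)
            pos += 1

    fill("PM-M6", {w: (n, "hormone") for w, n in _M6_NAMED.items()}, "Hormone", "hormone")
    fill("PM-M7", {w: (n, "metabolic_effector") for w, n in _M7_NAMED.items()}, "Effector", "metabolic_effector")

    m8 = {w: (n, "hormone") for w, n in _M8_NAMED.items()}
    m8["G10"] = ("TNF-alpha", "metabolic_effector")
    put("PM-M8", "A01", "Negative Control", "other")
    for rank, well in enumerate(["B01", "B02", "B03", "B04"], start=1):
        put("PM-M8", well, "IFN-gamma", "metabolic_effector", "M8-IFNG", rank)
    for well, (name, cat) in m8.items():
        put("PM-M8", well, name, cat)
    for well in _wells("PM-M8"):
        if WellAddress("PM-M8", well) not in entries:
            put("PM-M8", well, f"Hormone M8-{well}", "hormone")

    layout = PlateLayout(entries)
    assert layout.plates_present == frozenset(PLATE_IDS)
    return layout
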