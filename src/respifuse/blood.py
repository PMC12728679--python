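"""Blood-indicator schema: the 56 routine hematology/chemistry indicators.

The shipped schema is a cleaned transcription of the routine panel the
pipeline assumes.  The printed source list it was transcribed from is
internally inconsistent: it repeats the pair "eosinophil ratio / eosinophil
count" and omits basophils even though the downstream top-contribution
lists reference them, and it enumerates only 55 distinct entries.  The
schema therefore (i) replaces the duplicated eosinophil pair with
"basophil ratio" / "basophil count" and (ii) adds "total protein" (albumin
and globulin are both present, making total protein the conspicuous panel
omission) to reach the documented 56 indicators.

Each indicator carries one of the five clinical categories used by the
group-level evaluation: blood components, leukocyte (white-blood-cell
related), enzyme, electrolyte, biochemistry.
"""

from __future__ import annotations

BLOOD_CATEGORIES = (
    "components",
    "leukocyte",
    "enzyme",
    "electrolyte",
    "biochemistry",
)

# name -> category
BLOOD_SCHEMA: dict[str, str] = {
    "albumin": "biochemistry",
    "white blood cell ratio": "leukocyte",
    "white blood cell count": "leukocyte",
    "alanine aminotransferase": "enzyme",
    "large platelet ratio": "components",
    "monocyte ratio": "leukocyte",
    "monocyte count": "leukocyte",
    "low-density lipoprotein (dry)": "biochemistry",
    "amylase": "enzyme",
    "carbon dioxide binding rate": "electrolyte",
    "calcium": "electrolyte",
    "triglycerides": "biochemistry",
    "high-density lipoprotein (dry)": "biochemistry",
    "glutamyl transferase": "enzyme",
    "red blood cell distribution width CV": "components",
    "red blood cell distribution width SD": "components",
    "red blood cell count": "components",
    "average red blood cell volume": "components",
    "hematocrit": "components",
    "creatinine": "biochemistry",
    "creatine kinase": "enzyme",
    "creatine kinase isoenzyme": "enzyme",
    "potassium": "electrolyte",
    "indirect bilirubin (dry)": "biochemistry",
    "alkaline phosphatase": "enzyme",
    "lymphocyte ratio": "leukocyte",
    "lymphocyte count": "leukocyte",
    "phosphorus": "electrolyte",
    "chlorine": "electrolyte",
    "magnesium": "electrolyte",
    "sodium": "electrolyte",
    "urea": "biochemistry",
    "urea/creatinine": "biochemistry",
    "uric acid": "biochemistry",
    "average hemoglobin content": "components",
    "average hemoglobin concentration": "components",
    "average platelet volume": "components",
    "glucose": "biochemistry",
    "globulin": "biochemistry",
    "lactate dehydrogenase": "enzyme",
    "eosinophil ratio": "leukocyte",
    "eosinophil count": "leukocyte",
    "basophil ratio": "leukocyte",
    "basophil count": "leukocyte",
    "aspartate/alanine": "enzyme",
    "aspartate aminotransferase": "enzyme",
    "hemoglobin": "components",
    "platelets": "components",
    "platelet distribution width": "components",
    "platelet hematocrit": "components",
    "direct bilirubin (dry)": "biochemistry",
    "neutrophil ratio": "leukocyte",
    "neutrophil count": "leukocyte",
    "total cholesterol": "biochemistry",
    "total bilirubin": "biochemistry",
    "total protein": "biochemistry",
}

BLOOD_INDICATOR_NAMES: tuple[str, ...] = tuple(BLOOD_SCHEMA)

assert len(BLOOD_INDICATOR_NAMES) == 56

#: Leukocyte indicators whose class-conditional means the synthetic cohort
#: shifts by the planted effect size (immune-response signature).
EFFECT_INDICATORS: tuple[str, ...] = (
    "monocyte ratio",
    "basophil ratio",
    "eosinophil count",
    "white blood cell count",
    "eosinophil ratio",
    "basophil count",
    "lymphocyte ratio",
)


def blood_category(name: str) -> str:
    """Category of one indicator; raises ``KeyError`` for unknown names."""
    return BLOOD_SCHEMA[name]
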