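"""Curated reference feature sets for the lung-cancer screening task.

These are the high-contribution feature lists the pipeline's defaults
emulate: the top-20 contribution ranking per modality and the
representative subsets (9 fiber-frequency, 9 audio-rhythm, 7 blood
leukocyte) that feed fusion.  The blood top-20 is a reconciliation of an
internally inconsistent published tabulation (19 printed entries whose
category memberships disagree with the stated per-category counts); it is
normalized here to the stated counts — 7 components, 7 leukocyte,
2 enzyme, 1 electrolyte, 3 biochemistry.
"""

from __future__ import annotations

TOP20_FIBER: tuple[str, ...] = (
    "D5 variance", "D2 variance", "D1 variance", "D6 variance",
    "D6 kurtosis", "D1 skewness", "D1 kurtosis", "D5 kurtosis",
    "D4 kurtosis", "power spectrum maximum", "Cepstrum peak factor",
    "Fourier maximum", "Cepstrum skewness",
    "Cepstrum root mean square factor", "Cepstrum signal-to-noise ratio",
    "power spectrum signal-to-noise ratio", "Fourier mean",
    "Cepstrum impulse factor", "peak factor", "minimum",
)

TOP20_AUDIO: tuple[str, ...] = (
    "SPLmean", "Emean", "ZCR-de-range", "STEsk", "ZCR-de-min",
    "ZCR-de-max", "STEmin", "STEku", "SPL-de-range", "mfcc19mean",
    "mfcc6mean", "mfcc33mean", "mfcc38mean", "mfcc26sk", "B1-de-std",
    "B1sk", "F1-de2-sk", "F1mean", "F1max", "F1min",
)

TOP20_BLOOD: tuple[str, ...] = (
    # leukocyte (7)
    "monocyte ratio", "basophil ratio", "eosinophil count",
    "white blood cell count", "eosinophil ratio", "basophil count",
    "lymphocyte ratio",
    # blood components (7)
    "platelet distribution width", "red blood cell distribution width CV",
    "average hemoglobin content", "red blood cell distribution width SD",
    "hemoglobin", "platelets", "platelet hematocrit",
    # enzyme (2)
    "creatine kinase isoenzyme", "amylase",
    # electrolyte (1)
    "chlorine",
    # biochemistry (3)
    "albumin", "total cholesterol", "high-density lipoprotein (dry)",
)

#: Representative fused-input blocks: FFr (fiber frequency), ARh (audio
#: rhythm) and the leukocyte laboratory markers (LMLC).
REPRESENTATIVE_FIBER_FREQUENCY: tuple[str, ...] = (
    "power spectrum maximum", "Cepstrum peak factor", "Fourier maximum",
    "Cepstrum skewness", "Cepstrum root mean square factor",
    "Cepstrum signal-to-noise ratio", "power spectrum signal-to-noise ratio",
    "Fourier mean", "Cepstrum impulse factor",
)

REPRESENTATIVE_AUDIO_RHYTHM: tuple[str, ...] = (
    "SPLmean", "Emean", "ZCR-de-range", "STEsk", "ZCR-de-min",
    "ZCR-de-max", "STEmin", "STEku", "SPL-de-range",
)

REPRESENTATIVE_BLOOD_LEUKOCYTE: tuple[str, ...] = (
    "monocyte ratio", "basophil ratio", "eosinophil count",
    "white blood cell count", "eosinophil ratio", "basophil count",
    "lymphocyte ratio",
)
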