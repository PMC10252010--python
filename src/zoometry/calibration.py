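"""Reference calibration for the Andean Creole cattle population.

The package ships a single built-in calibration: the published morphometric
profile of the Creole cattle genetic nucleus kept at the Chuquibambilla
research centre in the Peruvian altiplano (three biotypes — Black 'Negro',
Colour-Sided 'Callejon', Brindle 'Atigrado' — measured on 95 adult animals).
It provides

* per-biotype trait means (cm) for the 17 linear body measurements,
* one pooled coefficient of variation (CV%) per trait,
* group sizes per biotype and sex,
* a qualitative correlation pattern between traits (sign and strength
  classes, the exact coefficients are not public), and
* the pooled zoometric-index means of the same population, used as
  recovery targets when validating the simulator end to end.

These numbers are *data*, not code: every consumer takes them as defaults
that can be overridden (see :class:`zoometry.simulate.HerdConfig`).
"""

from __future__ import annotations

from types import MappingProxyType

#: Biotype labels, in the fixed reporting order.
BIOTYPES = ("NEGRO", "CALLEJON", "ATIGRADO")

#: Sex labels.
SEXES = ("FEMALE", "MALE")

#: The 17 measurement codes in canonical schema order
#: (head, trunk heights/lengths, perimeters, widths/depths, rump, neck).
MEASUREMENTS = (
    "HL", "HW", "HD", "HaW", "TL", "BL", "TP", "SP", "AP",
    "TW", "TD", "ThL", "RL", "RW", "RH", "IW", "NL",
)

#: Long descriptive names for each code; all values are in centimetres.
MEASUREMENT_NAMES = MappingProxyType({
    "HL": "head length",
    "HW": "head width",
    "HD": "head depth",
    "HaW": "height at withers",
    "TL": "total length",
    "BL": "body length",
    "TP": "thoracic perimeter",
    "SP": "shank perimeter",
    "AP": "abdominal perimeter",
    "TW": "thoracic width",
    "TD": "thoracic depth",
    "ThL": "thoracic length",
    "RL": "rump length",
    "RW": "rump width",
    "RH": "rump height",
    "IW": "ischium width",
    "NL": "neck length",
})

#: Row order used by the measurement summary report (rump width listed
#: before rump length, as in the reference population's published table).
MEASUREMENT_REPORT_ORDER = (
    "HL", "HW", "HD", "HaW", "TL", "BL", "TP", "SP", "AP",
    "TW", "TD", "ThL", "RW", "RL", "RH", "IW", "NL",
)

#: Animals per biotype x sex cell in the reference population
#: (83 adult females, 12 adult males; 4 males per biotype).
REFERENCE_GROUP_SIZES = MappingProxyType({
    ("NEGRO", "FEMALE"): 53,
    ("NEGRO", "MALE"): 4,
    ("CALLEJON", "FEMALE"): 16,
    ("CALLEJON", "MALE"): 4,
    ("ATIGRADO", "FEMALE"): 14,
    ("ATIGRADO", "MALE"): 4,
})

#: Mean live weight of the reference population, kg.
REFERENCE_LIVE_WEIGHT_KG = 388.10

# Per-biotype trait means (cm): {trait: (Negro, Callejon, Atigrado)}.
_BIOTYPE_MEANS = {
    "HL": (50.70, 51.69, 53.14),
    "HW": (23.98, 23.06, 24.00),
    "HD": (29.02, 28.50, 29.86),
    "HaW": (124.02, 124.19, 124.50),
    "TL": (200.15, 208.13, 200.21),
    "BL": (145.49, 147.88, 144.43),
    "TP": (176.57, 180.81, 177.29),
    "SP": (17.98, 18.56, 18.36),
    "AP": (199.96, 204.63, 204.36),
    "TW": (39.11, 39.56, 39.00),
    "TD": (67.19, 67.56, 68.79),
    "ThL": (52.51, 51.94, 54.79),
    "RL": (48.00, 49.88, 48.21),
    "RW": (45.94, 48.00, 46.07),
    "RH": (125.75, 123.44, 124.57),
    "IW": (14.43, 14.75, 14.43),
    "NL": (33.51, 30.88, 32.14),
}

#: {biotype: {trait: mean cm}}.
REFERENCE_TRAIT_MEANS = MappingProxyType({
    biotype: MappingProxyType(
        {trait: _BIOTYPE_MEANS[trait][i] for trait in MEASUREMENTS}
    )
    for i, biotype in enumerate(BIOTYPES)
})

#: Pooled trait means (cm) across the whole reference population.
REFERENCE_POOLED_MEANS = MappingProxyType({
    "HL": 51.30, "HW": 23.81, "HD": 29.06, "HaW": 124.13, "TL": 201.70,
    "BL": 145.77, "TP": 177.51, "SP": 18.16, "AP": 201.60, "TW": 39.18,
    "TD": 67.53, "ThL": 52.78, "RL": 48.40, "RW": 46.36, "RH": 125.11,
    "IW": 14.49, "NL": 32.77,
})

#: Pooled coefficient of variation per trait (percent of the mean).
REFERENCE_TRAIT_CV = MappingProxyType({
    "HL": 6.02, "HW": 9.83, "HD": 10.56, "HaW": 3.63, "TL": 7.37,
    "BL": 6.49, "TP": 4.53, "SP": 7.52, "AP": 5.87, "TW": 9.61,
    "TD": 6.28, "ThL": 10.92, "RL": 5.91, "RW": 7.33, "RH": 9.23,
    "IW": 9.42, "NL": 11.32,
})

#: Pooled zoometric-index means of the reference population.  Used as the
#: end-to-end recovery target for the simulator (the generator is
#: calibrated on trait means and CVs only; these index means are what a
#: faithful simulation must reproduce via the index pipeline).
REFERENCE_INDEX_MEANS = MappingProxyType({
    "CEI": 46.53, "TI": 58.15, "BI": 82.19, "LBI": 85.47, "AI": 2.55,
    "PI": 95.85, "DTI": 10.24, "DCI": 46.70, "TPI": 37.36, "LPI": 38.99,
})

#: Per-biotype zoometric-index means of the reference population.
REFERENCE_INDEX_MEANS_BY_BIOTYPE = MappingProxyType({
    "NEGRO": MappingProxyType({
        "CEI": 47.42, "TI": 58.25, "BI": 82.47, "LBI": 85.58, "AI": 2.52,
        "PI": 95.76, "DTI": 10.20, "DCI": 46.27, "TPI": 37.06, "LPI": 38.70,
    }),
    "CALLEJON": MappingProxyType({
        "CEI": 44.71, "TI": 59.06, "BI": 81.88, "LBI": 84.11, "AI": 2.65,
        "PI": 96.32, "DTI": 10.26, "DCI": 47.63, "TPI": 38.68, "LPI": 40.21,
    }),
    "ATIGRADO": MappingProxyType({
        "CEI": 45.27, "TI": 56.74, "BI": 81.49, "LBI": 86.61, "AI": 2.52,
        "PI": 95.62, "DTI": 10.36, "DCI": 47.25, "TPI": 36.99, "LPI": 38.71,
    }),
})

# Strength classes for the qualitative correlation pattern.  Exact
# coefficients for the reference population are not public, so verbal
# strength classes are encoded as representative magnitudes.
STRONG = 0.7
INTERMEDIATE = 0.5
STRONG_NEGATIVE = -0.6

#: Qualitative trait-trait correlation pattern of the reference
#: population: {(trait_a, trait_b): target r}.  Pairs not listed default
#: to zero; head width (HW) correlates with nothing.
REFERENCE_CORRELATION_SPEC = MappingProxyType({
    # head length tracks overall frame size
    ("HL", "HaW"): STRONG,
    ("HL", "AP"): STRONG,
    ("HL", "RL"): STRONG,
    # head depth runs against thoracic depth
    ("HD", "TD"): STRONG_NEGATIVE,
    # height at withers tracks lengths, girths and rump dimensions
    ("HaW", "TL"): STRONG,
    ("HaW", "SP"): STRONG,
    ("HaW", "AP"): STRONG,
    ("HaW", "TW"): STRONG,
    ("HaW", "RW"): STRONG,
    ("HaW", "RL"): STRONG,
    # total length with trunk lengths and girths
    ("TL", "BL"): INTERMEDIATE,
    ("TL", "TP"): INTERMEDIATE,
    ("TL", "SP"): INTERMEDIATE,
    ("TL", "AP"): INTERMEDIATE,
    ("TL", "RL"): INTERMEDIATE,
    # body length with girths and rump length
    ("BL", "TP"): STRONG,
    ("BL", "AP"): STRONG,
    ("BL", "RL"): STRONG,
    # thoracic perimeter with abdominal girth and rump
    ("TP", "AP"): INTERMEDIATE,
    ("TP", "RL"): INTERMEDIATE,
    ("TP", "RW"): INTERMEDIATE,
    # shank perimeter
    ("SP", "AP"): INTERMEDIATE,
    ("SP", "RW"): INTERMEDIATE,
    # abdominal perimeter
    ("AP", "TW"): INTERMEDIATE,
    ("AP", "ThL"): INTERMEDIATE,
    ("AP", "RW"): INTERMEDIATE,
    # thoracic width
    ("TW", "TD"): INTERMEDIATE,
    ("TW", "RW"): INTERMEDIATE,
    ("TW", "RL"): INTERMEDIATE,
    ("TW", "NL"): INTERMEDIATE,
    # thoracic depth with rump dimensions
    ("TD", "RW"): STRONG,
    ("TD", "RL"): STRONG,
    # thoracic length vs ischium width (mild antagonism)
    ("ThL", "IW"): STRONG_NEGATIVE,
    # rump width and length grow together
    ("RW", "RL"): INTERMEDIATE,
})
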