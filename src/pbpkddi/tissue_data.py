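"""Reference tissue-composition table used by the partition-coefficient methods.

Fractional tissue volumes (extracellular water ``f_ew``, intracellular water
``f_iw``, neutral lipids ``f_nl``, neutral phospholipids ``f_np``), acidic
phospholipid content ``ap_mg_g`` (mg/g tissue) and the tissue:plasma albumin
ratio ``alb_ratio`` follow the published composition data commonly used with
the Rodgers & Rowland and Poulin & Theil distribution models.  Values are for
the reference adult; they are treated as composition *fractions* and are not
rescaled with body size.
"""

# pH of the relevant water spaces
PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_BLOOD_CELLS = 7.22

# plasma composition (fractions of plasma volume)
PLASMA_COMPOSITION = {"f_water": 0.945, "f_nl": 0.0023, "f_np": 0.0013}

# blood-cell composition, used to back-calculate acidic-phospholipid affinity
BLOOD_CELL_COMPOSITION = {
    "f_iw": 0.603,
    "f_nl": 0.0017,
    "f_np": 0.0029,
    "ap_mg_g": 0.5,
}

TISSUE_COMPOSITION = {
    #             f_ew    f_iw    f_nl     f_np     AP     alb
    "adipose":   (0.135, 0.017, 0.8530, 0.0016, 0.40, 0.049),
    "bone":      (0.100, 0.346, 0.0170, 0.0017, 0.67, 0.100),
    "brain":     (0.162, 0.620, 0.0390, 0.0015, 0.40, 0.048),
    "gut":       (0.282, 0.475, 0.0380, 0.0125, 2.41, 0.158),
    "heart":     (0.320, 0.456, 0.0140, 0.0111, 2.25, 0.157),
    "kidney":    (0.273, 0.483, 0.0120, 0.0240, 5.03, 0.130),
    "liver":     (0.161, 0.573, 0.0140, 0.0240, 4.56, 0.086),
    "lung":      (0.336, 0.446, 0.0220, 0.0128, 3.91, 0.212),
    "muscle":    (0.118, 0.630, 0.0100, 0.0072, 1.53, 0.064),
    "skin":      (0.382, 0.291, 0.0600, 0.0044, 1.32, 0.277),
    "spleen":    (0.207, 0.579, 0.0077, 0.0113, 3.18, 0.097),
    "gonads":    (0.255, 0.525, 0.0170, 0.0120, 3.00, 0.150),
    "stomach_wall": (0.282, 0.475, 0.0380, 0.0125, 2.41, 0.158),
    "rest":      (0.200, 0.550, 0.0400, 0.0100, 2.00, 0.150),
}

FIELDS = ("f_ew", "f_iw", "f_nl", "f_np", "ap_mg_g", "alb_ratio")


def composition(organ: str) -> dict:
    """Return the composition record for one organ as a dict."""
    try:
        row = TISSUE_COMPOSITION[organ]
    except KeyError:
        raise KeyError(f"no tissue composition for organ {organ!r}") from None
    return dict(zip(FIELDS, row))
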