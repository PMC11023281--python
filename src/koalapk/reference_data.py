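"""Published per-animal pharmacokinetic indices for paracetamol in koalas.

Eight animals received 15 mg/kg orally (K3-K8 went on to twice-daily
redosing; K2 and K4 were dosed a second time, giving eight oral profiles in
total) and two (K1, K2) received 15 mg/kg subcutaneously.  These printed
index values are the package's demonstration inputs: they drive the worked
example, the summary reproduction in ``scripts/acceptance.py`` and the
identity checks among MRT, Cl/F and Vz/F.  The underlying raw plasma
concentrations were never published, which is why the synthetic module -
not a data file - stands in for them everywhere else.

Units: ka, ke 1/h; t_half, tmax, mrt h; cmax ug/mL; AUCs ug h/mL;
AUMC ug h^2/mL; vz_f L/kg; cl_f L/(kg h).  Dose was 15 mg/kg throughout.
"""

DOSE_MG_PER_KG = 15.0

_FIELDS = (
    "ka", "ke", "t_half", "tmax", "cmax", "auc_0_24", "auc_0_inf",
    "auc_ratio", "aumc_0_inf", "mrt", "vz_f", "cl_f",
)


def _subject(*values):
    return dict(zip(_FIELDS, values))


#: single subcutaneous bolus, 15 mg/kg
SC_INDICES = {
    "K1": _subject(5.729, 0.144, 4.823, 0.5, 15.02, 124.53, 128.87, 0.97, 961.38, 7.460, 0.810, 0.116),
    "K2": _subject(1.588, 0.123, 5.616, 1.0, 19.61, 160.49, 170.15, 0.90, 1454.97, 8.545, 0.714, 0.088),
}

#: single oral administration, 15 mg/kg (K2r/K4r are the repeat dosings of
#: K2 and K4)
ORAL_INDICES = {
    "K3": _subject(0.295, 0.123, 5.658, 4.0, 17.33, 216.86, 233.91, 0.90, 2569.71, 10.986, 0.523, 0.064),
    "K4": _subject(0.691, 0.120, 5.788, 4.0, 16.10, 198.07, 213.79, 0.90, 2187.58, 10.232, 0.586, 0.070),
    "K5": _subject(0.194, 0.107, 6.449, 4.0, 17.21, 223.14, 248.73, 0.90, 2964.55, 11.919, 0.561, 0.060),
    "K6": _subject(0.225, 0.142, 4.889, 4.0, 20.25, 178.11, 186.40, 0.96, 1729.49, 9.279, 0.568, 0.080),
    "K7": _subject(0.159, 0.090, 7.669, 4.0, 18.59, 237.72, 279.05, 0.90, 3894.82, 14.957, 0.595, 0.054),
    "K8": _subject(0.323, 0.129, 5.363, 4.0, 14.30, 158.52, 168.66, 0.90, 1646.24, 9.761, 0.688, 0.089),
    "K2r": _subject(0.215, 0.149, 4.661, 4.0, 16.64, 182.32, 190.57, 0.96, 1813.98, 9.513, 0.593, 0.076),
    "K4r": _subject(0.175, 0.128, 5.423, 8.0, 13.66, 183.55, 197.90, 0.90, 2214.62, 11.191, 0.586, 0.070),
}

#: the six animals that continued on the twice-daily regimen
REPEAT_DOSE_SUBJECTS = ("K3", "K4", "K5", "K6", "K7", "K8")


def oral_values(field: str) -> list[float]:
    """The eight oral values of one index, in table order."""
    return [ORAL_INDICES[k][field] for k in ORAL_INDICES]


def sc_values(field: str) -> list[float]:
    """The two subcutaneous values of one index."""
    return [SC_INDICES[k][field] for k in SC_INDICES]


def repeat_dose_values(field: str) -> list[float]:
    """Values of one index for the six repeat-dose animals."""
    return [ORAL_INDICES[k][field] for k in REPEAT_DOSE_SUBJECTS]
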