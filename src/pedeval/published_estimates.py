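"""Published Dairy Gir variance components and genetic parameters.

Variance components (additive genetic, permanent environment, contemporary
group, residual) and the heritability/repeatability estimates published
for 18 conformation and milking traits of Brazilian Dairy Gir cattle under
the four repeatability models:

- M1, M2: contemporary group (CG) fixed; M3, M4: CG random;
- M1, M3 carry only screened fixed effects, M2, M4 all recorded effects;
- score traits additionally have threshold-scale estimates where the
  residual variance is the logistic constant pi^2/3 ~ 3.29.

These serve as worked examples: applying the heritability/repeatability
formulas to the variance components must reproduce the published h2 and r
at their printed precision.  The underlying records are not public; these
numbers are inputs, not outputs, of this package.

Each entry: (sigma_a2, sigma_pe2, sigma_cg2 or None, sigma_e2 or None) and
(h2, r).  Threshold entries have sigma_e2 = None (fixed at pi^2/3).
"""

from __future__ import annotations

from .mixed_model import VarianceComponents

TRAITS = ("STA", "HG", "BL", "RL", "PW", "HW", "RA", "FA", "LSV", "LRV",
          "FUA", "RUW", "UD", "TL", "TD", "NL", "ME", "TEM")

#: trait -> model label -> (sigma_a2, sigma_pe2, sigma_cg2, sigma_e2)
VARIANCE_COMPONENTS = {
    "STA": {"linear:M1": (8.54, 5.00, None, 3.54), "linear:M2": (8.54, 5.00, None, 3.53),
            "linear:M3": (8.90, 4.87, 3.29, 3.54), "linear:M4": (8.90, 4.87, 3.28, 3.54)},
    "HG":  {"linear:M1": (12.44, 18.53, None, 17.49), "linear:M2": (12.44, 18.53, None, 17.49),
            "linear:M3": (14.35, 17.39, 21.42, 17.54), "linear:M4": (14.35, 17.39, 21.42, 17.54)},
    "BL":  {"linear:M1": (7.65, 2.74, None, 15.76), "linear:M2": (4.46, 4.12, None, 14.18),
            "linear:M3": (5.00, 3.67, 4.73, 14.27), "linear:M4": (5.00, 3.67, 4.73, 14.27)},
    "RL":  {"linear:M1": (1.16, 1.55, None, 2.53), "linear:M2": (1.16, 1.55, None, 2.53),
            "linear:M3": (1.32, 1.40, 2.52, 2.62), "linear:M4": (1.32, 1.40, 2.52, 2.62)},
    "PW":  {"linear:M1": (0.65, 0.67, None, 1.77), "linear:M2": (0.65, 0.66, None, 1.77),
            "linear:M3": (0.66, 0.63, 2.19, 1.82), "linear:M4": (0.66, 0.63, 2.15, 1.82)},
    "HW":  {"linear:M1": (1.33, 1.35, None, 5.01), "linear:M2": (1.37, 1.95, None, 4.06),
            "linear:M3": (1.39, 1.32, 9.24, 5.00), "linear:M4": (1.55, 1.82, 4.04, 4.11)},
    "RA":  {"linear:M1": (3.54, 8.76, None, 17.66), "linear:M2": (3.54, 8.76, None, 17.66),
            "linear:M3": (3.43, 8.70, 7.32, 17.86), "linear:M4": (3.43, 8.71, 7.32, 17.86)},
    "FA":  {"linear:M1": (0.05, 0.10, None, 0.56), "linear:M2": (0.05, 0.11, None, 0.53),
            "linear:M3": (0.05, 0.09, 0.19, 0.56), "linear:M4": (0.05, 0.10, 0.10, 0.55),
            "threshold:M1": (0.31, 1.16, None, None), "threshold:M2": (0.33, 1.29, None, None),
            "threshold:M3": (0.28, 0.60, 1.18, None), "threshold:M4": (0.29, 0.66, 0.67, None)},
    "LSV": {"linear:M1": (0.07, 0.22, None, 0.50), "linear:M2": (0.07, 0.20, None, 0.45),
            "linear:M3": (0.06, 0.20, 0.07, 0.45), "linear:M4": (0.06, 0.20, 0.07, 0.45),
            "threshold:M1": (0.47, 1.68, None, None), "threshold:M2": (0.71, 2.50, None, None),
            "threshold:M3": (0.49, 1.53, 0.52, None), "threshold:M4": (0.49, 1.53, 0.52, None)},
    "LRV": {"linear:M1": (0.001, 0.27, None, 0.47), "linear:M2": (0.004, 0.26, None, 0.42),
            "linear:M3": (0.005, 0.26, 0.05, 0.42), "linear:M4": (0.006, 0.26, 0.05, 0.42),
            "threshold:M1": (0.00, 1.76, None, None), "threshold:M2": (0.04, 2.51, None, None),
            "threshold:M3": (0.03, 1.65, 0.40, None), "threshold:M4": (0.03, 1.66, 0.40, None)},
    "FUA": {"linear:M1": (0.04, 0.32, None, 0.29), "linear:M2": (0.05, 0.31, None, 0.28),
            "linear:M3": (0.04, 0.32, 0.27, 0.29), "linear:M4": (0.04, 0.31, 0.08, 0.29),
            "threshold:M1": (0.54, 5.70, None, None), "threshold:M2": (0.64, 5.74, None, None),
            "threshold:M3": (0.36, 3.31, 2.74, None), "threshold:M4": (0.41, 3.62, 0.87, None)},
    "RUW": {"linear:M1": (0.03, 0.14, None, 0.29), "linear:M2": (0.04, 0.13, None, 0.28),
            "linear:M3": (0.03, 0.15, 0.47, 0.29), "linear:M4": (0.04, 0.14, 0.13, 0.28),
            "threshold:M1": (0.50, 3.09, None, None), "threshold:M2": (0.58, 3.18, None, None),
            "threshold:M3": (0.92, 0.00, 5.73, None), "threshold:M4": (0.38, 1.69, 2.01, None)},
    "UD":  {"linear:M1": (0.08, 0.16, None, 0.44), "linear:M2": (0.08, 0.16, None, 0.44),
            "linear:M3": (0.07, 0.16, 0.10, 0.44), "linear:M4": (0.07, 0.16, 0.10, 0.44),
            "threshold:M1": (0.82, 2.99, None, None), "threshold:M2": (0.83, 2.99, None, None),
            "threshold:M3": (0.58, 1.49, 0.84, None), "threshold:M4": (0.58, 1.50, 0.85, None)},
    "TL":  {"linear:M1": (0.93, 0.57, None, 0.76), "linear:M2": (0.93, 0.57, None, 0.76),
            "linear:M3": (0.93, 0.56, 0.38, 0.77), "linear:M4": (0.93, 0.56, 0.38, 0.77)},
    "TD":  {"linear:M1": (0.16, 0.09, None, 0.29), "linear:M2": (0.09, 0.12, None, 0.24),
            "linear:M3": (0.10, 0.11, 0.11, 0.24), "linear:M4": (0.10, 0.11, 0.10, 0.24)},
    "NL":  {"linear:M1": (3.17, 2.89, None, 1.93), "linear:M2": (3.17, 2.89, None, 1.93),
            "linear:M3": (3.25, 2.80, 0.69, 1.95), "linear:M4": (3.25, 2.80, 0.69, 1.95)},
    "ME":  {"linear:M1": (0.08, 0.13, None, 0.33), "linear:M2": (0.09, 0.13, None, 0.33),
            "linear:M3": (0.09, 0.13, 0.14, 0.34), "linear:M4": (0.09, 0.13, 0.14, 0.34),
            "threshold:M1": (0.90, 1.24, None, None), "threshold:M2": (0.90, 1.25, None, None),
            "threshold:M3": (0.78, 0.58, 1.61, None), "threshold:M4": (0.77, 0.59, 1.57, None)},
    "TEM": {"linear:M1": (0.07, 0.19, None, 0.35), "linear:M2": (0.07, 0.19, None, 0.35),
            "linear:M3": (0.06, 0.19, 0.12, 0.35), "linear:M4": (0.06, 0.19, 0.12, 0.35),
            "threshold:M1": (0.66, 1.70, None, None), "threshold:M2": (0.65, 1.72, None, None),
            "threshold:M3": (0.52, 1.02, 1.21, None), "threshold:M4": (0.52, 1.03, 1.23, None)},
}

#: trait -> model label -> (h2, r) as published
GENETIC_PARAMETERS = {
    "STA": {"linear:M1": (0.50, 0.79), "linear:M2": (0.50, 0.79),
            "linear:M3": (0.43, 0.67), "linear:M4": (0.43, 0.67)},
    "HG":  {"linear:M1": (0.26, 0.64), "linear:M2": (0.26, 0.64),
            "linear:M3": (0.20, 0.45), "linear:M4": (0.20, 0.45)},
    "BL":  {"linear:M1": (0.29, 0.40), "linear:M2": (0.20, 0.38),
            "linear:M3": (0.18, 0.31), "linear:M4": (0.18, 0.31)},
    "RL":  {"linear:M1": (0.22, 0.52), "linear:M2": (0.22, 0.52),
            "linear:M3": (0.17, 0.35), "linear:M4": (0.17, 0.35)},
    "PW":  {"linear:M1": (0.21, 0.43), "linear:M2": (0.21, 0.43),
            "linear:M3": (0.12, 0.24), "linear:M4": (0.13, 0.24)},
    "HW":  {"linear:M1": (0.17, 0.35), "linear:M2": (0.19, 0.45),
            "linear:M3": (0.08, 0.16), "linear:M4": (0.13, 0.29)},
    "RA":  {"linear:M1": (0.12, 0.41), "linear:M2": (0.12, 0.41),
            "linear:M3": (0.09, 0.33), "linear:M4": (0.09, 0.33)},
    "FA":  {"linear:M1": (0.07, 0.21), "linear:M2": (0.07, 0.22),
            "linear:M3": (0.05, 0.16), "linear:M4": (0.06, 0.18),
            "threshold:M1": (0.07, 0.31), "threshold:M2": (0.07, 0.33),
            "threshold:M3": (0.05, 0.16), "threshold:M4": (0.06, 0.19)},
    "LSV": {"linear:M1": (0.09, 0.37), "linear:M2": (0.10, 0.37),
            "linear:M3": (0.08, 0.34), "linear:M4": (0.08, 0.33),
            "threshold:M1": (0.09, 0.40), "threshold:M2": (0.11, 0.49),
            "threshold:M3": (0.08, 0.35), "threshold:M4": (0.08, 0.35)},
    "LRV": {"linear:M1": (0.001, 0.37), "linear:M2": (0.007, 0.38),
            "linear:M3": (0.006, 0.36), "linear:M4": (0.008, 0.36),
            "threshold:M1": (0.00, 0.35), "threshold:M2": (0.01, 0.44),
            "threshold:M3": (0.01, 0.31), "threshold:M4": (0.01, 0.31)},
    "FUA": {"linear:M1": (0.06, 0.56), "linear:M2": (0.07, 0.56),
            "linear:M3": (0.04, 0.38), "linear:M4": (0.06, 0.48),
            "threshold:M1": (0.06, 0.65), "threshold:M2": (0.07, 0.66),
            "threshold:M3": (0.04, 0.38), "threshold:M4": (0.05, 0.49)},
    "RUW": {"linear:M1": (0.07, 0.38), "linear:M2": (0.08, 0.37),
            "linear:M3": (0.03, 0.19), "linear:M4": (0.06, 0.30),
            "threshold:M1": (0.07, 0.52), "threshold:M2": (0.08, 0.53),
            "threshold:M3": (0.09, 0.09), "threshold:M4": (0.05, 0.28)},
    "UD":  {"linear:M1": (0.11, 0.35), "linear:M2": (0.11, 0.35),
            "linear:M3": (0.09, 0.30), "linear:M4": (0.09, 0.30),
            "threshold:M1": (0.12, 0.54), "threshold:M2": (0.12, 0.54),
            "threshold:M3": (0.09, 0.33), "threshold:M4": (0.09, 0.33)},
    "TL":  {"linear:M1": (0.41, 0.66), "linear:M2": (0.41, 0.66),
            "linear:M3": (0.35, 0.56), "linear:M4": (0.35, 0.56)},
    "TD":  {"linear:M1": (0.30, 0.47), "linear:M2": (0.21, 0.47),
            "linear:M3": (0.18, 0.38), "linear:M4": (0.17, 0.38)},
    "NL":  {"linear:M1": (0.40, 0.76), "linear:M2": (0.40, 0.76),
            "linear:M3": (0.37, 0.70), "linear:M4": (0.37, 0.70)},
    "ME":  {"linear:M1": (0.15, 0.40), "linear:M2": (0.15, 0.40),
            "linear:M3": (0.13, 0.31), "linear:M4": (0.13, 0.32),
            "threshold:M1": (0.17, 0.39), "threshold:M2": (0.17, 0.40),
            "threshold:M3": (0.12, 0.22), "threshold:M4": (0.12, 0.22)},
    "TEM": {"linear:M1": (0.11, 0.43), "linear:M2": (0.11, 0.42),
            "linear:M3": (0.09, 0.35), "linear:M4": (0.09, 0.35),
            "threshold:M1": (0.12, 0.42), "threshold:M2": (0.12, 0.42),
            "threshold:M3": (0.09, 0.25), "threshold:M4": (0.09, 0.25)},
}

#: Biological trait ranges (continuous traits, measurement units).
TRAIT_RANGES = {
    "STA": (119, 155), "HG": (141, 210), "BL": (86, 127), "RL": (31, 59),
    "PW": (10, 29), "HW": (33, 62), "RA": (1, 50), "TL": (3, 14),
    "TD": (1, 8), "NL": (1, 20),
}


def variance_components(trait: str, model: str) -> VarianceComponents:
    """Published components as a :class:`VarianceComponents` object.

    Threshold entries get the logistic residual pi^2/3.
    """
    import numpy as np

    sa, spe, scg, se2 = VARIANCE_COMPONENTS[trait][model]
    if se2 is None:
        se2 = np.pi ** 2 / 3.0
    return VarianceComponents(sigma_a2=sa, sigma_pe2=spe, sigma_cg2=scg,
                              sigma_e2=se2)


def iter_worked_examples():
    """Yield (trait, model, VarianceComponents, published (h2, r))."""
    for trait, models in VARIANCE_COMPONENTS.items():
        for model, _ in models.items():
            if trait in GENETIC_PARAMETERS and model in GENETIC_PARAMETERS[trait]:
                yield (trait, model, variance_components(trait, model),
                       GENETIC_PARAMETERS[trait][model])
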