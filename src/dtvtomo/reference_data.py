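"""Published grey-value summaries from a birch-skewer water-uptake study.

Mean +/- standard deviation of voxel grey values per material category for
three processing chains applied to the *same* 9-seconds-of-data dynamic
time point on a laboratory microtomography system:

- ``conventional``: filtered backprojection of attenuation data
  (linear attenuation coefficient mu, cm^-1);
- ``analytical_pr``: filtered backprojection of phase-retrieved data
  (refractive decrement delta, x 1e-7, non-quantitative);
- ``regularised_pr``: directional-TV regularised reconstruction of
  phase-retrieved data against a high-quality dry reference
  (delta, x 1e-7).

These summaries serve as canonical inputs for the CNR arithmetic and the
halfway water-classification threshold; the raw projection data behind
them are not distributed.
"""

from __future__ import annotations

#: category -> (mean, sd); see module docstring for units per chain
GREY_VALUE_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "conventional": {  # mu, cm^-1
        "air": (-0.02, 0.28),
        "birch": (0.08, 0.28),
        "water": (0.10, 0.28),
    },
    "analytical_pr": {  # delta, x 1e-7
        "air": (0.81, 1.85),
        "birch": (4.00, 1.65),
        "water": (5.14, 1.62),
    },
    "regularised_pr": {  # delta, x 1e-7
        "air": (0.97, 0.35),
        "birch": (3.98, 0.24),
        "water": (5.11, 0.31),
    },
}

#: instrument geometry of the study, usable as defaults for simulations
STUDY_GEOMETRY = {
    "R1": 320.0,  # mm
    "R2": 140.0,  # mm
    "sigma_s": 70.0,  # um
    "sigma_d": 30.0,  # um
    "pixel_pitch": 15.0,  # um
    "lambda_eff": 6.53e-11,  # m (~19 keV effective)
    "delta_beta": 1000.0,  # empirically refined from a cellulose estimate of 1896
}
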