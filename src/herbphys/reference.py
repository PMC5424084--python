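"""Published group means used as inputs (scenario settings, arithmetic checks).

These are the reported trait panel means (+/- 1 SE) by treatment for the
three focal species, and the modelled late-June plant-level PPFD means.
They serve two roles: (1) settings for paper-like synthetic scenarios, and
(2) inputs to the percent-difference arithmetic that produces the headline
treatment-effect percentages.  Nothing here is an output of this package.
"""

# trait -> {treatment -> (mean, se)}; life-stage-split traits carry a suffix
TABLE2 = {
    "Alliaria": {
        "sla_rosette": {"unfenced": (350.0, 19.0), "fenced": (674.0, 54.0)},
        "sla_adult": {"unfenced": (451.0, 23.0), "fenced": (416.0, 25.0)},
        "leaf_area_rosette": {"unfenced": (6.21, 0.55), "fenced": (10.31, 1.15)},
        "leaf_area_adult": {"unfenced": (21.87, 1.98), "fenced": (19.59, 2.19)},
        "a_max": {"unfenced": (9.40, 0.82), "fenced": (6.26, 0.72)},
        "r_d": {"unfenced": (0.52, 0.07), "fenced": (0.34, 0.51)},
        "phi": {"unfenced": (0.077, 0.003), "fenced": (0.071, 0.006)},
        "lsp": {"unfenced": (643.9, 71.6), "fenced": (393.3, 71.3)},
        "lcp": {"unfenced": (6.9, 0.9), "fenced": (4.7, 0.5)},
        "v_cmax": {"unfenced": (27.73, 1.06), "fenced": (11.02, 1.09)},
        "j_max": {"unfenced": (43.49, 1.44), "fenced": (21.00, 1.44)},
    },
    "Maianthemum": {
        "sla": {"unfenced": (211.0, 6.0), "fenced": (314.0, 29.0)},
        "leaf_area": {"unfenced": (20.74, 1.22), "fenced": (37.76, 4.31)},
        "a_max": {"unfenced": (6.66, 0.56), "fenced": (4.70, 0.39)},
        "r_d": {"unfenced": (0.24, 0.02), "fenced": (0.12, 0.02)},
        "phi": {"unfenced": (0.075, 0.003), "fenced": (0.069, 0.003)},
        "lsp": {"unfenced": (468.4, 60.3), "fenced": (192.4, 28.3)},
        "lcp": {"unfenced": (3.3, 0.4), "fenced": (1.5, 0.2)},
        "v_cmax": {"unfenced": (24.6, 2.22), "fenced": (22.05, 0.76)},
        "j_max": {"unfenced": (40.66, 2.61), "fenced": (35.88, 0.68)},
    },
    "Trillium": {
        "sla": {"unfenced": (426.0, 17.0), "fenced": (416.0, 36.0)},
        "leaf_area": None,  # not measured (fixed-area punches)
        "a_max": {"unfenced": (4.99, 0.28), "fenced": (6.78, 0.19)},
        "r_d": {"unfenced": (0.13, 0.02), "fenced": (0.19, 0.02)},
        "phi": {"unfenced": (0.089, 0.004), "fenced": (0.084, 0.004)},
        "lsp": {"unfenced": (451.8, 51.8), "fenced": (512.8, 51.0)},
        "lcp": {"unfenced": (1.5, 0.3), "fenced": (2.4, 0.2)},
        # A/Ci curves exist for fenced plants only
        "v_cmax": {"unfenced": None, "fenced": (18.89, 1.23)},
        "j_max": {"unfenced": None, "fenced": (41.97, 2.38)},
    },
}

# modelled plant-level light availability (mean, se), umol photons m-2 s-1
PPFD_MEANS = {
    "mid_may": {"unfenced": (50.8, 12.5), "fenced": (57.4, 7.7)},
    "late_june": {"unfenced": (52.03, 11.27), "fenced": (15.63, 4.95)},
}
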