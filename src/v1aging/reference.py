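"""Published reference statistics for young-adult and senescent rat V1.

These constants are transcribed group summaries (mean, SD, n) from the
single-unit, immunofluorescence and western-blot comparisons that this
package models.  They serve two roles: they parameterize the synthetic-data
generator's group presets, and they are the inputs to the reproduction
report (percent-change block, layer-wise ratio decreases) so that no
analysis script ever hand-types them.

Units: firing rates in spikes/s, densities in cells/mm^2, proportions in
percent, fluorescence intensity on a [0, 1] scale, blot values as optical
density normalized to GAPDH (dimensionless).
"""

from __future__ import annotations

CORTICAL_LAYERS = ("I", "II-III", "IV", "V", "VI")

#: Per-group single-unit response summaries: metric -> group -> (mean, sd).
GROUP_STATS = {
    "osi": {"young": (0.71, 0.18), "old": (0.48, 0.18)},
    "dsi": {"young": (0.48, 0.25), "old": (0.33, 0.17)},
    "or": {"young": (47.1, 27.9), "old": (99.1, 29.5)},
    "ar": {"young": (21.9, 17.3), "old": (61.5, 23.2)},
    "sa": {"young": (3.4, 2.6), "old": (24.7, 11.7)},
    "snr": {"young": (18.3, 14.7), "old": (5.2, 3.2)},
}

#: Number of neurons analysed per group.
N_NEURONS = {"young": 79, "old": 83}

#: Simple/complex cell counts per group (simple, complex).
SIMPLE_COMPLEX = {"young": (32, 47), "old": (29, 54)}

#: Total-neuron (NeuN+) density per cortical layer, cells/mm^2: (mean, sd).
NEUN_DENSITY = {
    "young": {
        "I": (3309, 817),
        "II-III": (14668, 2948),
        "IV": (17882, 2928),
        "V": (16261, 3413),
        "VI": (13098, 3551),
    },
    "old": {
        "I": (3282, 522),
        "II-III": (14568, 2749),
        "IV": (17401, 1879),
        "V": (15868, 2275),
        "VI": (12887, 3869),
    },
}

#: GABA-positive neuron density per layer, cells/mm^2: (mean, sd).
GABA_DENSITY = {
    "young": {
        "I": (2765, 839),
        "II-III": (2139, 542),
        "IV": (3034, 681),
        "V": (2779, 495),
        "VI": (1821, 534),
    },
    "old": {
        "I": (954, 502),
        "II-III": (771, 242),
        "IV": (881, 196),
        "V": (1117, 426),
        "VI": (483, 151),
    },
}

#: Proportion of GABA-positive neurons per layer, percent: (mean, sd).
GABA_PROPORTION = {
    "young": {
        "I": (82.6, 10.6),
        "II-III": (14.8, 3.0),
        "IV": (16.8, 2.1),
        "V": (18.1, 5.6),
        "VI": (14.3, 3.2),
    },
    "old": {
        "I": (29.1, 13.8),
        "II-III": (5.3, 1.3),
        "IV": (5.1, 1.3),
        "V": (6.9, 2.3),
        "VI": (4.1, 1.9),
    },
}

#: Mean fluorescence intensity per marker, [0, 1] scale: group -> (mean, sd).
FLUOR_INTENSITY = {
    "gad65": {"young": (0.153, 0.045), "old": (0.136, 0.048)},
    "gad67": {"young": (0.166, 0.039), "old": (0.086, 0.032)},
    "gabaa_r_alpha1": {"young": (0.152, 0.037), "old": (0.118, 0.035)},
}

#: Western-blot OD normalized to GAPDH: marker -> group -> (mean, sd).
BLOT_RATIO = {
    "gad65": {"young": (0.671, 0.063), "old": (0.595, 0.056)},
    "gad67": {"young": (0.872, 0.079), "old": (0.694, 0.075)},
    "gabaa_r_alpha1": {"young": (0.513, 0.099), "old": (0.308, 0.127)},
}

#: Animals per group (blot lanes are per animal).
N_ANIMALS = {"young": 6, "old": 6}

#: Slices quantified per group for fluorescence intensity (10 per animal).
N_INTENSITY_SLICES = {"young": 60, "old": 60}
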