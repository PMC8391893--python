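"""Published reference tables used as test inputs.

Per-fold confusion matrices (rows in printed order, canonical class order
AFIB/AFL/NSR), the printed per-class percent metrics for each fold and the
pooled matrix, the pooled binary matrix, per-part RR-interval counts, and
the cohort-level counts.
"""

import numpy as np

FOLD_MATRICES = [
    np.array([[2064, 162, 0], [34, 2617, 0], [0, 0, 2015]]),
    np.array([[2268, 9, 0], [0, 2667, 0], [0, 0, 1980]]),
    np.array([[2068, 290, 0], [0, 2584, 0], [0, 0, 1980]]),
    np.array([[2143, 209, 0], [3, 2563, 0], [0, 0, 2029]]),
    np.array([[2217, 69, 0], [12, 2621, 0], [0, 0, 2020]]),
    np.array([[2298, 0, 0], [0, 2649, 0], [0, 3, 1970]]),
    np.array([[1965, 216, 0], [0, 2594, 0], [0, 0, 1992]]),
    np.array([[1749, 357, 0], [20, 2492, 0], [0, 0, 2017]]),
    np.array([[2064, 99, 0], [17, 2587, 0], [0, 9, 1966]]),
    np.array([[2361, 0, 0], [0, 2535, 0], [0, 0, 1975]]),
]

ALL_MATRIX = np.array([[21197, 1411, 0], [86, 25909, 0], [0, 12, 19944]])

# (fold, class) -> (ACC, SEN, SPE) in percent as printed
FOLD_METRICS = {
    (1, "AFIB"): (97.16, 92.72, 99.27), (1, "AFL"): (97.16, 98.72, 96.18),
    (1, "NSR"): (100.00, 100.00, 100.00),
    (2, "AFIB"): (99.87, 99.60, 100.00), (2, "AFL"): (99.87, 100.00, 99.79),
    (2, "NSR"): (100.00, 100.00, 100.00),
    (3, "AFIB"): (95.81, 87.70, 100.00), (3, "AFL"): (95.81, 100.00, 93.31),
    (3, "NSR"): (100.00, 100.00, 100.00),
    (4, "AFIB"): (96.95, 91.11, 99.93), (4, "AFL"): (96.95, 99.88, 95.23),
    (4, "NSR"): (100.00, 100.00, 100.00),
    (5, "AFIB"): (98.83, 96.98, 99.74), (5, "AFL"): (98.83, 99.54, 98.40),
    (5, "NSR"): (100.00, 100.00, 100.00),
    (6, "AFIB"): (100.00, 100.00, 100.00), (6, "AFL"): (99.96, 100.00, 99.93),
    (6, "NSR"): (99.96, 99.85, 100.00),
    (7, "AFIB"): (96.81, 90.10, 100.00), (7, "AFL"): (96.81, 100.00, 94.82),
    (7, "NSR"): (100.00, 100.00, 100.00),
    (8, "AFIB"): (94.32, 83.05, 99.56), (8, "AFL"): (94.32, 99.20, 91.34),
    (8, "NSR"): (100.00, 100.00, 100.00),
    (9, "AFIB"): (98.28, 95.42, 99.63), (9, "AFL"): (98.15, 99.35, 97.39),
    (9, "NSR"): (99.86, 99.54, 100.00),
    (10, "AFIB"): (100.00, 100.00, 100.00), (10, "AFL"): (100.00, 100.00, 100.00),
    (10, "NSR"): (100.00, 100.00, 100.00),
}

ALL_METRICS = {
    "AFIB": (97.82, 93.76, 99.81),
    "AFL": (97.80, 99.67, 96.66),
    "NSR": (99.98, 99.94, 100.00),
}

BINARY_MATRIX = np.array([[48603, 0], [12, 19944]])
BINARY_ACC = 99.98
BINARY_SEN_ARRHYTHMIA = 100.00  # abstract-style orientation
BINARY_SPE_ARRHYTHMIA = 99.94

# per-part RR-interval counts
PART_NSR = [2015, 1980, 1980, 2029, 2020, 1973, 1992, 2017, 1975, 1975]
PART_AFIB = [2651, 2667, 2584, 2566, 2633, 2649, 2594, 2512, 2604, 2535]
PART_AFL = [742, 759, 786, 784, 762, 766, 727, 702, 721, 787]
PART_AFLSC = [2226, 2277, 2358, 2352, 2286, 2298, 2181, 2106, 2163, 2361]

# cohort-level counts
RR_COUNTS = {"NSR": 33976, "AFIB": 25995, "AFL": 7536}
TOTAL_RR = 67507
N_BLOCKS = {"NSR": 1826, "AFIB": 1780, "AFL": 445}
NSR_SAMPLES = 109_560_000  # 1826 blocks x 12 leads x 5000 samples
COMPRESSION_RATIO = 3224.6291
FOLD1_TRAIN_TOTAL = 53823
FOLD1_TRAIN_PER_CLASS = 17941
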