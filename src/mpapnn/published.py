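"""Published hold-out benchmark results on the 11 UCI datasets.

These constants transcribe the reported per-dataset hold-out confusion
matrices and accuracy columns for the standard PNN, the MPA-trained PNN, and
the three competing metaheuristic-PNN hybrids (CHIO-PNN, ABO-PNN, B-HC-PNN),
together with the feature counts and accuracy gains used for the
dimensionality-sensitivity analysis.  They serve as fixed inputs for report
tables and arithmetic consistency checks; the competitor hybrids are never
re-implemented here.

Two reported MPA-PNN confusion rows (LD and Heart) do not sum to their
stated hold-out test sizes (85 vs 86 and 66 vs 68) and are therefore flagged
inconsistent and excluded from accuracy-consistency checks.
"""

from __future__ import annotations

from .evaluation import ConfusionMatrix

DATASET_NAMES = [
    "PID",
    "HSS",
    "AP",
    "BC",
    "LD",
    "Heart",
    "GCD",
    "Parkinson",
    "SPECTF",
    "ACA",
    "Fourclass",
]

# Hold-out confusion matrices (TP, FP, TN, FN) per dataset and method.
HOLDOUT_CONFUSION = {
    "PNN": {
        "PID": ConfusionMatrix(35, 28, 90, 39),
        "HSS": ConfusionMatrix(44, 12, 6, 15),
        "AP": ConfusionMatrix(23, 1, 1, 2),
        "BC": ConfusionMatrix(14, 9, 36, 13),
        "LD": ConfusionMatrix(18, 15, 34, 19),
        "Heart": ConfusionMatrix(27, 5, 23, 13),
        "GCD": ConfusionMatrix(133, 46, 39, 32),
        "Parkinson": ConfusionMatrix(38, 1, 6, 4),
        "SPECTF": ConfusionMatrix(49, 4, 5, 9),
        "ACA": ConfusionMatrix(60, 14, 84, 15),
        "Fourclass": ConfusionMatrix(78, 0, 138, 0),
    },
    "MPA-PNN": {
        "PID": ConfusionMatrix(42, 20, 122, 8),
        "HSS": ConfusionMatrix(52, 5, 15, 5),
        "AP": ConfusionMatrix(23, 1, 2, 1),
        "BC": ConfusionMatrix(19, 3, 48, 2),
        "LD": ConfusionMatrix(33, 3, 48, 1),
        "Heart": ConfusionMatrix(30, 0, 24, 12),
        "GCD": ConfusionMatrix(166, 13, 45, 26),
        "Parkinson": ConfusionMatrix(40, 1, 6, 2),
        "SPECTF": ConfusionMatrix(48, 3, 14, 2),
        "ACA": ConfusionMatrix(71, 4, 95, 3),
        "Fourclass": ConfusionMatrix(78, 0, 138, 0),
    },
}

# Confusion rows whose counts do not match the stated test size.
INCONSISTENT_ROWS = {("MPA-PNN", "LD"), ("MPA-PNN", "Heart")}

# Reported hold-out accuracy columns (percent) for the comparison table.
HOLDOUT_ACCURACY = {
    "PNN": {
        "PID": 65.104, "HSS": 64.935, "AP": 88.889, "BC": 69.444,
        "LD": 60.465, "Heart": 73.529, "GCD": 68.800, "Parkinson": 89.796,
        "SPECTF": 80.597, "ACA": 83.237, "Fourclass": 100.000,
    },
    "MPA-PNN": {
        "PID": 85.416, "HSS": 87.012, "AP": 92.592, "BC": 93.055,
        "LD": 94.860, "Heart": 81.818, "GCD": 84.400, "Parkinson": 93.877,
        "SPECTF": 92.537, "ACA": 95.953, "Fourclass": 100.000,
    },
    "CHIO-PNN": {
        "PID": 83.850, "HSS": 85.410, "AP": 96.760, "BC": 90.020,
        "LD": 91.860, "Heart": 82.350, "GCD": 83.600, "Parkinson": 91.830,
        "SPECTF": 94.020, "ACA": 95.790, "Fourclass": 100.000,
    },
    "ABO-PNN": {
        "PID": 83.330, "HSS": 84.420, "AP": 96.300, "BC": 84.720,
        "LD": 84.880, "Heart": 82.350, "GCD": 82.800, "Parkinson": 95.920,
        "SPECTF": 89.550, "ACA": 94.800, "Fourclass": 100.000,
    },
    "B-HC-PNN": {
        "PID": 81.250, "HSS": 85.720, "AP": 96.300, "BC": 84.720,
        "LD": 93.020, "Heart": 86.760, "GCD": 80.800, "Parkinson": 91.840,
        "SPECTF": 93.040, "ACA": 93.060, "Fourclass": 100.000,
    },
}

# Dimensionality-sensitivity inputs: feature count d and reported hold-out
# accuracy gain (MPA-PNN minus PNN, percentage points) per dataset.
FEATURE_COUNTS = {
    "Fourclass": 2, "HSS": 3, "LD": 6, "AP": 7, "PID": 8, "BC": 10,
    "Heart": 13, "ACA": 14, "GCD": 20, "Parkinson": 23, "SPECTF": 45,
}
ACCURACY_GAIN = {
    "Fourclass": 0.00, "HSS": 22.10, "LD": 34.80, "AP": 3.70, "PID": 20.30,
    "BC": 23.70, "Heart": 8.30, "ACA": 12.80, "GCD": 15.60,
    "Parkinson": 4.10, "SPECTF": 11.90,
}

# Number of pairwise method/dataset comparisons in the multiple-testing table.
N_PAIRWISE_COMPARISONS = 44
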