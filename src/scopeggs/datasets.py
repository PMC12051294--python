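"""Published summary statistics bundled as inputs.

Small numeric tables released with the *Bradysia coprophila* (fungus gnat)
chromosome-scale assembly: assembly contiguity statistics, the polytene
X-chromosome landmark distances, and the example fungus-gnat joint SCO
probability matrix.  They are inputs to the worked examples and regression
checks — everything derived from them is recomputed at run time.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ASSEMBLY_PRIMARY_STATS",
    "x_scaffold_length_from_stats",
    "x_scaffold_length_from_median",
    "X_SCAFFOLD_LENGTH",
    "X_LANDMARK_ROWS",
    "GNAT_PAIR_JOINT_PROBS",
    "GNAT_PAIR_LABELS_A",
    "GNAT_PAIR_LABELS_B",
    "GNAT_PAIR_PRINTED_MARGINALS_A",
]

# Contiguity statistics of the four-scaffold primary assembly (bp).  The
# four chromosome-scale scaffolds are X, II, III and IV; the X scaffold is
# neither the longest, shortest, nor the N50 sequence, so its length is
# recoverable from these summaries alone.
ASSEMBLY_PRIMARY_STATS = {
    "n_sequences": 4,
    "sum_len": 296_980_291,
    "max_len": 97_081_274,
    "min_len": 58_343_183,
    "median_len": 70_777_917,
    "n50": 71_047_972,
}


def x_scaffold_length_from_stats(stats: dict | None = None) -> int:
    """X scaffold length as total − longest − shortest − N50 (the four
    scaffolds comprise exactly those three plus the X)."""
    s = stats or ASSEMBLY_PRIMARY_STATS
    return int(s["sum_len"] - s["max_len"] - s["min_len"] - s["n50"])


def x_scaffold_length_from_median(stats: dict | None = None) -> int:
    """Cross-check: with 4 sequences the median is the mean of the two
    central lengths (X and the N50 sequence), so X = 2·median − N50."""
    s = stats or ASSEMBLY_PRIMARY_STATS
    return int(2 * s["median_len"] - s["n50"])


X_SCAFFOLD_LENGTH = x_scaffold_length_from_stats()  # 70,507,862 bp

# Polytene-map landmark pairs on the X: (locus_1, locus_2, distance in
# sub-zones on the banding map, observed scaffold distance in Mb).
X_LANDMARK_ROWS: list[tuple[str, str, float, float]] = [
    ("Centromere", "FBR1", 2.0, 3.49),
    ("5' X' break point", "FBR1", 0.5, 0.620),
    ("FBR1", "FBR2", 7.0, 10.3),
    ("FBR2", "FBR3", 26.0, 42.7),
    ("FBR3", "3' X' break point", 3.0, 4.65),
    ("FBR3", "3' end of chromosome", 6.0, 12.3),
]

# Example joint SCO probability matrix between the two fungus gnats
# (B. coprophila chromosomes X, II, III, IV against P. hygida X, C, B, A),
# as printed (rounded to 3 digits; the underlying entropies were computed
# on unrounded values, so rounded rows can differ from printed marginals
# in the third decimal).
GNAT_PAIR_LABELS_A = ["X", "II", "III", "IV"]
GNAT_PAIR_LABELS_B = ["X", "C", "B", "A"]
GNAT_PAIR_JOINT_PROBS = np.array(
    [
        [0.253, 0.002, 0.002, 0.003],
        [0.000, 0.166, 0.001, 0.003],
        [0.002, 0.001, 0.241, 0.004],
        [0.002, 0.002, 0.002, 0.315],
    ]
)
GNAT_PAIR_PRINTED_MARGINALS_A = {"X": 0.261, "II": 0.170, "III": 0.248, "IV": 0.321}
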