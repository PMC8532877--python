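"""Published summary tallies from the goat LD/BF skeletal-muscle
hybrid-sequencing study.

These printed numbers are *inputs* to bookkeeping recomputations — the
pipeline's category partitions, percentage arithmetic and summary-level
t statistics can be rebuilt from them without the raw reads.  LD =
longissimus dorsi, BF = biceps femoris.
"""

from __future__ import annotations

import pandas as pd

# CCS classification per size library.  Filtered short + non-full-length
# + full-length partitions the CCS total; FLNC is the non-concatemer
# subset of full-length.  5'/3'/polyA tallies are over all CCS.
CCS_CLASSIFICATION = pd.DataFrame(
    {
        "1-2kb": [144_625, 100_807, 105_218, 102_657, 10_454, 46_175, 87_996, 87_230],
        "2-3kb": [133_687, 90_964, 95_303, 93_083, 3_043, 50_806, 79_838, 77_147],
        "3-6kb": [135_310, 79_482, 84_285, 80_576, 6_894, 60_436, 67_980, 61_032],
    },
    index=["ccs", "reads_5p", "reads_3p", "polya", "filtered_short",
           "non_full_length", "full_length", "flnc"],
)

# FLNC-to-genome category counts: before correction, after short-read
# error correction, and the per-read best-of-both merge.
ALIGNMENT_CATEGORIES = pd.DataFrame(
    {
        "pre_correction": [2_645, 1_467, 14_116, 207_181],
        "post_correction": [1_159, 1_506, 11_041, 211_703],
        "merge": [1_144, 1_333, 9_935, 212_997],
    },
    index=["unmapped", "multiple_best", "low_pid", "high_quality"],
)

# Loci length distribution of the reference annotation vs the long-read
# catalogue, plus isoform totals.
LOCI_LENGTH_BINS = pd.DataFrame(
    {
        "refseq": [4_284, 5_770, 4_401, 8_115],
        "pacbio": [1_214, 3_254, 4_637, 9_386],
    },
    index=["<1K", "1-2K", "2-3K", ">=3K"],
)
TOTAL_LOCI = {"refseq": 22_570, "pacbio": 18_491}
TOTAL_ISOFORMS = {"refseq": 46_472, "pacbio": 45_574}

# Differential-expression bookkeeping (BF vs LD).
DEG_UP, DEG_DOWN = 84, 147
DEI_UP, DEI_DOWN = 534, 639
DEG_TOTAL, DEI_TOTAL = 231, 1_173
DEG_NOVEL, DEI_NOVEL = 45, 642

# Isoform detection by platform (hybrid union of 53,128 isoforms).
ISOFORM_SETS = {"shared": 11_422, "pacbio_only": 34_152, "illumina_only": 7_554}

# Meat-quality traits: per-group mean ± SEM, n = 4 animals, with the
# printed two-sided p-values.
MEAT_QUALITY = pd.DataFrame(
    [
        ("pH45min", 6.71, 0.13, 6.94, 0.13, 0.26),
        ("pH24h", 5.72, 0.06, 5.83, 0.08, 0.28),
        ("Lightness_L", 35.35, 1.59, 35.23, 1.46, 0.96),
        ("Redness_a", 11.63, 0.75, 14.08, 0.41, 0.03),
        ("Yellowness_b", 1.28, 0.43, 0.53, 0.37, 0.23),
        ("Water_loss_pct", 33.02, 2.12, 28.14, 5.22, 0.42),
        ("Water_hold_pct", 48.44, 1.98, 46.33, 0.75, 0.32),
        ("Shear_force_N", 29.06, 2.54, 48.65, 7.20, 0.04),
        ("Marbling_score", 6.00, 0.00, 5.25, 0.25, 0.02),
    ],
    columns=["trait", "mean_LD", "sem_LD", "mean_BF", "sem_BF", "printed_p"],
)
MEAT_QUALITY_N = 4


def meat_quality_summaries() -> pd.DataFrame:
    """Trait table in the shape trait_table_tests expects."""
    df = MEAT_QUALITY.rename(columns={
        "mean_LD": "mean1", "sem_LD": "sem1",
        "mean_BF": "mean2", "sem_BF": "sem2"})
    df["n1"] = MEAT_QUALITY_N
    df["n2"] = MEAT_QUALITY_N
    return df
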