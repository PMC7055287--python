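"""Declared numeric conventions shared across the pipeline.

Everything a downstream analysis might legitimately want to override lives
here as a plain module-level constant: amino-acid masses and pKa values for
the physicochemical summaries, the alignment scoring used for duplication
detection, the subfamily priority order, and the default thresholds of each
pipeline stage.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Average (not monoisotopic) residue masses in Daltons, ExPASy convention.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# pKa set for net-charge / pI calculation (Henderson-Hasselbalch, termini
# included). Positive groups gain a proton below their pKa, negative groups
# lose one above it.
PKA_POSITIVE = {"NTERM": 9.094, "K": 10.53, "R": 12.48, "H": 6.0}
PKA_NEGATIVE = {"CTERM": 3.55, "D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.07}

# Tandem-repeat profile scan defaults.
PROFILE_WIDTH = 33               # canonical ankyrin repeat length
PROFILE_PSEUDOCOUNT = 1.0
SCAN_SCORE_THRESHOLD = 10.0      # bits; well above background window scores
SIGNIFICANCE_CUTOFF = 1e-5       # candidates with best-hit significance above this are dropped
NULL_WINDOWS = 1000              # shuffled windows behind each significance estimate

# Subfamily classification: priority when several non-repeat domains co-occur.
SUBFAMILY_PRIORITY = ["TM", "PK", "ZnF", "BTB", "ACBP", "GPCR", "BPA", "IQ", "RF", "TPR"]
SUBFAMILY_VOCAB = ["ANK-U"] + [f"ANK-{d}" for d in SUBFAMILY_PRIORITY] + ["ANK-O"]

# Gene-density clustering defaults (the source study describes clusters only
# qualitatively, so these are deliberate, overridable choices).
CLUSTER_WINDOW_BP = 2_000_000
CLUSTER_STEP_BP = 100_000
CLUSTER_MIN_GENES = 3

# Duplication-pair detection (global protein alignment).
ALIGN_MATRIX = "BLOSUM62"
ALIGN_GAP_OPEN = -10.0
ALIGN_GAP_EXTEND = -0.5
MIN_COVERAGE_PCT = 70.0
MIN_IDENTITY_PCT = 70.0
MIN_DUPLICATION_EVENTS = 2
MAX_INTERVENING_GENES = 5        # tandem vs segmental cutoff

# Molecular clock: synonymous substitutions per site per year.
CLOCK_LAMBDA = 6.96e-9

# Promoter extraction window (bp upstream of the start codon).
PROMOTER_WINDOW = 1500

# Expression defaults.
RPKM_EXPRESSED_THRESHOLD = 0.0   # "expressed" means RPKM strictly above this
LOG_PSEUDOCOUNT = 1.0
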