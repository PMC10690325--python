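"""Shared configuration constants: organ-system vocabulary, chromosome
lengths, and the default X-region map.

Everything here is *configuration*, not science: the 22 organ/tissue/system
(OP) labels mirror the top-level phenotypic-abnormality categories of the
Human Phenotype Ontology, chromosome lengths are rounded hg38 values used
only to place synthetic genes, and the X-region intervals ship as editable
defaults (the pseudoautosomal coordinates are the NCBI GRCh38.p13
annotations; the conserved/added boundary and the strata intervals are
synthetic defaults meant to be replaced by user-supplied hg38 tables).
"""

from __future__ import annotations

# 22 organ/tissue/system phenotype categories, ordered by the fraction of
# disease genes annotated to each (OP1 = nervous system, OP7 = genitourinary).
SYSTEMS: list[tuple[str, str]] = [
    ("OP1", "the nervous system"),
    ("OP2", "the eye"),
    ("OP3", "the ear"),
    ("OP4", "the head and neck"),
    ("OP5", "the musculoskeletal system"),
    ("OP6", "the cardiovascular system"),
    ("OP7", "the genitourinary system"),
    ("OP8", "the respiratory system"),
    ("OP9", "the digestive system"),
    ("OP10", "the skin and integument"),
    ("OP11", "the endocrine system"),
    ("OP12", "the immune system"),
    ("OP13", "blood and blood-forming tissues"),
    ("OP14", "metabolism and homeostasis"),
    ("OP15", "growth"),
    ("OP16", "the connective tissue"),
    ("OP17", "the limbs"),
    ("OP18", "prenatal development or birth"),
    ("OP19", "the thoracic cavity"),
    ("OP20", "the voice"),
    ("OP21", "the cellular phenotype"),
    ("OP22", "constitutional symptoms"),
]

SYSTEM_LABELS: list[str] = [label for label, _ in SYSTEMS]
SYSTEM_NAMES: dict[str, str] = dict(SYSTEMS)

AUTOSOMES: list[str] = [str(i) for i in range(1, 23)]
SEX_CHROMOSOMES: list[str] = ["X", "Y"]
PLACED_CHROMOSOMES: set[str] = set(AUTOSOMES) | set(SEX_CHROMOSOMES)

# Rounded hg38 chromosome lengths (bp); used by the synthetic generator for
# gene placement, never by the analysis itself.
CHROMOSOME_SIZES: dict[str, int] = {
    "1": 248_000_000, "2": 242_000_000, "3": 198_000_000, "4": 190_000_000,
    "5": 182_000_000, "6": 171_000_000, "7": 159_000_000, "8": 145_000_000,
    "9": 138_000_000, "10": 134_000_000, "11": 135_000_000, "12": 133_000_000,
    "13": 114_000_000, "14": 107_000_000, "15": 102_000_000, "16": 90_000_000,
    "17": 83_000_000, "18": 80_000_000, "19": 59_000_000, "20": 64_000_000,
    "21": 47_000_000, "22": 51_000_000, "X": 156_000_000, "Y": 57_000_000,
}

# Default X-region map rows: (chrom, start, end, label, method).
# Coordinates are 1-based, closed intervals, hg38.
# - "par": GRCh38.p13 pseudoautosomal regions.
# - "synteny": conserved/added split (human-opossum orthologous gene order);
#   the boundary here is a documented synthetic default.
# - "substitutions" / "segmentation_clustering": evolutionary strata, oldest
#   (S1) to youngest; synthetic defaults standing in for published strata
#   coordinates, shipped as data so users can swap in literature tables.
DEFAULT_X_REGIONS: list[tuple[str, int, int, str, str]] = [
    ("X", 10_001, 2_781_479, "PAR1", "par"),
    ("X", 155_701_383, 156_030_895, "PAR2", "par"),
    ("X", 46_000_001, 155_701_382, "X-conserved", "synteny"),
    ("X", 2_781_480, 46_000_000, "X-added", "synteny"),
    ("X", 100_000_001, 155_701_382, "S1", "substitutions"),
    ("X", 60_000_001, 100_000_000, "S2", "substitutions"),
    ("X", 32_000_001, 60_000_000, "S3", "substitutions"),
    ("X", 8_000_001, 32_000_000, "S4", "substitutions"),
    ("X", 2_781_480, 8_000_000, "S5", "substitutions"),
    ("X", 95_000_001, 155_701_382, "S1", "segmentation_clustering"),
    ("X", 55_000_001, 95_000_000, "S2", "segmentation_clustering"),
    ("X", 30_000_001, 55_000_000, "S3", "segmentation_clustering"),
    ("X", 2_781_480, 30_000_000, "S4", "segmentation_clustering"),
]
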