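"""Bundled survey of 32 plant genome sequencing projects.

Summary statistics compiled from public genome-project reports and the
GenBank EST division, circa 2012: estimated genome size and released
assembly size (Mb), the dbEST library total, the randomly selected clean
EST count and the matched EST count per species, and — for the 13 species
with chromosome-level assemblies — the average GC percentage, the
percentage of 0.1 Mb segments with matching ESTs, and the published quality
level.  These are the worked-example inputs for the ratio, aggregation and
classification routines; sizes are as printed (Mb), so derived percentages
match the published tables digit for digit.
"""

from __future__ import annotations

import pandas as pd

_CSG = [
    # species, genome_mb, assembled_mb, dbest_total, selected, matched,
    # gc_avg_pct, pct_segments_matched, published_level
    ("Arabidopsis thaliana",    125,  119, 1_529_700, 15_297, 14_020, 35.97, 93.40, 1),
    ("Brachypodium distachyon", 272,  271,   128_092,  1_281,  1_259, 46.21, 33.49, 2),
    ("Fragaria vesca",          240,  195,    10_855,  1_086,    958, 35.78, 31.06, 3),
    ("Glycine max",           1_100,  950, 1_461_624, 14_616, 14_207, 34.21, 41.13, 2),
    ("Lotus japonicus",         472,  463,   242_432,  2_424,  1_283, 10.34, 12.88, 4),
    ("Malus x domestica",       742,  526,   324_847,  3_248,  2_957, 27.62, 33.40, 4),
    ("Medicago truncatula",     308,  291,   269_238,  2_692,  1_874, 27.39, 37.29, 4),
    ("Oryza sativa",            420,  382, 1_252_989, 12_530, 12_016, 42.41, 72.82, 1),
    ("Populus trichocarpa",     418,  379,    89_943,  8_994,  8_726, 32.84, 51.18, 2),
    ("Solanum lycopersicum",    900,  760,   298_306,  2_983,  2_907, 32.11, 20.83, 3),
    ("Sorghum bicolor",         730,  659,   209_835,  2_098,  2_017, 41.56, 18.31, 3),
    ("Vitis vinifera",          487,  426,   446_639,  4_466,  4_099, 33.67, 40.34, 2),
    ("Zea mays",              2_300, 2_059, 2_019_137, 20_191, 19_082, 46.60, 97.38, 1),
]

_SSG = [
    # species, genome_mb (None = unpublished), assembled_mb, dbest_total,
    # selected, matched
    ("Arabidopsis lyrata",           207,   207,     561,   548,   523),
    ("Carica papaya",                372,   343,  77_393, 7_739, 6_954),
    ("Citrus clementina",           None,   296, 117_865, 1_179, 1_082),
    ("Citrus sinensis",             None,   319, 214_142, 2_141, 1_906),
    ("Cucumis sativus",              367,   203,   8_146, 7_396, 7_057),
    ("Eucalyptus grandis",          None,   691,  42_576, 4_258, 4_004),
    ("Gossypium raimondii",         None,   764,  63_577, 6_358, 5_875),
    ("Linum usitatissimum",          350,   318, 286_852, 2_869, 2_827),
    ("Manihot esculenta",            760,   533,  80_631, 8_063, 7_583),
    ("Mimulus guttatus",             430,   322, 231_095, 2_311, 2_223),
    ("Panicum virgatum",           1_400, 1_358, 720_590, 7_206, 7_003),
    ("Phaseolus vulgaris",          None,   487, 123_988, 1_240, 1_148),
    ("Physcomitrella patens",       None,   480,  20_456, 2_046, 1_960),
    ("Prunus persica",               230,   227,  79_815, 7_982, 7_584),
    ("Ricinus communis",            None,   351,  62_592, 6_259, 6_022),
    ("Selaginella moellendorffii",  None,   213,  93_811, 9_381, 9_273),
    ("Setaria italica",              515,   401,  66_027, 6_603, 6_092),
    ("Solanum tuberosum",            840,   734, 249_920, 2_499, 2_442),
    ("Thellungiella halophila",     None,   243,  38_022, 3_802, 3_739),
]


def chromosome_survey() -> pd.DataFrame:
    """The 13 chromosome-level species with GC, segment-% and level."""
    return pd.DataFrame(
        _CSG,
        columns=["species", "genome_mb", "assembled_mb", "dbest_total",
                 "selected", "matched", "gc_avg_pct",
                 "pct_segments_matched", "published_level"],
    )


def scaffold_survey() -> pd.DataFrame:
    """The 19 scaffold-level species (genome_mb is NaN when unpublished)."""
    return pd.DataFrame(
        _SSG,
        columns=["species", "genome_mb", "assembled_mb", "dbest_total",
                 "selected", "matched"],
    )
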