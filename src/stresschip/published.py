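"""Published reference values for the fission-yeast H2O2 stress regulon.

Worked-example inputs: the top-20 Atf1/Pcr1-bound gene list with per-factor
enrichment levels and published ranks, the 31-gene Atf1/Pcr1-dependent Sty1
recruitment list with log2 levels and linear mutant/wild-type ratios, and
the printed group counts behind the binding-by-dependency and phenotype
cross tables.  These anchor the ranking, ratio-cutoff and fold-enrichment
operations against numbers that were computed on the full microarray data.
"""

from __future__ import annotations

import pandas as pd

# gene, Atf1 level (log2), Pcr1 level (log2), published dense rank
_TOP_BOUND_GENES = [
    ("SPCC320.03", 3.479445, 3.957555, 1),
    ("SPACUNK4.19", 3.612945, 3.77028, 2),
    ("SPBC1685.13", 3.46139, 3.850725, 3),
    ("SPBC660.05", 3.37339, 3.562445, 4),
    ("SPBC32F12.11|tdh1", 3.30439, 3.626775, 5),
    ("SPAP8A3.04c|hsp9", 3.16572, 3.74333, 6),
    ("SPACUNK4.15", 3.156445, 3.4805, 7),
    ("SPAC1039.11c", 3.213335, 3.35761, 8),
    ("SPBC1105.13c", 3.1415, 3.264165, 9),
    ("SPBC1105.14|rsv2", 3.1415, 3.264165, 9),
    ("SPCC63.14", 3.198835, 3.18039, 10),
    ("SPBC29B5.01|atf1", 3.068055, 3.25811, 11),
    ("SPCC1672.02c|sap1", 3.242055, 2.85228, 12),
    ("SPCC569.05c", 2.856775, 3.190445, 13),
    ("SPAC328.03|tps1", 2.92722, 3.0935, 14),
    ("SPAC16A10.01", 2.95439, 3.060225, 15),
    ("SPAC24C9.15c|spn5", 2.95439, 3.060225, 15),
    ("SPBC354.11c", 2.95222, 3.047945, 16),
    ("SPBC215.05|gpd1", 2.93778, 2.97672, 17),
    ("SPAC17A2.11", 2.837775, 2.890225, 18),
]

# gene, Sty1 level (log2), linear ratio of Sty1 recruitment mutants/wt
_STY1_DEPENDENT_GENES = [
    ("SPBC1683.01", 2.94, 0.54),
    ("SPBC1105.13c", 2.71, 0.57),
    ("SPBC1105.14|rsv2", 2.71, 0.57),
    ("SPAC1751.01c|gti1", 2.61, 0.41),
    ("SPAC343.12|rds1", 2.53, 0.44),
    ("SPAP8A3.04c|hsp9", 2.49, 0.35),
    ("SPAC25B8.12c", 2.35, 0.59),
    ("SPBC660.05", 2.26, 0.31),
    ("SPCC794.12c|mae2", 2.21, 0.56),
    ("SPAC22F8.05", 2.20, 0.25),
    ("SPAC328.03|tps1", 2.16, 0.39),
    ("SPAC16A10.01", 2.15, 0.38),
    ("SPAC24C9.15c|spn5", 2.15, 0.38),
    ("SPACUNK4.17", 2.09, 0.46),
    ("SPACUNK4.15", 2.03, 0.47),
    ("SPBC21C3.19", 2.01, 0.43),
    ("SPBC29B5.01|atf1", 1.99, 0.55),
    ("SPBPB21E7.08", 1.96, 0.20),
    ("SPAC23H3.15c", 1.86, 0.30),
    ("SPAC25H1.02|jmj1", 1.86, 0.30),
    ("SPCC757.07c|ctt1", 1.85, 0.59),
    ("SPAC19D5.01|pyp2", 1.73, 0.58),
    ("SPAC3A11.07", 1.67, 0.52),
    ("SPCC1322.07c", 1.66, 0.37),
    ("SPCC1322.08|srk1", 1.66, 0.37),
    ("SPAC13F5.03c", 1.61, 0.58),
    ("SPBP4G3.02|pho1", 1.52, 0.46),
    ("SPBC713.11c|pmp3", 1.28, 0.50),
    ("SPCP31B10.06", 1.25, 0.43),
    ("SPAC32A11.02c", 1.18, 0.56),
    ("SPAC8C9.03|cgs1", 1.16, 0.46),
]

# printed gene-group counts for the integration cross tables
COUNTS = {
    "induced_genes": 368,
    "repressed_genes": 245,
    "responsive_genes": 613,
    "bound_induced_genes": 61,
    "induced_dependent_both": 110,
    "induced_dependent_atf1_specific": 38,
    "induced_dependent_pcr1_specific": 10,
    "induced_independent": 210,
    "bound_of_dependent_both": 30,
    "bound_of_atf1_specific": 13,
    "bound_of_pcr1_specific": 2,
    "bound_of_independent": 16,
    "bound_strains_assayed": 26,
    "bound_strains_sensitive": 6,
    "unbound_strains_assayed": 34,
    "unbound_strains_sensitive": 1,
}


def top_bound_genes() -> pd.DataFrame:
    """Top-20 bound genes: per-factor log2 levels and the published rank."""
    df = pd.DataFrame(
        _TOP_BOUND_GENES,
        columns=["gene", "atf1_level", "pcr1_level", "published_rank"],
    )
    return df.set_index("gene")


def sty1_dependent_genes() -> pd.DataFrame:
    """The 31 genes with Atf1/Pcr1-dependent Sty1 recruitment (ratio < 0.6)."""
    df = pd.DataFrame(
        _STY1_DEPENDENT_GENES, columns=["gene", "sty1_level_log2", "ratio"]
    )
    return df.set_index("gene")
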