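"""Packaged study fixtures: the published 22-sample degradation-state and
region-size tables and the plastome-tree topology they were analyzed on.

The state code is 0 functional, 1 full-length with premature stop codon,
2 truncated, 3 completely lost; genes absent from a sample's pseudogene
list are functional (0), and the four outgroup taxa are fully functional.

Where the source's table and running text disagree, the value used for
analysis is listed in ``FIXTURE_ERRATA`` together with the printed value.
Branch lengths of the original ML tree were not published; the fixture
tree carries unit branch lengths throughout.
"""

from __future__ import annotations

import pandas as pd

from ._model import CharacterMatrix
from .tree import Tree

NDH_GENES = (
    "ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF",
    "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK",
)
FIXTURE_GENES = NDH_GENES + ("accD", "ccsA")

SECT_CYATHOPHORA = (
    "P_cyathophylla_1", "P_cyathophylla_2",
    "P_cyathophylloides_1", "P_cyathophylloides_2",
    "P_rex_var_rex", "P_rex_var_purpurea", "P_rex_var_rockii",
    "P_aff_thamnophila", "P_thamnophila",
    "P_connata",
    "P_superba_1", "P_superba_2", "P_superba_3",
)
SERIES_REGES = (
    "P_rex_var_rex", "P_rex_var_purpurea", "P_rex_var_rockii",
    "P_aff_thamnophila", "P_thamnophila",
)
OTHER_PEDICULARIS = (
    "P_przewalskii", "P_insignis", "P_lyrata", "P_tongolensis", "P_kangdingensis",
)
NON_PEDICULARIS = (
    "Phtheirospermum_japonicum", "Lindenbergia_muraria",
    "Paulownia_tomentosa", "Rehmannia_glutinosa",
)
ALL_TAXA = SECT_CYATHOPHORA + OTHER_PEDICULARIS + NON_PEDICULARIS

#: pseudogene/loss states exactly as printed (genes omitted = functional)
TABLE1_PRINTED_STATES: dict[str, dict[str, int]] = {
    "P_cyathophylla_1": {"ndhA": 2, "ndhD": 2, "ndhE": 3, "ndhF": 2, "ndhG": 3,
                         "ndhH": 1, "ndhI": 3, "ndhJ": 1, "ndhK": 1, "accD": 1, "ccsA": 1},
    "P_cyathophylla_2": {"ndhA": 2, "ndhD": 2, "ndhE": 3, "ndhF": 2, "ndhG": 3,
                         "ndhH": 1, "ndhI": 3, "ndhJ": 1, "ndhK": 1, "accD": 1, "ccsA": 1},
    "P_cyathophylloides_1": {"ndhA": 2, "ndhD": 1, "ndhE": 3, "ndhF": 2, "ndhG": 3,
                             "ndhH": 1, "ndhI": 3, "ndhJ": 2, "ndhK": 2, "accD": 1},
    "P_cyathophylloides_2": {"ndhA": 2, "ndhD": 1, "ndhE": 3, "ndhF": 2, "ndhG": 3,
                             "ndhH": 1, "ndhI": 3, "ndhJ": 1, "ndhK": 1, "accD": 2},
    "P_rex_var_rex": {"ndhA": 2, "ndhD": 1, "ndhE": 1, "ndhF": 2, "ndhG": 2,
                      "ndhH": 1, "ndhI": 3, "ndhJ": 1, "accD": 1, "ccsA": 1},
    "P_rex_var_purpurea": {"ndhA": 2, "ndhD": 1, "ndhE": 1, "ndhF": 2, "ndhG": 2,
                           "ndhH": 1, "ndhI": 3, "ndhJ": 1, "accD": 1, "ccsA": 1},
    "P_rex_var_rockii": {"ndhA": 2, "ndhD": 1, "ndhE": 1, "ndhF": 2,
                         "ndhH": 1, "ndhI": 1, "ndhJ": 1, "accD": 1, "ccsA": 1},
    "P_aff_thamnophila": {"ndhA": 3, "ndhD": 1, "ndhE": 1, "ndhF": 2,
                          "ndhH": 2, "ndhI": 3, "ndhJ": 1, "accD": 1, "ccsA": 1},
    "P_thamnophila": {"ndhA": 3, "ndhD": 1, "ndhE": 1, "ndhF": 2,
                      "ndhH": 2, "ndhI": 3, "ndhJ": 1, "accD": 1, "ccsA": 1},
    "P_connata": {"ndhA": 2, "ndhD": 2, "ndhE": 3, "ndhF": 2, "ndhG": 3,
                  "ndhH": 1, "ndhI": 3, "ndhJ": 1, "ndhK": 1, "accD": 1, "ccsA": 1},
    "P_superba_1": {"ndhA": 1, "ndhD": 1, "ndhE": 1, "ndhF": 2, "ndhG": 1,
                    "ndhH": 1, "ndhI": 1, "ndhJ": 1, "ndhK": 1, "accD": 1, "ccsA": 1},
    "P_superba_2": {"ndhA": 1, "ndhD": 1, "ndhE": 1, "ndhF": 2, "ndhG": 1,
                    "ndhH": 1, "ndhI": 1, "ndhJ": 1, "ndhK": 1, "accD": 1},
    "P_superba_3": {"ndhA": 1, "ndhD": 1, "ndhE": 1, "ndhF": 2, "ndhG": 1,
                    "ndhH": 1, "ndhI": 1, "ndhJ": 1, "ndhK": 1, "accD": 1},
    "P_przewalskii": {"ndhA": 2, "ndhB": 1, "ndhC": 2, "ndhD": 1, "ndhF": 3,
                      "ndhG": 2, "ndhH": 1, "ndhI": 1, "ndhK": 2, "accD": 1, "ccsA": 1},
    "P_insignis": {"ndhA": 2, "ndhB": 1, "ndhC": 1, "ndhD": 2, "ndhE": 1, "ndhF": 2,
                   "ndhG": 1, "ndhH": 1, "ndhI": 1, "ndhJ": 1, "ndhK": 1, "accD": 2, "ccsA": 2},
    "P_lyrata": {"ndhA": 1, "ndhD": 2, "ndhE": 1, "ndhF": 2, "ndhG": 1,
                 "ndhH": 1, "ndhI": 1, "accD": 2, "ccsA": 1},
    "P_tongolensis": {"ccsA": 1},
    "P_kangdingensis": {"ccsA": 1},
    "Phtheirospermum_japonicum": {},
    "Lindenbergia_muraria": {},
    "Paulownia_tomentosa": {},
    "Rehmannia_glutinosa": {},
}

FIXTURE_ERRATA = (
    "ndhG of P_rex_var_rex: printed state 2, analyzed as 0 (functional); the "
    "running text lists ndhG as functional in P. rex var. rex and the reported "
    "three Dollo reversals in series Reges require it.",
    "ndhG of P_aff_thamnophila: the running text omits the sample from the "
    "ndhG-functional list, but the table implies functional (0); the table value "
    "is used.",
    "ccsA of P_superba_2 and P_superba_3: absent from the table's pseudogene "
    "list (= functional), matching the text's two-functional-samples statement; "
    "the table value is used.",
    "LSC of P_cyathophylloides_2 is printed as 83,342 bp although the genome "
    "size equals sample 1 (LSC 82,342 bp); both printed values are stored "
    "unchanged and the inconsistency is flagged here rather than resolved.",
)

#: analysis-state overrides applied on top of the printed table (see errata)
_STATE_OVERRIDES: dict[tuple[str, str], int] = {
    ("P_rex_var_rex", "ndhG"): 0,
}

#: genome/region sizes (bp) and GC (%) as printed, plus unique gene counts
_REGION_ROWS = [
    # taxon, genome, gGC, lsc, lGC, ir, iGC, ssc, sGC, cds, trna, rrna
    ("P_cyathophylla_1", 154426, 38.3, 82962, 36.6, 33821, 40.7, 3822, 33.9, 69, 4, 30),
    ("P_cyathophylla_2", 154412, 38.3, 82972, 36.6, 33861, 40.7, 3718, 33.6, 69, 4, 30),
    ("P_cyathophylloides_1", 154238, 38.3, 82342, 36.6, 33833, 40.7, 4230, 34.3, 70, 4, 30),
    ("P_cyathophylloides_2", 154238, 38.3, 83342, 36.6, 33833, 40.7, 4230, 34.3, 70, 4, 30),
    ("P_rex_var_rex", 153415, 38.3, 82950, 36.6, 31421, 41.1, 7623, 34.2, 70, 4, 30),
    ("P_rex_var_purpurea", 153512, 38.3, 82999, 36.6, 31819, 41.1, 6875, 34.0, 70, 4, 30),
    ("P_rex_var_rockii", 156819, 38.2, 82920, 36.6, 33957, 40.6, 5985, 33.8, 71, 4, 30),
    ("P_aff_thamnophila", 153446, 38.3, 82999, 36.6, 31416, 41.1, 7615, 34.2, 71, 4, 30),
    ("P_thamnophila", 153612, 38.3, 82972, 36.6, 31411, 41.1, 7818, 34.3, 71, 4, 30),
    ("P_connata", 153908, 38.4, 82533, 36.6, 33800, 40.7, 3775, 33.9, 69, 4, 30),
    ("P_superba_1", 157028, 38.2, 83056, 36.6, 33148, 40.9, 7676, 33.2, 69, 4, 30),
    ("P_superba_2", 156942, 38.2, 83061, 36.6, 33079, 40.9, 7723, 33.2, 70, 4, 30),
    ("P_superba_3", 156947, 38.2, 83065, 36.6, 33148, 40.9, 7586, 33.4, 70, 4, 30),
    ("P_przewalskii", 146480, 38.5, 82246, 36.6, 24759, 43.5, 14716, 32.8, 69, 4, 30),
    ("P_insignis", 147267, 38.6, 82213, 36.7, 24936, 43.5, 15181, 32.7, 67, 4, 30),
    ("P_lyrata", 148379, 38.4, 82471, 36.6, 26227, 43.0, 13456, 31.9, 71, 4, 30),
    ("P_tongolensis", 151850, 38.3, 83240, 36.4, 25729, 43.3, 17251, 32.5, 79, 4, 30),
    ("P_kangdingensis", 151577, 38.3, 82805, 36.4, 25743, 43.3, 17286, 32.4, 79, 4, 30),
    ("Phtheirospermum_japonicum", 153372, 38.3, 84478, 36.4, 25608, 43.4, 17678, 32.3, 80, 4, 30),
    ("Lindenbergia_muraria", 154122, 37.7, 85029, 35.7, 25832, 43.2, 17429, 31.5, 80, 4, 30),
    ("Paulownia_tomentosa", 154798, 38.0, 85438, 36.0, 25814, 43.2, 17732, 32.4, 80, 4, 30),
    ("Rehmannia_glutinosa", 153777, 37.9, 84669, 36.0, 25759, 43.1, 17590, 32.2, 80, 4, 30),
]

_REGION_COLUMNS = (
    "genome_bp", "genome_gc", "lsc_bp", "lsc_gc", "ir_bp", "ir_gc",
    "ssc_bp", "ssc_gc", "n_cds", "n_trna", "n_rrna",
)

#: study topology; sect. Cyathophora = (clade III, (clade II, clade I)),
#: (P. insignis, P. przewalskii) sister to the section, then successively
#: P. lyrata, P. kangdingensis, P. tongolensis, and the four outgroups
FIXTURE_NEWICK = (
    "(Paulownia_tomentosa:1,(Rehmannia_glutinosa:1,(Lindenbergia_muraria:1,"
    "(Phtheirospermum_japonicum:1,(P_tongolensis:1,(P_kangdingensis:1,"
    "(P_lyrata:1,((P_insignis:1,P_przewalskii:1):1,"
    "(((P_cyathophylloides_1:1,P_cyathophylloides_2:1):1,"
    "(P_superba_1:1,(P_superba_2:1,P_superba_3:1):1):1):1,"
    "(((P_cyathophylla_1:1,P_cyathophylla_2:1):1,P_connata:1):1,"
    "(P_rex_var_rockii:1,((P_rex_var_rex:1,P_rex_var_purpurea:1):1,"
    "(P_thamnophila:1,P_aff_thamnophila:1):1):1):1):1):1):1):1):1):1):1):1):1);"
)


def fixture_table1() -> tuple[CharacterMatrix, pd.DataFrame]:
    """The 22 x 13 analysis state matrix and the region size/GC table."""
    states = {t: dict(TABLE1_PRINTED_STATES[t]) for t in ALL_TAXA}
    for (taxon, gene), value in _STATE_OVERRIDES.items():
        states[taxon][gene] = value
    matrix = CharacterMatrix.from_dict(states, taxa=ALL_TAXA, genes=FIXTURE_GENES)
    region = pd.DataFrame(
        [row[1:] for row in _REGION_ROWS],
        index=pd.Index([row[0] for row in _REGION_ROWS], name="taxon"),
        columns=_REGION_COLUMNS,
    )
    return matrix, region


def fixture_tree() -> Tree:
    """The study topology with unit branch lengths."""
    return Tree.from_newick(FIXTURE_NEWICK)
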