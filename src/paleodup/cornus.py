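"""Reference constants for the Cornus (dogwood) study system.

The pipeline is generic, but its canonical application is the ten-taxon
dogwood system: eight *Cornus* species plus the outgroups *Alangium
chinense* (ACH) and *Dichroa febrifuga* (DFE).  This module holds the dated
species tree, the two calibration node ages, the published per-species
ortholog-Ks peaks used for clock calibration, and the five candidate WGD
placements scored by the gene-count analysis.
"""

from __future__ import annotations

#: three-letter codes of the eight Cornus species
CORNUS_SPECIES: tuple[str, ...] = (
    "CAL",  # C. alternifolia
    "CCA",  # C. capitata
    "CCN",  # C. canadensis
    "CCO",  # C. controversa
    "CEL",  # C. elliptica
    "CFL",  # C. florida
    "CKO",  # C. kousa
    "COF",  # C. officinalis
)

#: outgroup codes: Alangium (closer) and Dichroa (root)
OUTGROUPS: tuple[str, str] = ("ACH", "DFE")

#: blue/white-fruited dogwood clade, one side of the deepest Cornus split
BW_GROUP: tuple[str, str] = ("CAL", "CCO")

#: age (myr) of the node uniting Cornus and Alangium
T_A: float = 80.21
#: age (myr) of the root node uniting Cornus, Alangium and Dichroa
T_D: float = 95.75

#: dated species tree: ultrametric newick, branch lengths in myr.
#: Crown Cornus at 72.77 myr, the split of the cornelian cherries from the
#: dwarf/big-bracted clade at 70.33 myr; shallower nodes follow the fossil
#: constraints (58, 32, 5.1 myr) with interpolated values elsewhere.
SPECIES_TREE_NEWICK: str = (
    "(DFE:95.75,(ACH:80.21,((CAL:30.0,CCO:30.0):42.77,"
    "(COF:70.33,(CCN:58.0,(CFL:32.0,(CKO:20.0,(CEL:5.1,CCA:5.1):14.9)"
    ":12.0):26.0):12.33):2.44):7.44):15.54);"
)

#: published per-species ortholog-Ks KDE peaks against Alangium (Ks_A) and
#: Dichroa (Ks_D); inputs to the local-clock calibration
ORTHOLOG_KS_PEAKS: dict[str, tuple[float, float]] = {
    "CAL": (0.4334, 0.5051),
    "CCA": (0.4610, 0.5227),
    "CCN": (0.5430, 0.6113),
    "CCO": (0.4337, 0.5075),
    "CEL": (0.4567, 0.5253),
    "CFL": (0.4595, 0.5249),
    "CKO": (0.4553, 0.5257),
    "COF": (0.4472, 0.5149),
}

#: published per-species synonymous clocks (substitutions/site/myr),
#: for use as realistic simulation defaults
REFERENCE_CLOCKS: dict[str, float] = {
    "CAL": 2.67e-3,
    "CCA": 2.81e-3,
    "CCN": 3.29e-3,
    "CCO": 2.68e-3,
    "CEL": 2.79e-3,
    "CFL": 2.80e-3,
    "CKO": 2.79e-3,
    "COF": 2.74e-3,
}


def default_divergence_times() -> dict[tuple[str, str], float]:
    """Ingroup-to-outgroup divergence times (myr) implied by the tree."""
    times: dict[tuple[str, str], float] = {}
    for sp in CORNUS_SPECIES:
        times[(sp, "ACH")] = T_A
        times[(sp, "DFE")] = T_D
    times[("ACH", "DFE")] = T_D
    return times


_NON_BW = tuple(s for s in CORNUS_SPECIES if s not in BW_GROUP)

#: the five candidate WGD placements; each event is the stem branch of the
#: named clade (a frozenset of descendant species codes)
HYPOTHESES: dict[str, tuple[frozenset, ...]] = {
    "H1": (frozenset(CORNUS_SPECIES + ("ACH",)),),
    "H2": (frozenset(CORNUS_SPECIES),),
    "H3": (frozenset(CORNUS_SPECIES), frozenset({"ACH"})),
    "H4": (frozenset(BW_GROUP), frozenset(_NON_BW)),
    "H5": (frozenset({"ACH"}), frozenset(BW_GROUP), frozenset(_NON_BW)),
}
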