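"""Packaged study fixtures: the ten host plants, their measured natural
weight variation, the study phylogeny, and the study-shaped design.

The plant table and the control means/SDs are the published study values.
The Newick tree is a SYNTHETIC ultrametric reconstruction: only the five
cophenetic distances from Ipomoea batatas to the five novel species were
published (0.236, 0.386, 0.012, 0.236, 0.236), and the packaged tree is
built to reproduce exactly those while keeping an APG-consistent topology
(monocots; caryophyllid + Haloragaceae eudicots; asterids with Convolvulaceae
sister to the Apiales/Asteraceae clade). Every other pairwise distance is a
fixture value, not a published one. Platycladus orientalis is the out-group.
"""

from __future__ import annotations

from .design import ControlVariation, ExperimentalDesign, SpeciesInfo

__all__ = [
    "STUDY_SPECIES",
    "STUDY_CONTROL_VARIATION",
    "STUDY_TREE_NEWICK",
    "OUTGROUP",
    "study_design",
    "familiar_species",
    "novel_species",
]

# name, common name, origin region, habitat; familiarity derives from origin
STUDY_SPECIES: tuple[SpeciesInfo, ...] = (
    SpeciesInfo("Alternanthera philoxeroides", "Alligator weed", "South America", "aquatic"),
    SpeciesInfo("Eichhornia crassipes", "Water hyacinth", "South America", "aquatic"),
    SpeciesInfo("Ipomoea batatas", "Sweet potato", "South America", "semiaquatic"),
    SpeciesInfo("Myriophyllum aquaticum", "Parrot feather", "South America", "aquatic"),
    SpeciesInfo("Pistia stratiotes", "Water lettuce", "South America", "aquatic"),
    SpeciesInfo("Apium graveolens", "Celery", "Mediterranean", "semiaquatic"),
    SpeciesInfo("Colocasia esculenta", "Taro", "India", "semiaquatic"),
    SpeciesInfo("Ipomoea aquatica", "Water spinach", "China", "aquatic"),
    SpeciesInfo("Hydrocotyle vulgaris", "Pennywort", "Europe", "aquatic"),
    SpeciesInfo("Lactuca sativa", "Lettuce", "Mediterranean", "semiaquatic"),
)

# Mean ± SD natural weight change (g, initial − final) over the 60 hr trial,
# measured in the no-herbivore controls.
STUDY_CONTROL_VARIATION = ControlVariation(
    {
        "Alternanthera philoxeroides": (-0.076, 0.15),
        "Eichhornia crassipes": (0.171, 0.18),
        "Ipomoea batatas": (0.895, 0.518),
        "Myriophyllum aquaticum": (1.179, 0.382),
        "Pistia stratiotes": (0.200, 0.098),
        "Apium graveolens": (0.376, 0.414),
        "Colocasia esculenta": (0.481, 0.178),
        "Ipomoea aquatica": (0.781, 0.380),
        "Hydrocotyle vulgaris": (0.014, 0.072),
        "Lactuca sativa": (0.571, 0.562),
    }
)

OUTGROUP = "Platycladus orientalis"

# Synthetic ultrametric ingroup (depth 0.193) + gymnosperm out-group.
# Reproduces the five published I. batatas -> novel cophenetic distances.
STUDY_TREE_NEWICK = (
    "((((Pistia_stratiotes:0.05,Colocasia_esculenta:0.05):0.07,"
    "Eichhornia_crassipes:0.12):0.073,"
    "((Alternanthera_philoxeroides:0.1,Myriophyllum_aquaticum:0.1):0.05,"
    "((Ipomoea_batatas:0.006,Ipomoea_aquatica:0.006):0.112,"
    "((Apium_graveolens:0.05,Hydrocotyle_vulgaris:0.05):0.04,"
    "Lactuca_sativa:0.09):0.028):0.032):0.043):0.107,"
    "Platycladus_orientalis:0.3);"
)


def study_design() -> ExperimentalDesign:
    """The study-shaped split-plot design: 3 blocks × 5 temperatures ×
    10 species × 7 biomass levels over a 60 hr trial (1,050 units)."""
    return ExperimentalDesign(
        n_blocks=3,
        temperatures_C=(26.0, 28.0, 30.0, 32.0, 34.0),
        species=STUDY_SPECIES,
        biomass_levels_g=(1, 2, 4, 6, 8, 10, 12),
        duration_hr=60.0,
    )


def familiar_species() -> list[str]:
    return [s.name for s in STUDY_SPECIES if s.familiarity == "familiar"]


def novel_species() -> list[str]:
    return [s.name for s in STUDY_SPECIES if s.familiarity == "novel"]
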