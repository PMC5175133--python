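"""Canonical 3-class amino-acid partitions for the CTD descriptors.

Each of the eight physicochemical properties partitions the 20-letter
amino-acid alphabet into three disjoint, exhaustive classes. The partitions
are the ones established for composition/transition/distribution protein
descriptors by Dubchak and co-workers and reused by the standard
188-dimensional feature set; they are shipped as auditable constants so a
user can inspect or override them.

Published variants of the set differ slightly in the surface-tension
partition; the grouping below is the one used by the common 188D
implementations. Replace ``PROPERTY_GROUPINGS`` entries to experiment with
other partitions — :func:`validate_groupings` checks the partition axioms.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import CANONICAL_AA


@dataclass(frozen=True)
class PropertyGrouping:
    """A named partition of the 20 amino acids into 3 classes."""

    name: str
    groups: tuple[str, str, str]

    def group_index(self) -> dict[str, int]:
        """Map residue -> 0-based group index."""
        return {aa: gi for gi, grp in enumerate(self.groups) for aa in grp}


# Order is fixed: it defines the layout of the 188D vector.
PROPERTY_GROUPINGS: tuple[PropertyGrouping, ...] = (
    # hydrophobicity: polar / neutral / hydrophobic
    PropertyGrouping("hydrophobicity", ("RKEDQN", "GASTPHY", "CLVIMFW")),
    # normalized van der Waals volume: 0-2.78 / 2.95-4.0 / 4.03-8.08
    PropertyGrouping("normalized_vdw_volume", ("GASCTPD", "NVEQIL", "MHKFRYW")),
    # polarity: 4.9-6.2 / 8.0-9.2 / 10.4-13.0
    PropertyGrouping("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    # polarizability: 0-0.108 / 0.128-0.186 / 0.219-0.409
    PropertyGrouping("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    # charge: positive / neutral / negative
    PropertyGrouping("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    # secondary-structure propensity: helix / strand / coil
    PropertyGrouping("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    # solvent accessibility: buried / exposed / intermediate
    PropertyGrouping("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MSPTHY")),
    # surface tension: common 188D-implementation variant
    PropertyGrouping("surface_tension", ("GQDNAHR", "KTSEC", "ILMFPWYV")),
)


def validate_groupings(groupings: tuple[PropertyGrouping, ...] = PROPERTY_GROUPINGS) -> None:
    """Assert each grouping is a disjoint, exhaustive 3-partition of the alphabet."""
    alphabet = set(CANONICAL_AA)
    for g in groupings:
        if len(g.groups) != 3:
            raise ValueError(f"{g.name}: needs exactly 3 groups")
        letters = [aa for grp in g.groups for aa in grp]
        if len(letters) != len(set(letters)):
            raise ValueError(f"{g.name}: groups are not disjoint")
        if set(letters) != alphabet:
            raise ValueError(f"{g.name}: groups do not cover the 20-letter alphabet")


validate_groupings()
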