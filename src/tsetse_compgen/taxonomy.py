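"""Nested clade membership for the 12-species Diptera panel.

The comparative analyses in this package classify orthology groups by the
smallest named clade that contains every species in which the group has
members.  The named clades form a nesting

    Diptera ⊇ Brachycera ⊇ Glossina ⊇ {Morsitans, Palpalis, Fusca} ⊇ species

with the Nematocera species (mosquitoes and sand fly) inside Diptera but
outside Brachycera.  Nematocera and the single-species Fusca sub-genus are
*membership* groups, not classification levels: a group found only in
Nematocera species is "common to Diptera", and a group found only in
G. brevipalpis is species-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Default panel: six Glossina plus six outgroup Diptera.
MORSITANS = ("G_m_morsitans", "G_pallidipes", "G_austeni")
PALPALIS = ("G_fuscipes", "G_palpalis")
FUSCA = ("G_brevipalpis",)
GLOSSINA = MORSITANS + PALPALIS + FUSCA
BRACHYCERA_OUTGROUPS = ("D_melanogaster", "M_domestica", "S_calcitrans")
NEMATOCERA = ("A_gambiae", "A_aegypti", "L_longipalpis")
DIPTERA = GLOSSINA + BRACHYCERA_OUTGROUPS + NEMATOCERA


@dataclass(frozen=True)
class TaxonMap:
    """Species panel with its nested named clades.

    ``clades`` maps a clade label to the set of member species.  Clades must
    be laterally disjoint or nested so that the containing clades of any
    species set form a chain (guaranteeing a unique smallest covering clade).
    Every species is implicitly its own single-member clade.
    """

    species: tuple[str, ...] = DIPTERA
    clades: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.clades:
            object.__setattr__(
                self,
                "clades",
                {
                    "Diptera": frozenset(self.species),
                    "Brachycera": frozenset(GLOSSINA + BRACHYCERA_OUTGROUPS),
                    "Glossina": frozenset(GLOSSINA),
                    "Morsitans": frozenset(MORSITANS),
                    "Palpalis": frozenset(PALPALIS),
                },
            )
        seen = set()
        for label, members in self.clades.items():
            unknown = members - set(self.species)
            if unknown:
                raise ValueError(f"clade {label!r} names unknown species {sorted(unknown)}")
            seen |= members
        for a, ma in self.clades.items():
            for b, mb in self.clades.items():
                if a != b and (ma & mb) and not (ma <= mb or mb <= ma):
                    raise ValueError(f"clades {a!r} and {b!r} overlap without nesting")

    @property
    def glossina_species(self) -> tuple[str, ...]:
        """The six tsetse species, in panel order (used by the variance screen)."""
        gl = self.clades.get("Glossina")
        if gl is None:
            raise KeyError("taxonomy has no 'Glossina' clade")
        return tuple(s for s in self.species if s in gl)

    def named_levels(self) -> dict[str, frozenset[str]]:
        """All classification levels: named clades plus one per species."""
        levels = dict(self.clades)
        for s in self.species:
            levels[s] = frozenset({s})
        return levels

    def smallest_covering_clade(self, present: set[str]) -> tuple[str, frozenset[str]]:
        """Return (label, members) of the smallest named level containing ``present``."""
        if not present:
            raise ValueError("empty species set has no covering clade")
        unknown = present - set(self.species)
        if unknown:
            raise ValueError(f"unknown species {sorted(unknown)}")
        best = None
        for label, members in self.named_levels().items():
            if present <= members and (best is None or len(members) < len(best[1])):
                best = (label, members)
        if best is None:
            raise ValueError("no named clade covers the species set (missing root clade?)")
        return best


DEFAULT_TAXONOMY = TaxonMap()
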