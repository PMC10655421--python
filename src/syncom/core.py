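"""Domain types for qualitative metabolic networks, growth media and targets.

The model is purely qualitative: a reaction is a pair of non-empty compound
sets (reactants, products) plus a reversibility flag. Stoichiometric
coefficients are ignored throughout, matching network-expansion semantics.
Compound identity is by string id; compartment suffixes, where present in an
SBML source, stay part of the id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPOUND_CATEGORIES = frozenset(
    {
        "amino acid",
        "organic acid",
        "aromatic compound",
        "vitamin",
        "phytohormone",
        "nucleotide component",
        "cofactor",
        "inorganic ion",
        "other",
    }
)


class SyncomError(Exception):
    """Base class for all package errors."""


class ValidationError(SyncomError):
    """A domain object violates one of its invariants."""


@dataclass(frozen=True)
class Compound:
    """A metabolite, identified by a non-empty string id.

    ``category`` is an optional functional label (amino acid, vitamin, ...)
    used when reporting which classes of compounds a community can reach.
    """

    id: str
    name: str | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("compound id must be non-empty")
        if self.category is not None and self.category not in COMPOUND_CATEGORIES:
            raise ValidationError(
                f"unknown compound category {self.category!r} for {self.id!r}; "
                f"expected one of {sorted(COMPOUND_CATEGORIES)}"
            )


@dataclass(frozen=True)
class Reaction:
    """A qualitative reaction: reactant set → product set.

    Reactants and products must each be non-empty; their overlap is allowed
    (a compound may be both consumed and produced, e.g. a carrier).
    A reversible reaction may fire in either direction during expansion.
    """

    id: str
    reactants: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        object.__setattr__(self, "reactants", frozenset(self.reactants))
        object.__setattr__(self, "products", frozenset(self.products))
        if not self.reactants:
            raise ValidationError(f"reaction {self.id!r} has an empty reactant list")
        if not self.products:
            raise ValidationError(f"reaction {self.id!r} has an empty product list")

    @property
    def compounds(self) -> frozenset[str]:
        return self.reactants | self.products

    def reversed(self) -> "Reaction":
        """The reaction with substrate/product roles swapped (irreversible)."""
        return Reaction(
            id=self.id + "__rev",
            reactants=self.products,
            products=self.reactants,
            reversible=False,
        )


@dataclass(frozen=True)
class MetabolicNetwork:
    """One species' qualitative genome-scale metabolic network (GSMN).

    ``compounds`` is derived: it is always exactly the union of all reactant
    and product sets, recomputed at construction.
    """

    species_id: str
    reactions: tuple[Reaction, ...]
    compounds: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValidationError("species_id must be non-empty")
        rxns = tuple(self.reactions)
        object.__setattr__(self, "reactions", rxns)
        seen: set[str] = set()
        for r in rxns:
            if r.id in seen:
                raise ValidationError(
                    f"duplicate reaction id {r.id!r} in network {self.species_id!r}"
                )
            seen.add(r.id)
        cpds: set[str] = set()
        for r in rxns:
            cpds |= r.reactants
            cpds |= r.products
        object.__setattr__(self, "compounds", frozenset(cpds))

    @classmethod
    def from_reactions(
        cls, species_id: str, reactions: "list[Reaction] | tuple[Reaction, ...]"
    ) -> "MetabolicNetwork":
        return cls(species_id=species_id, reactions=tuple(reactions))

    def irreversible_reactions(self) -> tuple[Reaction, ...]:
        """The network compiled to irreversible reactions only.

        Each reversible reaction becomes two one-way reactions, which makes
        the expansion fixed point manifestly order-independent.
        """
        out: list[Reaction] = []
        for r in self.reactions:
            if r.reversible:
                out.append(Reaction(r.id, r.reactants, r.products, False))
                out.append(r.reversed())
            else:
                out.append(r)
        return tuple(out)

    def __len__(self) -> int:
        return len(self.reactions)


@dataclass(frozen=True)
class SeedMedium:
    """The growth medium: compounds assumed freely available externally."""

    compounds: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", frozenset(self.compounds))

    def __iter__(self):
        return iter(self.compounds)

    def __len__(self) -> int:
        return len(self.compounds)

    def __contains__(self, cid: str) -> bool:
        return cid in self.compounds


@dataclass(frozen=True)
class TargetSet:
    """Compounds a designed community should be able to produce.

    ``categories`` maps a subset of the target ids to functional labels;
    every categorized id must be a member of ``compounds``.
    """

    compounds: frozenset[str]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", frozenset(self.compounds))
        object.__setattr__(self, "categories", dict(self.categories))
        extra = set(self.categories) - self.compounds
        if extra:
            raise ValidationError(
                f"categorized compounds not in target set: {sorted(extra)}"
            )

    def __iter__(self):
        return iter(self.compounds)

    def __len__(self) -> int:
        return len(self.compounds)


@dataclass(frozen=True)
class CommunityInstance:
    """A complete problem instance: member networks, medium, targets, host.

    The host, when present, contributes reactions to community expansions
    but is never a selectable community member.
    """

    members: tuple[MetabolicNetwork, ...]
    seeds: SeedMedium
    targets: TargetSet
    host: MetabolicNetwork | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        ids = [m.species_id for m in self.members]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate species ids: {sorted(dupes)}")
        if self.host is not None and self.host.species_id in ids:
            raise ValidationError(
                f"host species_id {self.host.species_id!r} collides with a member"
            )

    def member_ids(self) -> tuple[str, ...]:
        return tuple(m.species_id for m in self.members)

    def get_member(self, species_id: str) -> MetabolicNetwork:
        for m in self.members:
            if m.species_id == species_id:
                return m
        raise KeyError(species_id)


def summarize_network(network: MetabolicNetwork) -> dict:
    """Basic size counts for a network: compounds, reactions, reversible."""
    return {
        "species_id": network.species_id,
        "n_compounds": len(network.compounds),
        "n_reactions": len(network.reactions),
        "n_reversible": sum(1 for r in network.reactions if r.reversible),
    }
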