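"""Network expansion: individual and community metabolic potentials.

The *scope* of a network on a seed medium is the least fixed point of
qualitative reaction firing: starting from the seed compounds, a reaction
adds its products once every reactant is available; reversible reactions may
fire in either direction. The fixed point is unique and order-independent,
so the result does not depend on evaluation order.

Community ("mixed-bag") potentials pool all members' reactions — and the
host's, when one is given — into a single network before expansion,
modelling the community as one meta-organism with free internal exchange.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from statistics import mean

from syncom.core import MetabolicNetwork, Reaction, SeedMedium, ValidationError


@dataclass(frozen=True)
class ScopeResult:
    """Reachable compounds for one owner (species, community, or both).

    ``full_scope`` includes the seed compounds; ``producible`` is the
    seed-free view (``full_scope − seeds``). Both are exposed because size
    summaries conventionally count seeds while "newly producible" compound
    lists exclude them.
    """

    owner: str
    seeds: SeedMedium
    full_scope: frozenset[str]

    @property
    def producible(self) -> frozenset[str]:
        return self.full_scope - self.seeds.compounds

    def __len__(self) -> int:
        return len(self.full_scope)


@dataclass(frozen=True)
class ScopeStatistics:
    """Per-species scope sizes plus core/union across a community."""

    sizes: dict[str, int]
    minimum: int
    maximum: int
    mean: float
    core: frozenset[str]
    union_scope: frozenset[str]


def _closure(reactions: "tuple[Reaction, ...]", seeds: frozenset[str]) -> frozenset[str]:
    """Least fixed point via a worklist indexed by unmet-reactant counts.

    Linear in total reaction arity: each (compound, reaction) incidence is
    processed once.
    """
    # reversible reactions compiled to two one-way reactions
    directed: list[tuple[frozenset[str], frozenset[str]]] = []
    for r in reactions:
        directed.append((r.reactants, r.products))
        if r.reversible:
            directed.append((r.products, r.reactants))

    unmet = [len(rx[0]) for rx in directed]
    by_reactant: dict[str, list[int]] = defaultdict(list)
    for i, (reactants, _) in enumerate(directed):
        for c in reactants:
            by_reactant[c].append(i)

    reached = set(seeds)
    queue = list(seeds)
    fired = [False] * len(directed)

    def fire(i: int) -> None:
        fired[i] = True
        for p in directed[i][1]:
            if p not in reached:
                reached.add(p)
                queue.append(p)

    while queue:
        c = queue.pop()
        for i in by_reactant[c]:
            unmet[i] -= 1
            if unmet[i] == 0 and not fired[i]:
                fire(i)
    return frozenset(reached)


def compute_scope(network: MetabolicNetwork, seeds: SeedMedium) -> ScopeResult:
    """Individual metabolic potential (iscope) of one species.

    Seed compounds absent from the network still count as available
    substrates — the medium is external to any genome. An empty network
    yields ``full_scope == seeds``.
    """
    full = _closure(network.reactions, seeds.compounds)
    return ScopeResult(owner=network.species_id, seeds=seeds, full_scope=full)


def mixed_bag(
    members: "list[MetabolicNetwork] | tuple[MetabolicNetwork, ...]",
    host: MetabolicNetwork | None = None,
    label: str | None = None,
) -> MetabolicNetwork:
    """Pool members' (and optionally the host's) reactions into one network.

    Reaction ids are prefixed with their owner's species id so pooled ids
    stay unique even when species share reaction names.
    """
    if not members and host is None:
        raise ValidationError("mixed bag requires at least one network")
    pooled: list[Reaction] = []
    sources = list(members) + ([host] if host is not None else [])
    for net in sources:
        for r in net.reactions:
            pooled.append(
                Reaction(
                    id=f"{net.species_id}::{r.id}",
                    reactants=r.reactants,
                    products=r.products,
                    reversible=r.reversible,
                )
            )
    if label is None:
        label = "community" if host is None else "community+host"
    return MetabolicNetwork(species_id=label, reactions=tuple(pooled))


def community_scope(
    members: "list[MetabolicNetwork] | tuple[MetabolicNetwork, ...]",
    seeds: SeedMedium,
    host: MetabolicNetwork | None = None,
) -> ScopeResult:
    """Collective metabolic potential (cscope) of a community.

    Equal to :func:`compute_scope` on the mixed-bag union of all members
    (plus host reactions when a host is supplied). The owner label records
    whether a host participated.
    """
    if not members:
        raise ValidationError("community_scope requires at least one member")
    bag = mixed_bag(members, host=host)
    full = _closure(bag.reactions, seeds.compounds)
    return ScopeResult(owner=bag.species_id, seeds=seeds, full_scope=full)


def added_value(
    members: "list[MetabolicNetwork] | tuple[MetabolicNetwork, ...]",
    seeds: SeedMedium,
) -> frozenset[str]:
    """Cooperation gain: compounds only the full community can make.

    Community producible set minus the union of all individual producible
    sets; disjoint from every individual producible set by construction.
    """
    community = community_scope(members, seeds).producible
    individual: set[str] = set()
    for m in members:
        individual |= compute_scope(m, seeds).producible
    return community - individual


def scope_statistics(
    members: "list[MetabolicNetwork] | tuple[MetabolicNetwork, ...]",
    seeds: SeedMedium,
) -> ScopeStatistics:
    """Min/max/mean full-scope sizes plus core (∩) and union (∪) scopes."""
    if not members:
        raise ValidationError("scope_statistics requires at least one member")
    scopes = {m.species_id: compute_scope(m, seeds).full_scope for m in members}
    sizes = {sid: len(s) for sid, s in scopes.items()}
    all_scopes = list(scopes.values())
    core = frozenset.intersection(*all_scopes)
    union = frozenset.union(*all_scopes)
    vals = list(sizes.values())
    return ScopeStatistics(
        sizes=sizes,
        minimum=min(vals),
        maximum=max(vals),
        mean=float(mean(vals)),
        core=core,
        union_scope=union,
    )
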