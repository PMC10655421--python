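"""Reverse ecology: seed sets and pairwise interaction indices.

A species' **seed set** is the set of compounds it must acquire from its
environment. On the directed substrate→product compound graph, these are
exactly the members of source strongly-connected components (SCCs with no
incoming edge from outside). Each seed compound carries a confidence of
1/|component|: compounds in one source SCC are interchangeable entry
points, so the component's unit of "seed demand" is split evenly among
them.

Four indices are built on seed sets, each a confidence-weighted fraction of
the focal (or consumer) species' seed set, hence in [0, 1]:

* **competition** — focal seeds that are also the partner's seeds
  (both species demand the same exogenous compounds);
* **complementarity** — focal seeds the partner's network contains *outside*
  its own seed set (the partner can synthesize what the focal one needs);
* **biosynthetic support score (BSS)** — consumer seeds present anywhere in
  the supporter's network, seeds included (capacity to sustain);
* **metabolic complementarity index (MCI)** — the complementarity measure
  applied to host–microbe pairs; the formula is identical and is exposed
  under both names to avoid silent divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from syncom.core import MetabolicNetwork, SyncomError

METRICS = ("competition", "complementarity", "bss", "mci")


class EmptySeedSetError(SyncomError):
    """An index was requested for a species with an empty seed set."""


@dataclass(frozen=True)
class SeedSet:
    """A species' exogenously-acquired compounds with confidences.

    ``entries`` maps compound id → confidence in (0, 1]; ``components``
    lists the source SCCs, one tuple per component. Confidences within a
    component are equal and sum to 1.
    """

    owner: str
    entries: dict[str, float]
    components: tuple[tuple[str, ...], ...]

    @property
    def compounds(self) -> frozenset[str]:
        return frozenset(self.entries)

    def total_confidence(self) -> float:
        return sum(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PairwiseIndices:
    """All four indices for one ordered (focal, partner) species pair."""

    pair: tuple[str, str]
    competition: float
    complementarity: float
    bss: float
    mci: float


def build_compound_graph(
    network: MetabolicNetwork,
    exclude: "list[str] | set[str] | None" = None,
) -> nx.DiGraph:
    """Directed substrate→product graph of a network.

    Every reaction contributes an edge from each reactant to each product;
    reversible reactions also contribute the mirrored edges. Compounds in
    ``exclude`` (e.g. currency metabolites) are dropped with their incident
    edges; nothing is excluded by default.
    """
    excluded = set(exclude) if exclude else set()
    g = nx.DiGraph(species_id=network.species_id)
    g.add_nodes_from(network.compounds - excluded)
    for r in network.reactions:
        for s in r.reactants:
            if s in excluded:
                continue
            for p in r.products:
                if p in excluded:
                    continue
                g.add_edge(s, p)
                if r.reversible:
                    g.add_edge(p, s)
    return g


def compute_seed_set(graph: nx.DiGraph, owner: str | None = None) -> SeedSet:
    """Seed set of a compound graph via SCC condensation.

    Condense the graph into strongly-connected components; components with
    zero incoming edges in the condensation are *source* components, and
    their compounds form the seed set, each with confidence 1/|component|.
    An empty graph yields an empty seed set; an isolated node is its own
    source component (confidence 1).
    """
    if owner is None:
        owner = graph.graph.get("species_id", "")
    entries: dict[str, float] = {}
    components: list[tuple[str, ...]] = []
    if graph.number_of_nodes() > 0:
        cond = nx.condensation(graph)
        for comp_idx in cond.nodes:
            if cond.in_degree(comp_idx) == 0:
                member_ids = tuple(sorted(cond.nodes[comp_idx]["members"]))
                conf = 1.0 / len(member_ids)
                for cid in member_ids:
                    entries[cid] = conf
                components.append(member_ids)
    components.sort()
    return SeedSet(owner=owner, entries=entries, components=tuple(components))


def seed_set_of(network: MetabolicNetwork,
                exclude: "list[str] | None" = None) -> SeedSet:
    """Convenience: compound graph + seed set in one step."""
    return compute_seed_set(build_compound_graph(network, exclude=exclude),
                            owner=network.species_id)


def _weights(seed_set: SeedSet, weighted: bool) -> dict[str, float]:
    if weighted:
        return seed_set.entries
    return {c: 1.0 for c in seed_set.entries}


def _require_nonempty(seed_set: SeedSet, role: str) -> None:
    if not seed_set.entries:
        raise EmptySeedSetError(
            f"{role} species {seed_set.owner!r} has an empty seed set; "
            "the index is undefined"
        )


def competition_index(
    focal: SeedSet, partner: SeedSet, weighted: bool = True
) -> float:
    """Weighted fraction of the focal seed set shared with the partner's.

    1 for identical seed sets, 0 for disjoint ones; not symmetric in
    general (normalization is by the focal side). ``weighted=False`` gives
    the plain set fraction |overlap|/|focal seeds|.
    """
    _require_nonempty(focal, "focal")
    w = _weights(focal, weighted)
    total = sum(w.values())
    shared = sum(w[c] for c in focal.entries if c in partner.entries)
    return shared / total


def complementarity_index(
    focal: SeedSet,
    partner_network: MetabolicNetwork,
    partner_seeds: SeedSet | None = None,
    weighted: bool = True,
) -> float:
    """Weighted fraction of focal seeds the partner makes but does not need.

    Counts focal seed compounds present in the partner's compound set but
    absent from the partner's own seed set. A species against itself scores
    0: every own seed is, by definition, in its own seed set.
    """
    _require_nonempty(focal, "focal")
    if partner_seeds is None:
        partner_seeds = seed_set_of(partner_network)
    w = _weights(focal, weighted)
    total = sum(w.values())
    hit = sum(
        w[c]
        for c in focal.entries
        if c in partner_network.compounds and c not in partner_seeds.entries
    )
    return hit / total


def biosynthetic_support_score(
    consumer: SeedSet,
    supporter_network: MetabolicNetwork,
    weighted: bool = True,
) -> float:
    """Weighted fraction of consumer seeds found anywhere in the supporter.

    Unlike complementarity, the supporter's own seed compounds count as
    support: the score measures presence in the supporter's network, not
    biosynthetic exclusivity.
    """
    _require_nonempty(consumer, "consumer")
    w = _weights(consumer, weighted)
    total = sum(w.values())
    hit = sum(w[c] for c in consumer.entries if c in supporter_network.compounds)
    return hit / total


def metabolic_complementarity_index(
    focal: SeedSet,
    partner_network: MetabolicNetwork,
    partner_seeds: SeedSet | None = None,
    weighted: bool = True,
) -> float:
    """MCI: the complementarity index for host–microbe pairings."""
    return complementarity_index(focal, partner_network, partner_seeds, weighted)


def pairwise_indices(
    focal_network: MetabolicNetwork,
    partner_network: MetabolicNetwork,
    focal_seeds: SeedSet | None = None,
    partner_seeds: SeedSet | None = None,
    weighted: bool = True,
) -> PairwiseIndices:
    """All four indices for one ordered pair of networks."""
    if focal_seeds is None:
        focal_seeds = seed_set_of(focal_network)
    if partner_seeds is None:
        partner_seeds = seed_set_of(partner_network)
    comp = complementarity_index(focal_seeds, partner_network, partner_seeds, weighted)
    return PairwiseIndices(
        pair=(focal_network.species_id, partner_network.species_id),
        competition=competition_index(focal_seeds, partner_seeds, weighted),
        complementarity=comp,
        bss=biosynthetic_support_score(focal_seeds, partner_network, weighted),
        mci=comp,
    )


def pairwise_matrix(
    networks: "list[MetabolicNetwork] | tuple[MetabolicNetwork, ...]",
    metric: str = "competition",
    weighted: bool = True,
) -> pd.DataFrame:
    """Square matrix of one metric over every ordered species pair.

    Rows are focal species, columns partners; the diagonal holds each
    metric's self-value (1 for competition and BSS, 0 for complementarity
    and MCI). Species order is lexicographic.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    nets = sorted(networks, key=lambda n: n.species_id)
    if len(nets) < 2:
        raise SyncomError("pairwise_matrix requires at least two networks")
    ids = [n.species_id for n in nets]
    seeds = {n.species_id: seed_set_of(n) for n in nets}
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for focal in nets:
        fs = seeds[focal.species_id]
        for partner in nets:
            ps = seeds[partner.species_id]
            if metric == "competition":
                val = competition_index(fs, ps, weighted)
            elif metric == "bss":
                val = biosynthetic_support_score(fs, partner, weighted)
            else:  # complementarity / mci share the formula
                val = complementarity_index(fs, partner, ps, weighted)
            mat.loc[focal.species_id, partner.species_id] = val
    return mat
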