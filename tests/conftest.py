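"""Shared fixtures and independent oracles.

The oracles here are deliberately naive — repeated-sweep closure,
exhaustive subset search, reachability-based seed detection — and are kept
separate from the library's algorithms so each test compares two
independent routes to the same answer.
"""

from __future__ import annotations

import random
from itertools import combinations

import networkx as nx
import pytest

from syncom.core import (
    CommunityInstance,
    MetabolicNetwork,
    Reaction,
    SeedMedium,
    TargetSet,
)


def rxn(rid, reactants, products, reversible=False) -> Reaction:
    return Reaction(
        id=rid,
        reactants=frozenset(reactants),
        products=frozenset(products),
        reversible=reversible,
    )


@pytest.fixture
def s1() -> MetabolicNetwork:
    """Linear producer: A+B→C, C→D."""
    return MetabolicNetwork(
        "S1", (rxn("R1", {"A", "B"}, {"C"}), rxn("R2", {"C"}, {"D"}))
    )


@pytest.fixture
def s2() -> MetabolicNetwork:
    """Downstream consumer: D→E, E+A→F; inert without a D source."""
    return MetabolicNetwork(
        "S2", (rxn("R3", {"D"}, {"E"}), rxn("R4", {"E", "A"}, {"F"}))
    )


@pytest.fixture
def seeds_ab() -> SeedMedium:
    return SeedMedium(frozenset({"A", "B"}))


# ---------------------------------------------------------------- oracles


def sweep_closure(network: MetabolicNetwork, seeds: frozenset) -> frozenset:
    """Repeated full sweeps until no reaction adds anything new."""
    reached = set(seeds)
    directed = []
    for r in network.reactions:
        directed.append((set(r.reactants), set(r.products)))
        if r.reversible:
            directed.append((set(r.products), set(r.reactants)))
    changed = True
    while changed:
        changed = False
        for reactants, products in directed:
            if reactants <= reached and not products <= reached:
                reached |= products
                changed = True
    return frozenset(reached)


def pooled(members, host=None, label="bag") -> MetabolicNetwork:
    rxns = []
    for i, net in enumerate(list(members) + ([host] if host else [])):
        for r in net.reactions:
            rxns.append(Reaction(f"n{i}_{r.id}", r.reactants, r.products,
                                 r.reversible))
    return MetabolicNetwork(label, tuple(rxns))


def exhaustive_minimal_communities(instance: CommunityInstance):
    """All minimum-cardinality covering subsets, by brute-force enumeration.

    Returns (optimum_size, sorted tuple of frozensets, unproducible set).
    """
    members = sorted(instance.members, key=lambda m: m.species_id)
    seeds = instance.seeds.compounds
    full = sweep_closure(pooled(members, instance.host), seeds)
    goal = instance.targets.compounds & full
    unproducible = instance.targets.compounds - full
    for k in range(0, len(members) + 1):
        sols = []
        for combo in combinations(members, k):
            bag = pooled(combo, instance.host) if (combo or instance.host) else None
            reach = sweep_closure(bag, seeds) if bag else seeds
            if goal <= reach:
                sols.append(frozenset(m.species_id for m in combo))
        if sols:
            return k, tuple(sorted(sols, key=lambda s: tuple(sorted(s)))), unproducible
    raise AssertionError("unreachable: full community covers goal")


def brute_force_seed_compounds(graph: nx.DiGraph) -> set:
    """A compound is a seed iff every node reaching it is also reached by it."""
    seeds = set()
    for c in graph.nodes:
        anc = nx.ancestors(graph, c)
        desc = nx.descendants(graph, c)
        if anc <= desc:
            seeds.add(c)
    return seeds


def random_network(rng: random.Random, species_id="rand",
                   max_reactions=50, n_compounds=12) -> MetabolicNetwork:
    alphabet = [f"c{i}" for i in range(n_compounds)]
    n = rng.randint(1, max_reactions)
    rxns = []
    for i in range(n):
        reactants = frozenset(rng.sample(alphabet, rng.randint(1, 3)))
        products = frozenset(rng.sample(alphabet, rng.randint(1, 3)))
        rxns.append(Reaction(f"r{i}", reactants, products,
                             reversible=rng.random() < 0.3))
    return MetabolicNetwork(species_id, tuple(rxns))


def random_seeds(rng: random.Random, n_compounds=12) -> SeedMedium:
    alphabet = [f"c{i}" for i in range(n_compounds)]
    return SeedMedium(frozenset(rng.sample(alphabet, rng.randint(0, 4))))


def toy_instance(members, seeds, targets, host=None) -> CommunityInstance:
    return CommunityInstance(
        members=tuple(members),
        seeds=SeedMedium(frozenset(seeds)),
        targets=TargetSet(frozenset(targets)),
        host=host,
    )
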