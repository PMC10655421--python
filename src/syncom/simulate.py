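"""Planted-ground-truth community instance generator.

Instances emulate the structure of a real plant-microbiome design problem
at desk scale: most species are dispensable, a small hub is essential, and
some species compete strongly for the same exogenous compounds.

Construction (all randomness from ``rng_seed``):

* Each target gets a linear pathway chain: a fresh seed compound feeds
  ``chain_length`` reactions ending in the target compound.
* Chain reactions are partitioned across the ``n_hub`` hub species, each
  hub member receiving at least one reaction. Every chain reaction exists
  in exactly one species, so every hub member is indispensable for at
  least one target and the planted hub is the unique minimum community
  (before clones or host support are planted).
* Decoy species receive a single reaction whose reactant is a dead
  compound — produced by nothing and absent from the seeds — so decoys are
  provably inert. Species slots beyond hub + clones + decoys are filled
  with additional inert decoys.
* ``plant_competitor_pair`` adds two clone species carrying an identical
  copy of one hub member's reaction set. All three have identical seed
  sets (pairwise competition index 1), the minimum community becomes
  ambiguous (any of the three can fill the role), and the ambiguity flag
  is set. The cloned hub member thereby drops out of the essential set.
* ``plant_host_support`` adds a host network duplicating a different hub
  member's reactions, so the optimum with the host is one species smaller
  than without.

Ground truth (optima, essential set, competitor and complementary pairs)
is derived from the construction itself, never from running the solver.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import product as iproduct

from syncom.core import (
    CommunityInstance,
    MetabolicNetwork,
    Reaction,
    SeedMedium,
    SyncomError,
    TargetSet,
)

_TARGET_CATEGORIES = (
    "amino acid",
    "organic acid",
    "vitamin",
    "phytohormone",
    "nucleotide component",
    "cofactor",
    "aromatic compound",
    "inorganic ion",
    "other",
)


class GeneratorError(SyncomError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic instance.

    ``n_decoys`` counts declared decoys; any species slots left over after
    hub, clone-pair and decoys are filled with further inert decoys, so
    ``n_species`` is always honored exactly.
    """

    n_species: int = 10
    n_targets: int = 3
    chain_length: int = 4
    n_hub: int = 4
    n_decoys: int = 4
    plant_competitor_pair: bool = True
    plant_host_support: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        pair_slots = 2 if self.plant_competitor_pair else 0
        if self.n_species < 1 or self.n_targets < 1:
            raise GeneratorError("n_species and n_targets must be ≥ 1")
        if self.chain_length < 1:
            raise GeneratorError("chain_length must be ≥ 1")
        if self.n_hub < 1:
            raise GeneratorError("n_hub must be ≥ 1")
        if self.n_hub > self.n_species - self.n_decoys - pair_slots:
            raise GeneratorError(
                "infeasible config: n_hub must be ≤ "
                "n_species - n_decoys - (2 if competitor pair planted)"
            )
        if self.n_targets * self.chain_length < self.n_hub:
            raise GeneratorError(
                "infeasible config: fewer chain reactions than hub members"
            )
        if self.plant_competitor_pair and self.plant_host_support and self.n_hub < 2:
            raise GeneratorError(
                "planting both a competitor pair and host support needs n_hub ≥ 2"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for verification against solver output."""

    planted_hub: frozenset[str]
    planted_minimum_size: int
    planted_optima: tuple[frozenset[str], ...]
    planted_essential: frozenset[str]
    planted_competitor_pairs: tuple[tuple[str, str], ...]
    planted_complementary_pairs: tuple[tuple[str, str], ...]
    ambiguity: bool
    cloned_member: str | None = None
    host_covered_member: str | None = None
    planted_minimum_size_no_host: int = 0


@dataclass(frozen=True)
class SyntheticInstance:
    instance: CommunityInstance
    truth: GroundTruth
    config: GeneratorConfig = field(default=None)  # type: ignore[assignment]


def generate_instance(config: GeneratorConfig) -> SyntheticInstance:
    """Build one instance; a pure function of ``config``."""
    rng = random.Random(config.rng_seed)
    pair_slots = 2 if config.plant_competitor_pair else 0

    hub_ids = [f"hub_{i + 1:02d}" for i in range(config.n_hub)]
    n_fill = config.n_species - config.n_hub - pair_slots - config.n_decoys
    decoy_ids = [f"decoy_{i + 1:02d}" for i in range(config.n_decoys + n_fill)]
    clone_ids = ["clone_1", "clone_2"] if config.plant_competitor_pair else []

    # chains: seed_<k> -> t<k>_c1 -> ... -> t<k>_c<L-1> -> t<k>_target
    seeds = {f"seed_{k + 1}" for k in range(config.n_targets)}
    targets: set[str] = set()
    categories: dict[str, str] = {}
    chain_reactions: list[tuple[int, int, Reaction]] = []
    for k in range(config.n_targets):
        tname = f"t{k + 1}_target"
        targets.add(tname)
        categories[tname] = _TARGET_CATEGORIES[k % len(_TARGET_CATEGORIES)]
        prev = f"seed_{k + 1}"
        for j in range(config.chain_length):
            nxt = (
                tname
                if j == config.chain_length - 1
                else f"t{k + 1}_c{j + 1}"
            )
            chain_reactions.append(
                (k, j, Reaction(
                    id=f"t{k + 1}_r{j + 1}",
                    reactants=frozenset({prev}),
                    products=frozenset({nxt}),
                ))
            )
            prev = nxt

    # partition chain reactions across the hub: every member gets ≥ 1
    indices = list(range(len(chain_reactions)))
    rng.shuffle(indices)
    assignment: dict[int, str] = {}
    for slot, idx in enumerate(indices):
        if slot < config.n_hub:
            assignment[idx] = hub_ids[slot]
        else:
            assignment[idx] = rng.choice(hub_ids)

    hub_reactions: dict[str, list[Reaction]] = {h: [] for h in hub_ids}
    for idx, (_, _, rxn) in enumerate(chain_reactions):
        hub_reactions[assignment[idx]].append(rxn)

    members: list[MetabolicNetwork] = [
        MetabolicNetwork(species_id=h, reactions=tuple(sorted(
            hub_reactions[h], key=lambda r: r.id)))
        for h in hub_ids
    ]

    cloned_member: str | None = None
    if config.plant_competitor_pair:
        cloned_member = rng.choice(hub_ids)
        source = next(m for m in members if m.species_id == cloned_member)
        for cid in clone_ids:
            members.append(
                MetabolicNetwork(species_id=cid, reactions=source.reactions)
            )

    for did in decoy_ids:
        members.append(
            MetabolicNetwork(
                species_id=did,
                reactions=(
                    Reaction(
                        id=f"{did}_r1",
                        reactants=frozenset({f"{did}_dead"}),
                        products=frozenset({f"{did}_waste"}),
                    ),
                ),
            )
        )

    host: MetabolicNetwork | None = None
    host_covered: str | None = None
    if config.plant_host_support:
        eligible = [h for h in hub_ids if h != cloned_member]
        host_covered = rng.choice(eligible)
        source = next(m for m in members if m.species_id == host_covered)
        host = MetabolicNetwork(species_id="host", reactions=source.reactions)

    members.sort(key=lambda m: m.species_id)
    instance = CommunityInstance(
        members=tuple(members),
        seeds=SeedMedium(frozenset(seeds)),
        targets=TargetSet(compounds=frozenset(targets), categories=categories),
        host=host,
    )

    # ground truth from construction: each hub role is filled by the member
    # itself, or any clone of it; a role covered by the host disappears
    roles: list[list[str]] = []
    essential: set[str] = set()
    for h in hub_ids:
        if h == host_covered:
            continue
        providers = [h] + (clone_ids if h == cloned_member else [])
        roles.append(sorted(providers))
        if len(providers) == 1:
            essential.add(h)
    optima = tuple(
        sorted(
            (frozenset(choice) for choice in iproduct(*roles)),
            key=lambda s: tuple(sorted(s)),
        )
    ) if roles else (frozenset(),)

    competitor_pairs: list[tuple[str, str]] = []
    if config.plant_competitor_pair and cloned_member is not None:
        group = sorted([cloned_member] + clone_ids)
        for a in group:
            for b in group:
                if a != b:
                    competitor_pairs.append((a, b))

    complementary: set[tuple[str, str]] = set()
    for idx, (k, j, _) in enumerate(chain_reactions):
        if j == 0:
            continue
        prev_idx = next(
            i for i, (k2, j2, _) in enumerate(chain_reactions)
            if k2 == k and j2 == j - 1
        )
        consumer, producer = assignment[idx], assignment[prev_idx]
        if consumer != producer:
            complementary.add((consumer, producer))

    truth = GroundTruth(
        planted_hub=frozenset(hub_ids),
        planted_minimum_size=len(roles),
        planted_optima=optima,
        planted_essential=frozenset(essential),
        planted_competitor_pairs=tuple(sorted(competitor_pairs)),
        planted_complementary_pairs=tuple(sorted(complementary)),
        ambiguity=config.plant_competitor_pair,
        cloned_member=cloned_member,
        host_covered_member=host_covered,
        planted_minimum_size_no_host=config.n_hub,
    )
    return SyntheticInstance(instance=instance, truth=truth, config=config)


def generate_annotations(
    instance: SyntheticInstance,
    catalog,
    per_category_presence: float = 0.5,
    rng_seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene annotations for each member genome.

    Each (genome, gene) pair is present independently with probability
    ``per_category_presence``. The lexicographically first genome is forced
    to carry the catalog's first category in full, so screening always
    exercises the complete flag.
    """
    if not 0.0 <= per_category_presence <= 1.0:
        raise GeneratorError("per_category_presence must be in [0, 1]")
    rng = random.Random(rng_seed)
    genomes = sorted(instance.instance.member_ids())
    all_genes = catalog.all_genes()
    table: dict[str, set[str]] = {}
    for g in genomes:
        table[g] = {
            gene for gene in all_genes if rng.random() < per_category_presence
        }
    first_cat_genes = catalog.categories[0][1]
    table[genomes[0]].update(first_cat_genes)
    return table
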