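"""Minimal-community selection and essential-symbiont classification.

Given a community instance, find minimum-cardinality subsets of members
whose mixed-bag expansion from the seed medium produces every producible
target compound. Host reactions, when a host is present, join every
coverage check but the host is never a selectable member and never counts
toward community size.

Species present in *every* minimum-cardinality solution are **essential
symbionts**; species present in at least one but not all are **alternative
symbionts**. Classification is only sound when the enumeration of optima is
complete, so it refuses truncated results.

The search is exact: iterative deepening over subset size with a
feasibility prune (a partial selection is abandoned when even pooling all
remaining species cannot cover the targets). Members are explored in
lexicographic species-id order, so output is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from syncom.core import CommunityInstance, MetabolicNetwork, SyncomError
from syncom.expansion import _closure

DEFAULT_ENUMERATION_CAP = 1000


class MincomError(SyncomError):
    pass


class TruncatedEnumerationError(MincomError):
    """Classification was requested on an incomplete set of optima."""


@dataclass(frozen=True)
class MinimalCommunityResult:
    """Outcome of a minimal-community solve or enumeration.

    ``all_solutions`` holds every minimum-cardinality community found, in
    lexicographic order, up to the enumeration cap; ``truncated`` flags an
    incomplete enumeration. ``essential``/``alternative`` are empty when the
    enumeration is truncated (classification would be unsound).
    """

    optimum_size: int
    one_solution: frozenset[str]
    all_solutions: tuple[frozenset[str], ...]
    truncated: bool
    essential: frozenset[str]
    alternative: frozenset[str]
    unproducible_targets: frozenset[str]


def _coverage_reached(
    networks: "list[MetabolicNetwork]",
    host: MetabolicNetwork | None,
    seeds: frozenset[str],
) -> frozenset[str]:
    pooled: list = []
    for net in networks:
        pooled.extend(net.reactions)
    if host is not None:
        pooled.extend(host.reactions)
    return _closure(tuple(pooled), seeds)


def classify_symbionts(
    result: "MinimalCommunityResult | tuple[frozenset[str], ...] | list",
) -> tuple[frozenset[str], frozenset[str]]:
    """Essential (∩ optima) and alternative ((∪ optima) − essential) species.

    Refuses a truncated enumeration: with optima missing, a species absent
    from the enumerated list might still be in an unseen optimum.
    """
    if isinstance(result, MinimalCommunityResult):
        if result.truncated:
            raise TruncatedEnumerationError(
                "cannot classify symbionts from a truncated enumeration"
            )
        solutions = result.all_solutions
    else:
        solutions = tuple(frozenset(s) for s in result)
    if not solutions:
        raise MincomError("no solutions to classify")
    essential = frozenset.intersection(*solutions)
    alternative = frozenset.union(*solutions) - essential
    return essential, alternative


def enumerate_minimal_communities(
    instance: CommunityInstance,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> MinimalCommunityResult:
    """All minimum-cardinality communities covering the producible targets.

    Targets that even the full community (plus host) cannot produce are
    reported in ``unproducible_targets`` and dropped from the covering
    requirement, with a warning. The ``truncated`` flag is set only when
    more optima than ``cap`` actually exist.
    """
    if cap < 1:
        raise MincomError("cap must be positive")
    if not instance.members:
        raise MincomError("instance has no members")
    if not instance.targets.compounds:
        raise MincomError("instance has no targets")

    members = sorted(instance.members, key=lambda m: m.species_id)
    seeds = instance.seeds.compounds
    host = instance.host
    targets = instance.targets.compounds

    full_reach = _coverage_reached(members, host, seeds)
    unproducible = frozenset(targets - full_reach)
    goal = frozenset(targets & full_reach)
    if unproducible:
        warnings.warn(
            f"targets unproducible even by the full community: "
            f"{sorted(unproducible)}; excluded from the covering requirement",
            stacklevel=2,
        )

    if not goal:
        return MinimalCommunityResult(
            optimum_size=0,
            one_solution=frozenset(),
            all_solutions=(frozenset(),),
            truncated=False,
            essential=frozenset(),
            alternative=frozenset(),
            unproducible_targets=unproducible,
        )

    # seeds (or host alone) may already cover the goal → empty community
    if goal <= _coverage_reached([], host, seeds):
        return MinimalCommunityResult(
            optimum_size=0,
            one_solution=frozenset(),
            all_solutions=(frozenset(),),
            truncated=False,
            essential=frozenset(),
            alternative=frozenset(),
            unproducible_targets=unproducible,
        )

    n = len(members)
    solutions: list[frozenset[str]] = []
    overflow = False  # a (cap+1)-th optimum exists

    def covers(idx: tuple[int, ...]) -> bool:
        return goal <= _coverage_reached([members[i] for i in idx], host, seeds)

    def search(k: int, start: int, chosen: tuple[int, ...]) -> bool:
        """Enumerate size-k supersets of `chosen`; True when cap+1 reached."""
        nonlocal overflow
        if len(chosen) == k:
            if covers(chosen):
                if len(solutions) == cap:
                    overflow = True
                    return True
                solutions.append(
                    frozenset(members[i].species_id for i in chosen)
                )
            return False
        remaining_needed = k - len(chosen)
        for i in range(start, n - remaining_needed + 1):
            # feasibility prune: chosen + everything from i onward must cover
            if not covers(chosen + tuple(range(i, n))):
                # members are unordered w.r.t. capability; cannot break, but
                # this branch (forced to pick from i..n-1 only) is infeasible
                continue
            if search(k, i + 1, chosen + (i,)):
                return True
        return False

    for k in range(1, n + 1):
        search(k, 0, ())
        if solutions or overflow:
            optimum = k
            break
    else:  # pragma: no cover - goal ⊆ full_reach guarantees a solution
        raise MincomError("no covering community found despite feasible goal")

    solutions.sort(key=lambda s: tuple(sorted(s)))
    truncated = overflow
    if truncated:
        essential = frozenset()
        alternative = frozenset()
    else:
        essential, alternative = classify_symbionts(tuple(solutions))
    return MinimalCommunityResult(
        optimum_size=optimum,
        one_solution=solutions[0],
        all_solutions=tuple(solutions),
        truncated=truncated,
        essential=essential,
        alternative=alternative,
        unproducible_targets=unproducible,
    )


def solve_minimal_community(instance: CommunityInstance) -> MinimalCommunityResult:
    """One minimum-cardinality community (full enumeration of all optima).

    Equivalent to :func:`enumerate_minimal_communities` with the default
    cap; ``one_solution`` is the lexicographically first optimum.
    """
    return enumerate_minimal_communities(instance, cap=DEFAULT_ENUMERATION_CAP)
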