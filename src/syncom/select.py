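"""End-to-end SynCom selection.

Pipeline: enumerate all minimal communities (one run per host, plus a
hostless run when no host is given), classify essential symbionts per run,
pool species essential in every run in which they were evaluable, then
iteratively remove competitors whose pairwise competition index exceeds a
threshold (default 0.6, strict inequality). The final report carries the
before/after competition matrices, the exclusion trail, host-support scores
(BSS and MCI per direction), PGPT profiles and the supported-compound
lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from syncom.core import CommunityInstance, MetabolicNetwork, SyncomError
from syncom.mincom import enumerate_minimal_communities, MinimalCommunityResult
from syncom.pgpt import PGPTCatalog, PGPTProfile, screen_genomes
from syncom.reverse_ecology import (
    SeedSet,
    biosynthetic_support_score,
    complementarity_index,
    pairwise_matrix,
    seed_set_of,
)

DEFAULT_COMPETITION_THRESHOLD = 0.6


class SelectionError(SyncomError):
    pass


@dataclass(frozen=True)
class ExclusionRecord:
    """One pruning step: who was removed, why, and at what index value."""

    species_id: str
    reason: str
    triggering_value: float


@dataclass(frozen=True)
class HostSupportRecord:
    """BSS and MCI for one ordered (consumer/focal, supporter/partner) pair."""

    direction: str  # "host->member" or "member->host"
    host_id: str
    member_id: str
    bss: float
    mci: float
    bss_compounds: tuple[str, ...]
    mci_compounds: tuple[str, ...]


@dataclass(frozen=True)
class SynComReport:
    """Full record of a SynCom design run."""

    initial_members: tuple[str, ...]
    per_run_results: dict[str, MinimalCommunityResult]
    essential_symbionts: frozenset[str]
    excluded: tuple[ExclusionRecord, ...]
    final_members: frozenset[str]
    competition_before: pd.DataFrame | None
    competition_after: pd.DataFrame | None
    host_support: tuple[HostSupportRecord, ...] = ()
    pgpt_profiles: tuple[PGPTProfile, ...] = ()
    supported_compounds: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()


def _max_offdiag(mat: pd.DataFrame) -> float:
    vals = [
        mat.loc[i, j]
        for i in mat.index
        for j in mat.columns
        if i != j
    ]
    return max(vals) if vals else 0.0


def prune_competitors(
    members: "list[MetabolicNetwork] | tuple[MetabolicNetwork, ...]",
    threshold: float = DEFAULT_COMPETITION_THRESHOLD,
    weighted: bool = True,
) -> tuple[frozenset[str], tuple[ExclusionRecord, ...],
           pd.DataFrame | None, pd.DataFrame | None]:
    """Iteratively remove the worst competitor until no pair exceeds the cutoff.

    Each round recomputes the full pairwise competition matrix on the
    remaining members; if any off-diagonal entry strictly exceeds
    ``threshold``, the species involved in the most violating pairs is
    removed (ties broken by greater mean off-diagonal competition, then by
    lexicographically last id). Returns (kept ids, exclusion trail,
    before-matrix, after-matrix); all members removed is an error.
    """
    current = {m.species_id: m for m in members}
    if not current:
        raise SelectionError("prune_competitors requires at least one member")
    excluded: list[ExclusionRecord] = []
    before: pd.DataFrame | None = None
    after: pd.DataFrame | None = None

    while len(current) >= 2:
        mat = pairwise_matrix(list(current.values()), "competition", weighted)
        if before is None:
            before = mat
        after = mat
        ids = list(mat.index)
        violations = {sid: 0 for sid in ids}
        worst_val = {sid: 0.0 for sid in ids}
        any_violation = False
        for i in ids:
            for j in ids:
                if i == j:
                    continue
                v = float(mat.loc[i, j])
                if v > threshold:
                    any_violation = True
                    violations[i] += 1
                    violations[j] += 1
                    worst_val[i] = max(worst_val[i], v)
                    worst_val[j] = max(worst_val[j], v)
        if not any_violation:
            break
        mean_offdiag = {
            sid: float(
                sum(mat.loc[sid, j] for j in ids if j != sid)
                + sum(mat.loc[j, sid] for j in ids if j != sid)
            ) / (2 * (len(ids) - 1))
            for sid in ids
        }
        victim = max(
            ids,
            key=lambda s: (violations[s], mean_offdiag[s], s),
        )
        excluded.append(
            ExclusionRecord(
                species_id=victim,
                reason=(
                    f"competition > {threshold} in {violations[victim]} "
                    "pair(s)"
                ),
                triggering_value=worst_val[victim],
            )
        )
        del current[victim]
        if not current:
            raise SelectionError(
                "competitor pruning removed every member; exclusion trail: "
                + ", ".join(e.species_id for e in excluded)
            )

    if len(current) >= 2:
        after = pairwise_matrix(list(current.values()), "competition", weighted)
    else:
        # a single (or no-pair) community has no off-diagonal entries
        after = None
    return frozenset(current), tuple(excluded), before, after


def _supporting_compounds(
    consumer_seeds: SeedSet,
    supporter: MetabolicNetwork,
    supporter_seeds: SeedSet,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Seed compounds counted by BSS and by MCI respectively."""
    bss_cpds = tuple(
        sorted(c for c in consumer_seeds.entries if c in supporter.compounds)
    )
    mci_cpds = tuple(
        sorted(
            c
            for c in consumer_seeds.entries
            if c in supporter.compounds and c not in supporter_seeds.entries
        )
    )
    return bss_cpds, mci_cpds


def host_support_summary(
    members: "list[MetabolicNetwork]",
    hosts: "list[MetabolicNetwork]",
    categories: "dict[str, str] | None" = None,
    weighted: bool = True,
) -> tuple[tuple[HostSupportRecord, ...], dict]:
    """BSS/MCI for every (host, member) pair in both directions.

    ``member->host`` records treat the member as the consumer (can the host
    sustain it?); ``host->member`` the reverse. ``supported_compounds``
    aggregates the concrete seed compounds behind each score per direction,
    annotated with target categories when provided.
    """
    if not members or not hosts:
        raise SelectionError("host_support_summary needs ≥1 member and ≥1 host")
    categories = categories or {}
    seed_cache: dict[str, SeedSet] = {}

    def seeds(net: MetabolicNetwork) -> SeedSet:
        if net.species_id not in seed_cache:
            seed_cache[net.species_id] = seed_set_of(net)
        return seed_cache[net.species_id]

    records: list[HostSupportRecord] = []
    direction_cpds: dict[str, set[str]] = {
        "community->host": set(),
        "host->community": set(),
    }
    for host in sorted(hosts, key=lambda n: n.species_id):
        hs = seeds(host)
        for member in sorted(members, key=lambda n: n.species_id):
            ms = seeds(member)
            # member as consumer, host as supporter
            bss_c, mci_c = _supporting_compounds(ms, host, hs)
            records.append(
                HostSupportRecord(
                    direction="member->host",
                    host_id=host.species_id,
                    member_id=member.species_id,
                    bss=biosynthetic_support_score(ms, host, weighted),
                    mci=complementarity_index(ms, host, hs, weighted),
                    bss_compounds=bss_c,
                    mci_compounds=mci_c,
                )
            )
            direction_cpds["host->community"].update(bss_c)
            # host as consumer, member as supporter
            bss_c, mci_c = _supporting_compounds(hs, member, ms)
            records.append(
                HostSupportRecord(
                    direction="host->member",
                    host_id=host.species_id,
                    member_id=member.species_id,
                    bss=biosynthetic_support_score(hs, member, weighted),
                    mci=complementarity_index(hs, member, ms, weighted),
                    bss_compounds=bss_c,
                    mci_compounds=mci_c,
                )
            )
            direction_cpds["community->host"].update(bss_c)

    supported = {
        direction: [
            {"compound": c, **({"category": categories[c]} if c in categories else {})}
            for c in sorted(cpds)
        ]
        for direction, cpds in direction_cpds.items()
    }
    return tuple(records), supported


def design_syncom(
    instance: CommunityInstance,
    annotations: "dict[str, set[str]] | None" = None,
    hosts: "list[MetabolicNetwork] | None" = None,
    threshold: float = DEFAULT_COMPETITION_THRESHOLD,
    catalog: PGPTCatalog | None = None,
    weighted: bool = True,
) -> SynComReport:
    """Full design pipeline: minimal communities → essentials → pruning.

    One enumeration runs per host in ``hosts`` (the instance's own host, if
    any, is included automatically); with no host at all a single hostless
    run is used. The pooled essential set contains species essential in
    every run in which the run's targets were producible; a per-run
    breakdown is kept in the report so stricter or looser pooling can be
    applied downstream. Pruning then removes competitors above
    ``threshold``. Deterministic for a fixed instance.
    """
    warnings_: list[str] = []
    host_list = list(hosts) if hosts else []
    if instance.host is not None and all(
        h.species_id != instance.host.species_id for h in host_list
    ):
        host_list.append(instance.host)
    host_list.sort(key=lambda h: h.species_id)

    # stage 1: minimal-community enumeration, one run per host context
    runs: dict[str, MinimalCommunityResult] = {}
    contexts: list[tuple[str, MetabolicNetwork | None]] = (
        [(h.species_id, h) for h in host_list] if host_list else [("no_host", None)]
    )
    for label, host in contexts:
        run_instance = CommunityInstance(
            members=instance.members,
            seeds=instance.seeds,
            targets=instance.targets,
            host=host,
        )
        try:
            result = enumerate_minimal_communities(run_instance)
        except SyncomError as exc:
            raise SelectionError(f"minimal-community stage ({label}): {exc}") from exc
        if result.truncated:
            raise SelectionError(
                f"minimal-community stage ({label}): enumeration truncated; "
                "essential-symbiont classification would be unsound"
            )
        runs[label] = result

    # stage 2: pooled essentiality — essential in every evaluable run
    evaluable = {
        label: r for label, r in runs.items() if r.optimum_size > 0
    }
    if evaluable:
        pooled = frozenset.intersection(
            *(r.essential for r in evaluable.values())
        )
    else:
        pooled = frozenset()
    if not pooled:
        warnings_.append(
            "no species is essential across all runs; selection is empty"
        )

    # stage 3: competitor pruning on the essential set
    by_id = {m.species_id: m for m in instance.members}
    essential_networks = [by_id[s] for s in sorted(pooled)]
    if len(essential_networks) >= 2:
        try:
            kept, excluded, before, after = prune_competitors(
                essential_networks, threshold, weighted
            )
        except SelectionError as exc:
            raise SelectionError(f"pruning stage: {exc}") from exc
    else:
        kept = frozenset(pooled)
        excluded, before, after = (), None, None

    # stage 4: PGPT profiles for the final members
    profiles: tuple[PGPTProfile, ...] = ()
    if annotations is not None:
        final_annotations = {
            g: syms for g, syms in annotations.items() if g in kept
        }
        try:
            profiles = tuple(screen_genomes(final_annotations, catalog))
        except SyncomError as exc:
            raise SelectionError(f"pgpt stage: {exc}") from exc

    # stage 5: host support for the final members
    support: tuple[HostSupportRecord, ...] = ()
    supported: dict = {}
    if host_list and kept:
        try:
            support, supported = host_support_summary(
                [by_id[s] for s in sorted(kept)],
                host_list,
                categories=instance.targets.categories,
                weighted=weighted,
            )
        except SelectionError as exc:
            raise SelectionError(f"host-support stage: {exc}") from exc

    return SynComReport(
        initial_members=instance.member_ids(),
        per_run_results=runs,
        essential_symbionts=pooled,
        excluded=excluded,
        final_members=kept,
        competition_before=before,
        competition_after=after,
        host_support=support,
        pgpt_profiles=profiles,
        supported_compounds=supported,
        warnings=tuple(warnings_),
    )


def report_to_dict(report: SynComReport) -> dict:
    """JSON-serializable view of a report (matrices as nested dicts)."""

    def mat(m: pd.DataFrame | None):
        return None if m is None else {
            i: {j: round(float(m.loc[i, j]), 6) for j in m.columns}
            for i in m.index
        }

    return {
        "initial_members": list(report.initial_members),
        "per_run": {
            label: {
                "optimum_size": r.optimum_size,
                "all_solutions": [sorted(s) for s in r.all_solutions],
                "essential": sorted(r.essential),
                "alternative": sorted(r.alternative),
                "unproducible_targets": sorted(r.unproducible_targets),
            }
            for label, r in sorted(report.per_run_results.items())
        },
        "essential_symbionts": sorted(report.essential_symbionts),
        "excluded": [
            {"species": e.species_id, "reason": e.reason,
             "value": round(e.triggering_value, 6)}
            for e in report.excluded
        ],
        "final_members": sorted(report.final_members),
        "competition_before": mat(report.competition_before),
        "competition_after": mat(report.competition_after),
        "host_support": [
            {"direction": r.direction, "host": r.host_id, "member": r.member_id,
             "bss": round(r.bss, 6), "mci": round(r.mci, 6),
             "bss_compounds": list(r.bss_compounds),
             "mci_compounds": list(r.mci_compounds)}
            for r in report.host_support
        ],
        "pgpt": [
            {"genome": p.genome_id,
             "completeness": {c: round(v, 6) for c, v in p.completeness.items()},
             "complete": dict(p.complete)}
            for p in report.pgpt_profiles
        ],
        "supported_compounds": report.supported_compounds,
        "warnings": list(report.warnings),
    }
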