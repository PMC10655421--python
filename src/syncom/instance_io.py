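"""Reading and writing community problem instances.

Two on-disk forms are supported:

* a single JSON instance file::

      {"species": [{"id": ..., "reactions": [{"id": ..., "reactants": [...],
                    "products": [...], "reversible": false}, ...]}, ...],
       "seeds": [...],
       "targets": [{"id": ..., "category": ...}, ...],
       "host": {  # optional, same shape as one species
       }}

* a directory of per-species SBML files plus a YAML (or JSON) config with
  ``seeds`` and ``targets`` lists, and optionally ``host`` naming one of the
  SBML files.
"""

from __future__ import annotations

import json
import os
import warnings

import yaml

from syncom.core import (
    CommunityInstance,
    MetabolicNetwork,
    Reaction,
    SeedMedium,
    SyncomError,
    TargetSet,
    ValidationError,
)
from syncom.sbml import parse_sbml_network


class SchemaError(SyncomError):
    """An instance document does not match the expected schema."""


def _network_from_dict(obj: dict, *, where: str) -> MetabolicNetwork:
    if not isinstance(obj, dict) or "id" not in obj:
        raise SchemaError(f"{where}: expected an object with an 'id' field")
    reactions = []
    for i, r in enumerate(obj.get("reactions", [])):
        for key in ("id", "reactants", "products"):
            if key not in r:
                raise SchemaError(f"{where}.reactions[{i}]: missing field {key!r}")
        reactions.append(
            Reaction(
                id=str(r["id"]),
                reactants=frozenset(map(str, r["reactants"])),
                products=frozenset(map(str, r["products"])),
                reversible=bool(r.get("reversible", False)),
            )
        )
    return MetabolicNetwork(species_id=str(obj["id"]), reactions=tuple(reactions))


def _network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "id": network.species_id,
        "reactions": [
            {
                "id": r.id,
                "reactants": sorted(r.reactants),
                "products": sorted(r.products),
                "reversible": r.reversible,
            }
            for r in sorted(network.reactions, key=lambda r: r.id)
        ],
    }


def _targets_from_list(raw) -> TargetSet:
    compounds: set[str] = set()
    categories: dict[str, str] = {}
    for t in raw:
        if isinstance(t, str):
            compounds.add(t)
            continue
        if not isinstance(t, dict) or "id" not in t:
            raise SchemaError("targets: each entry must be a string or {'id': ...}")
        cid = str(t["id"])
        compounds.add(cid)
        if t.get("category"):
            categories[cid] = str(t["category"])
    return TargetSet(compounds=frozenset(compounds), categories=categories)


def _check_target_reachability(instance: CommunityInstance) -> None:
    known = set(instance.seeds.compounds)
    for m in instance.members:
        known |= m.compounds
    if instance.host is not None:
        known |= instance.host.compounds
    orphans = instance.targets.compounds - known
    if orphans:
        warnings.warn(
            "target compounds absent from every network and the seed medium "
            f"(cannot be produced): {sorted(orphans)}",
            stacklevel=3,
        )


def instance_from_dict(doc: dict) -> CommunityInstance:
    """Build a validated :class:`CommunityInstance` from a JSON-style dict."""
    if "species" not in doc:
        raise SchemaError("instance: missing field 'species'")
    if "seeds" not in doc:
        raise SchemaError("instance: missing field 'seeds'")
    members = tuple(
        _network_from_dict(s, where=f"species[{i}]")
        for i, s in enumerate(doc["species"])
    )
    seeds = SeedMedium(frozenset(map(str, doc["seeds"])))
    targets = _targets_from_list(doc.get("targets", []))
    host = None
    if doc.get("host") is not None:
        host = _network_from_dict(doc["host"], where="host")
    instance = CommunityInstance(members=members, seeds=seeds, targets=targets, host=host)
    _check_target_reachability(instance)
    return instance


def instance_to_dict(instance: CommunityInstance) -> dict:
    doc: dict = {
        "species": [_network_to_dict(m) for m in instance.members],
        "seeds": sorted(instance.seeds.compounds),
        "targets": [
            {"id": cid, **({"category": instance.targets.categories[cid]}
                           if cid in instance.targets.categories else {})}
            for cid in sorted(instance.targets.compounds)
        ],
    }
    if instance.host is not None:
        doc["host"] = _network_to_dict(instance.host)
    return doc


def _load_instance_dir(path: str) -> CommunityInstance:
    """Directory layout: ``*.sbml``/``*.xml`` networks + ``config.yaml``."""
    config_path = None
    for name in ("config.yaml", "config.yml", "config.json"):
        cand = os.path.join(path, name)
        if os.path.exists(cand):
            config_path = cand
            break
    if config_path is None:
        raise SchemaError(f"{path}: no config.yaml/config.yml/config.json found")
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "seeds" not in config:
        raise SchemaError(f"{config_path}: config must define 'seeds'")

    host_file = config.get("host")
    members = []
    host = None
    for name in sorted(os.listdir(path)):
        if not name.endswith((".sbml", ".xml")):
            continue
        net = parse_sbml_network(os.path.join(path, name))
        if host_file is not None and name == host_file:
            host = net
        else:
            members.append(net)
    if host_file is not None and host is None:
        raise SchemaError(f"{path}: host file {host_file!r} not found")
    instance = CommunityInstance(
        members=tuple(members),
        seeds=SeedMedium(frozenset(map(str, config["seeds"]))),
        targets=_targets_from_list(config.get("targets", [])),
        host=host,
    )
    _check_target_reachability(instance)
    return instance


def load_instance(path: "str | os.PathLike") -> CommunityInstance:
    """Load an instance from a JSON file or an SBML directory.

    Unknown target compounds (present in no network and not in the seeds)
    raise a warning, not an error: real target lists routinely contain
    unreachable compounds, which downstream solvers report explicitly.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        return _load_instance_dir(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON: {exc}") from exc
    return instance_from_dict(doc)


def save_instance(instance: CommunityInstance, path: "str | os.PathLike") -> None:
    """Write an instance as canonical (sorted-key, sorted-list) JSON."""
    with open(os.fspath(path), "w") as fh:
        json.dump(instance_to_dict(instance), fh, indent=1, sort_keys=True)
        fh.write("\n")


# duplicate-species detection lives in CommunityInstance.__post_init__;
# re-exported here for callers expecting an io-level error type
__all__ = [
    "SchemaError",
    "ValidationError",
    "load_instance",
    "save_instance",
    "instance_from_dict",
    "instance_to_dict",
]
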