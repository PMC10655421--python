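# syncom

Design of synthetic microbial communities (SynComs) from qualitative
genome-scale metabolic networks (GSMNs).

Plant-microbiome engineering starts from hundreds of metagenome-assembled
genomes and must shrink them to a handful of strains that together retain
the community's plant-beneficial metabolism. `syncom` implements that
in-silico reduction as a reusable, fully tested pipeline over purely
qualitative metabolic networks — reaction sets without stoichiometry or
flux — for microbial ecologists and bioinformaticians working on
community design.

## What it computes

**Metabolic potential (network expansion).** The *scope* of a species on a
growth medium *S* is the least fixed point of reaction firing: starting
from the seed compounds *S*, a reaction adds its products once all its
reactants are reachable (reversible reactions fire either way). The
community potential pools all members' reactions into one "mixed-bag"
network before expansion; the *added value* is what only the pooled
community can make.

**Minimal communities and essential symbionts.** Given target compounds
*T*, the solver finds every minimum-cardinality subset *C* of species whose
mixed-bag scope (optionally together with a host plant network, which
supports the community but is never selected) covers the producible part of
*T*. Species in **every** optimum are *essential symbionts*; species in
some but not all are *alternative symbionts*. The search is exact and
verified against brute-force subset enumeration.

**Reverse ecology.** A species' *seed set* — what it must take up from its
environment — is detected as the source strongly-connected components of
its substrate→product compound graph, each compound weighted 1/|component|.
From seed sets come four pairwise indices, all confidence-weighted
fractions in [0, 1]:

- *competition*: focal seeds also demanded by the partner,
- *complementarity*: focal seeds the partner synthesizes but does not
  itself demand,
- *BSS* (biosynthetic support score): consumer seeds present anywhere in a
  supporter's network,
- *MCI* (metabolic complementarity index): the complementarity measure for
  host–microbe pairs.

**Trait screening.** Genome annotations are screened against a packaged
catalog of plant growth-promoting trait (PGPT) genes in eight categories
(nitrogen fixation, EPS production, nodulation, ROS scavenging, iron
acquisition, potassium transport, spermidine metabolism, IAA-related
tryptophan metabolism), reporting per-category completeness.

**End-to-end selection.** `design_syncom` chains the stages: enumerate
minimal communities per host, intersect to the essential symbionts, then
iteratively drop the worst competitor while any pairwise competition index
exceeds a threshold (default 0.6, strict). A planted-ground-truth instance
generator makes every stage testable without external genome data.

## Worked example

```python
from syncom import (enumerate_minimal_communities, scope_statistics,
                    community_scope, design_syncom, load_catalog)
from syncom.simulate import (GeneratorConfig, generate_instance,
                             generate_annotations)

synth = generate_instance(GeneratorConfig(rng_seed=42))   # 10 species
inst = synth.instance

stats = scope_statistics(list(inst.members), inst.seeds)
print(f"scope sizes: min={stats.minimum} max={stats.maximum} mean={stats.mean:.2f}")

res = enumerate_minimal_communities(inst)
print("optimum size:", res.optimum_size)
print("essential:", sorted(res.essential), "alternative:", sorted(res.alternative))

ann = generate_annotations(synth, load_catalog(), 0.4, rng_seed=42)
report = design_syncom(inst, annotations=ann)
print("final SynCom:", sorted(report.final_members))
```

prints

```
scope sizes: min=3 max=5 mean=3.80
optimum size: 4
essential: ['hub_01', 'hub_03', 'hub_04'] alternative: ['clone_1', 'clone_2', 'hub_02']
final SynCom: ['hub_01', 'hub_03', 'hub_04']
```

The generated instance plants a 4-species hub (`hub_01`–`hub_04`) that is
jointly required for the targets, plus two clone species carrying an exact
copy of `hub_02`'s reactions. Any of the three interchangeable copies can
fill that role, so three size-4 optima exist and `hub_02` drops out of the
essential set; the three clones compete at index 1.0 pairwise. The final
SynCom is the planted hub minus that one competitor — exactly the designed
outcome.

A `syncom` command-line tool exposes the same stages
(`syncom simulate | summarize | iscope | cscope | mincom | seedset |
indices | pgpt | design`); run `syncom --help`.

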