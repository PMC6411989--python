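"""Synthetic ontologies and strain-structured cohorts.

The generator emulates the structure of an aging-colony necropsy
dataset: several inbred strains of genetically identical mice, each
mouse carrying zero or more diagnoses, where a diagnosis is an
(anatomy leaf, pathology leaf) pair.  Strain identity enters through
strain-specific propensity distributions over a shared pair vocabulary:

* default mode — each strain draws a Dirichlet propensity vector over
  the vocabulary; low ``concentration`` makes strains strongly
  idiosyncratic, high concentration makes them indistinguishable;
* ``combination_only`` mode — every strain uses the *same* anatomy
  marginal and the *same* pathology marginal, but pairs them up by a
  strain-specific permutation, so strain signal lives exclusively in
  the (anatomy, pathology) combinations.  Views that see only one side
  of a diagnosis carry no strain information in this mode.

Diagnosis counts are Poisson; a configurable fraction of mice is
forced healthy (zero diagnoses).  All randomness flows from one seeded
generator, so a config reproduces its cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, DiagnosisRecord
from .ontology import OntologyGraph

__all__ = ["SimConfig", "generate_toy_ontologies", "simulate_cohort"]

GROUPS = ("12m", "20m", "LONG")
SEXES = ("F", "M")


@dataclass(frozen=True)
class SimConfig:
    """Shape and signal parameters of a synthetic study.

    ``concentration`` is the symmetric Dirichlet parameter of the
    per-strain propensities over the pair vocabulary (smaller = more
    strain-specific).  ``n_pairs`` is the vocabulary size (capped by the
    number of available leaf pairs).
    """

    n_strains: int = 8
    mice_per_strain: int = 20
    healthy_fraction: float = 0.1
    diagnoses_per_mouse: float = 12.0
    anatomy_size: int = 40
    pathology_size: int = 30
    anatomy_depth: int = 4
    pathology_depth: int = 4
    part_of_density: float = 0.15
    n_pairs: int = 40
    concentration: float = 0.5
    combination_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strains", "mice_per_strain", "anatomy_size",
                     "pathology_size", "anatomy_depth", "pathology_depth",
                     "n_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("healthy_fraction", "part_of_density"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.diagnoses_per_mouse < 0 or self.concentration <= 0:
            raise ValueError("rates must be positive")


def _random_dag(
    rng: np.random.Generator,
    prefix: str,
    size: int,
    depth: int,
    part_of_density: float = 0.0,
    multi_parent_prob: float = 0.15,
) -> OntologyGraph:
    """A random rooted DAG with ``size`` classes and leaf depth ``depth``.

    One spine guarantees the requested depth; remaining classes attach
    to uniformly chosen shallower classes, occasionally gaining a second
    parent (which creates tangledness).  part_of edges are sprinkled at
    the requested density, always pointing from deeper parts to
    shallower wholes.
    """
    if size < depth + 1:
        raise ValueError(f"infeasible shape: size {size} < depth {depth} + 1")
    ids = [f"{prefix}:{i:07d}" for i in range(size)]
    root = ids[0]
    level = {root: 0}
    is_a: set[tuple[str, str]] = set()
    # spine
    for i in range(1, depth + 1):
        is_a.add((ids[i], ids[i - 1]))
        level[ids[i]] = i
    # the rest
    for i in range(depth + 1, size):
        placed = ids[:i]
        parent = placed[int(rng.integers(len(placed)))]
        if level[parent] >= depth:  # keep max depth bounded at `depth`
            parent = root
        is_a.add((ids[i], parent))
        level[ids[i]] = level[parent] + 1
        if rng.random() < multi_parent_prob:
            second = placed[int(rng.integers(len(placed)))]
            if second != parent and level[second] < level[ids[i]]:
                is_a.add((ids[i], second))
    part_of: set[tuple[str, str]] = set()
    if part_of_density > 0:
        nodes = ids[1:]
        for a in nodes:
            if rng.random() < part_of_density:
                b = nodes[int(rng.integers(len(nodes)))]
                # wholes sit strictly shallower than their parts, which
                # keeps the part_of relation acyclic by construction
                if b != a and level[b] < level[a]:
                    part_of.add((a, b))
    return OntologyGraph(
        classes=set(ids),
        labels={c: f"{prefix.lower()} class {i}" for i, c in enumerate(ids)},
        is_a_edges=is_a,
        part_of_edges=part_of,
        root=root,
    )


def generate_toy_ontologies(
    config: SimConfig,
) -> tuple[OntologyGraph, OntologyGraph]:
    """Random anatomy and pathology DAGs, deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    anatomy = _random_dag(
        rng, "ANAT", config.anatomy_size, config.anatomy_depth,
        part_of_density=config.part_of_density,
    )
    pathology = _random_dag(
        rng, "PATH", config.pathology_size, config.pathology_depth,
        part_of_density=0.0,
    )
    return anatomy, pathology


def _pair_vocabulary(
    rng: np.random.Generator,
    config: SimConfig,
    anatomy: OntologyGraph,
    pathology: OntologyGraph,
) -> list[tuple[str, str]]:
    a_leaves = sorted(anatomy.leaves())
    p_leaves = sorted(pathology.leaves())
    if not a_leaves or not p_leaves:
        raise ValueError("empty leaf vocabulary")
    n = min(config.n_pairs, len(a_leaves) * len(p_leaves))
    flat = rng.choice(len(a_leaves) * len(p_leaves), size=n, replace=False)
    return [(a_leaves[f // len(p_leaves)], p_leaves[f % len(p_leaves)]) for f in flat]


def _combination_vocabularies(
    rng: np.random.Generator,
    config: SimConfig,
    anatomy: OntologyGraph,
    pathology: OntologyGraph,
) -> list[list[tuple[str, str]]]:
    """Per-strain pair lists with identical anatomy/pathology marginals.

    A base set of q anatomy leaves is matched to q pathology leaves;
    strain s pairs anatomy i with pathology sigma_s(i) for a random
    permutation sigma_s, so each strain touches every chosen leaf
    exactly once and only the pairing differs.
    """
    a_leaves = sorted(anatomy.leaves())
    p_leaves = sorted(pathology.leaves())
    q = min(config.n_pairs, len(a_leaves), len(p_leaves))
    if q < 2:
        raise ValueError("combination mode needs at least two leaf pairs")
    a_sel = [a_leaves[i] for i in rng.choice(len(a_leaves), size=q, replace=False)]
    p_sel = [p_leaves[i] for i in rng.choice(len(p_leaves), size=q, replace=False)]
    vocabularies = []
    for _ in range(config.n_strains):
        sigma = rng.permutation(q)
        vocabularies.append([(a_sel[i], p_sel[sigma[i]]) for i in range(q)])
    return vocabularies


def simulate_cohort(
    config: SimConfig,
    anatomy: OntologyGraph,
    pathology: OntologyGraph,
) -> Cohort:
    """Draw a strain-structured cohort over the two ontologies."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5EED]).generate_state(1)[0]
    )
    strains = [f"STRAIN{s:02d}" for s in range(config.n_strains)]
    if config.combination_only:
        vocabularies = _combination_vocabularies(rng, config, anatomy, pathology)
        propensities = [np.full(len(v), 1.0 / len(v)) for v in vocabularies]
    else:
        vocab = _pair_vocabulary(rng, config, anatomy, pathology)
        vocabularies = [vocab] * config.n_strains
        propensities = [
            rng.dirichlet(np.full(len(vocab), config.concentration))
            for _ in range(config.n_strains)
        ]

    mice: dict[str, tuple[str, str, str]] = {}
    records: list[DiagnosisRecord] = []
    cell = 0
    for s, strain in enumerate(strains):
        n_mice = config.mice_per_strain
        n_healthy = int(round(config.healthy_fraction * n_mice))
        healthy_idx = set(
            rng.choice(n_mice, size=n_healthy, replace=False).tolist()
        )
        for i in range(n_mice):
            mouse_id = f"M{s:02d}-{i:03d}"
            group = GROUPS[cell % len(GROUPS)]
            sex = SEXES[(cell // len(GROUPS)) % len(SEXES)]
            cell += 1
            mice[mouse_id] = (strain, sex, group)
            if i in healthy_idx:
                continue
            n_diag = int(rng.poisson(config.diagnoses_per_mouse))
            if n_diag == 0:
                continue
            draws = rng.choice(len(vocabularies[s]), size=n_diag, p=propensities[s])
            for d in draws:
                a, p = vocabularies[s][int(d)]
                records.append(
                    DiagnosisRecord(mouse_id, strain, sex, group, a, p)
                )
    return Cohort(mice=mice, records=records)
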