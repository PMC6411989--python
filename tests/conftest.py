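import numpy as np
import pytest

from odpeval import OntologyGraph, SimConfig
from odpeval.simulate import _random_dag


@pytest.fixture
def anatomy_toy():
    """R; organ/Lu under R; H under organ; V is_a H, part_of H's sibling.

    Shape: V is part_of H (not is_a), the classic lung / respiratory
    system situation used to exercise the part_of closure.
    """
    return OntologyGraph(
        classes={"A:R", "A:H", "A:V", "A:Lu"},
        labels={"A:R": "root", "A:H": "heart", "A:V": "ventricle", "A:Lu": "lung"},
        is_a_edges={("A:H", "A:R"), ("A:V", "A:R"), ("A:Lu", "A:R")},
        part_of_edges={("A:V", "A:H")},
        root="A:R",
    )


@pytest.fixture
def pathology_toy():
    """RP; neoplasm N under RP; adenoma Ad under N; inflammation I under RP."""
    return OntologyGraph(
        classes={"P:RP", "P:N", "P:Ad", "P:I"},
        labels={"P:RP": "root", "P:N": "neoplasm", "P:Ad": "adenoma",
                "P:I": "inflammation"},
        is_a_edges={("P:N", "P:RP"), ("P:Ad", "P:N"), ("P:I", "P:RP")},
        part_of_edges=set(),
        root="P:RP",
    )


@pytest.fixture
def diamond_toy():
    """5-class DAG: R; O is_a R; H, Lu is_a O; V is_a H and is_a Lu."""
    return OntologyGraph(
        classes={"R", "O", "H", "Lu", "V"},
        labels={c: c for c in ("R", "O", "H", "Lu", "V")},
        is_a_edges={("O", "R"), ("H", "O"), ("Lu", "O"),
                    ("V", "H"), ("V", "Lu")},
        part_of_edges=set(),
        root="R",
    )


def random_ontology(seed: int, size: int = 20, depth: int = 4,
                    part_of_density: float = 0.2, prefix: str = "X"):
    rng = np.random.default_rng(seed)
    return _random_dag(rng, prefix, size, depth, part_of_density=part_of_density)


@pytest.fixture
def small_config():
    """A fast cohort for integration-style tests."""
    return SimConfig(
        n_strains=4, mice_per_strain=6, anatomy_size=20, pathology_size=15,
        anatomy_depth=3, pathology_depth=3, n_pairs=15, seed=11,
    )
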