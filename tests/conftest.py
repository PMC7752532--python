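from __future__ import annotations

import random

import pandas as pd
import pytest

from oncolex.ontology import ConceptNode, Ontology, TermEntry, load_skeleton


@pytest.fixture(scope="session")
def skeleton() -> Ontology:
    return load_skeleton()


def random_tree_ontology(seed: int, n_nodes: int = 50, n_roots: int = 3) -> Ontology:
    """A random forest with correct levels, one preferred term per node."""
    rng = random.Random(seed)
    nodes: list[ConceptNode] = []
    for i in range(n_nodes):
        cid = f"n{i:03d}"
        if i < n_roots:
            nodes.append(ConceptNode(cid, cid, None, 0))
        else:
            parent = nodes[rng.randrange(i)]
            nodes.append(ConceptNode(cid, cid, parent.concept_id, parent.level + 1))
    terms = [TermEntry(n.concept_id, n.concept_id, "preferred") for n in nodes]
    return Ontology(nodes, terms, [n.concept_id for n in nodes[:n_roots]],
                    max_depth_limit=n_nodes)


#: Registry incidence ranking used in comparison tests: the four
#: highest-incidence cancers (stomach, colon, thyroid, lung) first,
#: cervical cancer / leukemia / brain tumours absent from the top 10.
REGISTRY_ROWS = [
    ("stomach cancer", "stomach_cancer", 1),
    ("colon cancer", "colon_cancer", 2),
    ("thyroid cancer", "thyroid_cancer", 3),
    ("lung cancer", "lung_cancer", 4),
    ("breast cancer", "breast_cancer", 5),
    ("liver cancer", "liver_cancer", 6),
    ("prostate cancer", "prostate_cancer", 7),
    ("pancreatic cancer", "pancreatic_cancer", 8),
    ("gallbladder cancer", "gallbladder_cancer", 9),
    ("kidney cancer", "kidney_cancer", 10),
]


@pytest.fixture()
def registry_csv(tmp_path):
    path = tmp_path / "registry.csv"
    pd.DataFrame(
        REGISTRY_ROWS,
        columns=["cancer_type_label", "concept_id", "incidence_rank"],
    ).to_csv(path, index=False)
    return path
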