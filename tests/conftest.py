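import numpy as np
import pytest

from sigrank import AnnotationMap, ExpressionDataset, OntologyDAG


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """8 samples × 3 genes; gene g1 separates the classes, g2/g3 do not."""
    rng = np.random.default_rng(7)
    g1 = np.array([0.1, 0.3, 0.2, 0.4, 2.1, 2.3, 2.0, 2.4])
    g2 = rng.normal(size=8)
    g3 = rng.normal(size=8)
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(8)],
        gene_ids=["g1", "g2", "g3"],
        values=np.column_stack([g1, g2, g3]),
        labels=np.array(["normal"] * 4 + ["tumor"] * 4),
    )


@pytest.fixture
def toy_ontology() -> OntologyDAG:
    """Root with two children; each child has two leaf children.

            MF:0
           /    \\
        MF:1    MF:2
        /  \\    /  \\
     MF:3 MF:4 MF:5 MF:6
    """
    terms = {f"MF:{i}" for i in range(7)}
    parents = {
        "MF:0": set(),
        "MF:1": {"MF:0"},
        "MF:2": {"MF:0"},
        "MF:3": {"MF:1"},
        "MF:4": {"MF:1"},
        "MF:5": {"MF:2"},
        "MF:6": {"MF:2"},
    }
    return OntologyDAG(terms=terms, parents=parents)


@pytest.fixture
def toy_annotations() -> AnnotationMap:
    """8 genes over the toy ontology's leaves; one gene per leaf pattern."""
    return AnnotationMap(
        gene_to_terms={
            "a1": {"MF:3"},
            "a2": {"MF:4"},
            "a3": {"MF:3", "MF:4"},
            "a4": {"MF:5"},
            "a5": {"MF:6"},
            "a6": {"MF:5", "MF:6"},
            "a7": {"MF:1"},
            "a8": {"MF:2"},
        }
    )


@pytest.fixture
def toy_obo_text() -> str:
    return """format-version: 1.2

[Term]
id: MF:0000001
name: molecular_function root
namespace: molecular_function

[Term]
id: MF:0000002
name: binding
namespace: molecular_function
is_a: MF:0000001 ! root

[Term]
id: MF:0000003
name: catalysis
namespace: molecular_function
is_a: MF:0000001 ! root

[Term]
id: MF:0000004
name: dna binding
namespace: molecular_function
is_a: MF:0000002 ! binding

[Term]
id: MF:0000005
name: rna binding
namespace: molecular_function
is_a: MF:0000002 ! binding

[Term]
id: BP:0000001
name: some process
namespace: biological_process

[Term]
id: MF:0000099
name: defunct activity
namespace: molecular_function
is_obsolete: true
"""
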