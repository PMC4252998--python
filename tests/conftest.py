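import pytest

from polsa.ontology import Heading, OntologyTree


MESH_XML_FIXTURE = """<?xml version="1.0"?>
<DescriptorRecordSet>
 <DescriptorRecord>
  <DescriptorUI>D1</DescriptorUI>
  <DescriptorName><String>Pneumonia</String></DescriptorName>
  <ConceptList>
   <Concept>
    <TermList>
     <Term><String>Pneumonia</String></Term>
     <Term><String>Lung Inflammation</String></Term>
    </TermList>
   </Concept>
  </ConceptList>
  <TreeNumberList><TreeNumber>C08.381</TreeNumber></TreeNumberList>
 </DescriptorRecord>
 <DescriptorRecord>
  <DescriptorUI>D2</DescriptorUI>
  <DescriptorName><String>Fibroma</String></DescriptorName>
  <TreeNumberList><TreeNumber>C04.557</TreeNumber></TreeNumberList>
 </DescriptorRecord>
 <DescriptorRecord>
  <DescriptorUI>D3</DescriptorUI>
  <DescriptorName><String>Steel</String></DescriptorName>
  <TreeNumberList><TreeNumber>J01.637</TreeNumber></TreeNumberList>
 </DescriptorRecord>
</DescriptorRecordSet>
"""


@pytest.fixture
def mesh_xml_path(tmp_path):
    p = tmp_path / "mesh.xml"
    p.write_text(MESH_XML_FIXTURE, encoding="utf-8")
    return p


@pytest.fixture
def small_tree():
    """Hand-built polyhierarchy with named ancestors for chain tests."""
    return OntologyTree(
        [
            Heading("H_NEO", "Neoplasms", tree_numbers=["C04"], abstract_count=40000),
            Heading(
                "H_NNT",
                "Neoplasms by Histologic Type",
                tree_numbers=["C04.557"],
                abstract_count=20000,
            ),
            Heading(
                "H_FIB",
                "Fibroma",
                entry_terms=["Fibroid Tumor"],
                tree_numbers=["C04.557.450"],
                abstract_count=5000,
            ),
            Heading(
                "H_PD",
                "Proteostasis Deficiencies",
                tree_numbers=["C18.452"],
                abstract_count=3000,
            ),
            Heading(
                "H_AMY",
                "Amyloidosis",
                tree_numbers=["C18.452.284", "C04.557.111"],
                abstract_count=8000,
            ),
            Heading("H_STE", "Steel", tree_numbers=["J01.637"], abstract_count=2000),
            Heading(
                "H_SCL",
                "Scleroderma, Systemic",
                entry_terms=["Systemic Sclerosis"],
                tree_numbers=["C17.300"],
                abstract_count=12000,
            ),
        ]
    )


@pytest.fixture
def small_selection(small_tree):
    from polsa.ontology import select_headings

    return select_headings(small_tree)
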