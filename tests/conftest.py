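import pytest

from pathmodels import fixtures
from pathmodels.kgml import filter_organism, parse_kgml
from pathmodels.model import translate_metabolic

MINIMAL_KGML = """<pathway name="path:tst00010" org="tst">
 <entry id="1" name="cpd:C00031" type="compound">
   <graphics x="100" y="100" width="40" height="20"/></entry>
 <entry id="2" name="cpd:C00022" type="compound">
   <graphics x="220" y="100" width="40" height="20"/></entry>
 <entry id="3" name="tst:101 ec:2.7.1.1" type="enzyme" reaction="rn:R00299">
   <graphics x="160" y="60" width="46" height="17"/></entry>
 <reaction id="10" name="rn:R00299" type="reversible">
   <substrate id="1"/><product id="2"/></reaction>
</pathway>
"""


@pytest.fixture
def minimal_graph():
    return parse_kgml(MINIMAL_KGML)


@pytest.fixture
def minimal_model(minimal_graph):
    return translate_metabolic(filter_organism(minimal_graph, "metabolic"))


@pytest.fixture
def synthetic_graph():
    text, manifest = fixtures.gen_kgml(seed=11, n_relations=14)
    return parse_kgml(text), manifest
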