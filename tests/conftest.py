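import random

import pytest
from lxml import etree

from modeldiff.fixtures import make_fig2_pair
from modeldiff.xmltree import parse_document

from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def fig2_trees():
    v1, v2 = make_fig2_pair()
    return parse_document(v1), parse_document(v2)


def random_generic_xml(seed: int, max_depth: int = 4) -> str:
    """Small random namespace-free document for structural property tests."""
    rng = random.Random(seed)

    def build(depth: int) -> etree._Element:
        element = etree.Element(rng.choice("abcde"))
        for _ in range(rng.randint(0, 2)):
            element.set(rng.choice("pqrs"), str(rng.randint(0, 5)))
        if depth < max_depth:
            for _ in range(rng.randint(0, 3)):
                element.append(build(depth + 1))
        if len(element) == 0 and rng.random() < 0.3:
            element.text = rng.choice(("foo", "bar baz", "qux"))
        return element

    return etree.tostring(build(0)).decode()
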