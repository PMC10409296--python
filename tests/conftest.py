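import collections

import pytest

from unknome import gen_gaf


@pytest.fixture(scope="session")
def gaf_fixture():
    """A 200-protein synthetic annotation set with exact expected scores."""
    annotations, expected = gen_gaf(
        200, rates={"IDA": 1.2, "TAS": 0.6, "IEA": 2.0, "ISS": 0.8, "IMP": 0.5}, seed=42
    )
    by_protein = collections.defaultdict(list)
    for ann in annotations:
        by_protein[ann.protein_id].append(ann)
    return annotations, expected, by_protein
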