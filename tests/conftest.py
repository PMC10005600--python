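import numpy as np
import pytest

from chunkpbwt import HaplotypePanel


def panel_from_rows(rows) -> HaplotypePanel:
    return HaplotypePanel(np.array(rows, dtype=np.uint8))


@pytest.fixture
def toy_panel() -> HaplotypePanel:
    # three haplotypes over two loci; radix order at k=2 is [2, 0, 1]
    return panel_from_rows([[0, 1], [0, 1], [1, 0]])
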