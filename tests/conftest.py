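import math

import pytest

from hit2lead.chem_io import Compound


@pytest.fixture
def benzene_planar() -> Compound:
    """Benzene with an exact planar hexagon conformer (ring radius 1.39 A)."""
    conf = [
        ("C", 1.39 * math.cos(k * math.pi / 3), 1.39 * math.sin(k * math.pi / 3), 0.0)
        for k in range(6)
    ]
    return Compound(id="benzene", smiles="c1ccccc1", conformer=conf)


@pytest.fixture
def smiles_file(tmp_path):
    """Three-line SMILES library, one line malformed."""
    p = tmp_path / "lib.smi"
    p.write_text("c1ccccc1 benz\nnot_a_smiles((( bad\nCCO ethanol\n")
    return p
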