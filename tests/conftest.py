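import numpy as np
import pytest

from stochtit.ffcharges import ResidueBlock
from stochtit.sites import Site, SiteSystem

# Published ff14SB aspartate partial charges (deprotonated form); the
# residue totals -1 but its side-chain region does not sum to an integer,
# which is exactly what the localization protocol must fix.
FF14SB_ASP = [
    ("N", -0.5163), ("H", 0.2936), ("CA", 0.0381), ("HA", 0.0880),
    ("CB", -0.0303), ("HB2", -0.0122), ("HB3", -0.0122),
    ("CG", 0.7994), ("OD1", -0.8014), ("OD2", -0.8014),
    ("C", 0.5366), ("O", -0.5819),
]


@pytest.fixture
def asp_block() -> ResidueBlock:
    return ResidueBlock.from_charges("ASP", FF14SB_ASP)


@pytest.fixture
def isolated_acid() -> SiteSystem:
    return SiteSystem(
        [Site(id="A1", residue_type="Asp", pk_int=7.0)], np.zeros((1, 1))
    )


def make_isolated(pk_int: float, residue_type: str = "Asp") -> SiteSystem:
    return SiteSystem(
        [Site(id="X", residue_type=residue_type, pk_int=pk_int)],
        np.zeros((1, 1)),
    )
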