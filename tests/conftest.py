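from __future__ import annotations

from pathlib import Path

import pytest

from fgtools import structio as io
from fgtools import synthetic_data as syn

EXTERNAL_DIR = Path(__file__).resolve().parent.parent / "data" / "external"


def pdb_line(serial, name, res, chain, seq, x, y, z, occ=1.0, elem=None, alt=" ", record="ATOM"):
    elem = elem or name[0]
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{alt:1s}{res:>3s} {chain:1s}{seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {elem:>2s}"
    )


@pytest.fixture
def default_stack():
    """Synthetic 5-layer, 5-chains-per-layer fibril at rise 4.71 Å / twist −1.19°."""
    return syn.make_beta_stack(syn.StackSpec())


@pytest.fixture
def mixed_orientation_stack():
    """One layer of five chains: four parallel, one antiparallel at the edge."""
    spec = syn.StackSpec(
        n_layers=3,
        chains_per_layer=5,
        orientation_pattern=["parallel"] * 4 + ["antiparallel"],
    )
    return syn.make_beta_stack(spec)


@pytest.fixture
def two_chain_contact():
    """Two chains of one layer in contact — a minimal burial fixture."""
    model = syn.make_beta_stack(syn.StackSpec(n_layers=1, chains_per_layer=2, strand_spacing=4.0))
    return io.assign_radii(model)


def require_external(filename: str, what: str) -> Path:
    """Resolve a reference data file that cannot be redistributed here.

    Fails the calling test with fetch instructions when the file is absent.
    """
    path = EXTERNAL_DIR / filename
    if not path.exists():
        pytest.fail(
            f"reference input {filename} not present under data/external/ — {what}. "
            "See data/external/README.md for how to fetch it (requires network access).",
            pytrace=False,
        )
    return path
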