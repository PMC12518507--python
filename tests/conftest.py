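"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import pytest

from pepdock.msatools import Msa, MsaRow
from pepdock.synthgen import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def helix_complex():
    """Helix-against-helix toy complex with a handful of native contacts."""
    return make_toy_complex(ToyComplexSpec(seed=1))


@pytest.fixture(scope="session")
def strand_complex():
    """Paired-strand toy complex (many contacts across the interface)."""
    return make_toy_complex(ToyComplexSpec(seed=2, geometry="strand-pairing"))


@pytest.fixture
def small_msa():
    """Hand-written 4-row alignment (row 0 = query) with species tags."""
    return Msa(rows=[
        MsaRow(id="query", aligned="ACDEF", species="sp0"),
        MsaRow(id="r1", aligned="ACDEF", species="sp1"),
        MsaRow(id="r2", aligned="ACDGF", species="sp2"),
        MsaRow(id="r3", aligned="AC-EF", species=None),
    ])
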