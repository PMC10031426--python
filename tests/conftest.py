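"""Shared fixtures: small hand-built pedigrees with known relatedness."""

import numpy as np
import pytest

from sexvar.pedigree import Pedigree, PedigreeRecord


def _rec(id_, sire, dam, sex, gen=0):
    return PedigreeRecord(id_, sire, dam, sex, gen)


@pytest.fixture(scope="session")
def nuclear_family() -> Pedigree:
    """Founder pair with two daughters and two sons."""
    return Pedigree([
        _rec("s", "0", "0", "M"), _rec("d", "0", "0", "F"),
        _rec("f1", "s", "d", "F", 1), _rec("f2", "s", "d", "F", 1),
        _rec("m1", "s", "d", "M", 1), _rec("m2", "s", "d", "M", 1),
    ])


@pytest.fixture(scope="session")
def half_sib_pedigree() -> Pedigree:
    """One sire, two dams, two offspring each: paternal half sibs."""
    return Pedigree([
        _rec("s", "0", "0", "M"), _rec("d1", "0", "0", "F"), _rec("d2", "0", "0", "F"),
        _rec("a1", "s", "d1", "F", 1), _rec("a2", "s", "d1", "M", 1),
        _rec("b1", "s", "d2", "F", 1), _rec("b2", "s", "d2", "M", 1),
    ])


@pytest.fixture(scope="session")
def inbred_pedigree() -> Pedigree:
    """Full-sib mating: the offspring have F = 0.25."""
    return Pedigree([
        _rec("gs", "0", "0", "M"), _rec("gd", "0", "0", "F"),
        _rec("p1", "gs", "gd", "M", 1), _rec("p2", "gs", "gd", "F", 1),
        _rec("i1", "p1", "p2", "F", 2), _rec("i2", "p1", "p2", "M", 2),
    ])


@pytest.fixture(scope="session")
def double_first_cousins() -> Pedigree:
    """Two sib pairs married crosswise; cousins share all four grandparents."""
    return Pedigree([
        _rec("ga", "0", "0", "M"), _rec("gb", "0", "0", "F"),
        _rec("gc", "0", "0", "M"), _rec("gd", "0", "0", "F"),
        # family 1: son + daughter of (ga, gb); family 2: of (gc, gd)
        _rec("s1", "ga", "gb", "M", 1), _rec("d1", "ga", "gb", "F", 1),
        _rec("s2", "gc", "gd", "M", 1), _rec("d2", "gc", "gd", "F", 1),
        # crosswise marriages
        _rec("c1", "s1", "d2", "F", 2), _rec("c2", "s2", "d1", "M", 2),
        _rec("c3", "s1", "d2", "M", 2), _rec("c4", "s2", "d1", "F", 2),
    ])


@pytest.fixture(scope="session")
def three_generation_pedigree() -> Pedigree:
    """Patrilineal chain plus maternal half sibs for X / Y checks."""
    return Pedigree([
        _rec("gf", "0", "0", "M"), _rec("gm", "0", "0", "F"),
        _rec("u1", "0", "0", "M"), _rec("u2", "0", "0", "F"),
        _rec("f", "gf", "gm", "M", 1), _rec("a", "gf", "gm", "F", 1),
        _rec("m", "u1", "u2", "F", 1),
        _rec("x", "f", "m", "M", 2), _rec("y", "f", "m", "F", 2),
        # maternal half brother of x with an unrelated sire
        _rec("z_sire", "0", "0", "M"),
        _rec("z", "z_sire", "m", "M", 2),
    ])


@pytest.fixture(scope="session")
def toy_pedigrees(nuclear_family, half_sib_pedigree, inbred_pedigree,
                  double_first_cousins, three_generation_pedigree):
    return {
        "nuclear": nuclear_family,
        "half_sib": half_sib_pedigree,
        "inbred": inbred_pedigree,
        "double_first_cousins": double_first_cousins,
        "three_generation": three_generation_pedigree,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1)
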