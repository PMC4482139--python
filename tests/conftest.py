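import numpy as np
import pytest

from hsqcvar import (
    Haplotype,
    Peak,
    PeakList,
    Substitution,
    ToleranceSpec,
    VariantFamily,
    generate_variant_family,
    reference_haplotypes,
    reference_scenario,
)


@pytest.fixture(scope="session")
def tol():
    return ToleranceSpec()


@pytest.fixture(scope="session")
def scenario():
    return reference_scenario()


@pytest.fixture(scope="session")
def family(scenario):
    """The five-construct study family at a fixed seed."""
    return generate_variant_family(scenario, reference_haplotypes(), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def _grid_peaklist(ids_coords, hap=Haplotype()):
    return PeakList(
        peaks=tuple(Peak(id=i, h_shift=h, n_shift=n) for i, h, n in ids_coords),
        haplotype=hap,
    )


@pytest.fixture(scope="session")
def overlapping_family():
    """Hand-built family whose two substitutions share one disappearing peak,
    deliberately violating the independence assumption."""
    s147p = Substitution.from_string("S147P")
    p21h = Substitution.from_string("P21H")
    base = [(f"b{i}", 6.5 + 0.4 * i, 112.0 + 2.0 * i) for i in range(8)]
    x1 = ("x1", 10.5, 108.0)
    x2 = ("x2", 10.9, 130.0)
    a = Haplotype({s147p})
    b = Haplotype({p21h})
    ab = Haplotype({s147p, p21h})
    drop = {"a": {"b0", "b1"}, "b": {"b1", "b2"}}  # b1 shared
    lists = {
        Haplotype(): _grid_peaklist(base),
        a: _grid_peaklist([r for r in base if r[0] not in drop["a"]] + [x1], a),
        b: _grid_peaklist([r for r in base if r[0] not in drop["b"]] + [x2], b),
        ab: _grid_peaklist(
            [r for r in base if r[0] not in drop["a"] | drop["b"]] + [x1, x2], ab
        ),
    }
    return VariantFamily(lists=lists, scenario=reference_scenario())
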