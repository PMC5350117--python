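import pytest

from panelval.concordance import CallSet, GenotypeClass as G, VariantKey
from panelval.regions import RegionIndex, TargetRegion


def build_fixture_w():
    """The 10-site worked example: truth has 4 hom-ref, 4 het and 2 hom-alt
    sites recorded over one region; the evaluation set flips one hom-ref to
    het (a false positive) and one het to hom-ref (a false negative)."""
    index = RegionIndex([TargetRegion("chr1", 0, 1000, "GENE1", 1)])
    genotypes = [G.HOM_REF] * 4 + [G.HET] * 4 + [G.HOM_ALT] * 2
    truth_calls, eval_calls = {}, {}
    for i, gt in enumerate(genotypes):
        key = VariantKey("chr1", 10 + i, "A", "G")
        truth_calls[key] = gt
        flipped = gt
        if i == 0:
            flipped = G.HET
        elif i == 4:
            flipped = G.HOM_REF
        eval_calls[key] = flipped
    truth = CallSet("TRUTH", truth_calls, index)
    eval_ = CallSet("EVAL", eval_calls, index)
    return truth, eval_, index


@pytest.fixture
def fixture_w():
    return build_fixture_w()


@pytest.fixture
def registry():
    from panelval.registry import load_panels
    return load_panels()
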