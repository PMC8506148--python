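import pytest

from cpgx_eval import (
    FrequencyTable,
    GeneModel,
    StarAllele,
    TestPanel,
    hwe_diplotype_expansion,
)
from cpgx_eval.simulate import interval_rule_set


@pytest.fixture
def toy_model():
    """Three-allele activity-score gene: *1 normal, *2/*3 no-function."""
    return GeneModel(
        gene="CYPX",
        alleles=(
            StarAllele("CYPX", "*1", activity_value=1.0, function_class="normal"),
            StarAllele("CYPX", "*2", frozenset({"v2"}), 0.0, "no"),
            StarAllele("CYPX", "*3", frozenset({"v3"}), 0.0, "no"),
        ),
        known_variants=frozenset({"v2", "v3"}),
    )


@pytest.fixture
def toy_haps():
    """Haplotype frequencies p(*1)=.5, p(*2)=.3, p(*3)=.2 in one population."""
    return FrequencyTable(
        gene="CYPX",
        level="haplotype",
        populations=("POP1",),
        frequencies={("*1", "POP1"): 0.5, ("*2", "POP1"): 0.3, ("*3", "POP1"): 0.2},
    )


@pytest.fixture
def toy_dips(toy_haps):
    return hwe_diplotype_expansion(toy_haps)


@pytest.fixture
def toy_rules():
    """Activity-score rule: altered iff score < 2."""
    return interval_rule_set("CYPX")


@pytest.fixture
def toy_panel():
    """Panel targeting only *2's defining variant."""
    return TestPanel(test_name="toy", targets={"CYPX": frozenset({"v2"})})


@pytest.fixture
def cyp2c19_model():
    return GeneModel(
        gene="CYP2C19",
        alleles=(
            StarAllele("CYP2C19", "*1", activity_value=1.0, function_class="normal"),
            StarAllele("CYP2C19", "*2", frozenset({"rs4244285"}), 0.0, "no"),
            StarAllele("CYP2C19", "*17", frozenset({"rs12248560"}), None, "increased"),
        ),
        known_variants=frozenset({"rs4244285", "rs12248560"}),
    )


@pytest.fixture
def cyp3a5_model():
    return GeneModel(
        gene="CYP3A5",
        alleles=(
            StarAllele("CYP3A5", "*1", activity_value=1.0, function_class="normal"),
            StarAllele("CYP3A5", "*3", frozenset({"rs776746"}), 0.0, "no"),
        ),
        known_variants=frozenset({"rs776746"}),
    )
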