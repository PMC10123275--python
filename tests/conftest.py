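import numpy as np
import pytest

from sexdim import GenotypeCounts, SummaryRecord


@pytest.fixture
def record():
    """A complete two-sex summary record with a minor tested allele."""
    return SummaryRecord(
        chrom="14", pos=103_986_500, rsid="rs1", tested_allele="T",
        other_allele="C", freq_tested=0.39, beta_female=0.02,
        se_female=0.003, p_female=7.5e-14, beta_male=0.008,
        se_male=0.0032, p_male=0.013, p_combined=1e-15,
    )


# genotype count triples for the mutation-screen variants used in tests:
# (hom-ref, het, hom-alt) per study group
@pytest.fixture
def screen_counts():
    return {
        ("rs1136165", "obesity"): GenotypeCounts(31, 88, 73),
        ("rs1136165", "an"): GenotypeCounts(28, 88, 76),
        ("rs1136165", "controls"): GenotypeCounts(29, 96, 67),
        ("rs146047573", "obesity"): GenotypeCounts(191, 1, 0),
        ("rs146047573", "controls"): GenotypeCounts(192, 0, 0),
        ("rs146047573", "both_obesity"): GenotypeCounts(1291, 2, 0),
        ("rs146047573", "both_controls"): GenotypeCounts(445, 0, 0),
        ("rs1230355611", "both_obesity"): GenotypeCounts(1292, 1, 0),
        ("rs1230355611", "both_controls"): GenotypeCounts(444, 1, 0),
        ("rs758572075", "both_obesity"): GenotypeCounts(1291, 2, 0),
        ("rs758572075", "both_controls"): GenotypeCounts(443, 2, 0),
        ("thr79", "obesity"): GenotypeCounts(190, 2, 0),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
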