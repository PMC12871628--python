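import pytest

from sshash import (
    MinimizerScheme,
    SsHashIndex,
    SyntheticSpssSpec,
    gen_spss,
)


@pytest.fixture(scope="session")
def lex7():
    """k=7, m=3, lexicographic m-mer order (the small worked-example scheme)."""
    return MinimizerScheme(7, 3, "lexicographic")


@pytest.fixture(scope="session")
def small_spss():
    """A 3 kb, 5-string SPSS with k=15 (no duplicate canonical k-mers)."""
    return gen_spss(SyntheticSpssSpec(3000, 5, 15, seed=3))


@pytest.fixture(scope="session", params=["regular", "canonical"])
def small_index(request, small_spss):
    """Indexes over the small SPSS, one per modality."""
    return SsHashIndex.build(
        small_spss.strings, k=15, m=7, mode=request.param, seed=3
    )


@pytest.fixture(scope="session")
def repetitive_spss():
    """A k=9, m=3 setting with l=1 so that light and heavy (skew-index)
    minimizer types actually occur."""
    return gen_spss(SyntheticSpssSpec(4000, 4, 9, seed=5))


@pytest.fixture(scope="session", params=["regular", "canonical"])
def repetitive_index(request, repetitive_spss):
    return SsHashIndex.build(
        repetitive_spss.strings, k=9, m=3, mode=request.param, l=1, seed=5
    )


@pytest.fixture(scope="session")
def worked_example_strings():
    """A tiny SPSS whose first string begins with TCAAGTT, so that the
    reverse-complement query AACTTGA matches at position 1."""
    return ["TCAAGTTAC", "GGCATCGTT"]
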