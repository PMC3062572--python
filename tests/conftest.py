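import numpy as np
import pandas as pd
import pytest

from inscount import (
    CodeSet,
    CountMatrix,
    NormState,
    ProbeClass,
    ProbeDef,
    SampleMeta,
    SyntheticConfig,
)


@pytest.fixture(scope="session")
def tiny_codeset() -> CodeSet:
    """3 targets, 2 positives, 2 negatives — smallest full-class panel."""
    return CodeSet(
        (
            ProbeDef("geneA", ProbeClass.TARGET),
            ProbeDef("geneB", ProbeClass.TARGET),
            ProbeDef("geneC", ProbeClass.TARGET, specificity_flag="reports geneX"),
            ProbeDef("POS_A", ProbeClass.POSITIVE, spike_fmol=0.5),
            ProbeDef("POS_B", ProbeClass.POSITIVE, spike_fmol=4.0),
            ProbeDef("NEG_A", ProbeClass.NEGATIVE),
            ProbeDef("NEG_B", ProbeClass.NEGATIVE),
        )
    )


def make_matrix(codeset, columns, norm_state=NormState.RAW, meta=None):
    """Build a CountMatrix from a {sample_id: [counts...]} mapping."""
    df = pd.DataFrame(columns, index=codeset.gene_ids, dtype=float)
    if meta is None:
        samples = tuple(SampleMeta(sample_id=c) for c in df.columns)
    else:
        samples = tuple(meta)
    return CountMatrix(counts=df, codeset=codeset, samples=samples, norm_state=norm_state)


@pytest.fixture(scope="session")
def matrix_factory(tiny_codeset):
    def _make(columns, norm_state=NormState.RAW, meta=None):
        return make_matrix(tiny_codeset, columns, norm_state=norm_state, meta=meta)

    return _make


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
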