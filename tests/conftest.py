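import pytest
from hypothesis import HealthCheck, settings

from golink import (
    PValueMatrix,
    SyntheticCorpusConfig,
    analyze_records,
    simulate_corpus,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_pmat() -> PValueMatrix:
    """Three genes, three GO terms, hand-set p-values.

    g1 and g2 share t1/t2 with swapped strengths (the closed-form 0.8
    cosine pair); g3 is supported only on t3 (orthogonal); t3 has no pair
    with g1 or g2.
    """
    return PValueMatrix(
        genes=("g1", "g2", "g3"),
        gos=("t1", "t2", "t3"),
        p={
            ("g1", "t1"): 0.01,
            ("g1", "t2"): 0.1,
            ("g2", "t1"): 0.1,
            ("g2", "t2"): 0.01,
            ("g3", "t3"): 0.05,
        },
    )


@pytest.fixture(scope="session")
def benchmark_runs():
    """Twenty end-to-end runs of the reference planted-module benchmark.

    Each entry is ``(truth, result)`` for one seed of the default synthetic
    configuration, analysed at the corpus's own 99th-percentile cutoff.
    Shared session-wide because simulation dominates the suite's runtime.
    """
    runs = []
    for seed in range(20):
        cfg = SyntheticCorpusConfig(seed=seed)
        records, truth = simulate_corpus(cfg)
        result = analyze_records(records, cutoff_quantile=0.99, seed=seed)
        runs.append((truth, result))
    return runs
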