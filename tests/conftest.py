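import numpy as np
import pytest

import introcov as ic


@pytest.fixture(scope="session")
def default_ref() -> ic.HybridReference:
    return ic.default_hybrid_reference()


@pytest.fixture(scope="session")
def toy_ref() -> ic.HybridReference:
    """Two toy chromosomes: wheat 10 Mb (cen 5) and barley 8 Mb (cen 4)."""
    return ic.build_hybrid_reference(
        [ic.ChromosomeSpec("1W", "wheat", 10, 5, 1)],
        [ic.ChromosomeSpec("1X", "barley", 8, 4, 1)],
    )


def simulate_scenario(ref: ic.HybridReference, name: str, seed: int,
                      depth: float = 30.0) -> ic.BinCoverage:
    """Simulate and normalize per-bin coverage for a packaged scenario."""
    karyotype = ic.apply_events(ref, ic.get_scenario(name).events)
    raw = ic.simulate_bin_counts(karyotype, ic.SimParams(depth_per_bin=depth, seed=seed))
    return ic.normalize(ic.BinCoverage(ref=ref, raw=raw))


@pytest.fixture(scope="session")
def t6hs_cov(default_ref) -> ic.BinCoverage:
    return simulate_scenario(default_ref, "T6HS.6BL", seed=1)


@pytest.fixture(scope="session")
def t4bs_cov(default_ref) -> ic.BinCoverage:
    return simulate_scenario(default_ref, "T4BS.4HL", seed=1)


def noiseless_coverage(ref: ic.HybridReference, karyotype: ic.Karyotype,
                       present_value: float = 1.0,
                       absent_value: float = 0.01) -> ic.BinCoverage:
    """Idealised normalized profile: present bins at 1.0, absent at background."""
    normalized = np.where(karyotype.copy_number > 0, present_value, absent_value)
    raw = np.round(normalized * 100).astype(np.int64)
    return ic.BinCoverage(ref=ref, raw=raw, normalized=normalized.astype(float),
                          norm_constant=100.0, method="median_nonzero")
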