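import numpy as np
import pytest

from metaq import ArmSummary, EffectRecord, load_ocd_example, md_effect


@pytest.fixture(scope="session")
def ocd():
    """The packaged 24-study OCD SMD dataset."""
    return load_ocd_example()


@pytest.fixture(scope="session")
def ocd_records(ocd):
    return ocd.records


@pytest.fixture()
def md_records():
    """A small deterministic MD meta-analysis with arm SDs."""
    rng = np.random.default_rng(123)
    records = []
    for _ in range(6):
        n_t, n_c = int(rng.integers(10, 40)), int(rng.integers(10, 40))
        treat = ArmSummary(n_t, float(rng.normal(1.0, 0.5)), float(rng.uniform(0.5, 2.0)))
        ctrl = ArmSummary(n_c, float(rng.normal(0.0, 0.5)), float(rng.uniform(0.5, 2.0)))
        records.append(md_effect(treat, ctrl))
    return records


@pytest.fixture()
def big_md_records():
    """MD records with enormous arms, so the Welch corrections vanish."""
    rng = np.random.default_rng(5)
    records = []
    for _ in range(8):
        n = 10**6
        records.append(
            EffectRecord(
                estimate=float(rng.normal(0.3, 0.4)),
                variance=float(rng.uniform(0.05, 0.3)),
                n_treat=n,
                n_control=n,
                measure="MD",
                arm_sd_treat=1.0,
                arm_sd_control=1.0,
            )
        )
    return records
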