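import numpy as np
import pandas as pd
import pytest

from rnaiscreen import ScreenConfig, SimTruthSpec


@pytest.fixture
def config():
    return ScreenConfig()


@pytest.fixture
def small_config():
    """Two replicates to keep simulated studies fast in unit tests."""
    return ScreenConfig(replicates=2)


@pytest.fixture
def small_spec():
    """A 60-gene study small enough for per-test simulation."""
    return SimTruthSpec(
        n_genes=60,
        n_inhibitors=6,
        n_decoy_offtarget_genes=3,
        extra_off_target_rate=0.0,
        toxic_sirna_rate=0.02,
    )


def make_plate(
    plate_id="P1",
    neg_viab=(1.0, 1.1, 0.9),
    sample_activity=None,
    sample_viab=None,
    pos_activity=(200.0, 220.0),
    neg_activity=(1000.0, 1020.0, 980.0),
    screen_id="hek_tridap",
    stimulus="TriDAP",
    replicate=1,
):
    """Hand-built single plate well table for QC/normalization tests."""
    if sample_activity is None:
        sample_activity = [900.0, 700.0, 500.0, 300.0, 820.0]
    if sample_viab is None:
        sample_viab = [1.0] * len(sample_activity)
    rows = []
    well_i = 0

    def add(role, sirna, gene, act, viab):
        nonlocal well_i
        rows.append(
            dict(
                screen_id=screen_id,
                plate_id=plate_id,
                well=f"{chr(ord('A') + well_i // 24)}{well_i % 24 + 1:02d}",
                replicate=replicate,
                sirna_id=sirna,
                gene_id=gene,
                role=role,
                stimulus=stimulus,
                readout_activity=act,
                readout_viability=viab,
            )
        )
        well_i += 1

    for i, v in enumerate(neg_viab):
        act = neg_activity[i % len(neg_activity)]
        add("neg_ctrl", "ALLSTARS", "", act, v)
    for act in pos_activity:
        add("pos_ctrl_pathway", "SI_P65", "", act, 1.0)
    for j, (a, v) in enumerate(zip(sample_activity, sample_viab)):
        add("sample", f"G{j + 1:03d}_s1", f"G{j + 1:03d}", a, v)
    return pd.DataFrame(rows)


@pytest.fixture
def plate_factory():
    return make_plate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
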