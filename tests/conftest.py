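import pytest

from patpipe import synthetic_data as sd

DESIGN_3V3 = [
    ("ctrl_1", "control"),
    ("ctrl_2", "control"),
    ("ctrl_3", "control"),
    ("diff_1", "differentiated"),
    ("diff_2", "differentiated"),
    ("diff_3", "differentiated"),
]


@pytest.fixture(scope="session")
def design_map():
    return dict(DESIGN_3V3)


@pytest.fixture(scope="session")
def small_genome():
    return sd.simulate_genome(20, utr_len_range=(200, 800), templated_a_prob=0.5, seed=11)


@pytest.fixture(scope="session")
def small_read_sim(small_genome):
    conds = {
        "s1": sd.SimCondition(tail_mean=40.0, tail_sd=12.0, distal_usage=0.4, depth=30)
    }
    return sd.simulate_pat_reads(small_genome, conds, read_len=50, error_rate=0.0, seed=11)


@pytest.fixture()
def sim_files(tmp_path, small_genome, small_read_sim):
    genome_paths = small_genome.write(str(tmp_path))
    read_paths = small_read_sim.write(str(tmp_path))
    return {**genome_paths, **read_paths}
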