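import numpy as np
import pandas as pd
import pytest

from checseq import shape as shape_mod
from checseq import simulate
from checseq.genome import FragmentSet, GenomeIndex, SignalTrack
from checseq.pipeline import PipelineParams, run_pipeline


@pytest.fixture
def small_genome():
    return GenomeIndex({"chrI": 1000, "chrII": 500})


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_track(small_genome, rng):
    data = {n: rng.exponential(1.0, small_genome[n]) for n in small_genome.names}
    return SignalTrack(small_genome, data)


def make_fragments(genome, rows, **kw):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return FragmentSet(df, genome, **kw)


@pytest.fixture(scope="session")
def shape_table():
    return shape_mod.make_symmetric_shape_table(seed=7)


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions: 100-kb genome, 200 fast + 200 slow
    sites, 6 time points, fixed seed."""
    cfg = simulate.SimulationConfig(seed=1)
    sim = simulate.simulate_genome(cfg)
    samples, control = simulate.simulate_timecourse(cfg, sim)
    return cfg, sim, samples, control


@pytest.fixture(scope="session")
def pipeline_result(default_sim, shape_table):
    cfg, sim, samples, control = default_sim
    return run_pipeline(
        samples,
        control,
        sim.fasta,
        sim.genome,
        motif_counts=cfg.motif_counts,
        shape_table=shape_table,
        params=PipelineParams(seed=1),
    )
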