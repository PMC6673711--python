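import numpy as np
import pandas as pd
import pytest

from cnvwatch import coverage as cov
from cnvwatch import simulate as sim


def make_tracks(n_windows, gc=45, chrom="2R", accessibility=1.0, mq0=0.0,
                window_size=300):
    """Hand-built window track table for targeted unit tests."""
    starts = np.arange(n_windows) * window_size
    return pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": starts + window_size,
        "gc": np.broadcast_to(gc, n_windows).astype(int),
        "accessibility": np.broadcast_to(float(accessibility), n_windows).copy(),
        "mq0_frac": np.broadcast_to(float(mq0), n_windows).copy(),
    })


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-sample cohort on a 2-chromosome genome with two planted CNVs."""
    ref = sim.make_reference(11, (("2R", 150_000), ("X", 60_000)))
    samples = [sim.SimulatedSample(f"s{i}", sex="M" if i % 3 == 0 else "F")
               for i in range(6)]
    planted = [
        sim.PlantedCNV("s1", "2R", 200, 214, copies_added_per_chromosome=2,
                       allele_id="DupA"),
        sim.PlantedCNV("s2", "2R", 200, 214, copies_added_per_chromosome=2,
                       allele_id="DupA"),
    ]
    cm = sim.simulate_window_counts(ref, samples, planted, seed=12)
    constants = cov.compute_gc_normalizing_constants(cm.counts, cm.tracks)
    cm.norm = cov.normalize_coverage(cm.counts, constants, cm.tracks)
    wf = cov.build_window_filter(cm.tracks, min_gc_bin_windows=5)
    return ref, samples, planted, cm, wf
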