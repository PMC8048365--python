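import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from regulome.core_io import ActivityMatrix, GenomicInterval, SampleDesign
from regulome.synthetic import SimConfig

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def design_2v2():
    return [SampleDesign("lum_1", "luminal"), SampleDesign("lum_2", "luminal"),
            SampleDesign("bas_1", "basal"), SampleDesign("bas_2", "basal")]


@pytest.fixture()
def design_4v4():
    return ([SampleDesign(f"lum_{i}", "luminal") for i in range(1, 5)]
            + [SampleDesign(f"bas_{i}", "basal") for i in range(1, 5)])


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=300):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        out.append(GenomicInterval(str(rng.choice(chroms)), start,
                                   start + int(rng.integers(1, max_len))))
    return out


def activity_from_array(arr, prefix="f", samples=None):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ActivityMatrix(pd.DataFrame(
        arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=samples))


@pytest.fixture(scope="session")
def small_cfg():
    """Compact study used by several integration tests."""
    return SimConfig(seed=11, n_genes=300, n_enhancers=400, n_true_links=40,
                     chrom_len=5_000_000, loop_count=60, n_cobind_each=40,
                     n_fg_peaks=60, n_bg_peaks=200, n_tf_sites=400,
                     max_loop_distance_bins=150)


@pytest.fixture(scope="session")
def small_study(small_cfg, tmp_path_factory):
    from regulome.synthetic import write_study
    out = tmp_path_factory.mktemp("study")
    truth = write_study(small_cfg, out)
    return out, truth
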