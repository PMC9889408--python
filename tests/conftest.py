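import numpy as np
import pytest

from eracr.motif import bundled_motifs
from eracr.synthetic import ScenarioConfig, plant_scenario


@pytest.fixture(scope="session")
def pwms():
    return {p.motif_id: p for p in bundled_motifs()}


@pytest.fixture(scope="session")
def fox_pwm(pwms):
    return pwms["FOX_LIKE"]


@pytest.fixture(scope="session")
def half_pwm(pwms):
    return pwms["ERE_HALF"]


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A reduced fig4c scenario shared by recovery and pipeline tests."""
    out_dir = tmp_path_factory.mktemp("scenario_small")
    config = ScenarioConfig(seed=7, n_chip=500, n_common_acr=200, n_background=80)
    manifest = plant_scenario(config, out_dir)
    return config, manifest, out_dir


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_start=2000, max_width=60,
                     prefix="iv"):
    """Random, possibly overlapping intervals for oracle comparisons."""
    from eracr.intervals import GenomicInterval

    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_start))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width, name=f"{prefix}{i}"))
    return out
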