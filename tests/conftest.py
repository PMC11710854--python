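import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sexchromtk import simulate as sim
from sexchromtk import sexlink

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic scenario (seed 1, 30x depth) used by every
    parameter-recovery test."""
    return sim.simulate_genome(sim.ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def depth_tracks(scenario):
    return sim.simulate_depth(scenario, "male"), sim.simulate_depth(scenario, "female")


@pytest.fixture(scope="session")
def fm_ratios(scenario, depth_tracks):
    male, female = depth_tracks
    return sexlink.fm_ratio(female, male)


@pytest.fixture(scope="session")
def hic_set(scenario):
    return sim.simulate_hic(scenario)


@pytest.fixture(scope="session")
def assembly_pair(scenario):
    return sim.simulate_assembly_pair(scenario)


@pytest.fixture(scope="session")
def audit_result(assembly_pair):
    from sexchromtk import gaps

    old, new, _ = assembly_pair
    return gaps.audit(old, new)


@pytest.fixture(scope="session")
def self_segs(scenario):
    return sim.self_segments(scenario)


@pytest.fixture(scope="session")
def corrected_depth(scenario, depth_tracks):
    from sexchromtk import amplicons as amp

    male, _ = depth_tracks
    gc = sim.gc_track(scenario)
    corrected = amp.gc_correct_depth(male, gc)
    ref = amp.autosome_reference(corrected, scenario.autosome_regions())
    return corrected, ref


def interval_matches(found, truth, tol):
    """True when two intervals agree to within tol bp at both ends."""
    return (
        found.chrom == truth.chrom
        and abs(found.start - truth.start) <= tol
        and abs(found.end - truth.end) <= tol
    )


def rng_stream(seed, n):
    """Independent child seeds below 2**31 for n replicates."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]
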