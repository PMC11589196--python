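import pytest

from fragburst import (
    BurstPlan,
    FixtureSpec,
    generate_fixture,
)


@pytest.fixture(scope="session")
def three_burst_fixture():
    """Three well-separated single-bump bursts, comfortable SNR."""
    spec = FixtureSpec(
        duration=30.0,
        noise_sd=10.0,
        spike_amplitude=80.0,
        bursts=[
            BurstPlan(center_s=5.0),
            BurstPlan(center_s=15.0),
            BurstPlan(center_s=25.0),
        ],
        seed=7,
    )
    rec, gt = generate_fixture(spec)
    return spec, rec, gt


@pytest.fixture(scope="session")
def fragmented_fixture():
    """One burst of four sub-bumps 300 ms apart (fragmented NB)."""
    spec = FixtureSpec(
        duration=20.0,
        noise_sd=10.0,
        spike_amplitude=80.0,
        bursts=[
            BurstPlan(
                center_s=10.0,
                width_s=0.06,
                rate_hz=150.0,
                sub_bumps=[(0.0, 1.0), (0.3, 0.8), (0.6, 0.9), (0.9, 0.7)],
            )
        ],
        seed=11,
    )
    rec, gt = generate_fixture(spec)
    return spec, rec, gt
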