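"""Seedable, checkpointable random streams for the simulation kernel.

The integration kernel needs independent noise and asynchronous-release
streams whose internal state can be carried across scheduled-parameter
segment boundaries bit-exactly.  numba's global RNG state cannot be
extracted, so we use explicit xorshift128+ generators (state = two uint64
words held in a small array) with splitmix64 seeding, and a Box-Muller
transform for normal deviates.  Quality is ample for membrane noise and
binomial-approximation draws.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_stream", "rng_normal_fill", "rng_uniform", "rng_normal"]


@njit(cache=False)
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return z ^ (z >> np.uint64(31))


@njit(cache=False)
def seed_stream(seed, stream_id):
    """Initialize an xorshift128+ state array from (seed, stream_id)."""
    state = np.empty(3, dtype=np.uint64)
    base = _splitmix64(np.uint64(seed) ^ (np.uint64(stream_id) * np.uint64(0xA3EC4E2B)))
    s0 = _splitmix64(base)
    s1 = _splitmix64(s0)
    if s0 == np.uint64(0) and s1 == np.uint64(0):
        s0 = np.uint64(1)
    state[0] = s0
    state[1] = s1
    state[2] = np.uint64(0)  # spare-normal flag; slot unused for uniforms
    return state


@njit(cache=False)
def _next_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    return (s0 + s1) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=False)
def rng_uniform(state):
    """Uniform in (0, 1), never exactly 0 (safe for log)."""
    u = _next_u64(state) >> np.uint64(11)  # 53 random bits
    return (float(u) + 0.5) * (1.0 / 9007199254740992.0)


@njit(cache=False)
def rng_normal(state):
    """One standard-normal deviate (Box-Muller, no caching)."""
    u1 = rng_uniform(state)
    u2 = rng_uniform(state)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


@njit(cache=False)
def rng_normal_fill(state, out):
    """Fill ``out`` with standard-normal deviates (paired Box-Muller)."""
    n = out.shape[0]
    i = 0
    while i + 1 < n:
        u1 = rng_uniform(state)
        u2 = rng_uniform(state)
        r = np.sqrt(-2.0 * np.log(u1))
        a = 2.0 * np.pi * u2
        out[i] = r * np.cos(a)
        out[i + 1] = r * np.sin(a)
        i += 2
    if i < n:
        out[i] = rng_normal(state)
    return out
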