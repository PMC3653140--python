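"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's analytic code paths: the disc
random walk checks the Gaussian-phase-distribution series against brute
phase accrual, and the quadrature helpers integrate the axially symmetric
Watson signal directly.
"""

import numpy as np


def mc_disc_adc(
    r=1.0,
    D0=1.0,
    delta=10.0,
    Delta=20.0,
    b=1.0,
    n_walkers=100_000,
    dt=0.005,
    seed=0,
):
    """Transverse ADC from a random walk in an impermeable disc.

    Walkers start uniform in the disc, take Gaussian steps with specular
    radial reflection at the boundary, and accrue phase under a two-pulse
    gradient along x.  Returns −ln⟨cos φ⟩ / b.
    """
    rng = np.random.default_rng(seed)
    nsteps = int(round((Delta + delta) / dt))
    q = np.sqrt(b / (Delta - delta / 3.0))  # γ g δ
    g_eff = q / delta
    theta = rng.random(n_walkers) * 2 * np.pi
    rad = r * np.sqrt(rng.random(n_walkers))
    x = rad * np.cos(theta)
    y = rad * np.sin(theta)
    phase = np.zeros(n_walkers)
    sigma = np.sqrt(2 * D0 * dt)
    for i in range(nsteps):
        t = (i + 0.5) * dt
        x += sigma * rng.standard_normal(n_walkers)
        y += sigma * rng.standard_normal(n_walkers)
        rr = np.sqrt(x * x + y * y)
        out = rr > r
        if out.any():
            scale = (2 * r - rr[out]) / rr[out]
            x[out] *= scale
            y[out] *= scale
        if t < delta:
            phase += g_eff * x * dt
        elif Delta <= t:
            phase -= g_eff * x * dt
    return -np.log(np.mean(np.cos(phase))) / b
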