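"""Independent oracles used by the test suite.

The fixed-step Euler integrator below is written directly from the model
equations in plain Python floats, sharing no code with the package's
right-hand side or steppers, so it can serve as an independent reference for
the package integrators.
"""

import math


def euler_oracle(scenario, t_end, dt, y0=(1.0, 1.0, 1.0, 1.0, 0.0), n_save=101):
    """Forward-Euler reference solution.

    Returns (times, states) lists sampled at ~n_save points including both
    endpoints.  Biogenesis follows the balance rule (or the constant rate),
    matching the scenario's constants.
    """
    c = scenario.constants
    theta = (scenario.structural.c_n + math.exp(scenario.structural.m_p)) / (
        scenario.structural.c_w + scenario.structural.c_jw
    )
    F = c.F_0 * scenario.opa1
    K = c.K_0 * scenario.drp1
    es, ems = math.exp(c.stress), math.exp(-c.stress)
    MH, MD, al, ep, mu = c.M_H, c.M_D, c.alpha, c.epsilon, c.mu
    constant_B = c.biogenesis_mode == "constant"
    B_const = c.B_const

    hu, du, hf, df, atp = (float(v) for v in y0)
    n = round(t_end / dt)
    stride = max(1, n // (n_save - 1))
    times, states = [0.0], [(hu, du, hf, df, atp)]
    for i in range(n):
        tot = hu + du + hf + df
        if constant_B:
            B = B_const
        else:
            B = (MH * hu + MD * du) / tot if tot > 0 else 0.0
        fuse = F * atp * es
        fiss = K * atp * ems
        d_hu = (B - MH - fuse) * hu + fiss * hf
        d_du = (B - MD - fuse) * du + fiss * df
        d_hf = (B - fiss) * hf + fuse * hu
        d_df = (B - fiss) * df + fuse * du
        d_atp = (
            theta * (ep * (al * hf + df) + (al * hu + du))
            - mu - fiss * (hf + df) - fuse * du - fuse * hu
        )
        hu += dt * d_hu
        du += dt * d_du
        hf += dt * d_hf
        df += dt * d_df
        atp += dt * d_atp
        if (i + 1) % stride == 0 or i == n - 1:
            times.append((i + 1) * dt)
            states.append((hu, du, hf, df, atp))
    return times, states
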