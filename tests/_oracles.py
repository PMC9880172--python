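"""Independent closed-form oracles used only by the tests.

These deliberately avoid the package's ODE solver: the two-compartment
constant-clearance solution is the textbook bi-exponential superposition,
and the one-compartment expressions are elementary.
"""

import numpy as np


def two_comp_constant_cl(cl, v1, q, v2, events, times):
    """Concentration (ug/mL) of the constant-CL two-compartment model under
    a sequence of (start, rate mg/h, duration h) infusions, by superposition
    of the analytic infinite-infusion solution."""
    k10, k12, k21 = cl / v1, q / v1, q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha, beta = (s + disc) / 2.0, (s - disc) / 2.0
    A = (k21 - alpha) / (beta - alpha)
    B = (k21 - beta) / (alpha - beta)

    def infinite_infusion(t, rate):
        t = np.asarray(t, dtype=float)
        on = t > 0
        tt = np.where(on, t, 0.0)
        c = (rate / v1) * (
            A * (1.0 - np.exp(-alpha * tt)) / alpha
            + B * (1.0 - np.exp(-beta * tt)) / beta
        )
        return np.where(on, c, 0.0)

    times = np.asarray(times, dtype=float)
    c = np.zeros_like(times)
    for start, rate, duration in events:
        c += infinite_infusion(times - start, rate)
        c -= infinite_infusion(times - start - duration, rate)
    return c * 1000.0


def one_comp_bolus(dose, v1, k, times):
    """C(t) = (D/V1) exp(-k t), ug/mL."""
    return dose / v1 * np.exp(-k * np.asarray(times, dtype=float)) * 1000.0


def one_comp_bolus_auc(c0, k, t_end):
    """AUC of c0*exp(-k t) over [0, t_end]."""
    return c0 / k * (1.0 - np.exp(-k * t_end))
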