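"""Independent numerical oracles used only by the test suite.

The kinetics oracle integrates the gut/central ODE system directly with
solve_ivp (zero-order infusion input, first-order absorption and
elimination); it shares no code with the package's closed-form solutions.
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_profile(events, t_eval, p, rtol=1e-10, atol=1e-12):
    """Concentration at times ``t_eval`` by stiff ODE integration.

    ``events`` is a list of DoseEvent; ``p`` an IndividualParams.
    """
    t_eval = np.atleast_1d(np.asarray(t_eval, float))
    k = p.CL / p.V

    inf_on = np.array([e.time for e in events if not e.is_oral])
    inf_off = np.array([e.time + e.infusion_duration
                        for e in events if not e.is_oral])
    inf_rate = np.array([e.amount / e.infusion_duration
                         for e in events if not e.is_oral])
    oral_t = np.array([e.time for e in events if e.is_oral])
    oral_amt = np.array([e.amount for e in events if e.is_oral])

    def rhs(t, y):
        ag, ac = y
        rate = inf_rate[(inf_on <= t) & (t < inf_off)].sum() if inf_on.size else 0.0
        return [-p.Ka * ag, p.Ka * ag + rate - k * ac]

    brk = np.unique(np.concatenate([
        [0.0], oral_t, inf_on, inf_off, t_eval]))
    y = np.array([0.0, 0.0])
    out = np.full(t_eval.size, np.nan)
    for a, b in zip(brk, list(brk[1:]) + [brk[-1]]):
        if oral_t.size:
            y[0] += p.F * oral_amt[np.isclose(oral_t, a)].sum()
        out[np.isclose(t_eval, a)] = y[1] / p.V
        if b > a:
            sol = solve_ivp(rhs, (a, b), y, method="LSODA",
                            rtol=rtol, atol=atol, dense_output=False)
            y = sol.y[:, -1]
    return out if out.size > 1 else float(out[0])


def gauss_hermite_neg2ll(subject_pred, dv, omega2, sigma_add, n_nodes=80):
    """-2 log marginal likelihood for a one-eta subject with additive
    error, by Gauss-Hermite quadrature.

    ``subject_pred(eta)`` returns the prediction vector at a scalar eta.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    # eta = sqrt(omega2) * z with z ~ N(0,1); hermegauss integrates
    # against exp(-z^2/2), so normalize by sqrt(2 pi)
    total = 0.0
    for z, w in zip(nodes, weights):
        eta = np.sqrt(omega2) * z
        f = np.asarray(subject_pred(eta), float)
        ll = np.sum(-0.5 * np.log(2 * np.pi * sigma_add**2)
                    - 0.5 * (dv - f) ** 2 / sigma_add**2)
        total += w * np.exp(ll)
    total /= np.sqrt(2 * np.pi)
    return -2.0 * np.log(total)
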