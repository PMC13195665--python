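"""Independent brute-force oracles used only by the tests.

Deliberately naive: a fixed-step RK4 integrator of the 1:1 binding ODE
and a bisection inverter on top of it. These share no code with the
package's closed-form/adaptive-ODE paths and serve as the ground truth
the fast paths are checked against.
"""

from __future__ import annotations


def rk4_complex(
    p0: float, l0: float, kon: float, koff: float, t_end: float, dt: float = 1e-4
) -> float:
    """[PL](t_end) by fixed-step RK4 starting from zero complex."""

    def f(c: float) -> float:
        return kon * (p0 - c) * (l0 - c) - koff * c

    c = 0.0
    for _ in range(int(round(t_end / dt))):
        k1 = f(c)
        k2 = f(c + 0.5 * dt * k1)
        k3 = f(c + 0.5 * dt * k2)
        k4 = f(c + dt * k3)
        c += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return c


def bisect_time(
    p0: float,
    l0: float,
    kon: float,
    koff: float,
    target_complex: float,
    t_hi: float = 50.0,
    iters: int = 50,
    dt: float = 1e-3,
) -> float:
    """Time at which [PL] reaches ``target_complex``, by bisection on RK4."""
    lo, hi = 0.0, t_hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if rk4_complex(p0, l0, kon, koff, mid, dt=dt) < target_complex:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
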