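"""Optional numba-accelerated inner loops.

The delayed-Hebbian training loop touches every place cell at every 0.1 s
simulation step (~1e6 steps x ~1.5e3 cells at full scale), which is the
package's hottest path.  When numba is importable the loop is JIT-compiled;
otherwise a vectorized numpy fallback in :mod:`hebbian` is used.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True, fastmath=True)
def hebbian_train_loop(
    pos: np.ndarray,
    centers: np.ndarray,
    inv_sig2: np.ndarray,
    max_rate: float,
    E: np.ndarray,
    tau_steps: int,
    eta: float,
    h: float,
    s_const: float,
    th_down: float,
    th_up: float,
) -> np.ndarray:
    n = centers.shape[0]
    T = pos.shape[0]
    ring = np.empty((tau_steps, n))
    for t in range(T):
        r = np.empty(n)
        for i in range(n):
            dx = pos[t, 0] - centers[i, 0]
            dy = pos[t, 1] - centers[i, 1]
            r[i] = max_rate * np.exp(-(dx * dx + dy * dy) * inv_sig2[i])
        if t >= tau_steps:
            G = 0.0
            for i in range(n):
                G += E[i] * r[i]
            m = -1e300
            for i in range(n):
                E[i] += eta * (-E[i] + (r[i] - h * ring[t % tau_steps, i]) * G
                               + s_const)
                if E[i] < th_down:
                    E[i] = th_down
                if E[i] > m:
                    m = E[i]
            if m > th_up:
                shift = m - th_up
                for i in range(n):
                    E[i] -= shift
                    if E[i] < th_down:
                        E[i] = th_down
        for i in range(n):
            ring[t % tau_steps, i] = r[i]
    return E
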