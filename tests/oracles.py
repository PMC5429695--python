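"""Independent oracles used to cross-check the implementation.

These deliberately share no code with the package: superposition rmsd via
the quaternion characteristic-polynomial method, and the titration
equilibrium via bisection on the mass-action equation.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Optimal superposition rmsd via the quaternion eigenvalue method."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    n = P.shape[0]
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    G = (P0**2).sum() + (Q0**2).sum()
    return float(np.sqrt(max(G - 2.0 * lam_max, 0.0) / n))


def bisection_titration_heats(
    cell_volume: float,
    cell_conc: float,
    syringe_conc: float,
    injection_volumes,
    n: float,
    Ka: float,
    dH: float,
    q_offset: float = 0.0,
    tol: float = 1e-16,
) -> np.ndarray:
    """Per-injection heats (µcal) with the equilibrium solved by bisection.

    Same perfusion bookkeeping as the model definition; the bound
    concentration is found by bisecting f(B) = Ka*(n*Mt-B)*(Lt-B) - B on
    [0, min(n*Mt, Lt)] instead of the closed-form quadratic root.
    """
    V0 = cell_volume
    heats = []
    m, lig = cell_conc, 0.0
    Q_prev = 0.0
    for dv in injection_volumes:
        f = 1.0 - dv / V0
        m *= f
        lig = lig * f + syringe_conc * dv / V0
        lo, hi = 0.0, min(n * m, lig)

        def mass_action(B):
            return Ka * (n * m - B) * (lig - B) - B

        for _ in range(200):
            mid = (lo + hi) / 2.0
            if mass_action(mid) > 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol * max(hi, 1e-30):
                break
        B = (lo + hi) / 2.0
        Q = B * dH * V0 * 1.0e9
        heats.append(Q - Q_prev + (dv / V0) * (Q + Q_prev) / 2.0 + q_offset)
        Q_prev = Q
    return np.array(heats)
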