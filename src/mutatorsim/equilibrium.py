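"""Law-of-mass-action equilibria for the monomer–dimer cytoplasm.

Given total concentrations C_i and binding constants K_ij, the free
monomer concentrations solve

    F_i = C_i / (1 + 2 K_ii F_i + sum_{j != i} K_ij F_j)

with dimer concentrations F_ij = K_ij F_i F_j.  The factor 2 on the
self term encodes homodimer stoichiometry (two monomers per homodimer),
which makes species-wise mass conservation

    C_i = F_i + 2 F_ii + sum_{j != i} F_ij

exact at the fixed point.  The solver iterates the relation as written
(stopping when every free concentration changes by less than ``rel_tol``
of its new value, default 0.1%) and falls back to 0.5-damped iteration
when the plain map oscillates — which it does whenever some K is large,
since the plain map then alternates between over- and under-shooting.
The damped map is strongly contracting precisely in that stiff limit, so
the fallback changes robustness, not the fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "EquilibriumState",
    "ConvergenceError",
    "solve_lma",
    "functional_mmr_concentration",
    "functional_rcg_concentrations",
]

_PLAIN_ITERS = 100  # plain fixed-point attempts before damping kicks in


class ConvergenceError(RuntimeError):
    """LMA iteration failed to converge; carries the last state."""

    def __init__(self, state: "EquilibriumState"):
        super().__init__(
            f"LMA iteration did not converge within {state.iterations} iterations"
        )
        self.state = state


@dataclass(frozen=True)
class EquilibriumState:
    """Free monomer concentrations F and the dimer matrix F_pair."""

    F: np.ndarray
    F_pair: np.ndarray
    converged: bool
    iterations: int

    def mass_balance(self, C: np.ndarray) -> np.ndarray:
        """Residual C_i - (F_i + 2 F_ii + sum_{j!=i} F_ij) per species."""
        off = self.F_pair.sum(axis=1) - np.diag(self.F_pair)
        return np.asarray(C) - (self.F + 2 * np.diag(self.F_pair) + off)


@njit(cache=True)
def _lma_kernel(C, K, rel_tol, max_iter):  # pragma: no cover - numba
    n = C.shape[0]
    F = C.copy()
    Fn = np.empty(n, dtype=np.float64)
    it = 0
    while it < max_iter:
        it += 1
        damped = it > _PLAIN_ITERS
        for i in range(n):
            s = 0.0
            for j in range(n):
                if i == j:
                    s += 2.0 * K[i, j] * F[j]
                else:
                    s += K[i, j] * F[j]
            Fn[i] = C[i] / (1.0 + s)
        if damped:
            for i in range(n):
                Fn[i] = 0.5 * (Fn[i] + F[i])
        ok = True
        for i in range(n):
            if abs(Fn[i] - F[i]) > rel_tol * Fn[i]:
                ok = False
        for i in range(n):
            F[i] = Fn[i]
        if ok:
            return F, it, True
    return F, it, False


def solve_lma(
    C: np.ndarray,
    K: np.ndarray,
    rel_tol: float = 1e-3,
    max_iter: int = 10_000,
) -> EquilibriumState:
    """Solve the LMA equations for free and dimer concentrations.

    Parameters
    ----------
    C : total concentration per species (>= 0).
    K : symmetric matrix of binding constants (>= 0); K[i, i] is the
        homodimerisation constant of species i.
    rel_tol : per-species relative convergence tolerance (default 0.001,
        i.e. iteration stops when the change drops below 0.1% of the new
        value).

    Raises
    ------
    ConvergenceError
        if the iteration has not converged after ``max_iter`` steps; the
        exception carries the last state.
    """
    C = np.ascontiguousarray(C, dtype=np.float64)
    K = np.ascontiguousarray(K, dtype=np.float64)
    if np.any(C < 0):
        raise ValueError("total concentrations must be non-negative")
    if K.shape != (C.size, C.size) or not np.allclose(K, K.T):
        raise ValueError("K must be a symmetric matrix matching C")
    if not rel_tol > 0:
        raise ValueError("rel_tol must be positive")
    F, iters, ok = _lma_kernel(C, K, rel_tol, max_iter)
    if not ok:
        # Damped iteration stalls on near-degenerate stiff instances
        # (titration point: K large with nearly balancing totals), where the
        # map's dominant eigenvalue approaches +1.  Polish with a Newton-type
        # root solve in log-concentration space instead.
        F, ok = _root_fallback(C, K, F, rel_tol)
    F_pair = K * np.outer(F, F)
    state = EquilibriumState(F, F_pair, bool(ok), int(iters))
    if not ok:
        raise ConvergenceError(state)
    return state


def _root_fallback(
    C: np.ndarray, K: np.ndarray, F0: np.ndarray, rel_tol: float
) -> tuple[np.ndarray, bool]:
    """Damped Newton on z where F_i = C_i / (1 + e^{z_i}).

    The parameterisation keeps every iterate inside (0, C_i); the residual
    r_i = log1p(s_i) - log1p(e^{z_i}) with s_i = sum_j (1+delta_ij) K_ij F_j
    vanishes exactly at the LMA fixed point.
    """
    live = C > 0
    Kl = K[np.ix_(live, live)]
    Cl = C[live]
    Kd = np.diag(Kl).copy()
    n = Cl.size

    def f_of_z(z):
        return Cl / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))

    def residual(z):
        Fl = f_of_z(z)
        s = Kl @ Fl + Kd * Fl
        return np.log1p(s) - np.logaddexp(0.0, np.clip(z, -700.0, 700.0)), Fl, s

    # warm up with damped fixed-point iterations so Newton starts in the
    # basin even from a cold start
    Fw = np.clip(F0[live], 1e-290, Cl * (1 - 1e-12))
    for _ in range(300):
        Fw = 0.5 * (Fw + Cl / (1.0 + Kl @ Fw + Kd * Fw))
    F0l = np.clip(Fw, 1e-290, Cl * (1 - 1e-12))
    z = np.log(Cl / F0l - 1.0)
    r, Fl, s = residual(z)
    for _ in range(200):
        if np.max(np.abs(r)) < 1e-14:
            break
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -700.0, 700.0)))  # e^z/(1+e^z)
        dF = -Fl * sig  # dF_j/dz_j
        jac = ((Kl + np.diag(Kd)) * dF[None, :]) / (1.0 + s)[:, None]
        jac[np.diag_indices(n)] -= sig
        try:
            step = np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError:
            break
        # backtracking line search on the residual norm
        lam, r_norm = 1.0, np.linalg.norm(r)
        for _ls in range(60):
            r_new, F_new, s_new = residual(z + lam * step)
            if np.linalg.norm(r_new) < r_norm:
                z = z + lam * step
                r, Fl, s = r_new, F_new, s_new
                break
            lam *= 0.5
        else:
            break
    F = np.zeros_like(C)
    F[live] = Fl
    ok = bool(np.all(np.abs(Fl - Cl / (1.0 + s)) <= rel_tol * Fl))
    return F, ok


def functional_mmr_concentration(
    eq: EquilibriumState, p_int_44: float, p_nat_4: float
) -> float:
    """Concentration of functional mismatch-repair homodimers.

    G44 = F_44 * P_int(4,4) * P_nat(4)^2 — the dimer must sit in its
    native docking mode with both partners natively folded.
    """
    return float(eq.F_pair[3, 3] * p_int_44 * p_nat_4 ** 2)


def functional_rcg_concentrations(
    eq: EquilibriumState,
    p_nat_1: float,
    p_nat_2: float,
    p_nat_3: float,
    p_int_23: float,
) -> tuple[float, float]:
    """Functional concentrations of the replication-controlling proteins.

    G1 is the natively folded free monomer of protein 1; G23 the 2–3
    heterodimer in its native docking mode with both partners folded.
    """
    g1 = float(eq.F[0] * p_nat_1)
    g23 = float(eq.F_pair[1, 2] * p_int_23 * p_nat_2 * p_nat_3)
    return g1, g23
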