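"""Community ODE system and its integration to steady state.

The state vector of a B-species community on M metabolites has length
M + 3B: metabolite amounts C (moles), species abundances N (cells),
ribosome fractions phi_R, and internal energy pools a (ATP per cell).

    dC_beta/dt  = supply_beta - rho C_beta + sum_i (p_i,beta - c_i,beta) N_i
    dN_i/dt     = (lambda_i - d_i) N_i
    dphi_R,i/dt = (phi_R*(a_i) - phi_R,i) / tau_g,   tau_g = log2(100)/lambda_i
    da_i/dt     = J_i - chi m lambda_i - a_i lambda_i

Integration uses a stiff-capable adaptive solver (LSODA) in chunks on a
log-spaced time grid; between chunks species whose abundance has fallen
below the extinction threshold are clamped to zero and removed from the
active set.  The growth-rate floor inside tau_g keeps the ribosome
relaxation defined for non-growing species (relaxation freezes, consistent
with no translation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import LSODA

from .constants import ATP_GATE, LOG2_100, N_AVOGADRO
from .community import Community, RegimeConfig, initial_state
from .kinetics import community_rates
from . import thermo

#: growth-rate floor (s^-1) used inside tau_g only
LAMBDA_FLOOR = 1.0e-10

try:  # compiled fast path for the integrator; rhs() stays the reference
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


@dataclass
class CommunityState:
    """Full dynamical state at one time point."""

    C: np.ndarray
    N: np.ndarray
    phi_R: np.ndarray
    a: np.ndarray
    t: float = 0.0

    def pack(self) -> np.ndarray:
        return np.concatenate([self.C, self.N, self.phi_R, self.a])

    @classmethod
    def unpack(cls, y: np.ndarray, M: int, B: int, t: float = 0.0):
        return cls(C=y[:M].copy(), N=y[M:M + B].copy(),
                   phi_R=y[M + B:M + 2 * B].copy(), a=y[M + 2 * B:].copy(), t=t)


def rhs(t, y, flat, cell, supply, rho, active, signed=True):
    """Time derivative of the packed community state (reference path)."""
    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite state passed to rhs",
                               state=CommunityState.unpack(
                                   np.nan_to_num(y), flat.M, flat.B, t=t))
    M, B = flat.M, flat.B
    C = y[:M]
    N = y[M:M + B]
    phi_R = y[M + B:M + 2 * B]
    a = y[M + 2 * B:]

    Cc = np.maximum(C, 0.0)
    aa = np.maximum(a, 0.0)
    NN = np.maximum(N, 0.0) * active

    S = Cc[flat.sub]
    W = Cc[flat.prod]
    phi_P = np.maximum(1.0 - phi_R - cell.phi_Q, 0.0)
    E = cell.m * flat.nu * phi_P[flat.species] / cell.n_P
    q = flat.k * E * (S - W / flat.K) / (flat.K_S + S + flat.r * W / flat.K)
    if signed:
        # reverse flux spends ATP: gate it off smoothly as the pool empties
        gate = (aa / (aa + ATP_GATE))[flat.species]
        q = np.where(q < 0.0, q * gate, q)
    else:
        q = np.maximum(q, 0.0)

    J = np.bincount(flat.species, weights=flat.eta * q, minlength=B)
    gamma = cell.gamma_m * aa / (cell.gamma_half + aa)
    lam = gamma * cell.f_b * np.maximum(phi_R, 0.0) / cell.n_R

    mol = q / N_AVOGADRO * NN[flat.species]
    dC = (supply - rho * C
          + np.bincount(flat.prod, weights=mol, minlength=M)
          - np.bincount(flat.sub, weights=mol, minlength=M))
    dN = (lam - flat.d) * NN
    phi_star = aa / (cell.Omega_half + aa) * (1.0 - cell.phi_Q)
    dphi = (phi_star - phi_R) * np.maximum(lam, LAMBDA_FLOOR) / LOG2_100
    da = J - cell.chi * cell.m * lam - aa * lam
    dphi = dphi * active
    da = da * active
    return np.concatenate([dC, dN, dphi, da])


def _rhs_flat(t, y, sub, prod, species, k, K_S, r, K, eta, nu, d, active,
              supply, rho, M, B, gamma_m, gamma_half, Omega_half, phi_Q,
              f_b, n_R, n_P, m, chi, N_A, log2_100, lam_floor, signed,
              atp_gate):
    """Loop form of :func:`rhs` over flattened arrays (numba-compilable)."""
    dy = np.zeros_like(y)
    lam = np.zeros(B)
    J = np.zeros(B)
    for b in range(M):
        dy[b] = supply[b] - rho * y[b]
    for i in range(B):
        aa = max(y[M + 2 * B + i], 0.0)
        gamma = gamma_m * aa / (gamma_half + aa)
        lam[i] = gamma * f_b * max(y[M + B + i], 0.0) / n_R
    for row in range(len(sub)):
        i = species[row]
        if active[i] == 0.0:
            continue
        S = max(y[sub[row]], 0.0)
        W = max(y[prod[row]], 0.0)
        phi_P = max(1.0 - y[M + B + i] - phi_Q, 0.0)
        E = m * nu[row] * phi_P / n_P
        q = k[row] * E * (S - W / K[row]) / (K_S[row] + S + r[row] * W / K[row])
        if q < 0.0:
            if signed:
                aa = max(y[M + 2 * B + i], 0.0)
                q *= aa / (aa + atp_gate)
            else:
                q = 0.0
        if q == 0.0:
            continue
        J[i] += eta[row] * q
        mol = q / N_A * max(y[M + i], 0.0)
        dy[sub[row]] -= mol
        dy[prod[row]] += mol
    for i in range(B):
        if active[i] == 0.0:
            continue
        NN = max(y[M + i], 0.0)
        aa = max(y[M + 2 * B + i], 0.0)
        phi = y[M + B + i]
        dy[M + i] = (lam[i] - d[i]) * NN
        phi_star = aa / (Omega_half + aa) * (1.0 - phi_Q)
        dy[M + B + i] = (phi_star - phi) * max(lam[i], lam_floor) / log2_100
        dy[M + 2 * B + i] = J[i] - chi * m * lam[i] - aa * lam[i]
    return dy


def _jac_flat(t, y, sub, prod, species, k, K_S, r, K, eta, nu, d, active,
              supply, rho, M, B, gamma_m, gamma_half, Omega_half, phi_Q,
              f_b, n_R, n_P, m, chi, N_A, log2_100, lam_floor, signed,
              atp_gate):
    """Analytic Jacobian of :func:`_rhs_flat` (dense, numba-compilable).

    The exponential equilibrium factors make the system stiff, and LSODA
    refreshes its Jacobian often in the stiff regime; an analytic Jacobian
    replaces ~(M+3B) numerical RHS evaluations per refresh with one pass.
    Clamped branches (negative amounts, empty proteome, reverse-flux gate)
    use the same one-sided derivatives as the RHS.
    """
    n = M + 3 * B
    Jm = np.zeros((n, n))
    lam = np.zeros(B)
    dlam_dphi = np.zeros(B)
    dlam_da = np.zeros(B)
    for i in range(B):
        a_raw = y[M + 2 * B + i]
        aa = max(a_raw, 0.0)
        phi = y[M + B + i]
        gamma = gamma_m * aa / (gamma_half + aa)
        # one-sided (right) derivatives at clamped-zero boundaries
        dgamma = (gamma_m * gamma_half / (gamma_half + aa) ** 2
                  if a_raw >= 0.0 else 0.0)
        phip = max(phi, 0.0)
        lam[i] = gamma * f_b * phip / n_R
        dlam_dphi[i] = gamma * f_b / n_R if phi > 0.0 else 0.0
        dlam_da[i] = dgamma * f_b * phip / n_R
    for b in range(M):
        Jm[b, b] = -rho
    for row in range(len(sub)):
        i = species[row]
        if active[i] == 0.0:
            continue
        s_idx = sub[row]
        p_idx = prod[row]
        S_raw = y[s_idx]
        W_raw = y[p_idx]
        S = max(S_raw, 0.0)
        W = max(W_raw, 0.0)
        phi = y[M + B + i]
        phi_P = 1.0 - phi - phi_Q
        if phi_P <= 0.0:
            continue
        E = m * nu[row] * phi_P / n_P
        Kr = K[row]
        u = S - W / Kr
        den = K_S[row] + S + r[row] * W / Kr
        q0 = k[row] * E * u / den
        dq0_dS = k[row] * E * (den - u) / (den * den) if S_raw >= 0.0 else 0.0
        dq0_dW = (k[row] * E * (-den / Kr - u * r[row] / Kr) / (den * den)
                  if W_raw >= 0.0 else 0.0)
        dq0_dphi = -q0 / phi_P
        a_raw = y[M + 2 * B + i]
        aa = max(a_raw, 0.0)
        if q0 < 0.0:
            if not signed:
                continue
            g = aa / (aa + atp_gate)
            dq_da = (q0 * atp_gate / (aa + atp_gate) ** 2
                     if a_raw >= 0.0 else 0.0)
            q = q0 * g
            dq_dS = dq0_dS * g
            dq_dW = dq0_dW * g
            dq_dphi = dq0_dphi * g
        else:
            q = q0
            dq_dS = dq0_dS
            dq_dW = dq0_dW
            dq_dphi = dq0_dphi
            dq_da = 0.0
        N_raw = y[M + i]
        NN = max(N_raw, 0.0)
        c_molN = NN / N_A
        i_N = M + i
        i_phi = M + B + i
        i_a = M + 2 * B + i
        # metabolite rows
        Jm[s_idx, s_idx] -= dq_dS * c_molN
        Jm[s_idx, p_idx] -= dq_dW * c_molN
        Jm[p_idx, s_idx] += dq_dS * c_molN
        Jm[p_idx, p_idx] += dq_dW * c_molN
        if N_raw >= 0.0:
            Jm[s_idx, i_N] -= q / N_A
            Jm[p_idx, i_N] += q / N_A
        Jm[s_idx, i_phi] -= dq_dphi * c_molN
        Jm[p_idx, i_phi] += dq_dphi * c_molN
        Jm[s_idx, i_a] -= dq_da * c_molN
        Jm[p_idx, i_a] += dq_da * c_molN
        # energy row: da/dt includes eta * q
        Jm[i_a, s_idx] += eta[row] * dq_dS
        Jm[i_a, p_idx] += eta[row] * dq_dW
        Jm[i_a, i_phi] += eta[row] * dq_dphi
        Jm[i_a, i_a] += eta[row] * dq_da
    for i in range(B):
        if active[i] == 0.0:
            continue
        i_N = M + i
        i_phi = M + B + i
        i_a = M + 2 * B + i
        N_raw = y[i_N]
        NN = max(N_raw, 0.0)
        a_raw = y[i_a]
        aa = max(a_raw, 0.0)
        phi = y[i_phi]
        # population row
        if N_raw >= 0.0:
            Jm[i_N, i_N] = lam[i] - d[i]
        Jm[i_N, i_phi] = dlam_dphi[i] * NN
        Jm[i_N, i_a] = dlam_da[i] * NN
        # ribosome-fraction row
        lamf = lam[i] if lam[i] > lam_floor else lam_floor
        growing = lam[i] > lam_floor
        phi_star = aa / (Omega_half + aa) * (1.0 - phi_Q)
        dphistar = (Omega_half / (Omega_half + aa) ** 2 * (1.0 - phi_Q)
                    if a_raw >= 0.0 else 0.0)
        Jm[i_phi, i_phi] = (-lamf + ((phi_star - phi) * dlam_dphi[i]
                                     if growing else 0.0)) / log2_100
        Jm[i_phi, i_a] = (dphistar * lamf + ((phi_star - phi) * dlam_da[i]
                                             if growing else 0.0)) / log2_100
        # energy row (translation cost + dilution)
        Jm[i_a, i_phi] += -chi * m * dlam_dphi[i] - aa * dlam_dphi[i]
        da_daa = -chi * m * dlam_da[i] - aa * dlam_da[i]
        if a_raw >= 0.0:
            da_daa -= lam[i]
        Jm[i_a, i_a] += da_daa
    return Jm


if _numba is not None:
    _rhs_flat_fast = _numba.njit(cache=True, fastmath=False)(_rhs_flat)
    _jac_flat_fast = _numba.njit(cache=True, fastmath=False)(_jac_flat)
else:  # pragma: no cover
    _rhs_flat_fast = _rhs_flat
    _jac_flat_fast = _jac_flat


def _fast_rhs_args(flat, cell, supply, rho, active, signed=True):
    return (flat.sub, flat.prod, flat.species, flat.k, flat.K_S, flat.r,
            flat.K, flat.eta, flat.nu, flat.d, active, supply, rho,
            flat.M, flat.B, cell.gamma_m, cell.gamma_half, cell.Omega_half,
            cell.phi_Q, cell.f_b, cell.n_R, cell.n_P, cell.m, cell.chi,
            N_AVOGADRO, LOG2_100, LAMBDA_FLOOR, signed, ATP_GATE)


@dataclass
class Trajectory:
    """Sampled states plus derived growth-rate and entropy series."""

    t: np.ndarray
    C: np.ndarray       # (n, M)
    N: np.ndarray       # (n, B)
    phi_R: np.ndarray   # (n, B)
    a: np.ndarray       # (n, B)
    lam: np.ndarray     # (n, B)
    sigma: np.ndarray   # (n,)
    events: pd.DataFrame
    species_ids: list
    config: RegimeConfig | None = None

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def state_at(self, idx: int) -> CommunityState:
        return CommunityState(C=self.C[idx].copy(), N=self.N[idx].copy(),
                              phi_R=self.phi_R[idx].copy(),
                              a=self.a[idx].copy(), t=float(self.t[idx]))

    def final_state(self) -> CommunityState:
        return self.state_at(-1)

    def to_hdf5(self, path) -> None:
        import h5py
        import yaml as _yaml
        import dataclasses as _dc

        with h5py.File(path, "w") as fh:
            for name in ("t", "C", "N", "phi_R", "a", "lam", "sigma"):
                fh.create_dataset(name, data=getattr(self, name))
            fh.create_dataset("species_ids",
                              data=np.array(self.species_ids, dtype="S"))
            ev = fh.create_group("events")
            for col in self.events.columns:
                data = self.events[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                ev.create_dataset(col, data=data)
            if self.config is not None:
                d = _dc.asdict(self.config)
                fh.attrs["config"] = _yaml.safe_dump(d)

    @classmethod
    def from_hdf5(cls, path) -> "Trajectory":
        import h5py
        import yaml as _yaml

        with h5py.File(path, "r") as fh:
            kw = {name: fh[name][...]
                  for name in ("t", "C", "N", "phi_R", "a", "lam", "sigma")}
            ids = [s.decode() for s in fh["species_ids"][...]]
            ev = {col: fh["events"][col][...] for col in fh["events"]}
            for col, data in ev.items():
                if data.dtype.kind == "S":
                    ev[col] = np.array([s.decode() for s in data])
            events = pd.DataFrame(ev) if ev else pd.DataFrame(
                columns=["kind", "time", "index", "label"])
            config = None
            if "config" in fh.attrs:
                raw = _yaml.safe_load(fh.attrs["config"])
                config = RegimeConfig(**{k: tuple(v) if isinstance(v, list)
                                         and k.startswith(("N_O", "lognormal"))
                                         else v for k, v in raw.items()})
        return cls(events=events, species_ids=ids, config=config, **kw)


def _sample_grid(t_final: float, n_samples: int) -> np.ndarray:
    """Log-spaced output times (transients are early), starting at t = 0."""
    t1 = min(100.0, t_final / 100.0)
    return np.concatenate([[0.0], np.geomspace(t1, t_final, n_samples - 1)])


#: per-attempt step budget for one integration chunk; a healthy chunk needs
#: a few thousand steps, a weakly damped oscillator millions
MAX_STEPS_PER_CHUNK = 30_000


def _run_chunk(fun, jac, t0, t1, y0, t_eval, rtol, atol, max_steps):
    """Step LSODA through [t0, t1] under an explicit step budget.

    Returns (status, t_reached, y_reached, samples) with status one of
    'finished', 'budget' (step budget exhausted) or 'failed'; samples is a
    list of (t, y) pairs at the requested output times that were crossed.
    """
    try:
        solver = LSODA(fun, t0, y0, t1, rtol=rtol, atol=atol, jac=jac)
    except Exception:  # pragma: no cover - defensive
        return "failed", t0, y0, []
    samples = []
    idx = 0
    steps = 0
    while solver.status == "running":
        if steps >= max_steps:
            return "budget", solver.t, solver.y.copy(), samples
        solver.step()
        steps += 1
        if solver.status == "failed":
            return "failed", solver.t, solver.y.copy(), samples
        if idx < len(t_eval) and t_eval[idx] <= solver.t:
            dense = solver.dense_output()
            while idx < len(t_eval) and t_eval[idx] <= solver.t:
                samples.append((t_eval[idx], dense(t_eval[idx]).copy()))
                idx += 1
    return "finished", solver.t, solver.y.copy(), samples


def integrate(community: Community, config: RegimeConfig | None = None,
              state0: CommunityState | None = None,
              t_final: float | None = None, n_chunks: int = 14) -> Trajectory:
    """Integrate the community ODEs to ``t_final`` (default 1e8 s).

    Returns a Trajectory sampled on a log-spaced grid with derived
    per-species growth-rate and community entropy-production series, and an
    event log of extinctions and substrate threshold crossings.
    """
    cfg = config or community.config or RegimeConfig(M=community.network.M,
                                                     B=community.B)
    flat = community.flat()
    cell = community.cell
    supply = cfg.supply_vector()
    tf = float(t_final if t_final is not None else cfg.t_final)
    state0 = state0 or initial_state(community)
    y = state0.pack()
    M, B = flat.M, flat.B

    grid = _sample_grid(tf, cfg.n_samples)
    bounds = np.unique(grid[np.linspace(0, len(grid) - 1, n_chunks + 1,
                                        dtype=int)])
    active = np.ones(B)
    fast_args = _fast_rhs_args(flat, cell, supply, cfg.rho, active,
                               getattr(cfg, "signed_rates", True))
    use_jac = getattr(cfg, "use_jacobian", False)
    fun = lambda t, yy: _rhs_flat_fast(t, yy, *fast_args)  # noqa: E731
    jacfun = lambda t, yy: _jac_flat_fast(t, yy, *fast_args)  # noqa: E731
    times, states = [0.0], [y.copy()]
    events = []
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        t_eval = grid[(grid > t0) & (grid <= t1)]
        # Fallback ladder for pathological chunks: a few communities host
        # weakly damped oscillations whose tracking would take millions of
        # steps; each attempt runs under a step budget, retrying with the
        # analytic Jacobian and then with relaxed tolerance.  If no attempt
        # finishes, the chunk is truncated at the furthest state reached
        # (the trajectory sits on its oscillatory attractor there) and the
        # run is flagged via an `integration_truncated` event.
        attempts = [
            dict(rtol=cfg.rtol, atol=cfg.atol, jac=use_jac),
            dict(rtol=cfg.rtol, atol=cfg.atol, jac=not use_jac),
            dict(rtol=max(cfg.rtol * 100, 1e-6), atol=cfg.atol * 1e3,
                 jac=True),
        ]
        best = None
        for att in attempts:
            status, t_reached, y_reached, samples = _run_chunk(
                fun, jacfun if att["jac"] else None, t0, t1, y,
                t_eval, att["rtol"], att["atol"], MAX_STEPS_PER_CHUNK)
            ok = status == "finished" and np.all(np.isfinite(y_reached))
            if best is None or t_reached > best[1]:
                best = (status, t_reached, y_reached, samples)
            if ok:
                best = (status, t_reached, y_reached, samples)
                break
        status, t_reached, y_reached, samples = best
        if status == "failed" and not np.all(np.isfinite(y_reached)):
            raise IntegrationError(
                f"integrator failed in [{t0:g}, {t1:g}]",
                state=CommunityState.unpack(y, M, B, t=t0))
        for te, ye in samples:
            times.append(te)
            states.append(ye)
        if status != "finished":
            events.append({"kind": "integration_truncated",
                           "time": float(t_reached), "index": -1,
                           "label": f"chunk [{t0:g}, {t1:g}]"})
            # carry the furthest state; remaining output times in this
            # chunk repeat it so the sampling grid stays rectangular
            for te in t_eval[t_eval > (samples[-1][0] if samples else t0)]:
                times.append(float(te))
                states.append(y_reached.copy())
        y = y_reached.copy()
        if cfg.clamp_extinct:
            Nb = y[M:M + B]
            dying = (Nb < cfg.extinction_threshold) & (active > 0)
            for i in np.flatnonzero(dying):
                events.append({"kind": "extinction", "time": float(t1),
                               "index": int(i),
                               "label": community.species[i].id})
            Nb[dying] = 0.0
            active[dying] = 0.0

    t_arr = np.array(times)
    Y = np.array(states)
    # sub-tolerance negative round-off in sampled states is cleaned up;
    # anything beyond the per-component round-off scale would indicate an
    # integration failure
    # static term covers the fallback ladder's loosest tolerance rung
    floor = -np.maximum(1e7 * cfg.atol, 1e-8 * Y.max(axis=0))
    if (Y < floor).any():
        raise IntegrationError(
            f"state component reached {Y.min():g} (below round-off scale)",
            state=CommunityState.unpack(Y[-1], M, B, t=t_arr[-1]))
    Y[Y < 0.0] = 0.0
    C = Y[:, :M]
    N = Y[:, M:M + B]
    phi_R = Y[:, M + B:M + 2 * B]
    a = Y[:, M + 2 * B:]

    lam = np.empty_like(N)
    sigma = np.empty(len(t_arr))
    for s in range(len(t_arr)):
        rates = community_rates(flat, C[s], phi_R[s], a[s], cell)
        lam[s] = rates.lam
        sigma[s] = thermo.entropy_production_from_rates(
            flat, rates, np.maximum(N[s], 0.0), np.maximum(C[s], 0.0), cell)[0]

    events.extend(_threshold_events(t_arr, C))
    events_df = pd.DataFrame(events,
                             columns=["kind", "time", "index", "label"])
    return Trajectory(t=t_arr, C=C, N=N, phi_R=phi_R, a=a, lam=lam,
                      sigma=sigma, events=events_df,
                      species_ids=[sp.id for sp in community.species],
                      config=cfg)


def _threshold_events(t, C, support=1.0e-4, exhaustion=2.0e-3):
    """Scan sampled metabolite series for threshold crossings.

    Logs the first time each metabolite exceeds the growth-support amount,
    and each time an accumulated metabolite drops below the exhaustion
    amount (granularity = the sampling grid).
    """
    out = []
    M = C.shape[1]
    for b in range(M):
        above = C[:, b] > support
        if above.any():
            out.append({"kind": "support", "time": float(t[np.argmax(above)]),
                        "index": b, "label": f"metabolite {b + 1}"})
        high = C[:, b] > exhaustion
        fell = high[:-1] & ~high[1:]
        for s in np.flatnonzero(fell):
            out.append({"kind": "exhaustion", "time": float(t[s + 1]),
                        "index": b, "label": f"metabolite {b + 1}"})
    return out


def steady_state(trajectory: Trajectory, community: Community,
                 percap_tol: float = 1.0e-7) -> tuple[CommunityState, dict]:
    """Final state plus a convergence report.

    Convergence is judged by the per-capita growth imbalance |lambda - d|
    of the surviving species and the residual metabolite derivatives.
    """
    cfg = trajectory.config or community.config
    state = trajectory.final_state()
    flat = community.flat()
    active = (state.N > 0).astype(float)
    dy = rhs(state.t, state.pack(), flat, community.cell,
             cfg.supply_vector(), cfg.rho, active,
             signed=getattr(cfg, "signed_rates", True))
    M, B = flat.M, flat.B
    thr = cfg.extinction_threshold
    survivors = state.N > thr
    percap = np.zeros(B)
    with np.errstate(divide="ignore", invalid="ignore"):
        percap[survivors] = np.abs(dy[M:M + B][survivors] / state.N[survivors])
    def _blockmax(block):
        return float(np.max(np.abs(block))) if block.size else 0.0

    report = {
        "survivors": int(survivors.sum()),
        "survivor_ids": [community.species[i].id
                         for i in np.flatnonzero(survivors)],
        "max_abs_dC": _blockmax(dy[:M]),
        "max_percap_dN": float(percap.max()) if survivors.any() else 0.0,
        "max_abs_dphi": _blockmax(dy[M + B:M + 2 * B]),
        "max_abs_da": _blockmax(dy[M + 2 * B:]),
        "truncated": bool((trajectory.events["kind"]
                           == "integration_truncated").any()),
        "converged": bool(((not survivors.any())
                           or percap.max() < percap_tol)
                          and not (trajectory.events["kind"]
                                   == "integration_truncated").any()),
    }
    return state, report
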