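"""Contrast-source inversion (CSI) on the finite-element mesh.

The inversion minimizes F_CSI(w, χ) = F_S(w) + F_D(w, χ) where

* F_S is the normalized data mismatch  Σ_t‖u_t − M_S L w_t‖² / Σ_t‖u_t‖²,
* F_D is the normalized state mismatch Σ_t‖χ⊙E_inc,t − w_t + χ⊙M_D L w_t‖²
  / Σ_t‖χ⊙E_inc,t‖²,

with contrast sources w_t on the imaging domain D, contrast
χ = ε/ε_b − 1 relative to the (possibly inhomogeneous) background ε_b,
and L the factorized background Helmholtz operator mapping contrast
sources to scattered fields.  w is updated one Polak–Ribière
conjugate-gradient step per iteration with an exact line search (the
cost is quadratic along any direction, so the step never increases
F_S + F_D); χ is then updated either analytically (the closed-form
minimizer of the F_D numerator) or, with multiplicative regularization
enabled, by a conjugate-gradient step on the product of the domain cost
and a weighted-L2 total-variation factor whose steering parameter
shrinks with F_D.

Initialization is by backpropagation of the measured data; iterations
stop when the relative change of F_CSI drops below the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .forward import FemOperators, ScatterData, assemble_operators
from .meshing import ImagingDomain, TriMesh

__all__ = [
    "InversionConfig",
    "CsiState",
    "Reconstruction",
    "cost_FS",
    "cost_FD",
    "backpropagation_init",
    "update_w_cg",
    "update_chi_analytic",
    "MultiplicativeRegularizer",
    "invert",
    "simulate_contrast_sources",
    "set_inhomogeneous_background",
]


@dataclass(frozen=True)
class InversionConfig:
    """Tunable knobs of the CSI iteration."""

    max_iterations: int = 512
    tolerance: float = 1e-4          # stop when relative ΔF_CSI < tolerance
    mr: bool = True                  # multiplicative regularization on/off
    initialization: str = "backpropagation"
    seed: int = 0
    restart_every: int = 50          # Polak–Ribière restart cadence
    clamp_lossy: bool = False        # force reconstructed ε″ ≥ 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be ≥ 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class CsiState:
    """Evolving unknowns of the inversion.

    ``w`` and the incident fields are stored as (I, T) arrays, one
    column per transmitter; ``chi`` has length I.
    """

    chi: np.ndarray               # (I,)
    w: np.ndarray                 # (I, T)
    E_inc: np.ndarray             # (I, T) incident fields on D
    iteration: int = 0
    cost_history: list = field(default_factory=list)  # (F_CSI, F_S, F_D)
    g_prev: Optional[np.ndarray] = None   # previous w-gradient
    d_prev: Optional[np.ndarray] = None   # previous w-direction
    g_chi_prev: Optional[np.ndarray] = None
    d_chi_prev: Optional[np.ndarray] = None
    chi_flags: Optional[np.ndarray] = None  # nodes where the analytic update was undefined


@dataclass(frozen=True)
class Reconstruction:
    """Recovered complex permittivity on the imaging domain."""

    mesh: TriMesh
    domain: ImagingDomain
    eps: np.ndarray        # (I,) ε_b(1 + χ)
    chi: np.ndarray        # (I,)
    cost_history: np.ndarray  # (n_iter, 3): F_CSI, F_S, F_D
    config: InversionConfig

    @property
    def coords(self) -> np.ndarray:
        return self.mesh.nodes[self.domain.node_indices]

    @property
    def eps_real(self) -> np.ndarray:
        return self.eps.real

    @property
    def eps_imag(self) -> np.ndarray:
        """Loss factor ε″ (positive for lossy media, ε = ε′ − jε″)."""
        return -self.eps.imag


# ---------------------------------------------------------------------------
# cost functionals

def _predicted_data(ops: FemOperators, w: np.ndarray, exclude_diag: bool) -> np.ndarray:
    """M_S L w as a (T, R) matrix, with collocated entries zeroed."""
    p = (ops.M_S @ ops.L_apply(w)).T.copy()
    if exclude_diag:
        np.fill_diagonal(p, 0.0)
    return p


def cost_FS(w: np.ndarray, data: ScatterData, ops: FemOperators) -> float:
    """Normalized data mismatch Σ‖u_t − M_S L w_t‖² / Σ‖u_t‖²."""
    den = float(np.sum(np.abs(data.u) ** 2))
    if den == 0.0:
        raise ZeroDivisionError("all-zero measurement data: F_S undefined")
    p = _predicted_data(ops, w, data.collocated_excluded)
    return float(np.sum(np.abs(data.u - p) ** 2) / den)


def cost_FD(
    w: np.ndarray,
    chi: np.ndarray,
    E_inc: np.ndarray,
    ops: FemOperators,
) -> float:
    """Normalized state mismatch of the domain equation on D."""
    den = float(np.sum(np.abs(chi[:, None] * E_inc) ** 2))
    if den == 0.0:
        raise ZeroDivisionError("chi ≡ 0: F_D normalization undefined")
    mdlw = ops.M_D @ ops.L_apply(w)
    r = chi[:, None] * E_inc - w + chi[:, None] * mdlw
    return float(np.sum(np.abs(r) ** 2) / den)


# ---------------------------------------------------------------------------
# updates

def backpropagation_init(data: ScatterData, ops: FemOperators) -> np.ndarray:
    """Backpropagation starting guess for the contrast sources.

    w_t⁰ = (‖G^H u_t‖² / ‖G G^H u_t‖²) · G^H u_t with G = M_S L;
    transmitters with u_t = 0 start at w_t⁰ = 0.
    """
    U = data.u  # (T, R)
    V = ops.M_S.conj().T @ U.T  # M_S^H u_t stacked: (N, T)
    back = ops.L_adjoint(V)  # (I, T) = G^H u_t per column
    fwd = _predicted_data(ops, back, data.collocated_excluded)  # (T, R) = G G^H u
    w0 = np.zeros_like(back)
    for t in range(U.shape[0]):
        nb = float(np.sum(np.abs(back[:, t]) ** 2))
        nf = float(np.sum(np.abs(fwd[t]) ** 2))
        if nb > 0 and nf > 0:
            w0[:, t] = (nb / nf) * back[:, t]
    return w0


def _residuals(ops, data, w, chi, E_inc):
    """Data and domain residuals plus normalizations (shared by updates)."""
    lw = ops.L_apply(w)                      # (N, T)
    p = (ops.M_S @ lw).T.copy()
    if data.collocated_excluded:
        np.fill_diagonal(p, 0.0)
    rho = data.u - p                         # (T, R)
    mdlw = ops.M_D @ lw                      # (I, T)
    r = chi[:, None] * (E_inc + mdlw) - w    # (I, T)
    eta_s = 1.0 / float(np.sum(np.abs(data.u) ** 2))
    eta_d = 1.0 / float(np.sum(np.abs(chi[:, None] * E_inc) ** 2))
    return rho, r, eta_s, eta_d


def update_w_cg(state: CsiState, data: ScatterData, ops: FemOperators) -> CsiState:
    """One Polak–Ribière CG step on F_S + F_D with χ held fixed.

    The cost is quadratic along the search direction, so the exact line
    minimizer is closed-form and the step can never increase the cost.
    """
    chi, w, E_inc = state.chi, state.w, state.E_inc
    rho, r, eta_s, eta_d = _residuals(ops, data, w, chi, E_inc)

    # gradient wrt conj(w):  −η_S G^H ρ + η_D[(M_D L)^H (χ*⊙r) − r]
    adj_in = np.asarray(-eta_s * (ops.M_S.conj().T @ rho.T), dtype=complex)
    adj_in += eta_d * (ops.M_D.conj().T @ (np.conj(chi)[:, None] * r))
    g = ops.L_adjoint(adj_in) - eta_d * r

    gnorm2 = np.sum(np.abs(g) ** 2, axis=0)
    if np.all(gnorm2 == 0.0):
        return state  # already at a stationary point

    restart = (
        state.g_prev is None
        or state.d_prev is None
        or (state.iteration % 50 == 0 and state.iteration > 0)
    )
    if restart:
        d = -g
    else:
        gp = state.g_prev
        gpn = np.sum(np.abs(gp) ** 2, axis=0)
        beta = np.real(np.sum(np.conj(g) * (g - gp), axis=0)) / np.where(gpn > 0, gpn, 1.0)
        beta = np.where(gpn > 0, np.maximum(beta, 0.0), 0.0)
        d = -g + beta[None, :] * state.d_prev
        # enforce descent per transmitter; restart where violated
        desc = np.real(np.sum(np.conj(g) * d, axis=0))
        bad = desc >= 0
        if np.any(bad):
            d[:, bad] = -g[:, bad]

    # exact line search, per transmitter
    ld = ops.L_apply(d)
    gd = (ops.M_S @ ld).T.copy()
    if data.collocated_excluded:
        np.fill_diagonal(gd, 0.0)
    bd = chi[:, None] * (ops.M_D @ ld) - d
    num = eta_s * np.sum(np.conj(gd) * rho, axis=1) - eta_d * np.sum(np.conj(bd) * r, axis=0)
    den = eta_s * np.sum(np.abs(gd) ** 2, axis=1) + eta_d * np.sum(np.abs(bd) ** 2, axis=0)
    alpha = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    new = CsiState(
        chi=chi, w=w + alpha[None, :] * d, E_inc=E_inc,
        iteration=state.iteration, cost_history=state.cost_history,
        g_prev=g, d_prev=d,
        g_chi_prev=state.g_chi_prev, d_chi_prev=state.d_chi_prev,
        chi_flags=state.chi_flags)
    return new


def update_chi_analytic(state: CsiState, ops: FemOperators) -> CsiState:
    """Closed-form contrast update: the minimizer of the F_D numerator.

    χ_i = Σ_t w_t,i conj(E_t,i) / Σ_t |E_t,i|² with total fields
    E_t = E_inc,t + M_D L w_t.  Nodes where the denominator vanishes
    keep their previous value (flagged).
    """
    E_tot = state.E_inc + ops.M_D @ ops.L_apply(state.w)
    den = np.sum(np.abs(E_tot) ** 2, axis=1)
    num = np.sum(state.w * np.conj(E_tot), axis=1)
    chi = state.chi.copy()
    ok = den > 0
    chi[ok] = num[ok] / den[ok]
    state.chi = chi
    state.chi_flags = ~ok
    return state


class MultiplicativeRegularizer:
    """Weighted-L2 total-variation factor multiplying the CSI cost.

    F_MR(χ) = Σ_tri A b²(|∇χ|² + δ²_prev) with per-triangle weights
    b² = 1 / (A_D (|∇χ_prev|² + δ²_prev)), so F_MR(χ_prev) = 1 and a
    uniform contrast is not penalized.  The steering parameter
    δ² = F_D / h̄² (mean-edge-length scaling) decreases as the domain
    cost decreases, tightening the edge-preserving behavior.
    """

    def __init__(self, mesh: TriMesh, domain: ImagingDomain):
        idx = domain.node_indices
        in_d = np.zeros(mesh.num_nodes, dtype=bool)
        in_d[idx] = True
        keep = in_d[mesh.triangles].all(axis=1)
        tris = mesh.triangles[keep]
        remap = -np.ones(mesh.num_nodes, dtype=int)
        remap[idx] = np.arange(len(idx))
        tris_d = remap[tris]
        xy = mesh.nodes[tris]
        x, y = xy[..., 0], xy[..., 1]
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        area = 0.5 * ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
                      - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
        nt = len(tris_d)
        rows = np.repeat(np.arange(nt), 3)
        cols = tris_d.ravel()
        I = domain.size
        self.Dx = sp.csr_matrix(((b / (2 * area[:, None])).ravel(), (rows, cols)),
                                shape=(nt, I))
        self.Dy = sp.csr_matrix(((c / (2 * area[:, None])).ravel(), (rows, cols)),
                                shape=(nt, I))
        self.area = area
        self.total_area = float(area.sum())
        e = mesh.edge_lengths()
        self.mean_edge = float(e.mean())
        self.delta2_prev: float | None = None

    def grad_mag2(self, chi: np.ndarray) -> np.ndarray:
        gx = self.Dx @ chi
        gy = self.Dy @ chi
        return np.abs(gx) ** 2 + np.abs(gy) ** 2

    def weights(self, chi_prev: np.ndarray, f_d: float) -> np.ndarray:
        """Per-triangle b² from the previous iterate; updates δ²."""
        delta2 = f_d / self.mean_edge ** 2
        d2p = self.delta2_prev if self.delta2_prev is not None else delta2
        b2 = 1.0 / (self.total_area * (self.grad_mag2(chi_prev) + d2p))
        self.delta2_prev = delta2
        return b2

    def factor(self, chi: np.ndarray, b2: np.ndarray) -> float:
        d2p = self.delta2_prev
        return float(np.sum(self.area * b2 * (self.grad_mag2(chi) + d2p)))

    def total_variation(self, chi: np.ndarray) -> float:
        """Unweighted TV ∫|∇χ| dA (diagnostic used to compare runs)."""
        return float(np.sum(self.area * np.sqrt(self.grad_mag2(chi))))


def _update_chi_mr(
    state: CsiState,
    ops: FemOperators,
    reg: MultiplicativeRegularizer,
    f_d: float,
) -> CsiState:
    """One CG step on η_D‖χ⊙E − w‖² · F_MR(χ); falls back to the
    analytic update if the step fails to decrease the regularized cost."""
    E_tot = state.E_inc + ops.M_D @ ops.L_apply(state.w)
    eta_d = 1.0 / float(np.sum(np.abs(state.chi[:, None] * state.E_inc) ** 2))
    chi0 = state.chi
    b2 = reg.weights(chi0, f_d)
    W = sp.diags(reg.area * b2)
    lap = (reg.Dx.conj().T @ W @ reg.Dx + reg.Dy.conj().T @ W @ reg.Dy).tocsr()

    r_chi = chi0[:, None] * E_tot - state.w
    num0 = float(np.sum(np.abs(r_chi) ** 2))
    fmr0 = reg.factor(chi0, b2)
    f0 = eta_d * num0 * fmr0

    g = fmr0 * eta_d * np.sum(np.conj(E_tot) * r_chi, axis=1) \
        + eta_d * num0 * (lap @ chi0)

    if state.g_chi_prev is not None and state.d_chi_prev is not None:
        gp = state.g_chi_prev
        gpn = float(np.sum(np.abs(gp) ** 2))
        beta = max(0.0, float(np.real(np.sum(np.conj(g) * (g - gp)))) / gpn) if gpn > 0 else 0.0
        d = -g + beta * state.d_chi_prev
        if float(np.real(np.sum(np.conj(g) * d))) >= 0:
            d = -g
    else:
        d = -g

    # quartic line search along d (real step)
    de = d[:, None] * E_tot
    a2 = float(np.sum(np.abs(de) ** 2))
    a1 = 2.0 * float(np.real(np.sum(np.conj(de) * r_chi)))
    a0 = num0
    gx, gy = reg.Dx @ d, reg.Dy @ d
    gx0, gy0 = reg.Dx @ chi0, reg.Dy @ chi0
    p2 = float(np.sum(reg.area * b2 * (np.abs(gx) ** 2 + np.abs(gy) ** 2)))
    p1 = 2.0 * float(np.real(np.sum(reg.area * b2 * (np.conj(gx) * gx0 + np.conj(gy) * gy0))))
    p0 = fmr0
    # f(α) = η_D (a2α² + a1α + a0)(p2α² + p1α + p0)
    c4, c3 = a2 * p2, a2 * p1 + a1 * p2
    c2 = a2 * p0 + a1 * p1 + a0 * p2
    c1 = a1 * p0 + a0 * p1
    dcoef = [4 * c4, 3 * c3, 2 * c2, c1]
    roots = np.roots(dcoef) if any(abs(c) > 0 for c in dcoef[:-1]) else np.array([])
    alphas = [float(r.real) for r in roots if abs(r.imag) < 1e-10 * (1 + abs(r.real))]
    best_a, best_f = 0.0, f0
    for a in alphas:
        fa = eta_d * (a2 * a * a + a1 * a + a0) * (p2 * a * a + p1 * a + p0)
        if fa < best_f:
            best_a, best_f = a, fa

    if best_a == 0.0:
        state = update_chi_analytic(state, ops)
    else:
        state.chi = chi0 + best_a * d
        state.chi_flags = np.zeros(len(chi0), dtype=bool)
    state.g_chi_prev = g
    state.d_chi_prev = d
    return state


def invert(
    data: ScatterData,
    ops: FemOperators,
    E_inc: np.ndarray | None = None,
    config: InversionConfig | None = None,
) -> Reconstruction:
    """Run the CSI iteration and return the recovered permittivity map.

    Parameters
    ----------
    data : ScatterData
        Measured (synthetic) scattered fields, one row per transmitter.
    ops : FemOperators
        Background operators assembled on the *inversion* mesh with an
        imaging domain attached.
    E_inc : array, optional
        (I, T) incident fields on D; defaults to the fields stored in
        ``ops``.
    config : InversionConfig

    Returns
    -------
    Reconstruction
        ε_r = ε_b(1 + χ) on the imaging domain, plus the cost history.
    """
    if ops.domain is None or ops.M_D is None:
        raise ValueError("operators need an imaging domain for inversion")
    config = config or InversionConfig()
    idx = ops.domain.node_indices
    if E_inc is None:
        E_inc = ops.E_inc[idx, :]

    w0 = backpropagation_init(data, ops)
    state = CsiState(chi=np.zeros(ops.domain.size, dtype=complex), w=w0, E_inc=E_inc)
    state = update_chi_analytic(state, ops)
    if not np.any(np.abs(state.chi) > 0):
        # degenerate start (e.g. zero data): tiny uniform contrast keeps F_D defined
        state.chi = np.full(ops.domain.size, 1e-8, dtype=complex)

    reg = MultiplicativeRegularizer(ops.mesh, ops.domain) if config.mr else None
    f_prev = None
    for it in range(config.max_iterations):
        state.iteration = it
        state = update_w_cg(state, data, ops)
        f_d_pre = cost_FD(state.w, state.chi, E_inc, ops)
        if config.mr:
            state = _update_chi_mr(state, ops, reg, f_d_pre)
        else:
            state = update_chi_analytic(state, ops)
        if config.clamp_lossy:
            eps = ops.eps_b_nodes[idx] * (1.0 + state.chi)
            eps = eps.real + 1j * np.minimum(eps.imag, 0.0)
            state.chi = eps / ops.eps_b_nodes[idx] - 1.0

        f_s = cost_FS(state.w, data, ops)
        f_d = cost_FD(state.w, state.chi, E_inc, ops)
        f_csi = f_s + f_d
        state.cost_history.append((f_csi, f_s, f_d))
        if not np.isfinite(f_csi):
            raise ArithmeticError(
                f"CSI diverged at iteration {it}: F_CSI = {f_csi}")
        if f_prev is not None and abs(f_prev - f_csi) < config.tolerance * f_prev:
            break
        f_prev = f_csi

    eps = ops.eps_b_nodes[idx] * (1.0 + state.chi)
    return Reconstruction(
        mesh=ops.mesh, domain=ops.domain, eps=eps, chi=state.chi,
        cost_history=np.array(state.cost_history), config=config)


def simulate_contrast_sources(
    ops: FemOperators,
    chi: np.ndarray,
    exclude_collocated: bool = True,
) -> tuple[np.ndarray, ScatterData]:
    """Same-mesh forward model in contrast-source form.

    Solves the state equation (I − M_D L diag(χ)) E_D = E_inc,D for the
    self-consistent total field on the imaging domain, then returns
    w = χ⊙E_D and the data u = M_S L w those sources radiate.  By
    construction the pair (w, χ) satisfies both CSI equations exactly,
    which makes it the fixed-point oracle for the cost functionals; it
    is also a fast forward model for scenes defined by a contrast on D.
    """
    if ops.domain is None:
        raise ValueError("operators need an imaging domain")
    I = ops.domain.size
    E_inc_D = ops.E_inc[ops.domain.node_indices, :]
    # columns of M_D L diag(χ): one batched background solve
    G = ops.M_D @ ops.lu.solve(np.asarray((ops.S_D @ sp.diags(chi)).todense(),
                                          dtype=complex))
    E_D = np.linalg.solve(np.eye(I) - G, E_inc_D)
    w = chi[:, None] * E_D
    u = (ops.M_S @ ops.L_apply(w)).T.copy()
    if exclude_collocated:
        np.fill_diagonal(u, 0.0)
    data = ScatterData(u=u, frequency=ops.frequency,
                       background_id="contrast-source forward",
                       collocated_excluded=exclude_collocated)
    return w, data


def save_reconstruction(recon: Reconstruction, directory) -> None:
    """Persist a reconstruction as text: mesh (MSH 2.2), imaging-domain
    node indices, (x, y, Re ε, Im ε) table, and cost history CSV."""
    from pathlib import Path

    from .meshing import write_msh

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_msh(recon.mesh, d / "inversion_mesh.msh")
    np.savetxt(d / "domain_nodes.txt", recon.domain.node_indices, fmt="%d",
               header=f"total_nodes {recon.domain.total_nodes}")
    table = np.column_stack([recon.coords, recon.eps.real, recon.eps.imag])
    np.savetxt(d / "reconstruction.csv", table, delimiter=",",
               header="x_m,y_m,eps_real,eps_imag", comments="")
    np.savetxt(d / "cost_history.csv", recon.cost_history, delimiter=",",
               header="F_CSI,F_S,F_D", comments="")


def load_reconstruction(directory) -> Reconstruction:
    """Rebuild a :class:`Reconstruction` persisted by :func:`save_reconstruction`."""
    from pathlib import Path

    from .meshing import read_msh

    d = Path(directory)
    mesh = read_msh(d / "inversion_mesh.msh")
    header = (d / "domain_nodes.txt").read_text().splitlines()[0]
    total = int(header.split()[-1])
    idx = np.loadtxt(d / "domain_nodes.txt", dtype=int, ndmin=1)
    domain = ImagingDomain(node_indices=idx, total_nodes=total)
    table = np.loadtxt(d / "reconstruction.csv", delimiter=",", skiprows=1, ndmin=2)
    eps = table[:, 2] + 1j * table[:, 3]
    hist = np.loadtxt(d / "cost_history.csv", delimiter=",", skiprows=1, ndmin=2)
    if hist.size == 0:
        hist = np.zeros((0, 3))
    return Reconstruction(mesh=mesh, domain=domain, eps=eps, chi=np.zeros_like(eps),
                          cost_history=hist, config=InversionConfig())


def render_maps(recon: Reconstruction, path_prefix) -> list:
    """Rasterize real/imaginary permittivity maps to PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    paths = []
    x, y = recon.coords[:, 0], recon.coords[:, 1]
    for part, vals in (("real", recon.eps_real), ("imag", recon.eps_imag)):
        fig, ax = plt.subplots(figsize=(4, 3.5))
        sc = ax.tricontourf(x, y, vals, levels=32)
        fig.colorbar(sc, ax=ax, label=f"{part} relative permittivity")
        ax.set_aspect("equal")
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        p = Path(f"{path_prefix}_{part}.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def set_inhomogeneous_background(ops: FemOperators, prior_map) -> FemOperators:
    """Rebuild the background operators for an inhomogeneous prior.

    ``prior_map`` is anything :func:`legtomo.forward.assemble_operators`
    accepts as a background (a PhantomModel carrying e.g. matching
    medium + skin + fat shells with muscle elsewhere, a per-triangle
    array, or a callable).  The contrast is then defined relative to the
    new ε_b(r) and the incident fields are recomputed.
    """
    return assemble_operators(
        ops.mesh, prior_map, ops.frequency, ops.antennas, domain=ops.domain)
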