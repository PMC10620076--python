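"""Ohmic quasistatic potential solver on the voxel phantom.

Discretizes the electro-quasistatic equation div(sigma grad phi) = 0
with a 7-point finite-volume stencil.  Face conductances use the
harmonic mean of the two adjacent voxel conductivities, which keeps the
scheme robust across the large scalp/skull/CSF contrast and makes the
insulating outer boundary automatic (air has sigma = 0, so no current
crosses a tissue/air face).

Electrodes enter as Dirichlet patches on the scalp surface (+0.5 V on
the anode, -0.5 V on the cathode; contact treated as ideal).  The
resulting symmetric positive-definite system is solved by conjugate
gradients with diagonal (Jacobi) preconditioning.  Fields are rescaled
afterwards to the requested injected current (current normalization),
which is exact by linearity.

Tissue properties are treated as frequency-independent in the low kHz
range, so a single solve per electrode pair serves both carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, SolverError
from .phantom import AIR, ElectrodeSpec, HeadPhantom, electrode_patch


@dataclass(frozen=True)
class ChannelPair:
    """One stimulation channel: an electrode pair, carrier and current."""

    anode: ElectrodeSpec
    cathode: ElectrodeSpec
    carrier_frequency_Hz: float = 2000.0
    current_mA: float = 1.0

    def __post_init__(self):
        if self.anode.label == self.cathode.label and \
                self.anode.direction == self.cathode.direction:
            raise SolverError("anode and cathode must differ")
        if self.current_mA <= 0:
            raise SolverError("current_mA must be positive")
        if self.carrier_frequency_Hz <= 0:
            raise SolverError("carrier frequency must be positive")

    @property
    def label(self) -> str:
        return f"{self.anode.label}-{self.cathode.label}"


@dataclass
class PotentialVolume:
    """Scalar potential (V) on the phantom grid plus boundary metadata."""

    phi: np.ndarray
    anode_patch: np.ndarray
    cathode_patch: np.ndarray
    anode_voltage_V: float
    cathode_voltage_V: float
    spacing_mm: float
    iterations: int = 0
    residual: float = 0.0


@dataclass
class VectorFieldVolume:
    """Per-voxel 3-vector E-field (V/m), expressed at ``normalization_mA``."""

    E: np.ndarray                     # shape (nx, ny, nz, 3)
    normalization_mA: float
    channel: str
    spacing_mm: float

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.E, axis=-1)

    def same_grid(self, other: "VectorFieldVolume") -> bool:
        return (self.E.shape == other.E.shape
                and self.spacing_mm == other.spacing_mm)


def _face_conductance(sigma: np.ndarray, axis: int, h_m: float) -> np.ndarray:
    """Harmonic-mean conductance (S) of faces between voxel pairs along axis."""
    a = np.take(sigma, np.arange(sigma.shape[axis] - 1), axis=axis)
    b = np.take(sigma, np.arange(1, sigma.shape[axis]), axis=axis)
    s = a + b
    hm = np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)
    return hm * h_m  # face area h^2 / center distance h = h


def solve_dirichlet(sigma: np.ndarray, spacing_mm: float,
                    anode_mask: np.ndarray, cathode_mask: np.ndarray,
                    tol: float = 1e-8,
                    anode_V: float = 0.5, cathode_V: float = -0.5
                    ) -> tuple[PotentialVolume, VectorFieldVolume, float]:
    """Solve div(sigma grad phi) = 0 with two Dirichlet patches.

    ``sigma`` is the per-voxel conductivity in S/m (0 marks air); the
    two masks select the electrode-contact voxels.  Returns the
    potential, the E-field (V/m) and the injected current in mA.
    """
    if not (0 < tol <= 1e-3):
        raise SolverError(f"tol must lie in (0, 1e-3], got {tol}")
    anode = np.asarray(anode_mask, dtype=bool)
    cathode = np.asarray(cathode_mask, dtype=bool)
    if not anode.any() or not cathode.any():
        raise SolverError("electrode patches must be nonempty")
    if (anode & cathode).any():
        raise SolverError("electrode patches overlap")
    tissue = sigma > 0
    if (anode & ~tissue).any() or (cathode & ~tissue).any():
        raise SolverError("electrode patches must lie on conducting voxels")

    # a zero-conductivity shell separating the patches makes the
    # Dirichlet problem degenerate (no current path): reject up front
    from scipy.ndimage import label as cc_label

    comp, _ = cc_label(tissue)
    if not set(np.unique(comp[anode])) & set(np.unique(comp[cathode])):
        raise SolverError(
            "singular system: electrode patches lie in disconnected "
            "conducting regions")

    h_m = spacing_mm / 1000.0
    fixed = anode | cathode
    unknown = tissue & ~fixed
    n_unknown = int(unknown.sum())
    if n_unknown == 0:
        raise SolverError("no interior unknowns between the electrode patches")
    idx = -np.ones(sigma.shape, dtype=np.int64)
    idx[unknown] = np.arange(n_unknown)

    phi_fixed = np.zeros(sigma.shape)
    phi_fixed[anode] = anode_V
    phi_fixed[cathode] = cathode_V

    diag = np.zeros(n_unknown)
    rows, cols, vals = [], [], []
    b = np.zeros(n_unknown)
    for axis in range(3):
        g = _face_conductance(sigma, axis, h_m)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        iu_lo, iu_hi = idx[lo], idx[hi]
        active = g > 0  # conducting face (both sides tissue by construction)

        both = active & (iu_lo >= 0) & (iu_hi >= 0)
        rows.append(iu_lo[both]); cols.append(iu_hi[both]); vals.append(-g[both])
        rows.append(iu_hi[both]); cols.append(iu_lo[both]); vals.append(-g[both])

        lo_unk = active & (iu_lo >= 0)
        hi_unk = active & (iu_hi >= 0)
        np.add.at(diag, iu_lo[lo_unk], g[lo_unk])
        np.add.at(diag, iu_hi[hi_unk], g[hi_unk])
        lo_unk_hi_fix = lo_unk & (iu_hi < 0)
        hi_unk_lo_fix = hi_unk & (iu_lo < 0)
        np.add.at(b, iu_lo[lo_unk_hi_fix],
                  g[lo_unk_hi_fix] * phi_fixed[hi][lo_unk_hi_fix])
        np.add.at(b, iu_hi[hi_unk_lo_fix],
                  g[hi_unk_lo_fix] * phi_fixed[lo][hi_unk_lo_fix])

    if not np.all(diag > 0):
        raise SolverError(
            "singular system: some tissue voxel has no conducting face "
            "(a zero-conductivity shell separates the domain)")

    A = sp.csr_matrix(
        (np.concatenate(vals + [diag]),
         (np.concatenate(rows + [np.arange(n_unknown)]),
          np.concatenate(cols + [np.arange(n_unknown)]))),
        shape=(n_unknown, n_unknown))

    M = sp.diags(1.0 / diag)
    cap = int(20 * n_unknown ** (1.0 / 3.0) * 100)
    n_iter = 0

    def _count(_):
        nonlocal n_iter
        n_iter += 1

    x, info = spla.cg(A, b, rtol=tol, atol=0.0, maxiter=cap, M=M,
                      callback=_count)
    resid = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300))
    if info > 0:
        raise ConvergenceError(
            f"CG did not converge within {cap} iterations "
            f"(relative residual {resid:.3e})", residual=resid)
    if info < 0:
        raise SolverError(f"CG reported illegal input (info={info})")

    phi = np.zeros(sigma.shape)
    phi[unknown] = x
    phi[anode] = anode_V
    phi[cathode] = cathode_V

    potential = PotentialVolume(
        phi=phi, anode_patch=anode.astype(np.uint8),
        cathode_patch=cathode.astype(np.uint8),
        anode_voltage_V=anode_V, cathode_voltage_V=cathode_V,
        spacing_mm=spacing_mm, iterations=n_iter, residual=resid)

    E = electric_field(phi, tissue, spacing_mm)
    field = VectorFieldVolume(E=E, normalization_mA=float("nan"),
                              channel="", spacing_mm=spacing_mm)
    injected = patch_current_mA(sigma, spacing_mm, potential, which="anode")
    if injected <= 0:
        raise SolverError(
            f"nonpositive injected current ({injected:.3e} mA): solver failure")
    return potential, field, injected


def solve_channel(phantom: HeadPhantom, pair: ChannelPair,
                  tol: float = 1e-8) -> tuple[PotentialVolume, VectorFieldVolume, float]:
    """Solve one channel's electrode pair on the head phantom.

    Returns the raw Dirichlet solution (anode +0.5 V, cathode -0.5 V)
    and the injected current in mA; use :func:`normalize_current` to
    express the field at a target current.
    """
    anode = electrode_patch(phantom, pair.anode).astype(bool)
    cathode = electrode_patch(phantom, pair.cathode).astype(bool)
    if (anode & cathode).any():
        raise SolverError(
            f"electrode patches of {pair.label} overlap at this resolution")
    sigma = phantom.conductivity_volume()
    potential, field, injected = solve_dirichlet(
        sigma, phantom.spacing_mm, anode, cathode, tol=tol)
    field.channel = pair.label
    return potential, field, injected


def electric_field(phi: np.ndarray, tissue: np.ndarray,
                   spacing_mm: float) -> np.ndarray:
    """E = -grad(phi) in V/m: central differences in the tissue interior,
    one-sided differences at tissue/air faces, zero on air voxels."""
    h_m = spacing_mm / 1000.0
    E = np.zeros(phi.shape + (3,))
    for axis in range(3):
        fwd_t = np.zeros_like(tissue, dtype=bool)
        bwd_t = np.zeros_like(tissue, dtype=bool)
        fwd = np.zeros_like(phi)
        bwd = np.zeros_like(phi)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        src[axis] = slice(1, None)
        dst[axis] = slice(0, -1)
        fwd[tuple(dst)] = phi[tuple(src)]
        fwd_t[tuple(dst)] = tissue[tuple(src)]
        bwd[tuple(src)] = phi[tuple(dst)]
        bwd_t[tuple(src)] = tissue[tuple(dst)]

        both = tissue & fwd_t & bwd_t
        only_fwd = tissue & fwd_t & ~bwd_t
        only_bwd = tissue & bwd_t & ~fwd_t
        comp = np.zeros_like(phi)
        comp[both] = -(fwd[both] - bwd[both]) / (2 * h_m)
        comp[only_fwd] = -(fwd[only_fwd] - phi[only_fwd]) / h_m
        comp[only_bwd] = -(phi[only_bwd] - bwd[only_bwd]) / h_m
        E[..., axis] = comp
    return E


def patch_current_mA(sigma: np.ndarray, spacing_mm: float,
                     potential: PotentialVolume, which: str = "anode") -> float:
    """Net ohmic current (mA) through the faces of an electrode patch.

    For the anode this is the current leaving the patch into the rest of
    the tissue; for the cathode, the current arriving at it.  Computed
    by independent summation of face currents, so it doubles as a
    conservation check on the solve.
    """
    patch = (potential.anode_patch if which == "anode"
             else potential.cathode_patch).astype(bool)
    tissue = sigma > 0
    h_m = spacing_mm / 1000.0
    phi = potential.phi
    total = 0.0
    for axis in range(3):
        g = _face_conductance(sigma, axis, h_m)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        p_lo, p_hi = patch[lo], patch[hi]
        out_lo = p_lo & ~p_hi & tissue[hi] & (g > 0)
        out_hi = p_hi & ~p_lo & tissue[lo] & (g > 0)
        total += float(np.sum(g[out_lo] * (phi[lo][out_lo] - phi[hi][out_lo])))
        total += float(np.sum(g[out_hi] * (phi[hi][out_hi] - phi[lo][out_hi])))
    if which == "cathode":
        total = -total
    return total * 1000.0


def normalize_current(potential: PotentialVolume, field: VectorFieldVolume,
                      injected_current_mA: float, target_current_mA: float = 1.0
                      ) -> tuple[PotentialVolume, VectorFieldVolume]:
    """Rescale a Dirichlet solution to the requested injected current.

    Exact by linearity: multiplies phi and E by
    ``target_current_mA / injected_current_mA``.
    """
    if injected_current_mA <= 0:
        raise SolverError("injected current must be positive; solver failed")
    scale = target_current_mA / injected_current_mA
    pot = replace(potential,
                  phi=potential.phi * scale,
                  anode_voltage_V=potential.anode_voltage_V * scale,
                  cathode_voltage_V=potential.cathode_voltage_V * scale)
    fld = replace(field, E=field.E * scale,
                  normalization_mA=float(target_current_mA))
    return pot, fld


def solve_channel_normalized(phantom: HeadPhantom, pair: ChannelPair,
                             tol: float = 1e-8, target_current_mA: float = 1.0
                             ) -> tuple[PotentialVolume, VectorFieldVolume]:
    """Convenience: solve one channel and normalize to ``target_current_mA``."""
    pot, field, injected = solve_channel(phantom, pair, tol=tol)
    return normalize_current(pot, field, injected, target_current_mA)


def slab_oracle(voltage_V: float, thickness_m: float) -> float:
    """Uniform-field closed form for a parallel-plate slab: |E| = V / d."""
    if thickness_m <= 0:
        raise SolverError("slab thickness must be positive")
    return voltage_V / thickness_m


def sphere_axis_potential_oracle(z_mm: np.ndarray, current_mA: float,
                                 sigma_S_per_m: float, radius_mm: float,
                                 n_terms: int = 400) -> np.ndarray:
    """Legendre-series axis potential of a homogeneous conducting sphere.

    Point current +I injected at the +z pole and -I withdrawn at the -z
    pole of a sphere of radius R gives, on the polar axis (|z| < R),

        phi(z) = I / (2 pi sigma R) * sum_{n odd} (2n+1)/n * (z/R)^n .

    Derived by expanding the surface current density in Legendre
    polynomials and matching the Neumann boundary condition term by
    term.  Used only as an independent oracle in tests and the
    acceptance script; truncated after ``n_terms`` odd terms.
    """
    z = np.asarray(z_mm, dtype=float) / radius_mm
    if np.any(np.abs(z) >= 1.0):
        raise SolverError("axis points must lie strictly inside the sphere")
    I = current_mA / 1000.0
    R = radius_mm / 1000.0
    pref = I / (2.0 * np.pi * sigma_S_per_m * R)
    out = np.zeros_like(z)
    for n in range(1, 2 * n_terms, 2):
        out += (2 * n + 1) / n * z ** n
    return pref * out
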