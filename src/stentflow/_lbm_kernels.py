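"""Numba kernels for the D3Q19 BGK lattice-Boltzmann solver.

Pull-scheme fused stream/collide with halfway bounce-back at solid links,
Guo forcing for the Darcy-Forchheimer porous drag (velocity solved
implicitly, which keeps the drag unconditionally stable), and simple
equilibrium velocity/pressure boundary cells. Everything is in lattice
units; conversion lives in :mod:`stentflow.lbm`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# D3Q19 velocity set; opposite pairs are adjacent (q, q+1) for q = 1,3,...
C = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0],
        [0, 1, 0], [0, -1, 0],
        [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0],
        [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1],
        [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1],
        [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)
W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)
OPP = np.array([0, 2, 1, 4, 3, 6, 5, 8, 7, 10, 9, 12, 11, 14, 13, 16, 15, 18, 17],
               dtype=np.int64)

KIND_FLUID = 0
KIND_VELOCITY = 1
KIND_PRESSURE = 2


@njit(cache=True, fastmath=True)
def step(f_src, f_dst, nbr, kind, bc_u, bc_nbr, pa, pb, body, omega, sfac):
    """One fused stream(pull)/collide update. f arrays are (19, n)."""
    n = f_src.shape[1]
    fi = np.empty(19)
    for i in range(n):
        k = kind[i]
        if k == KIND_FLUID:
            for q in range(19):
                j = nbr[i, OPP[q]]
                if j >= 0:
                    fi[q] = f_src[q, j]
                else:
                    fi[q] = f_src[OPP[q], i]  # halfway bounce-back
            rho = 0.0
            mx = 0.0
            my = 0.0
            mz = 0.0
            for q in range(19):
                fq = fi[q]
                rho += fq
                mx += fq * C[q, 0]
                my += fq * C[q, 1]
                mz += fq * C[q, 2]
            mx += 0.5 * body[0]
            my += 0.5 * body[1]
            mz += 0.5 * body[2]
            a = pa[i]
            b = pb[i]
            denom = rho + 0.5 * a
            M = np.sqrt(mx * mx + my * my + mz * mz)
            if M > 0.0:
                if b > 0.0:
                    s = (-denom + np.sqrt(denom * denom + 2.0 * b * M)) / b
                else:
                    s = M / denom
                ux = mx / M * s
                uy = my / M * s
                uz = mz / M * s
            else:
                s = 0.0
                ux = 0.0
                uy = 0.0
                uz = 0.0
            Fx = body[0] - a * ux - b * s * ux
            Fy = body[1] - a * uy - b * s * uy
            Fz = body[2] - a * uz - b * s * uz
            usq = ux * ux + uy * uy + uz * uz
            uF = ux * Fx + uy * Fy + uz * Fz
            for q in range(19):
                cu = C[q, 0] * ux + C[q, 1] * uy + C[q, 2] * uz
                cF = C[q, 0] * Fx + C[q, 1] * Fy + C[q, 2] * Fz
                feq = W[q] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
                src = W[q] * (3.0 * (cF - uF) + 9.0 * cu * cF)
                f_dst[q, i] = fi[q] + omega * (feq - fi[q]) + (1.0 - 0.5 * omega) * src
        elif k == KIND_VELOCITY:
            j = bc_nbr[i]
            rho = 0.0
            for q in range(19):
                rho += f_src[q, j]
            ux = bc_u[0, i] * sfac
            uy = bc_u[1, i] * sfac
            uz = bc_u[2, i] * sfac
            usq = ux * ux + uy * uy + uz * uz
            for q in range(19):
                cu = C[q, 0] * ux + C[q, 1] * uy + C[q, 2] * uz
                f_dst[q, i] = W[q] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
        else:  # KIND_PRESSURE: rho = 1, velocity copied from the interior
            j = bc_nbr[i]
            rho = 0.0
            mx = 0.0
            my = 0.0
            mz = 0.0
            for q in range(19):
                fq = f_src[q, j]
                rho += fq
                mx += fq * C[q, 0]
                my += fq * C[q, 1]
                mz += fq * C[q, 2]
            ux = mx / rho
            uy = my / rho
            uz = mz / rho
            usq = ux * ux + uy * uy + uz * uz
            for q in range(19):
                cu = C[q, 0] * ux + C[q, 1] * uy + C[q, 2] * uz
                f_dst[q, i] = W[q] * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)


@njit(cache=True, fastmath=True)
def macro(f, pa, pb, body, rho_out, u_out):
    """Density and (force-corrected) velocity per cell; u_out is (3, n)."""
    n = f.shape[1]
    for i in range(n):
        rho = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        for q in range(19):
            fq = f[q, i]
            rho += fq
            mx += fq * C[q, 0]
            my += fq * C[q, 1]
            mz += fq * C[q, 2]
        mx += 0.5 * body[0]
        my += 0.5 * body[1]
        mz += 0.5 * body[2]
        a = pa[i]
        b = pb[i]
        denom = rho + 0.5 * a
        M = np.sqrt(mx * mx + my * my + mz * mz)
        if M > 0.0:
            if b > 0.0:
                s = (-denom + np.sqrt(denom * denom + 2.0 * b * M)) / b
            else:
                s = M / denom
            u_out[0, i] = mx / M * s
            u_out[1, i] = my / M * s
            u_out[2, i] = mz / M * s
        else:
            u_out[0, i] = 0.0
            u_out[1, i] = 0.0
            u_out[2, i] = 0.0
        rho_out[i] = rho


def equilibrium_init(n, rho0=1.0):
    f = np.empty((19, n))
    for q in range(19):
        f[q, :] = W[q] * rho0
    return f
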