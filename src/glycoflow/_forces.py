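"""Numba force kernels for the coarse model.

Potential terms (Å, kcal/mol, amu, ps):

* bond      V = 1/2 k (r - r0)^2
* angle     V = 1/2 k (theta - theta0)^2
* torsion   V = k (1 + cos(n*phi - gamma))
* nonbonded V = eps * (sig_ij/r)^12 - shift, truncated at the cutoff,
  sig_ij = (sig_i + sig_j)/2, minimum image in an orthorhombic box
* tether    V = 1/2 k |x - x_ref|^2 (force -k(x - x_ref))

All kernels accumulate forces in place and return the potential energy
of their term.  Gradients are analytic; the test suite checks them
against finite differences.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def nonbonded(pos, box, cutoff, eps, sigma, excl, n_excl, forces):
    """Pairwise soft-sphere repulsion with minimum image.

    ``excl`` is a dense (n_excl, n_excl) int8 matrix of excluded pairs
    covering the first ``n_excl`` atoms (the solute); all other pairs
    interact.
    """
    n = pos.shape[0]
    cutoff2 = cutoff * cutoff
    pe = 0.0
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        si = sigma[i]
        for j in range(i + 1, n):
            if i < n_excl and j < n_excl and excl[i, j]:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cutoff2 or r2 == 0.0:
                continue
            sij = 0.5 * (si + sigma[j])
            s2 = sij * sij / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            sc = sij * sij / cutoff2
            sc6 = sc * sc * sc
            pe += eps * (s12 - sc6 * sc6)
            fmag = 12.0 * eps * s12 / r2  # -dV/dr / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
    return pe


@njit(cache=True)
def bonds(pos, idx, k, r0, forces):
    pe = 0.0
    for b in range(idx.shape[0]):
        i = idx[b, 0]
        j = idx[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[b]
        pe += 0.5 * k[b] * dr * dr
        fmag = -k[b] * dr / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return pe


@njit(cache=True)
def angles(pos, idx, k, theta0, forces):
    pe = 0.0
    for a in range(idx.shape[0]):
        i = idx[a, 0]
        j = idx[a, 1]
        l = idx[a, 2]
        rijx = pos[i, 0] - pos[j, 0]
        rijy = pos[i, 1] - pos[j, 1]
        rijz = pos[i, 2] - pos[j, 2]
        rkjx = pos[l, 0] - pos[j, 0]
        rkjy = pos[l, 1] - pos[j, 1]
        rkjz = pos[l, 2] - pos[j, 2]
        rij = math.sqrt(rijx * rijx + rijy * rijy + rijz * rijz)
        rkj = math.sqrt(rkjx * rkjx + rkjy * rkjy + rkjz * rkjz)
        cost = (rijx * rkjx + rijy * rkjy + rijz * rkjz) / (rij * rkj)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = math.acos(cost)
        dth = theta - theta0[a]
        pe += 0.5 * k[a] * dth * dth
        sint = math.sqrt(1.0 - cost * cost)
        if sint < 1e-8:
            sint = 1e-8
        coef = k[a] * dth / sint
        # dtheta/dri and dtheta/drk
        fix = coef / rij * (rkjx / rkj - cost * rijx / rij)
        fiy = coef / rij * (rkjy / rkj - cost * rijy / rij)
        fiz = coef / rij * (rkjz / rkj - cost * rijz / rij)
        flx = coef / rkj * (rijx / rij - cost * rkjx / rkj)
        fly = coef / rkj * (rijy / rij - cost * rkjy / rkj)
        flz = coef / rkj * (rijz / rij - cost * rkjz / rkj)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz
        forces[j, 0] -= fix + flx
        forces[j, 1] -= fiy + fly
        forces[j, 2] -= fiz + flz
    return pe


@njit(cache=True)
def torsions(pos, idx, k, n_per, gamma, forces):
    pe = 0.0
    for t in range(idx.shape[0]):
        i1 = idx[t, 0]
        i2 = idx[t, 1]
        i3 = idx[t, 2]
        i4 = idx[t, 3]
        b1x = pos[i2, 0] - pos[i1, 0]
        b1y = pos[i2, 1] - pos[i1, 1]
        b1z = pos[i2, 2] - pos[i1, 2]
        b2x = pos[i3, 0] - pos[i2, 0]
        b2y = pos[i3, 1] - pos[i2, 1]
        b2z = pos[i3, 2] - pos[i2, 2]
        b3x = pos[i4, 0] - pos[i3, 0]
        b3y = pos[i4, 1] - pos[i3, 1]
        b3z = pos[i4, 2] - pos[i3, 2]
        # normals
        ax = b1y * b2z - b1z * b2y
        ay = b1z * b2x - b1x * b2z
        az = b1x * b2y - b1y * b2x
        bx = b2y * b3z - b2z * b3y
        by = b2z * b3x - b2x * b3z
        bz = b2x * b3y - b2y * b3x
        a2 = ax * ax + ay * ay + az * az
        bsq = bx * bx + by * by + bz * bz
        b2n = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if a2 < 1e-12 or bsq < 1e-12 or b2n < 1e-8:
            continue
        cosphi = (ax * bx + ay * by + az * bz) / math.sqrt(a2 * bsq)
        sinphi = (b2x * (ay * bz - az * by)
                  + b2y * (az * bx - ax * bz)
                  + b2z * (ax * by - ay * bx)) / (b2n * math.sqrt(a2 * bsq))
        phi = math.atan2(sinphi, cosphi)
        nn = n_per[t]
        pe += k[t] * (1.0 + math.cos(nn * phi - gamma[t]))
        dvdphi = -k[t] * nn * math.sin(nn * phi - gamma[t])
        # standard analytic torsion forces
        f1s = dvdphi * b2n / a2
        f4s = -dvdphi * b2n / bsq
        f1x = f1s * ax
        f1y = f1s * ay
        f1z = f1s * az
        f4x = f4s * bx
        f4y = f4s * by
        f4z = f4s * bz
        tf = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        tg = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        sx = tf * f1x - tg * f4x
        sy = tf * f1y - tg * f4y
        sz = tf * f1z - tg * f4z
        forces[i1, 0] += f1x
        forces[i1, 1] += f1y
        forces[i1, 2] += f1z
        forces[i2, 0] += -f1x - sx
        forces[i2, 1] += -f1y - sy
        forces[i2, 2] += -f1z - sz
        forces[i3, 0] += -f4x + sx
        forces[i3, 1] += -f4y + sy
        forces[i3, 2] += -f4z + sz
        forces[i4, 0] += f4x
        forces[i4, 1] += f4y
        forces[i4, 2] += f4z
    return pe


@njit(cache=True)
def tether(pos, idx, k, ref, forces):
    pe = 0.0
    for t in range(idx.shape[0]):
        i = idx[t]
        dx = pos[i, 0] - ref[t, 0]
        dy = pos[i, 1] - ref[t, 1]
        dz = pos[i, 2] - ref[t, 2]
        pe += 0.5 * k * (dx * dx + dy * dy + dz * dz)
        forces[i, 0] -= k * dx
        forces[i, 1] -= k * dy
        forces[i, 2] -= k * dz
    return pe
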