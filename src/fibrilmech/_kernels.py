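"""Numba-compiled energy/force kernel.

Mirrors the pure-numpy evaluation in :mod:`fibrilmech.forcefield` exactly
(same force laws, same switching); the numpy path remains the reference
implementation and the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def evaluate_kernel(
    pos: np.ndarray,  # (N, 3)
    bond_i: np.ndarray,
    bond_j: np.ndarray,
    bond_fam: np.ndarray,  # 0 collagen, 1 age, 2 strengthened
    broken: np.ndarray,  # bool per bond
    br0: np.ndarray,  # per-family trilinear params [3]
    br1: np.ndarray,
    brk: np.ndarray,
    bk0: np.ndarray,
    bk1: np.ndarray,
    ba: np.ndarray,
    angle_i: np.ndarray,
    angle_j: np.ndarray,
    angle_k: np.ndarray,
    k_bend: float,
    theta0: np.ndarray,  # per-angle equilibrium
    pair_i: np.ndarray,
    pair_j: np.ndarray,
    sigma: float,
    epsilon: float,
    cutoff: float,
    r_on: float,
    max_force: float,
    has_pair: bool,
) -> tuple:
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    e_fam = np.zeros(3)
    e_angle = 0.0
    e_pair = 0.0

    for b in range(bond_i.shape[0]):
        if broken[b]:
            continue
        i = bond_i[b]
        j = bond_j[b]
        f = bond_fam[b]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = (dx * dx + dy * dy + dz * dz) ** 0.5
        r0 = br0[f]
        r1 = br1[f]
        rb = brk[f]
        k0 = bk0[f]
        k1 = bk1[f]
        a = ba[f]
        f1 = k0 * (r1 - r0)
        fpk = f1 + k1 * (rb - r1)
        w = 0.5 * k0 * (r1 - r0) ** 2 + f1 * (rb - r1) + 0.5 * k1 * (rb - r1) ** 2
        if r < r1:
            t = k0 * (r - r0)
            e = 0.5 * k0 * (r - r0) ** 2
        elif r < rb:
            t = f1 + k1 * (r - r1)
            e = 0.5 * k0 * (r1 - r0) ** 2 + f1 * (r - r1) + 0.5 * k1 * (r - r1) ** 2
        elif a > 0.0 and r < rb + a:
            d3 = r - rb
            t = fpk * (1.0 - d3 / a)
            e = w + fpk * d3 - fpk * d3 * d3 / (2.0 * a)
        else:
            t = 0.0
            e = w + 0.5 * fpk * a
        e_fam[f] += e
        if r > 0.0:
            ux = dx / r
            uy = dy / r
            uz = dz / r
            forces[i, 0] += t * ux
            forces[i, 1] += t * uy
            forces[i, 2] += t * uz
            forces[j, 0] -= t * ux
            forces[j, 1] -= t * uy
            forces[j, 2] -= t * uz

    if k_bend > 0.0:
        for q in range(angle_i.shape[0]):
            i = angle_i[q]
            j = angle_j[q]
            k = angle_k[q]
            ax = pos[i, 0] - pos[j, 0]
            ay = pos[i, 1] - pos[j, 1]
            az = pos[i, 2] - pos[j, 2]
            bx = pos[k, 0] - pos[j, 0]
            by = pos[k, 1] - pos[j, 1]
            bz = pos[k, 2] - pos[j, 2]
            na = (ax * ax + ay * ay + az * az) ** 0.5
            nb = (bx * bx + by * by + bz * bz) ** 0.5
            cos = (ax * bx + ay * by + az * bz) / (na * nb)
            if cos > 1.0:
                cos = 1.0
            elif cos < -1.0:
                cos = -1.0
            t0 = theta0[q]
            if abs(t0 - np.pi) < 1e-9:
                # cosine form at straight equilibria
                e_angle += 2.0 * k_bend * (1.0 + cos)
                decos = 2.0 * k_bend
            else:
                theta = np.arccos(cos)
                e_angle += k_bend * (theta - t0) ** 2
                s2 = 1.0 - cos * cos
                if s2 < 1e-12:
                    s2 = 1e-12
                decos = -2.0 * k_bend * (theta - t0) / (s2**0.5)
            inb = 1.0 / (na * nb)
            ina2 = 1.0 / (na * na)
            inb2 = 1.0 / (nb * nb)
            gax = decos * (bx * inb - cos * ax * ina2)
            gay = decos * (by * inb - cos * ay * ina2)
            gaz = decos * (bz * inb - cos * az * ina2)
            gbx = decos * (ax * inb - cos * bx * inb2)
            gby = decos * (ay * inb - cos * by * inb2)
            gbz = decos * (az * inb - cos * bz * inb2)
            forces[i, 0] -= gax
            forces[i, 1] -= gay
            forces[i, 2] -= gaz
            forces[k, 0] -= gbx
            forces[k, 1] -= gby
            forces[k, 2] -= gbz
            forces[j, 0] += gax + gbx
            forces[j, 1] += gay + gby
            forces[j, 2] += gaz + gbz

    if has_pair:
        width = cutoff - r_on
        for p in range(pair_i.shape[0]):
            i = pair_i[p]
            j = pair_j[p]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cutoff * cutoff:
                continue
            r = r2**0.5
            sr6 = (sigma / r) ** 6
            phi = 4.0 * epsilon * (sr6 * sr6 - sr6)
            fmag = 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r
            if r < r_on:
                S = 1.0
                dS = 0.0
            else:
                s = (r - r_on) / width
                S = 1.0 - s * s * (3.0 - 2.0 * s)
                dS = -6.0 * s * (1.0 - s) / width
            e_pair += phi * S
            f = fmag * S - phi * dS
            if f > max_force:
                f = max_force
            elif f < -max_force:
                f = -max_force
            ux = dx / r
            uy = dy / r
            uz = dz / r
            forces[j, 0] += f * ux
            forces[j, 1] += f * uy
            forces[j, 2] += f * uz
            forces[i, 0] -= f * ux
            forces[i, 1] -= f * uy
            forces[i, 2] -= f * uz

    return e_fam[0], e_fam[1], e_fam[2], e_angle, e_pair, forces
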