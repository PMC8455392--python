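"""Hayes correction for flat-punch indentation of a bonded elastic layer.

A rigid plane-ended cylindrical indenter (radius ``a``) pressed a depth ``w0``
into an elastic layer (thickness ``h``, shear modulus ``G``, Poisson ratio
``nu``) bonded to a rigid substrate carries the load

    P = 2 E a w0 kappa / (1 - nu^2) = 4 G a w0 kappa / (1 - nu),

where ``kappa(a/h, nu) >= 1`` accounts for the finite layer thickness and
tends to 1 in the half-space limit a/h -> 0.  Indentation moduli are read off
by inverting this relation:  E = P (1 - nu^2) / (2 a w0 kappa).

``kappa`` is obtained here by solving the mixed boundary-value problem
directly.  The bonded-layer surface compliance in Hankel space is, with
kp = 3 - 4 nu and x = xi * h,

    u_z-hat = (1 - nu)/G * Omega(x, nu) * p-hat / xi,
    Omega   = (2 kp sinh 2x - 4x) / (2 kp cosh 2x + 4 x^2 + kp^2 + 1),

derived from Love's stress function with a clamped base (it coincides with
the kernel function of the classical dual-integral-equation treatment).
Writing the contact pressure through Sneddon's representation
p-hat(xi) = int_0^a theta(t) cos(xi t) dt -- which makes the pressure vanish
identically outside the contact circle -- reduces the punch condition
u_z = w0 (r < a) to

    int_0^r theta(t)/sqrt(r^2 - t^2) dt
        + int_0^a theta(t) k(r, t) dt = G w0 / (1 - nu),
    k(r, t) = int_0^inf (Omega(xi h) - 1) cos(xi t) J0(xi r) dxi,

using int_0^inf J0(xi r) cos(xi t) dxi = H(r - t)/sqrt(r^2 - t^2).  The
auxiliary function theta is smooth (constant in the half-space limit, where
the classical p ~ 1/sqrt(a^2 - r^2) profile is recovered), so the equation
is solved by collocation on an even polynomial basis; the half-space Abel
part acts on t^(2n) in closed form and the correction kernel decays like
exp(-2 xi h).  The total load is P = 2 pi int_0^a theta(t) dt.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j0

from .exceptions import RangeError

__all__ = ["hayes_kappa", "layer_compliance", "flat_punch_force", "indentation_modulus"]

#: solvable aspect-ratio range; outside it the collocation is untested.
ASPECT_RANGE = (0.0, 12.0)


def layer_compliance(x, nu):
    """Surface compliance factor Omega(x, nu) of a bonded elastic layer.

    x = xi * h (Hankel wavenumber times thickness).  Omega -> 1 as x -> inf
    (half space) and Omega ~ x (1 - 2 nu)/(2 (1 - nu)^2) as x -> 0 (thin
    confined layer).
    """
    x = np.asarray(x, dtype=float)
    kp = 3.0 - 4.0 * nu
    # divide through by cosh(2x) for overflow-free evaluation at large x
    xs = np.minimum(x, 400.0)
    sech = 1.0 / np.cosh(2.0 * xs)
    num = 2.0 * kp * np.tanh(2.0 * xs) - 4.0 * xs * sech
    den = 2.0 * kp + (4.0 * xs**2 + kp**2 + 1.0) * sech
    out = num / den
    return out if out.ndim else float(out)


@lru_cache(maxsize=4096)
def solve_punch(aspect: float, nu: float, nbasis: int = 8):
    """Solve the punch problem; returns (kappa, theta polynomial coefficients).

    theta(t) = sum_n c_n t^(2n) on [0, a=1] is the auxiliary pressure
    function; the contact pressure follows from its cosine transform and the
    total load is P = 2 pi int theta dt.
    """
    kappa, c = _kappa_impl(aspect, nu, nbasis)
    return kappa, c


@lru_cache(maxsize=4096)
def _kappa_impl(aspect: float, nu: float, nbasis: int):
    # work in units a = G = w0 = 1; layer thickness H = 1/aspect
    H = 1.0 / aspect
    rhs = 1.0 / (1.0 - nu)

    rc = np.sin(0.5 * np.pi * (np.arange(nbasis) + 0.5) / nbasis)  # collocation radii

    # Abel (half-space) part on theta = t^(2n):
    #   int_0^r t^(2n)/sqrt(r^2-t^2) dt = (pi/2) * binom(2n,n)/4^n * r^(2n)
    A = np.empty((nbasis, nbasis))
    for n in range(nbasis):
        A[:, n] = 0.5 * np.pi * comb(2 * n, n) / 4.0**n * rc ** (2 * n)

    # correction kernel W_n(r) = int_0^inf (Omega-1) J0(xi r) S_n(xi) dxi,
    # S_n(xi) = int_0^1 t^(2n) cos(xi t) dt
    ximax = 40.0 / H
    gx, gw = leggauss(64)
    npanel = max(3, int(16 * ximax) // 64 + 1)
    panels = np.linspace(0.0, ximax, min(npanel, 120))
    xi_nodes, xi_w = [], []
    for lo, hi in zip(panels[:-1], panels[1:]):
        xi_nodes.append(0.5 * (hi - lo) * gx + 0.5 * (hi + lo))
        xi_w.append(0.5 * (hi - lo) * gw)
    xi_nodes = np.concatenate(xi_nodes)
    xi_w = np.concatenate(xi_w)

    om = layer_compliance(xi_nodes * H, nu) - 1.0
    tg, tgw = leggauss(48)
    tg = 0.5 * (tg + 1.0)
    tgw = 0.5 * tgw
    cos_mat = np.cos(np.outer(xi_nodes, tg))  # (nxi, nt)
    S = np.empty((nbasis, xi_nodes.size))
    for n in range(nbasis):
        S[n] = cos_mat @ (tg ** (2 * n) * tgw)
    J = j0(np.outer(rc, xi_nodes))  # (nc, nxi)
    W = J @ (om[:, None] * xi_w[:, None] * S.T)  # (nc, nbasis)

    c = np.linalg.solve(A + W, np.full(nbasis, rhs))
    P = 2.0 * np.pi * sum(c[n] / (2 * n + 1) for n in range(nbasis))
    return float(P * (1.0 - nu) / 4.0), tuple(c)


def hayes_kappa(aspect, nu, nbasis: int = 8) -> float:
    """Hayes correction factor kappa(a/h, nu) for the plane-ended punch.

    Parameters
    ----------
    aspect : float
        Indenter radius over layer thickness, a/h (> 0).
    nu : float
        Poisson's ratio of the layer, in [0, 0.5].  0.5 is the
        incompressible short-time limit used for instantaneous and dynamic
        moduli.
    nbasis : int
        Number of collocation basis functions (convergence parameter).

    Returns
    -------
    float
        kappa >= 1, monotone increasing in both ``aspect`` and ``nu``.
    """
    aspect = float(aspect)
    nu = float(nu)
    if not np.isfinite(aspect) or aspect <= ASPECT_RANGE[0] or aspect > ASPECT_RANGE[1]:
        raise RangeError(f"aspect ratio {aspect} outside solvable range {ASPECT_RANGE}")
    if not 0.0 <= nu <= 0.5:
        raise RangeError(f"Poisson ratio {nu} outside [0, 0.5]")
    return _kappa_impl(aspect, nu, nbasis)[0]


def flat_punch_force(E, nu, a, h, w0) -> float:
    """Equilibrium indenter load P = 2 E a w0 kappa / (1 - nu^2)  (N for MPa/mm)."""
    return 2.0 * E * a * w0 * hayes_kappa(a / h, nu) / (1.0 - nu**2)


def indentation_modulus(force, w0, a, h, nu) -> float:
    """Elastic modulus from flat-punch load and depth, Hayes-corrected:
    E = P (1 - nu^2) / (2 a w0 kappa)."""
    return force * (1.0 - nu**2) / (2.0 * a * w0 * hayes_kappa(a / h, nu))
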