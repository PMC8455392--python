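"""Independent analytical oracles used by the test suite.

These implementations deliberately share no code with the package's solvers:
the consolidation series is the classical closed-form solution of the linear
confined-compression problem, and the punch-deflection reconstruction
evaluates the mixed boundary condition of the layer contact problem by
direct quadrature of the Hankel-space representation.
"""

import numpy as np
from scipy.special import j0


def consolidation_stress(t, eps0, t_ramp, H_A, c, h, nterms=500):
    """Surface stress of linear confined compression, ramp-and-hold.

    A layer of thickness ``h`` (drained at the loaded top, sealed at the
    base) is compressed to strain ``eps0`` over ``t_ramp`` and held.  The
    axial strain field obeys a diffusion equation with consolidation
    coefficient c = H_A * k; with the constant-flux boundary condition of a
    linear ramp the classical cosine-series solution gives, with
    q = eps0 h^2 / (c t_ramp) and mu_n = n^2 pi^2 c / h^2:

      sigma(t <= t_ramp) = H_A [ eps0 t/t_ramp + q/3
                                 - (2q/pi^2) sum exp(-mu_n t)/n^2 ]
      sigma(t >  t_ramp) = H_A [ eps0 + (2q/pi^2) sum
                                 (exp(-mu_n (t-t_ramp)) - exp(-mu_n t))/n^2 ]
    """
    t = np.asarray(t, dtype=float)
    q = eps0 * h * h / (c * t_ramp)
    n = np.arange(1, nterms + 1)[:, None]
    mu = (n * np.pi) ** 2 * c / h**2
    out = np.empty_like(t)
    ramp = t <= t_ramp
    tr = t[ramp]
    out[ramp] = H_A * (
        eps0 * tr / t_ramp + q / 3.0
        - (2.0 * q / np.pi**2) * np.sum(np.exp(-mu * tr) / n**2, axis=0)
    )
    th = t[~ramp]
    out[~ramp] = H_A * (
        eps0 + (2.0 * q / np.pi**2)
        * np.sum((np.exp(-mu * (th - t_ramp)) - np.exp(-mu * th)) / n**2, axis=0)
    )
    return out


def consolidation_stress_fd(t_eval, eps0, t_ramp, H_A, c, h, nz=400, dt=None):
    """Crank-Nicolson finite-difference solution of the same problem; used
    to validate the series solution itself."""
    z = np.linspace(0.0, h, nz + 1)
    dz = z[1] - z[0]
    if dt is None:
        dt = min(t_ramp / 50.0, 0.25 * float(np.max(t_eval)) / 2000.0)
    # strain field theta: theta_t = c theta_zz, theta_z(0)=0, theta_z(h)=flux
    theta = np.zeros(nz + 1)
    lam = c * dt / dz**2
    main = np.full(nz + 1, 1.0 + lam)
    off = np.full(nz, -lam / 2.0)
    main[0] = 1.0 + lam  # mirrors at both ends handled via modified RHS
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    A = sp.diags([off, main, off], [-1, 0, 1], format="csc")
    # Neumann via ghost nodes: fold ghost into neighbor (factor 2)
    A = A.tolil()
    A[0, 1] = -lam
    A[nz, nz - 1] = -lam
    A = A.tocsc()
    lu = spla.splu(A)

    out = np.empty(len(t_eval))
    t = 0.0
    i_eval = 0
    t_eval = np.asarray(t_eval, dtype=float)
    sig = []
    times = []
    while t < t_eval.max() + dt:
        flux = eps0 * h / (c * t_ramp) if t + dt <= t_ramp + 1e-12 else 0.0
        rhs = theta.copy()
        rhs[1:-1] += lam / 2.0 * (theta[2:] - 2 * theta[1:-1] + theta[:-2])
        rhs[0] += lam * (theta[1] - theta[0])
        rhs[-1] += lam * (theta[-2] - theta[-1])
        # boundary flux enters as source at z = h (both half steps)
        rhs[-1] += (2.0 * c * dt / dz) * flux
        theta = lu.solve(rhs)
        t += dt
        times.append(t)
        sig.append(H_A * theta[-1])
    return np.interp(t_eval, times, sig)


def hayes_punch_deflection(aspect, nu, theta_coeffs, nbasis, radii):
    """Surface deflection under the punch reconstructed from a solved
    auxiliary pressure function, by direct quadrature of the original mixed
    boundary-value problem (units a = G = 1).

    The contact solution is correct iff this returns w0 at every radius
    under the punch.  theta(t) = sum_n c_n t^(2n) on [0, 1].
    """
    from poroindent.hayes import layer_compliance  # kernel only; no solver reuse

    H = 1.0 / aspect
    radii = np.asarray(radii, dtype=float)

    # half-space part in closed form: int_0^r t^(2n)/sqrt(r^2-t^2) dt
    from math import comb

    half = np.zeros_like(radii)
    for n, c in enumerate(theta_coeffs):
        half += c * 0.5 * np.pi * comb(2 * n, n) / 4.0**n * radii ** (2 * n)

    # correction by adaptive quadrature per radius
    from scipy.integrate import quad

    out = []
    for r, hpart in zip(radii, half):
        def integrand(xi):
            om = layer_compliance(xi * H, nu) - 1.0
            S = sum(
                c * quad_cos(n, xi) for n, c in enumerate(theta_coeffs)
            )
            return om * j0(xi * r) * S

        val, _ = quad(integrand, 0.0, 60.0 / H, limit=400)
        out.append(hpart + val)
    return np.array(out)


def quad_cos(n, xi, npts=200):
    """S_n(xi) = int_0^1 t^(2n) cos(xi t) dt by fixed Gauss quadrature."""
    from numpy.polynomial.legendre import leggauss

    x, w = leggauss(npts if xi > 50 else 60)
    t = 0.5 * (x + 1.0)
    return float(np.sum(0.5 * w * t ** (2 * n) * np.cos(xi * t)))
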