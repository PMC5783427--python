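"""Parametric fits turning tabulated factors into named model parameters.

The factorization produces tabulated one-variable functions; these fits
compress them into the handful of parameters the behavioural model
uses: the speed dissipation time ``tau0``, the wall interaction range
``l_w``, the attraction profile parameters ``(d_0, l_att)``, the
alignment profile parameters ``(d_0p, l_ali)``, and low-order Fourier
coefficients of the angular factors.

All fits carry a free amplitude, so they are invariant under rescaling
of the input table (the factorization fixes scales only by convention).
Weighted mode uses the per-bin effective counts from the factorization,
which down-weights the sparsely populated large-distance bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FitResult",
    "fit_exponential_decay",
    "fit_wall_range",
    "fit_attraction_profile",
    "fit_alignment_profile",
    "fit_fourier",
]


@dataclass
class FitResult:
    params: dict
    residual_norm: float
    converged: bool
    extras: dict = field(default_factory=dict)


def _sigma_from_weights(weights, n):
    if weights is None:
        return None
    w = np.asarray(weights, dtype=float)
    if len(w) != n:
        raise ValueError("weights length mismatch")
    w = np.where(w > 0, w, np.nan)
    return 1.0 / np.sqrt(w)


def fit_exponential_decay(time, speed) -> FitResult:
    """Fit ``v(t) = v0 exp(-t/tau0)`` to a mean post-kick speed profile.

    Returns ``tau0`` (s) and ``v0`` (mm/s).  A profile that does not
    decay (constant or rising) yields a divergent time constant and is
    flagged as non-converged.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(speed, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    if np.any(v <= 0):
        raise ValueError("speeds must be positive for an exponential fit")
    # log-linear seed, then nonlinear refinement
    slope, intercept = np.polyfit(t, np.log(v), 1)
    if slope >= -1e-12:
        return FitResult(
            params={"tau0": math.inf, "v0": float(np.mean(v))},
            residual_norm=float(np.linalg.norm(v - np.mean(v))),
            converged=False,
        )
    p0 = (math.exp(intercept), -1.0 / slope)
    try:
        popt, _ = curve_fit(
            lambda t, v0, tau: v0 * np.exp(-t / tau), t, v, p0=p0, maxfev=10_000
        )
        v0, tau0 = popt
        ok = tau0 > 0
    except RuntimeError:
        v0, tau0 = p0
        ok = False
    resid = float(np.linalg.norm(v - v0 * np.exp(-t / tau0)))
    return FitResult(params={"tau0": float(tau0), "v0": float(v0)},
                     residual_norm=resid, converged=bool(ok))


def _informative(x, y, weights, min_count, use_weights, min_bins):
    """Mask to finite values in sufficiently populated bins.

    Bins below ``min_count`` effective records carry mostly noise and are
    excluded; the remaining bins enter the loss equally unless
    ``use_weights`` asks for inverse-variance (count) weighting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    w = None
    if weights is not None:
        w_all = np.asarray(weights, dtype=float)
        keep &= w_all >= min_count
        if use_weights:
            w = w_all
    x, y = x[keep], y[keep]
    if w is not None:
        w = w[keep]
    if len(x) < min_bins:
        raise ValueError(f"need at least {min_bins} informative bins")
    return x, y, w


def fit_wall_range(r_w, f_values, weights=None, min_count: float = 100.0,
                   use_weights: bool = False) -> FitResult:
    """Fit ``A exp(-(r/l_w)^2)`` to the tabulated wall distance factor.

    The amplitude is free, so the result does not depend on the
    (conventional) scale of the factorized table; ``l_w`` is the
    interaction range in mm.  By default all informative bins (those
    with at least ``min_count`` effective records) enter the loss
    equally; ``use_weights=True`` switches to inverse-variance (count)
    weighting, which emphasises the heavily populated near-wall bins.
    """
    r, f, w = _informative(r_w, f_values, weights, min_count, use_weights, 3)
    a0 = f[np.argmax(np.abs(f))]
    # Gaussian second moment: E[r^2] under exp(-r^2/l^2) on r>=0 is l^2/2
    absf = np.abs(f)
    l0 = math.sqrt(max(2.0 * float(np.sum(r**2 * absf) / np.sum(absf)), 1.0))
    popt, _ = curve_fit(
        lambda r, a, l: a * np.exp(-((r / l) ** 2)),
        r, f, p0=(a0, l0),
        sigma=None if w is None else 1.0 / np.sqrt(w),
        maxfev=20_000,
    )
    a, l = popt
    resid = float(np.linalg.norm(f - a * np.exp(-((r / abs(l)) ** 2))))
    return FitResult(
        params={"l_w": float(abs(l)), "amplitude": float(a)},
        residual_norm=resid, converged=True,
    )


def fit_attraction_profile(d, F_values, weights=None, min_count: float = 100.0,
                           use_weights: bool = False) -> FitResult:
    """Fit ``A (d - d_0) / (1 + (d/l_att)^2)`` to the attraction factor.

    ``d_0`` is the zero crossing separating short-range repulsion from
    attraction, ``l_att`` the range above which the interaction decays.
    Bin selection and weighting as in :func:`fit_wall_range`.
    """
    d_arr, F, w = _informative(d, F_values, weights, min_count, use_weights, 4)

    def model(d, a, d0, latt):
        return a * (d - d0) / (1.0 + (d / latt) ** 2)

    sgn = np.sign(F[np.argmax(np.abs(F))]) or 1.0
    p0 = (sgn * np.max(np.abs(F)) / max(d_arr.max() / 2, 1.0), 30.0, d_arr.max() / 1.5)
    popt, _ = curve_fit(
        model, d_arr, F, p0=p0,
        sigma=None if w is None else 1.0 / np.sqrt(w),
        maxfev=50_000,
    )
    a, d0, latt = popt
    resid = float(np.linalg.norm(F - model(d_arr, *popt)))
    return FitResult(
        params={"d_0": float(d0), "l_att": float(abs(latt)), "amplitude": float(a)},
        residual_norm=resid, converged=True,
    )


def fit_alignment_profile(d, F_values, weights=None, min_count: float = 100.0,
                          use_weights: bool = False) -> FitResult:
    """Fit ``A (d + d_0p) exp(-(d/l_ali)^2)`` to the alignment factor.

    Bin selection and weighting as in :func:`fit_wall_range`.
    """
    d_arr, F, w = _informative(d, F_values, weights, min_count, use_weights, 4)

    def model(d, a, d0p, lali):
        return a * (d + d0p) * np.exp(-((d / lali) ** 2))

    p0 = (np.max(np.abs(F)) / max(d_arr.mean(), 1.0), 30.0, d_arr.max() / 1.5)
    popt, _ = curve_fit(
        model, d_arr, F, p0=p0,
        sigma=None if w is None else 1.0 / np.sqrt(w),
        maxfev=50_000,
    )
    a, d0p, lali = popt
    resid = float(np.linalg.norm(F - model(d_arr, *popt)))
    return FitResult(
        params={"d_0p": float(d0p), "l_ali": float(abs(lali)), "amplitude": float(a)},
        residual_norm=resid, converged=True,
    )


def fit_fourier(theta, values, parity: str, harmonics=(1, 2), weights=None,
                parity_tol: float = 0.2) -> FitResult:
    """Low-order Fourier fit of an angular factor with declared parity.

    Odd factors are fitted as ``A sin(t) (1 + sum_k a_k cos(k t))`` and
    even factors as ``A (1 + sum_k b_k cos(k t))``; ``harmonics`` lists
    which cosine multiples ``k`` are allowed (at most two by
    convention).  The returned coefficients are the normalized ``a_k`` /
    ``b_k`` — ratios of cosine-modulation to leading amplitude — so they
    do not depend on the scale of the input.

    The data's parity is checked first: if the odd (resp. even) part of
    the table does not dominate, the declaration is inconsistent and an
    error is raised.
    """
    if parity not in ("odd", "even"):
        raise ValueError("parity must be 'odd' or 'even'")
    if len(harmonics) > 2:
        raise ValueError("at most 2 cosine harmonics by convention")
    t = np.asarray(theta, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(v)
    t, v = t[keep], v[keep]
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[keep]
        w = np.where(w > 0, w, 0.0)

    # parity consistency check on a symmetric table
    order = np.argsort(t)
    ts, vs = t[order], v[order]
    if np.allclose(ts, -ts[::-1], atol=1e-9):
        odd_part = 0.5 * (vs - vs[::-1])
        even_part = 0.5 * (vs + vs[::-1])
        off = even_part if parity == "odd" else odd_part
        total = float(np.linalg.norm(vs))
        if total > 0:
            frac_off = float(np.linalg.norm(off)) / total
            if frac_off > parity_tol:
                raise ValueError(
                    f"data parity inconsistent with '{parity}' "
                    f"(off-parity fraction {frac_off:.2f})"
                )

    base = np.sin(t) if parity == "odd" else np.ones_like(t)
    cols = [base] + [base * np.cos(k * t) for k in harmonics]
    X = np.column_stack(cols)
    if w is not None:
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], v * sw, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    if abs(coef[0]) < 1e-12:
        raise ValueError("leading Fourier amplitude vanishes; cannot normalize")
    normalized = {f"c{k}": float(c / coef[0]) for k, c in zip(harmonics, coef[1:])}
    resid = float(np.linalg.norm(v - X @ coef))
    return FitResult(
        params=normalized,
        residual_norm=resid,
        converged=True,
        extras={"amplitude": float(coef[0])},
    )
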