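"""Symmetry-constrained product factorization of stimulus-response data.

The systematic part of the per-kick heading change is measured directly
from kick tables by binning responses over the stimulus space and
fitting a product of one-variable tabulated functions by weighted least
squares.  Left/right symmetry of behaviour (a trajectory and its mirror
image are equally likely) is first exploited by *symmetrizing* the data
set — every record is paired with its mirror — and then imposed on the
factors: angular factors are constrained to be exactly odd (O) or even
(E) on a mesh symmetric about zero.

Wall case (2 factors).  Minimise over tabulated ``f_i`` (distance) and
``O_j`` (angle, odd)::

    Delta = sum_ij  eps_ij (dphi_ij - f_i O_j)^2

where ``eps_ij`` is the record count and ``dphi_ij`` the mean response
in cell ``(i, j)`` of an ``(r_w, theta_w)`` mesh.

Pair case (two 3-factor terms).  Minimise over six tabulated functions::

    Delta = sum_klm eps_klm (dphi_klm - F_att,k O_att,l E_att,m
                                       - F_ali,k O_ali,m E_ali,l)^2

on a ``(d, psi, dphi)`` mesh, after excluding kicks closer than 2 BL to
the wall where wall avoidance contaminates the signal.

Both problems are solved by a damped fixed-point iteration of the
normal equations (damping ``p = 0.25``), renormalizing every angular
factor to unit mean square after each cycle and re-imposing parity; the
distance factors carry the remaining scale (in radians).  No smoothing
or regularization is applied: smoothness of the recovered factors is
itself evidence that the product form captures the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Mesh",
    "BinnedResponse",
    "FactorizationResult",
    "symmetrize",
    "bin_2d",
    "bin_3d",
    "factorize_2d",
    "factorize_3d",
]


@dataclass(frozen=True)
class Mesh:
    """Per-dimension bin edges for the stimulus space.

    Angular dimensions span ``[-pi, pi]`` with an even number of bins so
    that mirroring maps bins onto bins.
    """

    edges: tuple

    def __post_init__(self):
        for e in self.edges:
            e = np.asarray(e)
            if len(e) < 2 or np.any(np.diff(e) <= 0):
                raise ValueError("mesh edges must be strictly increasing")

    @classmethod
    def wall(cls, radius: float, n_r: int = 40, n_theta: int = 30) -> "Mesh":
        return cls(
            edges=(
                np.linspace(0.0, radius, n_r + 1),
                np.linspace(-np.pi, np.pi, n_theta + 1),
            )
        )

    @classmethod
    def pair(
        cls, d_max: float = 280.0, n_d: int = 40, n_psi: int = 30, n_dphi: int = 30
    ) -> "Mesh":
        return cls(
            edges=(
                np.linspace(0.0, d_max, n_d + 1),
                np.linspace(-np.pi, np.pi, n_psi + 1),
                np.linspace(-np.pi, np.pi, n_dphi + 1),
            )
        )

    def centers(self, dim: int) -> np.ndarray:
        e = np.asarray(self.edges[dim])
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class BinnedResponse:
    """Per-cell record counts and mean observed heading change."""

    mesh: Mesh
    counts: np.ndarray
    mean_dphi: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        if self.counts.shape != self.mean_dphi.shape:
            raise ValueError("counts and mean_dphi shapes differ")


@dataclass
class FactorizationResult:
    """Tabulated factors plus convergence diagnostics."""

    factors: dict            # name -> 1-D array on the mesh centers
    mesh: Mesh
    error: float             # final weighted squared error Delta
    error_history: list
    iterations: int
    converged: bool
    damping: float
    tol: float
    degenerate: bool = False
    bin_weights: dict = field(default_factory=dict)  # name -> effective counts


# ---------------------------------------------------------------------------
# data preparation

_ANGLE_COLS = ("theta_w_rad", "psi_rad", "dphi_pair_rad", "dphi_rad")


def symmetrize(records: pd.DataFrame) -> pd.DataFrame:
    """Double the data set by appending the mirror of every record.

    The mirror record negates all signed angles (wall angle, viewing
    angle, heading difference, and the response) and keeps distances and
    kinematics unchanged.  The output has exactly twice as many rows.
    """
    if len(records) == 0:
        return records.copy()
    mirror = records.copy()
    for col in _ANGLE_COLS:
        if col in mirror:
            mirror[col] = -mirror[col]
    return pd.concat([records, mirror], ignore_index=True)


def _bin_nd(values, response, mesh: Mesh):
    """Counts and per-cell mean response on an arbitrary-dimension mesh.

    Bins are left-closed right-open; the last bin is closed.  Records
    outside the mesh are dropped (counted in ``n_dropped``).
    """
    edges = [np.asarray(e, dtype=float) for e in mesh.edges]
    sample = np.column_stack([np.asarray(v, dtype=float) for v in values])
    response = np.asarray(response, dtype=float)
    ok = np.ones(len(response), dtype=bool)
    for dim, e in enumerate(edges):
        ok &= (sample[:, dim] >= e[0]) & (sample[:, dim] <= e[-1])
    sample = sample[ok]
    counts, _ = np.histogramdd(sample, bins=edges)
    sums, _ = np.histogramdd(sample, bins=edges, weights=response[ok])
    mean = np.zeros_like(counts)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    return counts, mean, int(len(response) - ok.sum())


def bin_2d(records: pd.DataFrame, mesh: Mesh) -> BinnedResponse:
    """Bin (symmetrized) single-fish kicks over the ``(r_w, theta_w)`` mesh."""
    counts, mean, dropped = _bin_nd(
        (records["r_w_mm"].to_numpy(), records["theta_w_rad"].to_numpy()),
        records["dphi_rad"].to_numpy(),
        mesh,
    )
    return BinnedResponse(mesh=mesh, counts=counts, mean_dphi=mean, n_dropped=dropped)


def bin_3d(
    records: pd.DataFrame,
    mesh: Mesh,
    wall_cutoff_mm: float = 60.0,
) -> BinnedResponse:
    """Bin (symmetrized) pair kicks over ``(d, psi, dphi)``.

    Kicks with the focal fish closer than ``wall_cutoff_mm`` (~2 BL) to
    the wall are excluded first: there the wall interaction is not
    negligible and would contaminate the social signal.
    """
    keep = records["r_w_mm"].to_numpy() > wall_cutoff_mm
    sub = records[keep]
    counts, mean, dropped = _bin_nd(
        (
            sub["d_mm"].to_numpy(),
            sub["psi_rad"].to_numpy(),
            sub["dphi_pair_rad"].to_numpy(),
        ),
        sub["dphi_rad"].to_numpy(),
        mesh,
    )
    return BinnedResponse(
        mesh=mesh,
        counts=counts,
        mean_dphi=mean,
        n_dropped=dropped + int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# parity / normalization helpers


def _antisymmetrize(v: np.ndarray) -> np.ndarray:
    return 0.5 * (v - v[::-1])


def _symmetrize_even(v: np.ndarray) -> np.ndarray:
    return 0.5 * (v + v[::-1])


def _unit_ms(v: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale to unit mean square; returns (rescaled, applied norm)."""
    ms = float(np.mean(v**2))
    if ms <= 0:
        return v, 1.0
    c = math.sqrt(ms)
    return v / c, c


def _positive_half_mean(v: np.ndarray) -> float:
    """Mean over the bins with positive angle centre (symmetric mesh)."""
    n = len(v)
    return float(np.mean(v[n // 2 :]))


# ---------------------------------------------------------------------------
# 2-factor (wall) factorization


def factorize_2d(
    binned: BinnedResponse,
    p: float = 0.25,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    init_O: np.ndarray | None = None,
) -> FactorizationResult:
    """Weighted least-squares factorization ``dphi_ij ~ f_i O_j``.

    Damped fixed-point iteration of the normal equations; after each
    cycle ``O`` is anti-symmetrized, renormalized to unit mean square
    (the scale moving into ``f``), and the sign convention (mean of
    ``O`` over the positive half non-negative) applied.  Converges when
    the largest relative change of any tabulated value drops below
    ``tol``.  Non-convergence is reported in the result, not raised.
    """
    eps = binned.counts
    dphi = binned.mean_dphi
    if not np.any(eps > 0):
        raise ValueError("empty binned response: all counts zero")
    theta = binned.mesh.centers(1)
    O = np.sin(theta) if init_O is None else np.asarray(init_O, dtype=float).copy()
    O = _antisymmetrize(O)
    O, _ = _unit_ms(O)
    # start f at its exact normal-equation value given O
    f = _ls_update_rows(eps, dphi, O)

    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f_new = (1 - p) * f + p * _ls_update_rows(eps, dphi, O)
        O_new = (1 - p) * O + p * _ls_update_rows(eps.T, dphi.T, f_new)
        O_new = _antisymmetrize(O_new)
        O_new, c = _unit_ms(O_new)
        f_new = f_new * c
        if _positive_half_mean(O_new) < 0:
            O_new = -O_new
            f_new = -f_new
        history.append(float(np.sum(eps * (dphi - np.outer(f_new, O_new)) ** 2)))
        delta = max(_max_rel_change(f, f_new), _max_rel_change(O, O_new))
        f, O = f_new, O_new
        if delta < tol:
            converged = True
            break

    row_weights = eps.sum(axis=1)
    col_weights = eps.sum(axis=0)
    return FactorizationResult(
        factors={"f": f, "O": O},
        mesh=binned.mesh,
        error=history[-1] if history else math.inf,
        error_history=history,
        iterations=it,
        converged=converged,
        damping=p,
        tol=tol,
        bin_weights={"f": row_weights, "O": col_weights},
    )


def _ls_update_rows(eps: np.ndarray, dphi: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Exact minimiser of the row factor given the column factor."""
    num = (eps * dphi) @ other
    den = eps @ (other**2)
    out = np.zeros(eps.shape[0])
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def _max_rel_change(old: np.ndarray, new: np.ndarray) -> float:
    return float(np.max(np.abs(new - old) / (np.abs(old) + 1e-12)))


# ---------------------------------------------------------------------------
# 6-function (pair) factorization


def factorize_3d(
    binned: BinnedResponse,
    p: float = 0.25,
    tol: float = 1e-6,
    max_iter: int = 20_000,
    init: dict | None = None,
) -> FactorizationResult:
    """Two-term product factorization of the pair response.

    ``dphi_klm ~ F_att,k O_att,l E_att,m + F_ali,k O_ali,m E_ali,l`` on
    the ``(d, psi, dphi)`` mesh (axis order k, l, m).  Each of the six
    tabulated functions is updated in turn from its weighted normal
    equation with the other term subtracted as a counter-term, damped by
    ``p``; every cycle the four angular factors are re-projected onto
    their parity, renormalized to unit mean square (scale into the F's)
    and sign-fixed (non-negative mean of each angular factor over the
    positive half).
    """
    eps = binned.counts
    dphi = binned.mean_dphi
    if not np.any(eps > 0):
        raise ValueError("empty binned response: all counts zero")
    psi = binned.mesh.centers(1)
    dph = binned.mesh.centers(2)
    K = eps.shape[0]

    fa = np.full(K, 0.05)
    Oa = np.sin(psi)
    Ea = np.ones(len(dph))
    fl = np.full(K, 0.05)
    Ol = np.sin(dph)
    El = np.ones(len(psi))
    if init is not None:
        fa = np.asarray(init.get("F_att", fa), dtype=float).copy()
        Oa = np.asarray(init.get("O_att", Oa), dtype=float).copy()
        Ea = np.asarray(init.get("E_att", Ea), dtype=float).copy()
        fl = np.asarray(init.get("F_ali", fl), dtype=float).copy()
        Ol = np.asarray(init.get("O_ali", Ol), dtype=float).copy()
        El = np.asarray(init.get("E_ali", El), dtype=float).copy()
    Oa, _ = _unit_ms(_antisymmetrize(Oa))
    Ol, _ = _unit_ms(_antisymmetrize(Ol))
    Ea, _ = _unit_ms(_symmetrize_even(Ea))
    El, _ = _unit_ms(_symmetrize_even(El))

    w = eps
    wd = eps * dphi

    def att_field(fa, Oa, Ea):
        return np.einsum("k,l,m->klm", fa, Oa, Ea)

    def ali_field(fl, Ol, El):
        return np.einsum("k,m,l->klm", fl, Ol, El)

    def residual_error():
        model = att_field(fa, Oa, Ea) + ali_field(fl, Ol, El)
        return float(np.sum(w * (dphi - model) ** 2))

    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = np.concatenate([fa, Oa, Ea, fl, Ol, El])

        # --- attraction term updates (counter-term: alignment) ---
        ali = ali_field(fl, Ol, El)
        resid = wd - w * ali
        num = np.einsum("klm,l,m->k", resid, Oa, Ea)
        den = np.einsum("klm,l,m->k", w, Oa**2, Ea**2)
        fa = _damped(fa, num, den, p)

        ali = ali_field(fl, Ol, El)
        resid = wd - w * ali
        num = np.einsum("klm,k,m->l", resid, fa, Ea)
        den = np.einsum("klm,k,m->l", w, fa**2, Ea**2)
        Oa = _damped(Oa, num, den, p)

        ali = ali_field(fl, Ol, El)
        resid = wd - w * ali
        num = np.einsum("klm,k,l->m", resid, fa, Oa)
        den = np.einsum("klm,k,l->m", w, fa**2, Oa**2)
        Ea = _damped(Ea, num, den, p)

        # --- alignment term updates (counter-term: attraction) ---
        att = att_field(fa, Oa, Ea)
        resid = wd - w * att
        num = np.einsum("klm,m,l->k", resid, Ol, El)
        den = np.einsum("klm,m,l->k", w, Ol**2, El**2)
        fl = _damped(fl, num, den, p)

        att = att_field(fa, Oa, Ea)
        resid = wd - w * att
        num = np.einsum("klm,k,l->m", resid, fl, El)
        den = np.einsum("klm,k,l->m", w, fl**2, El**2)
        Ol = _damped(Ol, num, den, p)

        att = att_field(fa, Oa, Ea)
        resid = wd - w * att
        num = np.einsum("klm,k,m->l", resid, fl, Ol)
        den = np.einsum("klm,k,m->l", w, fl**2, Ol**2)
        El = _damped(El, num, den, p)

        # --- parity, normalization, sign conventions ---
        Oa, ca = _unit_ms(_antisymmetrize(Oa))
        Ea, cb = _unit_ms(_symmetrize_even(Ea))
        fa = fa * ca * cb
        Ol, cc = _unit_ms(_antisymmetrize(Ol))
        El, cd = _unit_ms(_symmetrize_even(El))
        fl = fl * cc * cd
        if _positive_half_mean(Oa) < 0:
            Oa, fa = -Oa, -fa
        if _positive_half_mean(Ol) < 0:
            Ol, fl = -Ol, -fl
        if np.mean(Ea) < 0:
            Ea, fa = -Ea, -fa
        if np.mean(El) < 0:
            El, fl = -El, -fl

        history.append(residual_error())
        cur = np.concatenate([fa, Oa, Ea, fl, Ol, El])
        delta = float(np.max(np.abs(cur - prev) / (np.abs(prev) + 1e-12)))
        if delta < tol:
            converged = True
            break

    degenerate = bool(
        np.max(np.abs(fa)) < 1e-10 or np.max(np.abs(fl)) < 1e-10
    )
    return FactorizationResult(
        factors={
            "F_att": fa, "O_att": Oa, "E_att": Ea,
            "F_ali": fl, "O_ali": Ol, "E_ali": El,
        },
        mesh=binned.mesh,
        error=history[-1] if history else math.inf,
        error_history=history,
        iterations=it,
        converged=converged,
        damping=p,
        tol=tol,
        degenerate=degenerate,
        bin_weights={
            "F_att": eps.sum(axis=(1, 2)),
            "F_ali": eps.sum(axis=(1, 2)),
            "O_att": eps.sum(axis=(0, 2)),
            "E_ali": eps.sum(axis=(0, 2)),
            "E_att": eps.sum(axis=(0, 1)),
            "O_ali": eps.sum(axis=(0, 1)),
        },
    )


def _damped(old: np.ndarray, num: np.ndarray, den: np.ndarray, p: float) -> np.ndarray:
    new = old.copy()
    nz = den > 0
    new[nz] = num[nz] / den[nz]
    return (1 - p) * old + p * new
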