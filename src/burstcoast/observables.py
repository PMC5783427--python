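"""Summary statistics and distributions for model/data comparison.

These observables mirror the quantities usually plotted for
burst-and-coast swimmers: distributions of kick duration and length,
distance and relative angle to the wall, the wall-signed heading change
``dphi_+ = dphi * sign(theta_w)`` (positive = turning away from the
wall), and for pairs the inter-fish distance, viewing angle, heading
difference and per-role (leader/follower) wall distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import FishState, pair_frame

__all__ = [
    "DistributionSummary",
    "signed_turn",
    "leader_follower",
    "kick_statistics",
    "compare_distributions",
]

N_ANGLE_BINS = 60   # over (-pi, pi]
N_RADIAL_BINS = 40


@dataclass
class DistributionSummary:
    """Normalized histogram plus scalar summaries."""

    edges: np.ndarray
    density: np.ndarray
    mean: float
    mode: float
    sd: float
    unit: str = ""

    @classmethod
    def from_samples(cls, x, edges, unit="") -> "DistributionSummary":
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if len(x) == 0:
            raise ValueError("no finite samples")
        density, edges = np.histogram(x, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return cls(
            edges=edges,
            density=density,
            mean=float(np.mean(x)),
            mode=float(centers[np.argmax(density)]),
            sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            unit=unit,
        )

    @property
    def bin_width(self) -> float:
        return float(np.mean(np.diff(self.edges)))


def signed_turn(row) -> float:
    """Wall-signed heading change ``dphi * sign(theta_w)``.

    Positive values mean turning away from the wall.  Rows with
    ``theta_w`` exactly zero have no defined wall side and return 0 (they
    are dropped from signed-turn histograms).
    """
    theta = float(row["theta_w_rad"])
    return float(row["dphi_rad"]) * float(np.sign(theta))


def leader_follower(state_a: FishState, state_b: FishState):
    """Geometrical leader/follower labels for a pair of fish at one time.

    The leader is the fish with the larger absolute viewing angle |psi|
    — the one that would have to turn more to face its partner.  Exact
    ties or degenerate geometry return ``None``.
    """
    fa = pair_frame(state_a, state_b)
    fb = pair_frame(state_b, state_a)
    if fa.degenerate or fb.degenerate:
        return None
    if abs(fa.psi) > abs(fb.psi):
        return ("leader", "follower")
    if abs(fb.psi) > abs(fa.psi):
        return ("follower", "leader")
    return None


def kick_statistics(kicks: pd.DataFrame, radius: float | None = None,
                    pair: bool | None = None) -> dict:
    """Distribution summaries and scalars from a kick table.

    Returns a dict of :class:`DistributionSummary` keyed by variable
    (``tau``, ``l``, ``v``, ``r_w``, ``theta_w``, ``dphi_plus`` and, for
    pairs, ``d``, ``psi``, ``dphi_pair``) plus scalar conveniences
    (``mean_tau_s``, ``mean_l_mm``, ``mean_glide_speed_mm_s``,
    ``mean_peak_speed_mm_s`` and for pairs ``mode_d_mm``).
    """
    if len(kicks) == 0:
        raise ValueError("empty kick table")
    if pair is None:
        pair = "d_mm" in kicks.columns
    if radius is None:
        radius = float(kicks["r_w_mm"].max()) * 1.02

    angle_edges = np.linspace(-np.pi, np.pi, N_ANGLE_BINS + 1)
    out: dict = {}
    out["tau"] = DistributionSummary.from_samples(
        kicks["tau_s"], np.linspace(0, 2.0, 51), unit="s"
    )
    out["l"] = DistributionSummary.from_samples(
        kicks["l_mm"], np.linspace(0, 250.0, 51), unit="mm"
    )
    out["v"] = DistributionSummary.from_samples(
        kicks["v_peak_mm_s"], np.linspace(0, 500.0, 51), unit="mm/s"
    )
    out["r_w"] = DistributionSummary.from_samples(
        kicks["r_w_mm"], np.linspace(0, radius, N_RADIAL_BINS + 1), unit="mm"
    )
    out["theta_w"] = DistributionSummary.from_samples(
        kicks["theta_w_rad"], angle_edges, unit="rad"
    )
    signed = kicks["dphi_rad"].to_numpy() * np.sign(kicks["theta_w_rad"].to_numpy())
    signed = signed[kicks["theta_w_rad"].to_numpy() != 0.0]
    out["dphi_plus"] = DistributionSummary.from_samples(signed, angle_edges, unit="rad")

    out["mean_tau_s"] = float(kicks["tau_s"].mean())
    out["mean_l_mm"] = float(kicks["l_mm"].mean())
    out["mean_peak_speed_mm_s"] = float(kicks["v_peak_mm_s"].mean())
    # mean speed over the glide = length / duration, the "active" speed
    out["mean_glide_speed_mm_s"] = float(
        (kicks["l_mm"] / kicks["tau_s"]).replace([np.inf, -np.inf], np.nan).mean()
    )

    if pair:
        d_edges = np.linspace(0, 300.0, 41)
        out["d"] = DistributionSummary.from_samples(kicks["d_mm"], d_edges, unit="mm")
        out["psi"] = DistributionSummary.from_samples(
            kicks["psi_rad"], angle_edges, unit="rad"
        )
        out["dphi_pair"] = DistributionSummary.from_samples(
            kicks["dphi_pair_rad"], angle_edges, unit="rad"
        )
        out["mode_d_mm"] = out["d"].mode
        # per-role wall distance: the focal fish is the geometrical leader
        # at its kick when its own |psi| exceeds that of its partner seen
        # from the partner's log row nearest in time
        roles = _roles_from_kicks(kicks)
        if roles is not None:
            lead = kicks["r_w_mm"].to_numpy()[roles == 1]
            foll = kicks["r_w_mm"].to_numpy()[roles == 0]
            if len(lead) and len(foll):
                out["leader_mean_r_w_mm"] = float(np.mean(lead))
                out["follower_mean_r_w_mm"] = float(np.mean(foll))
    return out


def _roles_from_kicks(kicks: pd.DataFrame):
    """1 = leader, 0 = follower, -1 = unresolved, per two-fish kick row.

    Compares each kick's |psi| with the partner's |psi| at its nearest
    kick in time.
    """
    if "psi_rad" not in kicks.columns or kicks["fish_id"].nunique() != 2:
        return None
    ids = sorted(kicks["fish_id"].unique())
    roles = np.full(len(kicks), -1, dtype=int)
    by_id = {
        fid: kicks[kicks.fish_id == fid].reset_index() for fid in ids
    }
    for fid in ids:
        own = by_id[fid]
        other = by_id[ids[0] if fid == ids[1] else ids[1]]
        pos = np.searchsorted(other["t_s"].to_numpy(), own["t_s"].to_numpy())
        pos = np.clip(pos, 0, len(other) - 1)
        own_psi = np.abs(own["psi_rad"].to_numpy())
        other_psi = np.abs(other["psi_rad"].to_numpy())[pos]
        r = np.where(own_psi > other_psi, 1, np.where(own_psi < other_psi, 0, -1))
        roles[own["index"].to_numpy()] = r
    return roles


def compare_distributions(a: DistributionSummary, b: DistributionSummary) -> dict:
    """L1 distance (and max-bin discrepancy) between two histograms.

    Both must share the same binning.  Two disjoint unit masses give an
    L1 distance of 2; identical histograms give 0.
    """
    if len(a.edges) != len(b.edges) or not np.allclose(a.edges, b.edges):
        raise ValueError("histograms must share the same binning")
    widths = np.diff(a.edges)
    l1 = float(np.sum(np.abs(a.density - b.density) * widths))
    return {"l1": l1, "max_bin": float(np.max(np.abs(a.density - b.density) * widths))}
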