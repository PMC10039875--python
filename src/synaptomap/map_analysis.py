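"""Slice geometry and map-level connectivity summaries.

Recorded slices are referenced by three mutually orthogonal planes: a
least-squares slice-surface plane (distance from it is the cell's depth in
the slice, reported as the AP position), a midline plane through the dorsal
and ventral midline ends orthogonal to the surface (ML position), and a
dorsal-end plane orthogonal to both (DV position).  Map summaries cover
connection probability within a radius, connection strength, weighted
input (non-connected cells count as zero), directional inputs, the
co-stimulation overestimation bias from spatially overlapping stimulation
ellipsoids, the slicing-depth effect, and depth-dependent light-power
compensation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default stimulation-specificity ellipsoid: FWHM of spiking probability
DEFAULT_FWHM_AXIAL_UM = 55.9
DEFAULT_FWHM_RADIAL_UM = 24.2
#: default tissue light-attenuation length
DEFAULT_ATTENUATION_UM = 147.6


# ---------------------------------------------------------------------------
# slice-coordinate transform
# ---------------------------------------------------------------------------

@dataclass
class SlicePlanes:
    """Three mutually orthogonal reference planes (point, unit normal)."""

    surface_point: np.ndarray
    surface_normal: np.ndarray
    midline_point: np.ndarray
    midline_normal: np.ndarray
    dorsal_point: np.ndarray
    dorsal_normal: np.ndarray


def fit_slice_planes(surface_points: np.ndarray, dorsal_end: np.ndarray,
                     ventral_end: np.ndarray) -> SlicePlanes:
    """Construct the surface, midline and dorsal-end planes.

    The surface plane is the least-squares plane of the surface point
    cloud; the midline plane passes through the two midline ends and is
    orthogonalized against the surface plane; the dorsal-end plane is
    orthogonal to both through the dorsal end.
    """
    pts = np.asarray(surface_points, float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 surface points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("surface points are collinear")
    n_surf = vt[2]
    if n_surf[2] < 0:  # orient toward +z for a reproducible sign
        n_surf = -n_surf

    d = np.asarray(ventral_end, float) - np.asarray(dorsal_end, float)
    n_mid = np.cross(d, n_surf)
    norm = np.linalg.norm(n_mid)
    if norm < 1e-12:
        raise ValueError("midline axis is parallel to the surface normal")
    n_mid = n_mid / norm
    n_dors = np.cross(n_surf, n_mid)
    n_dors = n_dors / np.linalg.norm(n_dors)
    return SlicePlanes(surface_point=centroid, surface_normal=n_surf,
                       midline_point=np.asarray(dorsal_end, float),
                       midline_normal=n_mid,
                       dorsal_point=np.asarray(dorsal_end, float),
                       dorsal_normal=n_dors)


def slice_coordinate_transform(surface_points: np.ndarray,
                               dorsal_end: np.ndarray,
                               ventral_end: np.ndarray,
                               cell_positions: np.ndarray) -> pd.DataFrame:
    """Per-cell (AP depth, ML, DV) as signed distances from the planes."""
    planes = fit_slice_planes(surface_points, dorsal_end, ventral_end)
    cells = np.atleast_2d(np.asarray(cell_positions, float))
    ap = (cells - planes.surface_point) @ planes.surface_normal
    ml = (cells - planes.midline_point) @ planes.midline_normal
    dv = (cells - planes.dorsal_point) @ planes.dorsal_normal
    return pd.DataFrame(dict(ap_um=-ap, ml_um=ml, dv_um=dv))


# ---------------------------------------------------------------------------
# map summaries
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMap:
    """One input map: the recorded cell plus all stimulated cells."""

    recorded_position_um: np.ndarray
    positions_um: np.ndarray         # (n_cells, 3): stimulated cells
    responsive: np.ndarray           # bool
    connected: np.ndarray            # bool, implies responsive
    strengths_pa: np.ndarray         # >= 0; 0 for non-connected
    recorded_depth_um: float = np.nan
    layer: str = ""

    def __post_init__(self):
        self.recorded_position_um = np.asarray(self.recorded_position_um, float)
        self.positions_um = np.atleast_2d(np.asarray(self.positions_um, float))
        self.responsive = np.asarray(self.responsive, bool)
        self.connected = np.asarray(self.connected, bool)
        self.strengths_pa = np.asarray(self.strengths_pa, float)
        if np.any(self.connected & ~self.responsive):
            raise ValueError("connected cells must be responsive")
        if np.any(self.strengths_pa < 0):
            raise ValueError("strengths must be nonnegative")


@dataclass
class MapSummary:
    probability: float
    mean_strength_pa: float
    weighted_input_pa: float
    directional_pa: dict = field(default_factory=dict)
    n_responsive_in_radius: int = 0
    probability_defined: bool = True


def map_summaries(m: ConnectivityMap, radius_um: float = 300.0) -> MapSummary:
    """Connection probability (within the radius), mean strength of the
    connected cells (no radius cap), weighted input (non-connected count as
    zero), and weighted input split by the sign of the ML and DV offsets of
    the presynaptic cells relative to the recorded cell."""
    if not np.any(m.responsive):
        raise ValueError("map has no responsive cells")
    dist = np.linalg.norm(m.positions_um - m.recorded_position_um, axis=1)
    in_r = dist <= radius_um
    resp_r = m.responsive & in_r
    n_resp = int(resp_r.sum())
    prob = float((m.connected & in_r).sum() / n_resp) if n_resp else np.nan

    conn = m.connected
    mean_strength = float(m.strengths_pa[conn].mean()) if conn.any() else 0.0
    resp = m.responsive
    weighted = float(np.where(conn, m.strengths_pa, 0.0)[resp].mean())

    offs = m.positions_um - m.recorded_position_um
    directional = {}
    for axis, name in ((0, "ml"), (1, "dv")):
        for sign, side in ((-1, "neg"), (1, "pos")):
            sel = resp & (np.sign(offs[:, axis]) == sign)
            directional[f"{name}_{side}"] = (
                float(np.where(conn, m.strengths_pa, 0.0)[sel].mean())
                if sel.any() else 0.0)
    return MapSummary(probability=prob, mean_strength_pa=mean_strength,
                      weighted_input_pa=weighted, directional_pa=directional,
                      n_responsive_in_radius=n_resp,
                      probability_defined=n_resp > 0)


# ---------------------------------------------------------------------------
# co-stimulation bias
# ---------------------------------------------------------------------------

@dataclass
class CostimulationStats:
    fraction_with_neighbor: float     # f_co
    mean_neighbors_given_any: float
    pairwise_fraction: float
    bias: float                       # 1 - 1/(1 + f_co)


def costimulation_bias(positions_um: np.ndarray,
                       fwhm_axial_um: float = DEFAULT_FWHM_AXIAL_UM,
                       fwhm_radial_um: float = DEFAULT_FWHM_RADIAL_UM,
                       axial_axis: int = 2,
                       semi_axis_equals_fwhm: bool = False
                       ) -> CostimulationStats:
    """Connection-probability overestimation from co-stimulated neighbors.

    Each cell carries an ellipsoid whose axes are the FWHM of the spiking
    probability (by default full-axis length = FWHM, i.e. semi-axis =
    FWHM/2; ``semi_axis_equals_fwhm`` switches to the wider reading).  With
    f_co the fraction of cells having at least one neighbor inside their
    ellipsoid, the measured connection probability overestimates the true
    one by a factor (1 + f_co), i.e. bias = 1 - 1/(1 + f_co).
    """
    pos = np.atleast_2d(np.asarray(positions_um, float))
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    semi = np.full(3, fwhm_radial_um)
    semi[axial_axis] = fwhm_axial_um
    if not semi_axis_equals_fwhm:
        semi = semi / 2.0
    scaled = pos / semi
    d2 = np.sum((scaled[:, None, :] - scaled[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    inside = d2 <= 1.0
    n_neigh = inside.sum(axis=1)
    f_co = float(np.mean(n_neigh >= 1))
    mean_given = float(n_neigh[n_neigh >= 1].mean()) if f_co > 0 else 0.0
    n = pos.shape[0]
    pairwise = float(np.triu(inside, 1).sum() / (n * (n - 1) / 2))
    return CostimulationStats(fraction_with_neighbor=f_co,
                              mean_neighbors_given_any=mean_given,
                              pairwise_fraction=pairwise,
                              bias=costim_bias_from_fraction(f_co))


def costim_bias_from_fraction(f_co: float) -> float:
    """bias = 1 - 1/(1 + f_co): relative connection-probability inflation."""
    if f_co < 0:
        raise ValueError("f_co must be nonnegative")
    return 1.0 - 1.0 / (1.0 + f_co)


# ---------------------------------------------------------------------------
# slicing-depth effect
# ---------------------------------------------------------------------------

@dataclass
class DepthSplit:
    prob_above: float      # between the surface and the recorded cell
    prob_below: float      # from the recorded cell down to twice its depth
    ratio_below_over_above: float
    strength_above_pa: float
    strength_below_pa: float


def depth_split_connectivity(maps: list[ConnectivityMap],
                             depth_axis: int = 2) -> DepthSplit:
    """Pooled connectivity in two equal-thickness shells around the
    recorded cell's depth: cells shallower than the recorded cell vs cells
    between its depth and twice its depth.  The shells differ only in
    distance from the cut surface, so their ratio measures the loss of
    connections caused by slicing."""
    n_conn = np.zeros(2)
    n_resp = np.zeros(2)
    strengths: list[list[float]] = [[], []]
    for m in maps:
        if not np.isfinite(m.recorded_depth_um):
            raise ValueError("recorded-cell depth required for every map")
        d0 = m.recorded_depth_um
        depth = m.positions_um[:, depth_axis]
        shells = [(depth >= 0) & (depth < d0),
                  (depth >= d0) & (depth < 2 * d0)]
        for i, sel in enumerate(shells):
            sel = sel & m.responsive
            n_resp[i] += sel.sum()
            n_conn[i] += (sel & m.connected).sum()
            strengths[i].extend(m.strengths_pa[sel & m.connected].tolist())
    probs = np.where(n_resp > 0, n_conn / np.maximum(n_resp, 1), np.nan)
    ratio = probs[1] / probs[0] if probs[0] > 0 else np.nan
    return DepthSplit(
        prob_above=float(probs[0]), prob_below=float(probs[1]),
        ratio_below_over_above=float(ratio),
        strength_above_pa=float(np.mean(strengths[0])) if strengths[0] else np.nan,
        strength_below_pa=float(np.mean(strengths[1])) if strengths[1] else np.nan)


# ---------------------------------------------------------------------------
# light-power compensation
# ---------------------------------------------------------------------------

def attenuation_compensation(depth_um: float,
                             tau_um: float = DEFAULT_ATTENUATION_UM) -> float:
    """Power multiplier exp(depth/tau) holding focal-point power constant
    against monoexponential light attenuation in tissue."""
    if depth_um < 0:
        raise ValueError("depth must be nonnegative")
    if tau_um <= 0:
        raise ValueError("attenuation length must be positive")
    return float(np.exp(depth_um / tau_um))
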