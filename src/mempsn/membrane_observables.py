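"""Membrane-binding observables.

* Shrake-Rupley SASA time series for a named selection (e.g. the myristoyl
  chain), with every non-solvent atom acting as an occluder, and a
  baseline-relative detector for the membrane-insertion event (the SASA drop
  from the solvated plateau to the buried level).
* Protein macrodipole projected on the membrane normal (z), in Debye.
* Time-averaged 2D number-density maps of selected species in a z-slab.
* Lateral (xy) mean-square displacement of lipid head groups per lipid type,
  with a diffusion coefficient from the Einstein relation MSD = 4Dt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import MissingChargeError, MissingRadiusError
from .trajectory_io import (
    LIPID_CLASSES,
    Topology,
    Trajectory,
    load_vdw_radii,
    minimum_image,
)

E_ANGSTROM_TO_DEBYE = 4.8032  # 1 e·Å in Debye

A2_PER_NS_TO_CM2_PER_S = 1e-7  # 1 Å²/ns = 1e-7 cm²/s


# -- SASA ------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def _radii_for(topology: Topology, indices: np.ndarray,
               vdw: dict) -> np.ndarray:
    radii = np.empty(len(indices))
    for k, i in enumerate(indices):
        atom = topology.atoms[i]
        if atom.radius is not None:
            radii[k] = atom.radius
        else:
            key = atom.element.upper()
            if key in vdw:
                radii[k] = vdw[key]
            elif "default" in {x.lower() for x in vdw}:
                radii[k] = vdw.get("DEFAULT", vdw.get("default"))
            else:
                raise MissingRadiusError(
                    f"no van der Waals radius for atom {atom.name} "
                    f"(element {atom.element}, id {atom.atom_id})"
                )
        if radii[k] <= 0:
            raise MissingRadiusError(
                f"nonpositive radius for atom {atom.name} (id {atom.atom_id})"
            )
    return radii


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    selection: np.ndarray | None = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Ų) of ``selection`` atoms,
    occluded by every atom in ``coords``.

    Test points are placed on each atom's solvent-accessible sphere
    (radius r_i + probe) and counted accessible when outside every
    neighbour's accessible sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if selection is None:
        selection = np.arange(len(coords))
    unit = sphere_points(n_sphere_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_reach = 2 * expanded.max()
    areas = np.zeros(len(selection))
    for k, i in enumerate(selection):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        neigh = tree.query_ball_point(coords[i], ri + max_reach / 2)
        neigh = [j for j in neigh if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= expanded[j]
            if not accessible.any():
                break
        areas[k] = 4.0 * np.pi * ri ** 2 * accessible.sum() / n_sphere_points
    return areas


@dataclass
class SASASeries:
    times: np.ndarray      # ns
    values: np.ndarray     # Ų, summed over the selection
    probe_radius: float
    selection_label: str = ""


def sasa_series(
    trajectory: Trajectory,
    topology: Topology,
    selection: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    occluders: str = "all",
    vdw_radii: dict | None = None,
    selection_label: str = "",
) -> SASASeries:
    """SASA of ``selection`` per frame.

    ``occluders='all'`` (default) includes every non-water, non-ion atom —
    lipids occlude an inserted acyl chain, which carries the burial signal;
    ``'protein'`` restricts occlusion to protein/myristoyl atoms.
    """
    vdw = vdw_radii or load_vdw_radii()
    selection = np.asarray(selection, dtype=int)
    if occluders == "all":
        keep_classes = {"protein", "myristoyl", *LIPID_CLASSES, "unknown"}
    elif occluders == "protein":
        keep_classes = {"protein", "myristoyl"}
    else:
        raise ValueError("occluders must be 'all' or 'protein'")
    occ_mask = np.zeros(topology.n_atoms, dtype=bool)
    for r in topology.residues:
        if r.molecule_class in keep_classes:
            occ_mask[r.atom_indices] = True
    occ_mask[selection] = True
    occ_indices = np.flatnonzero(occ_mask)
    radii = _radii_for(topology, occ_indices, vdw)
    # positions of selection atoms inside the occluder subset
    sel_pos = np.searchsorted(occ_indices, selection)
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        areas = shrake_rupley(
            trajectory.coords[f][occ_indices], radii, sel_pos,
            probe_radius=probe_radius, n_sphere_points=n_sphere_points,
        )
        values[f] = areas.sum()
    return SASASeries(trajectory.times.copy(), values, probe_radius,
                      selection_label)


# -- insertion-event detection --------------------------------------------

@dataclass
class InsertionEvent:
    start_time: float   # ns
    end_time: float     # ns
    completed: bool


def moving_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving median; window is clipped at the series edges."""
    values = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out


def detect_insertion(
    series: SASASeries,
    baseline_window: tuple[float, float] | None = None,
    low_fraction: float = 0.25,
    stable_span: float = 10.0,
    smooth_window: int = 5,
) -> InsertionEvent | None:
    """Detect a burial event in a SASA trace.

    Operational definition (all thresholds baseline-relative, so the call is
    invariant to uniform scaling of the trace):

    * baseline — median of the smoothed series over ``baseline_window``
      (ns; default the first quarter of the trace);
    * end — first time the smoothed series falls below
      ``low_fraction``·baseline and stays below it for ``stable_span`` ns;
    * start — last time before the end at which the series is still above
      (1 − ``low_fraction``)·baseline;
    * completed — the low state persists to the end of the series.

    Returns ``None`` when no stable low state exists (flat traces and
    dip-and-recover excursions are not events).
    """
    t = series.times
    s = moving_median(series.values, smooth_window)
    if baseline_window is None:
        baseline_window = (t[0], t[0] + (t[-1] - t[0]) / 4.0)
    base_mask = (t >= baseline_window[0]) & (t <= baseline_window[1])
    if not base_mask.any():
        raise ValueError("baseline window contains no frames")
    baseline = float(np.median(s[base_mask]))
    if baseline <= 0:
        return None
    low = low_fraction * baseline
    high = (1.0 - low_fraction) * baseline

    below = s < low
    end_idx = None
    final_run = False
    i, n = 0, len(s)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if t[j - 1] - t[i] >= stable_span or j == n:
                end_idx = i
                final_run = j == n
                break
            i = j
        else:
            i += 1
    if end_idx is None or end_idx == 0:
        return None  # no stable low state, or trace starts buried
    above = np.flatnonzero(s[:end_idx] >= high)
    if len(above) == 0:
        return None
    start_idx = int(above[-1])
    return InsertionEvent(float(t[start_idx]), float(t[end_idx]),
                          bool(final_run))


# -- macrodipole -----------------------------------------------------------

@dataclass
class DipoleSeries:
    times: np.ndarray   # ns
    mu_z: np.ndarray    # Debye

    @property
    def sign_reversals(self) -> int:
        signs = np.sign(self.mu_z[np.abs(self.mu_z) > 1e-12])
        return int(np.sum(signs[1:] != signs[:-1]))


def macrodipole_z(
    trajectory: Trajectory,
    topology: Topology,
    selection: np.ndarray | None = None,
    charges: np.ndarray | None = None,
    formal_charge_fallback: bool = False,
    role_map=None,
) -> DipoleSeries:
    """z-projection of the selection's dipole moment, referenced to the
    selection centroid so that net-charged proteins report an
    origin-independent value.

    ``charges`` overrides the topology's per-atom charges; with
    ``formal_charge_fallback`` missing charges are replaced by formal charges
    (±1 on charged side-chain atoms per the role map) — explicit opt-in, no
    silent fallback.
    """
    if selection is None:
        selection = topology.select_atoms(
            molecule_class=["protein", "myristoyl"]
        )
    selection = np.asarray(selection, dtype=int)
    if charges is None:
        charges = topology.charges()[selection]
    else:
        charges = np.asarray(charges, dtype=float)
        if len(charges) == topology.n_atoms:
            charges = charges[selection]
    missing = np.isnan(charges)
    if missing.any():
        if not formal_charge_fallback:
            raise MissingChargeError(
                f"{int(missing.sum())} selection atoms lack partial charges "
                "(enable formal_charge_fallback or supply charges)"
            )
        from .trajectory_io import load_role_map

        rm = role_map or load_role_map()
        charges = charges.copy()
        charges[missing] = 0.0
        for k, i in enumerate(selection):
            if not missing[k]:
                continue
            atom = topology.atoms[i]
            fc = rm.formal_charge(atom.residue_name) if \
                atom.residue_name in rm else None
            if fc and fc["atom"] == atom.name:
                charges[k] = float(fc["charge"])
    z = trajectory.coords[:, selection, 2]
    z_ref = z.mean(axis=1, keepdims=True)  # geometric centroid (bead model)
    mu_e_angstrom = ((z - z_ref) * charges[None, :]).sum(axis=1)
    return DipoleSeries(trajectory.times.copy(),
                        mu_e_angstrom * E_ANGSTROM_TO_DEBYE)


# -- 2D density maps -------------------------------------------------------

@dataclass
class DensityMap2D:
    density: np.ndarray     # (nx, ny) Å⁻³, time-averaged
    x_edges: np.ndarray
    y_edges: np.ndarray
    cell_edge: float
    z_slab: tuple[float, float]
    species: str
    n_frames: int

    @property
    def cell_volume(self) -> float:
        return self.cell_edge ** 2 * (self.z_slab[1] - self.z_slab[0])

    @property
    def total_observations(self) -> float:
        """sum(density × cell volume) × n_frames = atom-in-slab observations."""
        return float(self.density.sum() * self.cell_volume * self.n_frames)

    def maximum_position(self) -> np.ndarray:
        i, j = np.unravel_index(np.argmax(self.density), self.density.shape)
        return np.array([
            0.5 * (self.x_edges[i] + self.x_edges[i + 1]),
            0.5 * (self.y_edges[j] + self.y_edges[j + 1]),
        ])


def density_map(
    trajectory: Trajectory,
    topology: Topology,
    species_selection: np.ndarray,
    z_slab: tuple[float, float],
    cell_edge: float = 1.0,
    center_on: np.ndarray | None = None,
    species_label: str = "",
) -> DensityMap2D:
    """Time-averaged lateral number-density map of the species atoms inside a
    z-slab: atoms per cell divided by the cell volume.

    With ``center_on``, each frame is translated laterally so the centroid of
    that selection sits at the box centre (and wrapped), so the map is drawn
    in the anchor's co-moving frame.
    """
    species_selection = np.asarray(species_selection, dtype=int)
    if len(species_selection) == 0:
        raise ValueError("empty species selection")
    box = trajectory.box[0]
    nx_ = max(1, int(round(box[0] / cell_edge)))
    ny_ = max(1, int(round(box[1] / cell_edge)))
    x_edges = np.linspace(0.0, box[0], nx_ + 1)
    y_edges = np.linspace(0.0, box[1], ny_ + 1)
    if not (z_slab[0] < z_slab[1]):
        raise ValueError("z_slab must be (low, high)")
    counts = np.zeros((nx_, ny_))
    for f in range(trajectory.n_frames):
        xyz = trajectory.coords[f][species_selection].copy()
        if center_on is not None:
            centroid = trajectory.coords[f][center_on].mean(axis=0)
            shift = np.array([box[0] / 2 - centroid[0],
                              box[1] / 2 - centroid[1], 0.0])
            xyz += shift
        xyz[:, 0] %= box[0]
        xyz[:, 1] %= box[1]
        in_slab = (xyz[:, 2] >= z_slab[0]) & (xyz[:, 2] < z_slab[1])
        h, _, _ = np.histogram2d(
            xyz[in_slab, 0], xyz[in_slab, 1], bins=[x_edges, y_edges]
        )
        counts += h
    volume = cell_edge ** 2 * (z_slab[1] - z_slab[0])
    density = counts / (trajectory.n_frames * volume)
    return DensityMap2D(density, x_edges, y_edges, cell_edge,
                        tuple(z_slab), species_label, trajectory.n_frames)


# -- lateral MSD -----------------------------------------------------------

@dataclass
class MSDCurve:
    lag_times: np.ndarray       # ns
    msd: np.ndarray             # Ų
    diffusion_coefficient: float  # cm²/s
    fit_window: tuple[float, float]
    lipid_type: str
    anomalous_exponent: float    # log-log slope over the fit window

    @property
    def super_diffusive(self) -> bool:
        return self.anomalous_exponent > 1.5


def unwrap_lateral(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from lateral positions by accumulating
    minimum-image frame-to-frame displacements."""
    steps = coords[1:] - coords[:-1]
    steps = minimum_image(steps, box[1:, None, :2])
    return np.concatenate([coords[:1], coords[:1] + np.cumsum(steps, axis=0)])


def _msd_xy(positions: np.ndarray, times: np.ndarray,
            max_lag_fraction: float = 0.5):
    """MSD over all time origins for lags up to a fraction of the run."""
    n = len(positions)
    max_lag = max(1, int(n * max_lag_fraction))
    lags = np.arange(max_lag + 1)
    msd = np.zeros(len(lags))
    for li, lag in enumerate(lags[1:], start=1):
        d = positions[lag:] - positions[:-lag]
        msd[li] = np.mean(np.sum(d ** 2, axis=-1))
    return times[lags] - times[0], msd


def lateral_msd(
    trajectory: Trajectory,
    topology: Topology,
    fit_window: tuple[float, float] | None = None,
    max_lag_fraction: float = 0.5,
) -> dict[str, MSDCurve]:
    """Per-lipid-type lateral MSD, averaged over head groups of the type and
    over multiple time origins, with D = slope/4 over ``fit_window``.

    The default fit window spans 10-50% of the covered lags: the shortest
    lags are dominated by discrete-hop noise and the longest by the few,
    strongly correlated time origins available, so the middle of the curve
    gives the statistically reliable slope.
    """
    if trajectory.n_frames < 2:
        raise ValueError("MSD requires at least 2 frames")
    curves: dict[str, MSDCurve] = {}
    for lipid_class in LIPID_CLASSES:
        residues = topology.residues_of_class(lipid_class)
        if not residues:
            continue
        head_xy = np.stack([
            trajectory.coords[:, r.headgroup_indices, :2].mean(axis=1)
            for r in residues
        ], axis=1)  # (frames, lipids, 2)
        unwrapped = unwrap_lateral(head_xy, trajectory.box)
        lag_t, msd = _msd_xy(unwrapped, trajectory.times, max_lag_fraction)
        window = fit_window or (0.1 * lag_t[-1], 0.5 * lag_t[-1])
        mask = (lag_t >= window[0]) & (lag_t <= window[1]) & (lag_t > 0)
        if mask.sum() < 2:
            mask = lag_t > 0
        slope, _ = np.polyfit(lag_t[mask], msd[mask], 1)
        d_cm2_s = max(slope, 0.0) / 4.0 * A2_PER_NS_TO_CM2_PER_S
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pos = mask & (msd > 0)
            alpha = (
                np.polyfit(np.log(lag_t[pos]), np.log(msd[pos]), 1)[0]
                if pos.sum() >= 2 else 0.0
            )
        label = lipid_class.split("_")[1]
        curves[label] = MSDCurve(
            lag_t, msd, float(d_cm2_s), tuple(window), label, float(alpha)
        )
    return curves
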