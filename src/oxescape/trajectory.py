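"""Trajectory loading, binding-site geometry and per-ligand distance series.

A :class:`Trajectory` couples a PDB-derived :class:`Topology` (atom labels
plus named selections for the tracked ligands and the binding site) with a
frame-indexed coordinate array in Angstrom.  The central product of this
module is the :class:`DistanceSeries`: for every analysis frame, the
distance between a tracked ligand's centre of mass and the binding-site
centre of mass, optionally block-averaged ("binned") from a finer raw frame
spacing.

File handling is delegated to MDAnalysis: the topology must be a PDB, and
coordinates may come from a multi-model PDB, a plain XYZ frame file, or any
binary container MDAnalysis understands.  Text formats carry no time
metadata, so the raw frame interval must be given explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

# Average atomic masses (u) keyed by element symbol.  Only elements that
# plausibly occur in protein/ligand PDB files are listed; anything else
# falls back to carbon with a warning.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}

_FALLBACK_MASS = 12.0

# Two-letter symbols that a bare leading character would mis-read.
_TWO_LETTER = {"CL", "BR", "FE", "ZN", "MG", "NA", "MN", "CU", "NI", "CO", "SE"}


def element_from_atom_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    PDB atom names lead with the element (possibly offset by digits, e.g.
    ``1HB``).  Two-letter metals/halogens are recognised explicitly so that
    ``CA`` stays calcium only when it cannot be an alpha-carbon; in protein
    context ``CA``/``CB``/... are carbons, so the single-letter reading wins
    unless the full stripped name is a known two-letter symbol.
    """
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        return ""
    if stripped in _TWO_LETTER:
        return stripped
    return stripped[0]


def mass_of(atom_name: str, element: str = "") -> float:
    sym = element.upper().strip() or element_from_atom_name(atom_name)
    if sym in ELEMENT_MASSES:
        return ELEMENT_MASSES[sym]
    logger.warning("unresolvable element for atom name %r; using %.1f u",
                   atom_name, _FALLBACK_MASS)
    return _FALLBACK_MASS


@dataclass
class Topology:
    """Atom labels plus the named selections the analysis needs.

    ``ligand_selectors`` maps each tracked-ligand id to the atom indices of
    that ligand; ``site_selector`` holds the indices of the binding-site
    selection (e.g. the FAD isoalloxazine ring).  ``site_selectors`` may
    override the site per ligand — in a dimer each tracked molecule is
    referenced to its own monomer's site.
    """

    atom_ids: np.ndarray
    atom_names: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    ligand_selectors: dict[str, np.ndarray] = field(default_factory=dict)
    site_selector: np.ndarray | None = None
    site_selectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(np.unique(self.atom_ids)) != len(self.atom_ids):
            raise DataError("topology atom ids are not unique")
        for name, idx in self.ligand_selectors.items():
            if len(idx) == 0:
                raise ConfigError(f"ligand selector {name!r} matches no atoms")
        if self.site_selector is not None and len(self.site_selector) == 0:
            raise ConfigError("site selector matches no atoms")
        site = set() if self.site_selector is None else set(self.site_selector.tolist())
        for name, idx in self.ligand_selectors.items():
            if site & set(idx.tolist()):
                raise ConfigError(
                    f"ligand selector {name!r} overlaps the site selector")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def masses(self, indices: np.ndarray | None = None) -> np.ndarray:
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        return np.array([mass_of(self.atom_names[i], self.elements[i]) for i in idx])

    def site_for(self, ligand_id: str) -> np.ndarray:
        """Site selection for a given ligand (per-ligand override or global)."""
        if ligand_id in self.site_selectors:
            return self.site_selectors[ligand_id]
        if self.site_selector is None:
            raise ConfigError("no binding-site selection configured")
        return self.site_selector

    def heavy_atom_indices(self) -> np.ndarray:
        elems = [
            self.elements[i].upper().strip() or element_from_atom_name(self.atom_names[i])
            for i in range(self.n_atoms)
        ]
        return np.array([i for i, e in enumerate(elems) if e not in ("H", "D")],
                        dtype=np.intp)


@dataclass
class Trajectory:
    """Frame-indexed coordinates (Angstrom) bound to a topology."""

    topology: Topology
    times: np.ndarray          # ns, strictly increasing
    coords: np.ndarray         # (n_frames, n_atoms, 3) Angstrom

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise DataError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise DataError("times and coords disagree on frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise DataError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise DataError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def frame_interval_ns(self) -> float:
        if self.n_frames < 2:
            raise DataError("frame interval undefined for a single-frame trajectory")
        return float(self.times[1] - self.times[0])


@dataclass
class DistanceSeries:
    """Per-analysis-frame ligand-to-site distance for one tracked ligand."""

    ligand_id: str
    frame_interval_ns: float
    values: np.ndarray                     # Angstrom
    replicate_id: str = ""
    variant_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_interval_ns <= 0:
            raise DataError("frame interval must be positive")
        if np.any(self.values < 0):
            raise DataError("distances must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns


def _resolve(universe, selection: str) -> np.ndarray:
    group = universe.select_atoms(selection)
    if len(group) == 0:
        raise ConfigError(f"selection {selection!r} matches no atoms")
    return group.ix.astype(np.intp)


def load_trajectory(
    topology_path: str | Path,
    coords_path: str | Path | None = None,
    *,
    frame_interval_ns: float | None = None,
    ligand_selections: dict[str, str] | None = None,
    site_selection: str | None = None,
    site_selections: dict[str, str] | None = None,
) -> Trajectory:
    """Read a PDB topology plus a coordinate time series into a Trajectory.

    Selections use the MDAnalysis selection language (e.g.
    ``"resname OXY and resid 900"``).  ``frame_interval_ns`` is mandatory
    for text coordinate formats (PDB models, XYZ), which carry no physical
    time; binary containers supply their own frame times.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise DataError(f"topology file not found: {topology_path}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            top_only = mda.Universe(str(topology_path))
        except Exception as exc:  # pragma: no cover - format zoo
            raise DataError(
                f"could not parse topology {topology_path} as PDB: {exc}") from exc

    n_top = len(top_only.atoms)
    if coords_path is None:
        universe = top_only
    else:
        coords_path = Path(coords_path)
        if not coords_path.exists():
            raise DataError(f"coordinate file not found: {coords_path}")
        if coords_path.suffix.lower() == ".xyz":
            with open(coords_path) as fh:
                first = fh.readline().split()
            n_xyz = int(first[0]) if first else 0
            if n_xyz != n_top:
                raise DataError(
                    f"atom count mismatch: topology has {n_top} atoms, "
                    f"coordinate file has {n_xyz}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                universe = mda.Universe(str(topology_path), str(coords_path))
            except ValueError as exc:
                raise DataError(
                    f"atom count mismatch between {topology_path} and "
                    f"{coords_path}: {exc}") from exc
            except Exception as exc:
                raise DataError(
                    f"unreadable coordinate file {coords_path} (expected "
                    f"multi-model PDB, XYZ frame blocks, or an MDAnalysis-"
                    f"supported container): {exc}") from exc

    text_coords = coords_path is None or coords_path.suffix.lower() in (
        ".pdb", ".ent", ".xyz", ".crd")
    if frame_interval_ns is None:
        if text_coords:
            raise ConfigError(
                "frame_interval_ns is required: text coordinate formats "
                "carry no time metadata")
        times = np.array([ts.time for ts in universe.trajectory]) / 1000.0  # ps->ns
    else:
        times = np.arange(len(universe.trajectory)) * float(frame_interval_ns)

    coords = np.empty((len(universe.trajectory), n_top, 3))
    for i, ts in enumerate(universe.trajectory):
        coords[i] = ts.positions

    atoms = universe.atoms
    try:
        chain_ids = atoms.chainIDs
    except AttributeError:
        chain_ids = np.array([""] * n_top)
    try:
        elements = atoms.elements
    except AttributeError:
        elements = np.array([""] * n_top)

    topo = Topology(
        atom_ids=atoms.ids.copy(),
        atom_names=atoms.names.copy(),
        residue_ids=atoms.resids.copy(),
        residue_names=atoms.resnames.copy(),
        chain_ids=np.asarray(chain_ids).copy(),
        elements=np.asarray(elements).copy(),
        ligand_selectors={k: _resolve(universe, v)
                          for k, v in (ligand_selections or {}).items()},
        site_selector=(None if site_selection is None
                       else _resolve(universe, site_selection)),
        site_selectors={k: _resolve(universe, v)
                        for k, v in (site_selections or {}).items()},
    )
    return Trajectory(topology=topo, times=times, coords=coords)


def center_of_mass(traj: Trajectory, indices: np.ndarray, frame: int) -> np.ndarray:
    masses = traj.topology.masses(indices)
    return np.average(traj.coords[frame, indices], axis=0, weights=masses)


def site_center(traj: Trajectory, frame: int, ligand_id: str | None = None) -> np.ndarray:
    """Mass-weighted centre of the binding-site selection at one frame."""
    if ligand_id is None:
        if traj.topology.site_selector is None:
            raise ConfigError("no binding-site selection configured")
        idx = traj.topology.site_selector
    else:
        idx = traj.topology.site_for(ligand_id)
    return center_of_mass(traj, idx, frame)


def bin_series(values: np.ndarray, bin_factor: int) -> np.ndarray:
    """Block-mean consecutive groups of ``bin_factor`` samples.

    A trailing partial block is dropped.  ``bin_factor=1`` is the identity.
    """
    values = np.asarray(values, dtype=float)
    if bin_factor < 1:
        raise ConfigError("bin_factor must be >= 1")
    if bin_factor > len(values):
        raise DataError(
            f"bin_factor {bin_factor} exceeds series length {len(values)}")
    n = (len(values) // bin_factor) * bin_factor
    return values[:n].reshape(-1, bin_factor).mean(axis=1)


def distance_series(
    traj: Trajectory,
    ligand_id: str,
    bin_factor: int = 1,
    *,
    replicate_id: str = "",
    variant_label: str = "",
) -> DistanceSeries:
    """Per-frame ligand-COM to site-COM distance, block-binned.

    The binding-site centre is re-evaluated every raw frame, so the series
    is invariant to rigid-body motion of the whole system.
    """
    topo = traj.topology
    if ligand_id not in topo.ligand_selectors:
        raise ConfigError(f"unknown ligand id {ligand_id!r}")
    lig_idx = topo.ligand_selectors[ligand_id]
    site_idx = topo.site_for(ligand_id)

    m_lig = topo.masses(lig_idx)
    m_site = topo.masses(site_idx)
    lig_com = np.einsum("fij,i->fj", traj.coords[:, lig_idx], m_lig) / m_lig.sum()
    site_com = np.einsum("fij,i->fj", traj.coords[:, site_idx], m_site) / m_site.sum()
    raw = np.linalg.norm(lig_com - site_com, axis=1)

    binned = bin_series(raw, bin_factor)
    if traj.n_frames >= 2:
        raw_dt = traj.frame_interval_ns
    else:
        raw_dt = 1.0  # single frame: interval is nominal
    return DistanceSeries(
        ligand_id=ligand_id,
        frame_interval_ns=raw_dt * bin_factor,
        values=binned,
        replicate_id=replicate_id,
        variant_label=variant_label,
    )


def rmsd_series(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """Per-frame RMSD of a selection against frame 0 after rigid superposition.

    Optimal rotation by the Kabsch procedure (via scipy's ``align_vectors``),
    unweighted, after removing the centroids.  Frame 0 gives exactly 0.
    """
    selection = np.asarray(selection, dtype=np.intp)
    if len(selection) < 3:
        raise DataError("RMSD superposition needs at least 3 atoms")
    ref = traj.coords[0, selection]
    ref_c = ref - ref.mean(axis=0)
    out = np.empty(traj.n_frames)
    n = len(selection)
    for f in range(traj.n_frames):
        mob = traj.coords[f, selection]
        mob_c = mob - mob.mean(axis=0)
        _, rssd = Rotation.align_vectors(ref_c, mob_c)
        out[f] = rssd / np.sqrt(n)
    out[0] = 0.0
    return out


# ---------------------------------------------------------------------------
# Tabular output

_SERIES_COLUMNS = ["variant", "replicate", "ligand", "frame", "time_ns", "distance_A"]


def series_to_frame(series_list: list[DistanceSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        rows.append(pd.DataFrame({
            "variant": s.variant_label,
            "replicate": s.replicate_id,
            "ligand": s.ligand_id,
            "frame": np.arange(s.n_frames),
            "time_ns": s.times_ns,
            "distance_A": s.values,
        }))
    return pd.concat(rows, ignore_index=True)[_SERIES_COLUMNS]


def write_distance_series(series_list: list[DistanceSeries], path: str | Path) -> None:
    series_to_frame(series_list).to_csv(path, sep="\t", index=False,
                                        float_format="%.6g")


def read_distance_series(path: str | Path) -> list[DistanceSeries]:
    df = pd.read_csv(path, sep="\t", dtype={"variant": str, "replicate": str,
                                            "ligand": str})
    out = []
    for (variant, rep, lig), grp in df.groupby(
            ["variant", "replicate", "ligand"], sort=False):
        grp = grp.sort_values("frame")
        if len(grp) < 2:
            raise DataError("cannot infer frame interval from a 1-row series")
        dt = float(np.diff(grp["time_ns"].to_numpy())[0])
        out.append(DistanceSeries(
            ligand_id=str(lig), frame_interval_ns=dt,
            values=grp["distance_A"].to_numpy(),
            replicate_id=str(rep), variant_label=str(variant)))
    return out
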