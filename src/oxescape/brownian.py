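"""Seeded Brownian-dynamics generator for cavity-plus-tunnel escape problems.

The generator stands in for all-atom MD of a buried small molecule: a
point ligand performs an overdamped random walk inside a spherical cavity
from which straight cylindrical tunnels lead to solvent.  Cavity and
tunnel walls reflect; each tunnel's outer end is an absorbing plane whose
first crossing is the ground-truth escape (time and exit tunnel).  Static
"pseudo-residue" spheres line the cavity and tunnel walls so that the
contact/occupancy analysis has labelled geometry to rank.

Only the first-passage structure matters to the analysis layer, so the
dynamics are position-Langevin (no inertia, no interactions): per step the
displacement is isotropic Gaussian with sigma = sqrt(2 D dt).  Reflection
is a single specular fold per violated surface; the time step must keep
sigma below a third of the narrowest tunnel radius so multi-fold events
are negligible.  After absorption the walk continues force-free in
solvent, so recorded trajectories show the escaped ligand drifting away —
which is what the persistence-based detector needs to see.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numba import njit

from .channels import ChannelDefinition, write_channels
from .errors import ConfigError, DataError, NumericalError

# Defaults emulating the study design: a ~8 A active-site cavity, escape
# tunnels as long as the mean channel length (16.31 A, measured from the
# site centre), a narrow/wide tunnel-radius pair for the variant contrast,
# and O2-like diffusivity.
DEFAULT_CAVITY_RADIUS_A = 8.0
DEFAULT_TUNNEL_LENGTH_A = 16.31
DEFAULT_NARROW_RADIUS_A = 1.5
DEFAULT_WIDE_FACTOR = 2.0
DEFAULT_DIFFUSION_A2_PER_NS = 20.0
DEFAULT_TIMESTEP_NS = 1e-4
DEFAULT_FRAME_INTERVAL_NS = 0.2

LIGAND_RESNAME = "OXY"
SITE_RESNAME = "FAD"
SITE_RESID = 999


@dataclass(frozen=True)
class Tunnel:
    tunnel_id: str
    direction: tuple[float, float, float]
    length_A: float
    radius_A: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-8:
            raise ConfigError(f"tunnel {self.tunnel_id!r} direction not unit-norm")
        if self.length_A <= 0 or self.radius_A <= 0:
            raise ConfigError("tunnel length and radius must be positive")


@dataclass(frozen=True)
class PseudoResidue:
    chain: str
    resid: int
    resname: str
    center: tuple[float, float, float]
    radius_A: float
    lining: str          # "cavity", a tunnel_id, or "site"
    mutated: bool = False


@dataclass
class CavityGeometry:
    cavity_radius_A: float
    tunnels: list[Tunnel]
    pseudo_residues: list[PseudoResidue] = field(default_factory=list)
    mutations: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cavity_radius_A < 0:
            raise ConfigError("cavity radius must be non-negative")
        ids = [t.tunnel_id for t in self.tunnels]
        if len(set(ids)) != len(ids):
            raise ConfigError("tunnel ids are not unique")
        for t in self.tunnels:
            if t.length_A <= self.cavity_radius_A:
                raise ConfigError(
                    f"tunnel {t.tunnel_id!r} must extend past the cavity "
                    f"(length {t.length_A} <= radius {self.cavity_radius_A})")

    def min_tunnel_radius(self) -> float:
        return min(t.radius_A for t in self.tunnels)

    def arrays(self):
        dirs = np.ascontiguousarray([t.direction for t in self.tunnels],
                                    dtype=np.float64)
        lengths = np.array([t.length_A for t in self.tunnels], dtype=np.float64)
        radii = np.array([t.radius_A for t in self.tunnels], dtype=np.float64)
        return dirs, lengths, radii

    def contains(self, points: np.ndarray, tol: float = 1e-6,
                 include_escaped: bool = True) -> np.ndarray:
        """Boolean per point: inside cavity, inside a tunnel, or (by
        default) beyond an absorbing plane within the tunnel bore
        (escaped).  With ``include_escaped=False`` only the confined
        region counts."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        r2 = np.einsum("ij,ij->i", p, p)
        ok = r2 <= (self.cavity_radius_A + tol) ** 2
        for t in self.tunnels:
            d = np.asarray(t.direction)
            s = p @ d
            rho2 = r2 - s ** 2
            in_bore = (s >= -tol) & (rho2 <= (t.radius_A + tol) ** 2)
            if not include_escaped:
                in_bore &= s <= t.length_A + tol
            ok |= in_bore
        return ok


@dataclass(frozen=True)
class LigandDynamics:
    diffusion_A2_per_ns: float = DEFAULT_DIFFUSION_A2_PER_NS
    timestep_ns: float = DEFAULT_TIMESTEP_NS
    max_time_ns: float = 100.0
    frame_interval_ns: float = DEFAULT_FRAME_INTERVAL_NS
    seed: int = 0
    start: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.timestep_ns, self.max_time_ns, self.frame_interval_ns) <= 0:
            raise ConfigError("dynamics parameters must be positive")
        if self.diffusion_A2_per_ns < 0:
            raise ConfigError("diffusion coefficient must be non-negative")

    @property
    def step_sigma_A(self) -> float:
        return math.sqrt(2.0 * self.diffusion_A2_per_ns * self.timestep_ns)


# ---------------------------------------------------------------------------
# Geometry construction


def _orthonormal_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _build_lining(cavity_radius: float, tunnels: list[Tunnel],
                  mutated_positions: dict[tuple[str, int], str] | None = None,
                  n_cavity: int = 40, ring_spacing_A: float = 2.5,
                  n_per_ring: int = 6) -> list[PseudoResidue]:
    """Static spheres decorating the cavity surface and tunnel walls.

    Tunnel residues sit one Angstrom outside the bore so that a ligand in
    transit is within van-der-Waals contact distance of the local ring — a
    narrow tunnel is side-chain-lined, so its marker atoms hug the surface.
    Cavity markers stand three Angstrom behind the wall, the typical
    CA-backbone standoff of a cavity surface, so only a wall-hugging ligand
    registers cavity contacts.  Cavity points that would fall inside a
    tunnel mouth are skipped so the cavity class stays clean for occupancy
    comparisons.
    """
    mutated_positions = mutated_positions or {}
    residues: list[PseudoResidue] = []

    # cavity lining
    pts = _fibonacci_sphere(n_cavity) * (cavity_radius + 3.0)
    resid = 1
    for p in pts:
        near_mouth = False
        for t in tunnels:
            d = np.asarray(t.direction)
            s = p @ d
            rho = math.sqrt(max((p @ p) - s * s, 0.0))
            if 0 <= s <= t.length_A + 4 and rho < t.radius_A + 3.0:
                near_mouth = True
                break
        if near_mouth:
            continue
        residues.append(PseudoResidue("A", resid, "CAV", tuple(p), 1.5, "cavity"))
        resid += 1

    # tunnel linings
    for k, t in enumerate(tunnels):
        d = np.asarray(t.direction)
        u, v = _orthonormal_frame(d)
        base = 500 + 100 * k
        i = 0
        s = max(cavity_radius - 1.0, ring_spacing_A)
        wall = t.radius_A + 1.0
        while s <= t.length_A + 1e-9:
            for j in range(n_per_ring):
                ang = 2 * np.pi * j / n_per_ring + (0.5 if i % 2 else 0.0)
                c = s * d + wall * (np.cos(ang) * u + np.sin(ang) * v)
                key = ("A", base + i * n_per_ring + j)
                label = mutated_positions.get(key)
                if label is not None:
                    # mutated positions get their own resid so reports can
                    # address them; resname marks them as engineered
                    residues.append(PseudoResidue(
                        "A", int(label_resid(label)), "MUT", tuple(c), 1.5,
                        t.tunnel_id, mutated=True))
                else:
                    residues.append(PseudoResidue(
                        "A", base + i * n_per_ring + j, f"TN{k + 1}",
                        tuple(c), 1.5, t.tunnel_id))
            i += 1
            s += ring_spacing_A
    return residues


def label_resid(label: str) -> int:
    """Residue number embedded in a mutation label like ``F210L`` -> 210."""
    digits = "".join(c for c in label if c.isdigit())
    if not digits:
        raise ConfigError(f"mutation label {label!r} has no residue number")
    return int(digits)


def default_geometry(cavity_radius_A: float = DEFAULT_CAVITY_RADIUS_A,
                     tunnel_length_A: float = DEFAULT_TUNNEL_LENGTH_A,
                     tunnel_radius_A: float = DEFAULT_NARROW_RADIUS_A,
                     n_tunnels: int = 2) -> CavityGeometry:
    """Two-tunnel cavity emulating a primary/secondary substrate channel pair."""
    axes = [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0),
            (0.0, 0.0, 1.0), (-1.0, 0.0, 0.0)]
    names = ["primary", "secondary", "alternate_1", "alternate_2"]
    tunnels = [Tunnel(names[i], axes[i], tunnel_length_A, tunnel_radius_A)
               for i in range(n_tunnels)]
    lining = _build_lining(cavity_radius_A, tunnels)
    return CavityGeometry(cavity_radius_A, tunnels, lining)


#: Mutation labels marking the widened-tunnel lining in the wide variant,
#: echoing the substrate-channel substitutions of the evolved enzyme.
WIDE_VARIANT_MUTATIONS = ["F210L", "L213T", "M242Q"]


def make_variant_pair(base: CavityGeometry | None = None,
                      wide_factor: float = DEFAULT_WIDE_FACTOR
                      ) -> tuple[CavityGeometry, CavityGeometry]:
    """Narrow/wide geometry pair differing only in tunnel radii.

    The wide variant's primary-tunnel lining carries three positions
    relabelled as engineered mutations, mirroring a variant whose widened
    substrate channel is lined by its exclusive substitutions.
    """
    if wide_factor <= 1:
        raise ConfigError("wide_factor must exceed 1")
    narrow = base if base is not None else default_geometry()
    wide_tunnels = [replace(t, radius_A=t.radius_A * wide_factor)
                    for t in narrow.tunnels]
    # mark three mid-tunnel lining positions of the first tunnel as mutated
    primary_first = 500
    mutated = {("A", primary_first + i * 6): lab  # first sphere of rings 0..2
               for i, lab in enumerate(WIDE_VARIANT_MUTATIONS)}
    wide_lining = _build_lining(narrow.cavity_radius_A, wide_tunnels, mutated)
    wide = CavityGeometry(
        narrow.cavity_radius_A, wide_tunnels, wide_lining,
        mutations=[("A", label_resid(lab), lab)
                   for lab in WIDE_VARIANT_MUTATIONS])
    return narrow, wide


def channels_for(geom: CavityGeometry) -> list[ChannelDefinition]:
    """Channel definitions matching the generated tunnel linings."""
    out = []
    for t in geom.tunnels:
        members = [(r.chain, r.resid) for r in geom.pseudo_residues
                   if r.lining == t.tunnel_id]
        out.append(ChannelDefinition(t.tunnel_id, members, t.length_A))
    return out


# ---------------------------------------------------------------------------
# The Brownian stepper


@njit(cache=True)
def _classify(qx, qy, qz, R2, dirs, lengths, radii):
    """0 inside; t+1 beyond tunnel t's absorbing plane; -1 outside."""
    q2 = qx * qx + qy * qy + qz * qz
    if q2 <= R2:
        return 0
    for t in range(dirs.shape[0]):
        s = qx * dirs[t, 0] + qy * dirs[t, 1] + qz * dirs[t, 2]
        if s >= 0.0:
            rho2 = q2 - s * s
            if rho2 <= radii[t] * radii[t]:
                if s >= lengths[t]:
                    return t + 1
                return 0
    return -1


@njit(cache=True)
def _bd_walk(seed, x0, y0, z0, R, dirs, lengths, radii, sigma,
             n_steps, record_every, stop_on_escape):
    np.random.seed(seed)
    n_rec = n_steps // record_every
    frames = np.empty((n_rec, 3))
    px, py, pz = x0, y0, z0
    R2 = R * R
    escape_step = -1
    exit_tunnel = -1
    escaped = False
    rec = 0
    for step in range(1, n_steps + 1):
        if escaped and stop_on_escape:
            break
        qx = px + np.random.normal(0.0, sigma)
        qy = py + np.random.normal(0.0, sigma)
        qz = pz + np.random.normal(0.0, sigma)
        if escaped:
            px, py, pz = qx, qy, qz
        else:
            c = _classify(qx, qy, qz, R2, dirs, lengths, radii)
            if c < 0:
                # reflect off the wall of the region holding the current point
                p2 = px * px + py * py + pz * pz
                if p2 <= R2:
                    # fold radially across the cavity sphere
                    qn = math.sqrt(qx * qx + qy * qy + qz * qz)
                    f = (2.0 * R - qn) / qn if qn > 0 else 0.0
                    qx *= f
                    qy *= f
                    qz *= f
                else:
                    # current point is inside some tunnel bore
                    tt = -1
                    for t in range(dirs.shape[0]):
                        s = px * dirs[t, 0] + py * dirs[t, 1] + pz * dirs[t, 2]
                        if s >= 0.0 and p2 - s * s <= radii[t] * radii[t]:
                            tt = t
                            break
                    if tt >= 0:
                        dxd, dyd, dzd = dirs[tt, 0], dirs[tt, 1], dirs[tt, 2]
                        s = qx * dxd + qy * dyd + qz * dzd
                        ex = qx - s * dxd
                        ey = qy - s * dyd
                        ez = qz - s * dzd
                        rho = math.sqrt(ex * ex + ey * ey + ez * ez)
                        r = radii[tt]
                        if rho > r and rho > 0.0:
                            g = (2.0 * r - rho) / rho
                            ex *= g
                            ey *= g
                            ez *= g
                        if s < 0.0:
                            s = -s
                        qx = s * dxd + ex
                        qy = s * dyd + ey
                        qz = s * dzd + ez
                c = _classify(qx, qy, qz, R2, dirs, lengths, radii)
            if c == 0:
                px, py, pz = qx, qy, qz
            elif c > 0:
                escaped = True
                escape_step = step
                exit_tunnel = c - 1
                px, py, pz = qx, qy, qz
            # c < 0 after the single fold: reject the step, stay put
        if step % record_every == 0:
            frames[rec, 0] = px
            frames[rec, 1] = py
            frames[rec, 2] = pz
            rec += 1
    # hold the final position for any frames not reached (early stop)
    for k in range(rec, n_rec):
        frames[k, 0] = px
        frames[k, 1] = py
        frames[k, 2] = pz
    return frames, escape_step, exit_tunnel


@dataclass
class SimResult:
    """One ligand's Brownian trajectory plus generator ground truth."""

    positions: np.ndarray          # (n_frames, 3) recorded at frame_interval
    frame_interval_ns: float
    escape_time_ns: float | None
    exit_tunnel_id: str | None
    seed: int

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(len(self.positions)) * self.frame_interval_ns

    @property
    def distances_A(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)


def simulate_ligand(geom: CavityGeometry, dyn: LigandDynamics,
                    stop_on_escape: bool = False) -> SimResult:
    """Run one seeded Brownian walk until absorption or ``max_time_ns``.

    Ground truth is the first crossing of any tunnel's absorbing plane;
    afterwards the walk continues unconfined so the recorded trajectory
    shows the ligand in solvent.  Identical seeds give identical output.
    """
    sigma = dyn.step_sigma_A
    rmin = geom.min_tunnel_radius()
    if sigma >= rmin / 3.0:
        good_dt = (rmin / 3.0) ** 2 / (2.0 * dyn.diffusion_A2_per_ns)
        raise NumericalError(
            f"step sigma {sigma:.3g} A exceeds a third of the narrowest "
            f"tunnel radius {rmin:.3g} A; use timestep_ns < {good_dt:.3g}")
    start = np.asarray(dyn.start, dtype=float)
    if not geom.contains(start[None, :], include_escaped=False)[0]:
        raise ConfigError("start position lies outside the geometry")

    n_steps = int(round(dyn.max_time_ns / dyn.timestep_ns))
    record_every = max(int(round(dyn.frame_interval_ns / dyn.timestep_ns)), 1)
    dirs, lengths, radii = geom.arrays()
    frames, escape_step, exit_tunnel = _bd_walk(
        dyn.seed, start[0], start[1], start[2], geom.cavity_radius_A,
        dirs, lengths, radii, sigma, n_steps, record_every, stop_on_escape)
    return SimResult(
        positions=frames,
        frame_interval_ns=dyn.frame_interval_ns,
        escape_time_ns=(escape_step * dyn.timestep_ns
                        if escape_step >= 0 else None),
        exit_tunnel_id=(geom.tunnels[exit_tunnel].tunnel_id
                        if exit_tunnel >= 0 else None),
        seed=dyn.seed,
    )


def first_passage_times(geom: CavityGeometry, dyn: LigandDynamics,
                        n_seeds: int, base_seed: int = 0) -> np.ndarray:
    """Ground-truth escape times over consecutive seeds (NaN = censored)."""
    out = np.empty(n_seeds)
    # first-passage statistics need no frames: record sparsely, stop at escape
    fast = replace(dyn, frame_interval_ns=dyn.max_time_ns)
    for i in range(n_seeds):
        res = simulate_ligand(geom, replace(fast, seed=(base_seed + i) % 2**31),
                              stop_on_escape=True)
        out[i] = np.nan if res.escape_time_ns is None else res.escape_time_ns
    return out


def trajectory_from_sim(geom: CavityGeometry, sims: list[SimResult],
                        replicate_id: str = "", variant_label: str = ""):
    """Build an in-memory Trajectory from simulated ligand paths.

    Pseudo-residues become static CA carbons, the binding site a small
    carbon triad at the origin, each ligand a single oxygen; identical to
    what the PDB/XYZ bundle round-trips through :func:`load_trajectory`,
    minus the files.
    """
    from .trajectory import Topology, Trajectory

    if not sims:
        raise DataError("no simulated ligands supplied")
    n_frames = len(sims[0].positions)
    if any(len(s.positions) != n_frames for s in sims):
        raise DataError("simulated ligands disagree on frame count")

    site_atoms = np.array([(0.5, 0.0, 0.0), (-0.25, 0.433, 0.0),
                           (-0.25, -0.433, 0.0)])
    static = np.array([r.center for r in geom.pseudo_residues]
                      ).reshape(-1, 3)
    n_static = len(static)
    n_atoms = n_static + 3 + len(sims)

    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, :n_static] = static
    coords[:, n_static:n_static + 3] = site_atoms
    for j, s in enumerate(sims):
        coords[:, n_static + 3 + j] = s.positions

    names, resids, resnames, chains, elems = [], [], [], [], []
    for r in geom.pseudo_residues:
        names.append("CA")
        resids.append(r.resid)
        resnames.append(r.resname)
        chains.append(r.chain)
        elems.append("C")
    for j in range(3):
        names.append(f"C{j + 1}")
        resids.append(SITE_RESID)
        resnames.append(SITE_RESNAME)
        chains.append("A")
        elems.append("C")
    for j in range(len(sims)):
        names.append("O1")
        resids.append(901 + j)
        resnames.append(LIGAND_RESNAME)
        chains.append("L")
        elems.append("O")

    topo = Topology(
        atom_ids=np.arange(1, n_atoms + 1),
        atom_names=np.array(names),
        residue_ids=np.array(resids),
        residue_names=np.array(resnames),
        chain_ids=np.array(chains),
        elements=np.array(elems),
        ligand_selectors={f"O2_{j + 1}": np.array([n_static + 3 + j])
                          for j in range(len(sims))},
        site_selector=np.arange(n_static, n_static + 3),
    )
    times = np.arange(n_frames) * sims[0].frame_interval_ns
    return Trajectory(topology=topo, times=times, coords=coords)


def degenerate_tunnel_geometry(length_A: float = DEFAULT_TUNNEL_LENGTH_A,
                               radius_A: float = DEFAULT_NARROW_RADIUS_A
                               ) -> CavityGeometry:
    """Single tunnel with a vanishing cavity: the 1-D reflecting/absorbing
    limit whose mean first-passage time is L^2 / (2 D)."""
    t = Tunnel("only", (0.0, 0.0, 1.0), length_A, radius_A)
    return CavityGeometry(1e-3, [t], [])


# ---------------------------------------------------------------------------
# Replicate design and fixture bundles


@dataclass(frozen=True)
class ReplicateDesign:
    """Per-variant replicate layout: durations, tracked ligands, frame spacing."""

    durations_ns: tuple[float, ...] = (200.0, 200.0, 200.0, 100.0, 100.0, 100.0)
    ligands_per_replicate: int = 2
    frame_interval_ns: float = DEFAULT_FRAME_INTERVAL_NS

    def frames_per_variant(self, time_scale: float = 1.0) -> int:
        """Pooled analysis-frame count across replicates and ligands."""
        per_rep = [int(round(d * time_scale / self.frame_interval_ns))
                   for d in self.durations_ns]
        return self.ligands_per_replicate * int(sum(per_rep))


def _child_seed(base: int, variant_i: int, rep_i: int, lig_i: int) -> int:
    return (base * 1_000_003 + variant_i * 10_007 + rep_i * 101 + lig_i) % 2**31


def _write_topology_pdb(geom: CavityGeometry, n_ligands: int,
                        path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    site_atoms = [(0.5, 0.0, 0.0), (-0.25, 0.433, 0.0), (-0.25, -0.433, 0.0)]
    n = len(geom.pseudo_residues) + len(site_atoms) + n_ligands
    arr = struc.AtomArray(n)
    coords = []
    i = 0
    for r in geom.pseudo_residues:
        arr.chain_id[i] = r.chain
        arr.res_id[i] = r.resid
        arr.res_name[i] = r.resname
        arr.atom_name[i] = "CA"
        arr.element[i] = "C"
        arr.hetero[i] = False
        coords.append(r.center)
        i += 1
    for j, c in enumerate(site_atoms):
        arr.chain_id[i] = "A"
        arr.res_id[i] = SITE_RESID
        arr.res_name[i] = SITE_RESNAME
        arr.atom_name[i] = f"C{j + 1}"
        arr.element[i] = "C"
        arr.hetero[i] = True
        coords.append(c)
        i += 1
    for j in range(n_ligands):
        arr.chain_id[i] = "L"
        arr.res_id[i] = 901 + j
        arr.res_name[i] = LIGAND_RESNAME
        arr.atom_name[i] = "O1"
        arr.element[i] = "O"
        arr.hetero[i] = True
        coords.append((0.0, 0.0, 0.0))
        i += 1
    arr.coord = np.asarray(coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def _write_xyz(path: Path, static_xyz: np.ndarray, static_elems: list[str],
               ligand_frames: list[np.ndarray]) -> None:
    """Plain XYZ frame blocks: static pseudo-protein plus moving ligands."""
    n_frames = ligand_frames[0].shape[0]
    n_atoms = len(static_xyz) + len(ligand_frames)
    with open(path, "w") as fh:
        for f in range(n_frames):
            fh.write(f"{n_atoms}\nframe {f}\n")
            for e, (x, y, z) in zip(static_elems, static_xyz):
                fh.write(f"{e} {x:.4f} {y:.4f} {z:.4f}\n")
            for lig in ligand_frames:
                x, y, z = lig[f]
                fh.write(f"O {x:.4f} {y:.4f} {z:.4f}\n")


def make_fixture_set(
    variants: dict[str, CavityGeometry],
    out_dir: str | Path,
    seed: int,
    design: ReplicateDesign = ReplicateDesign(),
    time_scale: float = 1.0,
    dynamics: LigandDynamics = LigandDynamics(),
) -> dict:
    """Write a full study bundle: topology, trajectories, ground truth.

    Per variant the replicate layout of ``design`` is simulated at
    ``time_scale`` (1.0 = full study durations), each replicate tracking
    ``ligands_per_replicate`` independent ligands from the cavity centre.
    Returns the manifest (also written as ``manifest.json``).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out_dir}: {exc}") from exc

    manifest = {
        "seed": int(seed),
        "time_scale": time_scale,
        "design": {
            "durations_ns": list(design.durations_ns),
            "ligands_per_replicate": design.ligands_per_replicate,
            "frame_interval_ns": design.frame_interval_ns,
        },
        "dynamics": {
            "diffusion_A2_per_ns": dynamics.diffusion_A2_per_ns,
            "timestep_ns": dynamics.timestep_ns,
        },
        "site_selection": f"resname {SITE_RESNAME}",
        "variants": {},
    }

    for vi, (label, geom) in enumerate(variants.items()):
        vdir = out_dir / label
        vdir.mkdir(exist_ok=True)
        n_lig = design.ligands_per_replicate
        _write_topology_pdb(geom, n_lig, vdir / "topology.pdb")
        write_channels(channels_for(geom), vdir / "channels.yaml")

        static_xyz = np.array(
            [r.center for r in geom.pseudo_residues]
            + [(0.5, 0.0, 0.0), (-0.25, 0.433, 0.0), (-0.25, -0.433, 0.0)])
        static_elems = ["C"] * len(static_xyz)

        events = []
        replicate_files = []
        for ri, dur in enumerate(design.durations_ns):
            lig_frames = []
            for li in range(n_lig):
                dyn = replace(
                    dynamics,
                    max_time_ns=dur * time_scale,
                    frame_interval_ns=design.frame_interval_ns,
                    seed=_child_seed(seed, vi, ri, li),
                )
                res = simulate_ligand(geom, dyn)
                lig_frames.append(res.positions)
                events.append({
                    "replicate": f"rep{ri + 1}",
                    "ligand": f"O2_{li + 1}",
                    "escape_time_ns": res.escape_time_ns,
                    "tunnel_id": res.exit_tunnel_id,
                })
            fname = f"rep{ri + 1}.xyz"
            _write_xyz(vdir / fname, static_xyz, static_elems, lig_frames)
            replicate_files.append(fname)

        with open(vdir / "ground_truth.json", "w") as fh:
            json.dump({"variant": label, "events": events}, fh, indent=1)

        manifest["variants"][label] = {
            "directory": label,
            "topology": "topology.pdb",
            "replicates": replicate_files,
            "channels": "channels.yaml",
            "ground_truth": "ground_truth.json",
            "ligand_selections": {
                f"O2_{li + 1}": f"resname {LIGAND_RESNAME} and resid {901 + li}"
                for li in range(n_lig)},
            "mutations": [list(m) for m in geom.mutations],
        }

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
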