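"""Exit-channel assignment and residue-contact occupancy ranking.

Channels are user-supplied residue lists (the field's tunnel catalogues,
e.g. CAVER output, reduce to exactly this).  For each escape the ligand's
pre-escape contacts are counted per residue — a contact is a frame in which
the minimum ligand-to-heavy-atom distance falls within a cutoff — and the
escape is assigned to the channel whose member residues accumulate the
largest summed occupancy.  The same table yields the top-k residue ranking
and a per-mutation presence report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .escape import EscapeEvent
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF_A = 4.0
#: Time before the escape excursion start included in the exit window.
DEFAULT_LEAD_IN_NS = 5.0


@dataclass
class ChannelDefinition:
    """A named exit pathway given as the residues lining it."""

    channel_id: str
    residues: list[tuple[str, int]]          # (chain, resid)
    avg_length_A: float | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ConfigError(f"channel {self.channel_id!r} has no residues")

    @property
    def unique_residues(self) -> set[tuple[str, int]]:
        return set(self.residues)


def _parse_residue(spec) -> tuple[str, int]:
    if isinstance(spec, dict):
        return str(spec["chain"]), int(spec["resid"])
    parts = str(spec).split(":")
    if len(parts) < 2:
        raise ConfigError(f"residue spec {spec!r} is not 'chain:resid'")
    return parts[0], int(parts[1])


def load_channels(path: str | Path) -> list[ChannelDefinition]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    channels = []
    for entry in doc.get("channels", []):
        channels.append(ChannelDefinition(
            channel_id=str(entry["id"]),
            residues=[_parse_residue(r) for r in entry["residues"]],
            avg_length_A=(float(entry["avg_length_A"])
                          if entry.get("avg_length_A") is not None else None),
        ))
    ids = [c.channel_id for c in channels]
    if len(set(ids)) != len(ids):
        raise ConfigError("channel ids are not unique")
    if not channels:
        raise ConfigError(f"no channels defined in {path}")
    return channels


def write_channels(channels: list[ChannelDefinition], path: str | Path) -> None:
    doc = {"channels": [
        {"id": c.channel_id,
         "residues": [f"{ch}:{ri}" for ch, ri in c.residues],
         "avg_length_A": c.avg_length_A}
        for c in channels]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class ContactTable:
    """Per-residue contact occupancy counts over an analysis window."""

    table: pd.DataFrame        # chain, resid, resname, occupancy
    ligand_id: str = ""
    replicate_id: str = ""
    n_frames: int = 0
    cutoff_A: float = DEFAULT_CONTACT_CUTOFF_A

    def occupancy_of(self, chain: str, resid: int) -> int:
        hit = self.table[(self.table["chain"] == chain)
                         & (self.table["resid"] == resid)]
        return int(hit["occupancy"].iloc[0]) if len(hit) else 0

    def merged(self, other: "ContactTable") -> "ContactTable":
        """Sum occupancies residue-wise across tables (replicate pooling)."""
        combined = (pd.concat([self.table, other.table])
                    .groupby(["chain", "resid", "resname"], as_index=False)
                    ["occupancy"].sum())
        return ContactTable(table=combined, ligand_id="pooled",
                            replicate_id="pooled",
                            n_frames=self.n_frames + other.n_frames,
                            cutoff_A=self.cutoff_A)


def residue_contacts(
    traj: Trajectory,
    ligand_id: str,
    window: tuple[int, int],
    contact_cutoff_A: float = DEFAULT_CONTACT_CUTOFF_A,
) -> ContactTable:
    """Occupancy per residue over ``window`` = (start, stop) frame range.

    A residue is "in contact" on a frame when the minimum distance between
    any ligand atom and any of its heavy atoms is at most the cutoff.
    Hydrogens are ignored; ligand atoms are excluded from the residue pool.
    """
    if contact_cutoff_A <= 0:
        raise ConfigError("contact cutoff must be positive")
    start, stop = window
    start, stop = int(start), int(stop)
    start = max(start, 0)
    stop = min(stop, traj.n_frames)
    if stop <= start:
        raise DataError(f"empty contact window ({start}, {stop})")

    topo = traj.topology
    lig_idx = topo.ligand_selectors.get(ligand_id)
    if lig_idx is None:
        raise ConfigError(f"unknown ligand id {ligand_id!r}")
    all_lig = np.concatenate(list(topo.ligand_selectors.values()))
    heavy = topo.heavy_atom_indices()
    prot = np.setdiff1d(heavy, all_lig)
    if len(prot) == 0:
        raise DataError("no heavy protein atoms to compute contacts against")

    # order protein atoms by residue so per-residue minima reduce contiguously
    keys = [(topo.chain_ids[i], int(topo.residue_ids[i])) for i in prot]
    order = sorted(range(len(prot)), key=lambda k: keys[k])
    prot = prot[order]
    keys = [keys[k] for k in order]
    boundaries = [0] + [i for i in range(1, len(keys)) if keys[i] != keys[i - 1]]
    res_keys = [keys[b] for b in boundaries]
    res_names = [str(topo.residue_names[prot[b]]) for b in boundaries]
    boundaries = np.asarray(boundaries, dtype=np.intp)

    counts = np.zeros(len(res_keys), dtype=np.intp)
    cut = float(contact_cutoff_A)
    for f in range(start, stop):
        lig_xyz = traj.coords[f, lig_idx]            # (nl, 3)
        prot_xyz = traj.coords[f, prot]              # (np, 3)
        d = np.linalg.norm(prot_xyz[None, :, :] - lig_xyz[:, None, :], axis=2)
        per_atom_min = d.min(axis=0)
        per_res_min = np.minimum.reduceat(per_atom_min, boundaries)
        counts += per_res_min <= cut

    table = pd.DataFrame({
        "chain": [c for c, _ in res_keys],
        "resid": [r for _, r in res_keys],
        "resname": res_names,
        "occupancy": counts,
    })
    table = table[table["occupancy"] > 0].reset_index(drop=True)
    return ContactTable(table=table, ligand_id=ligand_id,
                        replicate_id="", n_frames=stop - start,
                        cutoff_A=cut)


def assign_channel(event: EscapeEvent, contacts: ContactTable,
                   channels: list[ChannelDefinition]) -> str:
    """Channel whose member residues have the largest summed occupancy.

    Duplicated residue entries within a channel count once.  Ties go to the
    earlier channel in the list (logged); zero contact everywhere returns
    ``"unassigned"``.
    """
    if not channels:
        raise ConfigError("at least one channel must be defined")
    sums = []
    for ch in channels:
        total = sum(contacts.occupancy_of(c, r) for c, r in ch.unique_residues)
        sums.append(total)
    best = int(np.argmax(sums))
    if sums[best] == 0:
        event.channel_id = "unassigned"
        return "unassigned"
    if sums.count(sums[best]) > 1:
        logger.warning("channel tie (%s); keeping first in config order",
                       ", ".join(c.channel_id for c, s in zip(channels, sums)
                                 if s == sums[best]))
    event.channel_id = channels[best].channel_id
    return event.channel_id


def top_residues(contacts: ContactTable, k: int) -> pd.DataFrame:
    """Top-k residues by occupancy; ties broken by (chain, resid)."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    ranked = contacts.table.sort_values(
        ["occupancy", "chain", "resid"],
        ascending=[False, True, True]).reset_index(drop=True)
    ranked = ranked.head(k).copy()
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


def mutation_report(contacts: ContactTable,
                    mutations: list[tuple[str, int, str]],
                    k: int = 25,
                    topology_residues: set[tuple[str, int]] | None = None) -> dict:
    """Presence of each mutated position in the top-k occupancy ranking.

    ``mutations`` holds (chain, resid, label) triples, e.g.
    ``("A", 246, "I246T")``.  A position absent from the topology is
    reported with ``in_topology: false`` and a warning.
    """
    if not mutations:
        raise ConfigError("mutation set must be non-empty")
    top = top_residues(contacts, k)
    top_keys = {(row.chain, int(row.resid)): int(row.rank)
                for row in top.itertuples()}
    report = {}
    for chain, resid, label in mutations:
        in_topo = (topology_residues is None
                   or (chain, resid) in topology_residues)
        if not in_topo:
            logger.warning("mutated position %s (%s:%d) absent from topology",
                           label, chain, resid)
        occ = contacts.occupancy_of(chain, resid)
        rank = top_keys.get((chain, resid))
        report[label] = {
            "chain": chain,
            "resid": resid,
            "in_topology": in_topo,
            "occupancy": occ,
            "in_top_k": rank is not None,
            "rank": rank,
        }
    return report
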