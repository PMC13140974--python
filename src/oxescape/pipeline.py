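"""End-to-end analysis of a trajectory bundle.

Drives the full chain per variant: load topology + replicate coordinate
files, build per-ligand distance series, detect escapes, compute contact
occupancy over each escape's exit window, assign exit channels, and emit
summary statistics, cumulative escape curves, pooled distance histograms
and the mutation presence report.  Both the CLI and the acceptance checks
run through this module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import (ChannelDefinition, ContactTable, assign_channel,
                       load_channels, mutation_report, residue_contacts,
                       top_residues, DEFAULT_CONTACT_CUTOFF_A,
                       DEFAULT_LEAD_IN_NS)
from .errors import DataError
from .escape import (EscapeCriterion, EscapeEvent, EscapeSummary,
                     cumulative_escape_curve, detect_escape,
                     distance_histogram, events_to_frame, summarize_escapes)
from .trajectory import (DistanceSeries, Trajectory, distance_series,
                         load_trajectory, write_distance_series)

logger = logging.getLogger(__name__)


@dataclass
class VariantResult:
    variant_label: str
    summary: EscapeSummary
    events: list[EscapeEvent | None]
    labels: list[tuple[str, str, str]]          # (variant, replicate, ligand)
    series: list[DistanceSeries]
    contacts: ContactTable | None               # pooled over escapes
    curve_grid_ns: np.ndarray
    curve_counts: np.ndarray
    histogram: object
    mutations: dict | None = None
    ground_truth: dict | None = None


def exit_window(event: EscapeEvent, bin_factor: int, lead_in_ns: float,
                frame_interval_ns: float) -> tuple[int, int]:
    """Raw-frame window from ``lead_in_ns`` before the excursion start
    through the escape frame (inclusive)."""
    lead_frames = int(round(lead_in_ns / frame_interval_ns))
    start = max(event.escape_frame - lead_frames, 0) * bin_factor
    stop = (event.escape_frame + 1) * bin_factor
    return start, stop


def analyze_variant(
    label: str,
    topology_path: Path,
    replicate_paths: list[Path],
    ligand_selections: dict[str, str],
    site_selection: str,
    channels: list[ChannelDefinition],
    frame_interval_ns: float,
    crit: EscapeCriterion = EscapeCriterion(),
    contact_cutoff_A: float = DEFAULT_CONTACT_CUTOFF_A,
    lead_in_ns: float = DEFAULT_LEAD_IN_NS,
    bin_factor: int = 1,
    per_channel_thresholds: bool = False,
    mutations: list[tuple[str, int, str]] | None = None,
) -> VariantResult:
    events: list[EscapeEvent | None] = []
    labels: list[tuple[str, str, str]] = []
    all_series: list[DistanceSeries] = []
    pooled: ContactTable | None = None
    max_time = 0.0

    for rep_i, coords_path in enumerate(replicate_paths):
        rep_id = f"rep{rep_i + 1}"
        traj = load_trajectory(
            topology_path, coords_path,
            frame_interval_ns=frame_interval_ns,
            ligand_selections=ligand_selections,
            site_selection=site_selection)
        for lig_id in ligand_selections:
            series = distance_series(traj, lig_id, bin_factor,
                                     replicate_id=rep_id, variant_label=label)
            max_time = max(max_time, series.n_frames * series.frame_interval_ns)
            all_series.append(series)
            event = detect_escape(series, crit)
            labels.append((label, rep_id, lig_id))
            if event is None:
                events.append(None)
                continue
            start, stop = exit_window(event, bin_factor, lead_in_ns,
                                      series.frame_interval_ns)
            contacts = residue_contacts(traj, lig_id, (start, stop),
                                        contact_cutoff_A)
            assign_channel(event, contacts, channels)
            if per_channel_thresholds and event.channel_id not in (
                    None, "unassigned"):
                ch = next(c for c in channels
                          if c.channel_id == event.channel_id)
                if ch.avg_length_A is not None:
                    redetected = detect_escape(
                        series, EscapeCriterion(ch.avg_length_A,
                                                crit.persistence_ns))
                    if redetected is not None:
                        redetected.channel_id = event.channel_id
                        event = redetected
            events.append(event)
            pooled = contacts if pooled is None else pooled.merged(contacts)

    summary = summarize_escapes(events, label)
    grid = np.arange(0.0, max_time + frame_interval_ns * bin_factor,
                     frame_interval_ns * bin_factor)
    curve = cumulative_escape_curve(events, grid)
    hist = distance_histogram(all_series, threshold_A=crit.threshold_A)
    mut_report = None
    if mutations and pooled is not None:
        mut_report = mutation_report(pooled, mutations)
    return VariantResult(
        variant_label=label, summary=summary, events=events, labels=labels,
        series=all_series, contacts=pooled, curve_grid_ns=grid,
        curve_counts=curve, histogram=hist, mutations=mut_report)


def analyze_bundle(
    bundle_dir: str | Path,
    out_dir: str | Path | None = None,
    crit: EscapeCriterion = EscapeCriterion(),
    contact_cutoff_A: float = DEFAULT_CONTACT_CUTOFF_A,
    lead_in_ns: float = DEFAULT_LEAD_IN_NS,
    bin_factor: int = 1,
    per_channel_thresholds: bool = False,
) -> dict[str, VariantResult]:
    """Analyze every variant of a generated (or equivalent) bundle.

    The bundle layout is the one ``make_fixture_set`` writes: a
    ``manifest.json`` naming per-variant topology, replicate coordinate
    files, channels YAML and optional ground truth.
    """
    bundle_dir = Path(bundle_dir)
    manifest_path = bundle_dir / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest.json under {bundle_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    results: dict[str, VariantResult] = {}
    for label, vinfo in manifest["variants"].items():
        vdir = bundle_dir / vinfo["directory"]
        channels = load_channels(vdir / vinfo["channels"])
        mutations = [tuple(m) for m in vinfo.get("mutations", [])] or None
        res = analyze_variant(
            label,
            topology_path=vdir / vinfo["topology"],
            replicate_paths=[vdir / f for f in vinfo["replicates"]],
            ligand_selections=vinfo["ligand_selections"],
            site_selection=manifest["site_selection"],
            channels=channels,
            frame_interval_ns=manifest["design"]["frame_interval_ns"],
            crit=crit, contact_cutoff_A=contact_cutoff_A,
            lead_in_ns=lead_in_ns, bin_factor=bin_factor,
            per_channel_thresholds=per_channel_thresholds,
            mutations=mutations)
        gt_path = vdir / vinfo.get("ground_truth", "ground_truth.json")
        if gt_path.exists():
            with open(gt_path) as fh:
                res.ground_truth = json.load(fh)
        results[label] = res
        logger.info("%s: %d/%d escaped, mean %s ns", label,
                    res.summary.n_escaped, res.summary.n_tracked,
                    f"{res.summary.mean_escape_time_ns:.2f}"
                    if res.summary.mean_escape_time_ns is not None else "n/a")

    if out_dir is not None:
        write_results(results, out_dir)
    return results


def write_results(results: dict[str, VariantResult],
                  out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for label, res in results.items():
        vdir = out_dir / label
        vdir.mkdir(exist_ok=True)
        events_to_frame(res.events, res.labels).to_csv(
            vdir / "events.tsv", sep="\t", index=False)
        with open(vdir / "summary.json", "w") as fh:
            json.dump({
                "variant": label,
                "n_tracked": res.summary.n_tracked,
                "n_escaped": res.summary.n_escaped,
                "mean_escape_time_ns": res.summary.mean_escape_time_ns,
                "escape_times_ns": res.summary.escape_times,
            }, fh, indent=1)
        pd.DataFrame({"time_ns": res.curve_grid_ns,
                      "cumulative_escapes": res.curve_counts}).to_csv(
            vdir / "cumulative_curve.tsv", sep="\t", index=False)
        h = res.histogram
        pd.DataFrame({"bin_left_A": h.bin_edges_A[:-1],
                      "bin_right_A": h.bin_edges_A[1:],
                      "count": h.counts}).to_csv(
            vdir / "distance_histogram.tsv", sep="\t", index=False)
        write_distance_series(res.series, vdir / "distance_series.tsv")
        if res.contacts is not None:
            top_residues(res.contacts, len(res.contacts.table)).to_csv(
                vdir / "contacts.tsv", sep="\t", index=False)
        if res.mutations is not None:
            with open(vdir / "mutation_report.json", "w") as fh:
                json.dump(res.mutations, fh, indent=1)
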