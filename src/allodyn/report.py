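"""Pipeline orchestration: run every applicable stage and merge the verdicts.

A ligand-binding perturbation is convincing when independent observables
agree.  `run_pipeline` executes whichever stages the configuration provides
inputs for — pairwise distance fluctuations and strain from apo/holo
trajectories, CSP and intensity changes from peak tables, exchange flags
and model-free order parameters from relaxation tables — classifies each
residue per stage, and reports the consensus set of residues flagged by at
least `consensus_min_stages` independent stages (default 2).

The report is a pure function of inputs and configuration: no timestamps,
keys sorted, input files identified by content hash.
"""

from __future__ import annotations

import hashlib
import logging
import time

import numpy as np

from . import __version__
from .core_io import (
    ResidueRange,
    read_peak_table,
    read_relaxation_table,
    read_trajectory,
    write_matrix,
    write_report,
)
from .fluctuation import call_perturbed_regions, difference_matrix, distance_fluctuation_matrix
from .modelfree import fit_dataset
from .nmr import csp, csp_significance, ephogsy_classify, exchange_flags, intensity_change
from .regions import significance_threshold
from .strain import average_strain_profile, neighbor_map, strain_hotspots, strain_series

log = logging.getLogger("allodyn")

__all__ = ["PipelineError", "ConfigError", "run_pipeline", "annotate_regions"]

DEFAULTS = {
    "range": None,          # required when trajectories or relaxation present
    "atom": "CA",
    "format": "auto",
    "cutoff": 8.0,
    "window": 50,
    "k": 1.0,
    "min_len": 3,
    "alpha": 0.154,
    "criterion": "AIC",
    "up_thr": 1.5,
    "down_thr": 0.67,
    "consensus_min_stages": 2,
}


class ConfigError(ValueError):
    """Invalid or insufficient pipeline configuration (exit code 2)."""


class PipelineError(RuntimeError):
    """A stage failed while running (exit code 3); carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _params(config: dict) -> dict:
    p = dict(DEFAULTS)
    p.update(config.get("parameters", {}))
    return p


def _region_list(calls) -> list[dict]:
    return [
        {"first": c.range.first, "last": c.range.last,
         "direction": c.direction, "score": round(c.score, 9)}
        for c in calls
    ]


def _residues_of(calls) -> set[int]:
    out: set[int] = set()
    for c in calls:
        out.update(range(c.range.first, c.range.last + 1))
    return out


def run_pipeline(config: dict, outdir: str | None = None) -> dict:
    """Run all stages for which the config names inputs; return the report.

    config = {"inputs": {...paths...}, "parameters": {...}}.  Recognised
    inputs: apo_trajectory/holo_trajectory (each {"path": ..., "format":
    ..., optional "topology"}), apo_peaks/holo_peaks, apo_relaxation/
    holo_relaxation, hydration {apo_noe, apo_roe, holo_noe, holo_roe}.
    Artifacts (matrices, profiles) are written under `outdir` when given.
    """
    inputs = config.get("inputs") or {}
    if not inputs:
        raise ConfigError("configuration names no inputs")
    p = _params(config)
    stages: dict[str, dict] = {}
    flagged: dict[str, set[int]] = {}
    provenance = {"tool": "allodyn", "version": __version__, "inputs": {},
                  "parameters": {k: v for k, v in p.items()}}

    def input_path(entry) -> str:
        return entry["path"] if isinstance(entry, dict) else entry

    for name, entry in inputs.items():
        if name == "hydration":
            for sub, path in entry.items():
                provenance["inputs"][f"hydration.{sub}"] = _sha256(path)
        else:
            provenance["inputs"][name] = _sha256(input_path(entry))

    rng = ResidueRange.parse(p["range"]) if p["range"] else None

    # --- MD stages -------------------------------------------------------
    if "apo_trajectory" in inputs and "holo_trajectory" in inputs:
        if rng is None:
            raise ConfigError("trajectory analysis requires parameters.range")
        try:
            t0 = time.perf_counter()
            trajs = {}
            for state in ("apo", "holo"):
                entry = inputs[f"{state}_trajectory"]
                entry = entry if isinstance(entry, dict) else {"path": entry}
                trajs[state] = read_trajectory(
                    entry["path"], format=entry.get("format", p["format"]),
                    selection=entry.get("selection", p["atom"]),
                    topology=entry.get("topology"))
            dfs = {s: distance_fluctuation_matrix(t, rng) for s, t in trajs.items()}
            diff = difference_matrix(dfs["holo"], dfs["apo"])
            calls = call_perturbed_regions(diff, k=p["k"], min_len=p["min_len"])
            stages["distance_fluctuation"] = {
                "regions": _region_list(calls),
                "n_frames": {s: m.n_frames for s, m in dfs.items()},
            }
            flagged["distance_fluctuation"] = _residues_of(calls)
            if outdir:
                for s, m in dfs.items():
                    write_matrix(m.values, m.residue_ids, f"{outdir}/df_{s}.tsv")
                write_matrix(diff.values, diff.residue_ids, f"{outdir}/df_diff.tsv")
            log.info("distance_fluctuation done in %.1fs", time.perf_counter() - t0)

            t0 = time.perf_counter()
            profiles = {}
            for state, traj in trajs.items():
                nmap = neighbor_map(traj, cutoff=p["cutoff"], rng=rng)
                window = min(p["window"], traj.select_range(rng).n_frames)
                series = strain_series(traj, nmap, window=window, rng=rng)
                profiles[state] = average_strain_profile(series)
            hot = strain_hotspots(profiles["apo"], profiles["holo"],
                                  k=p["k"], min_len=p["min_len"])
            stages["strain"] = {"hotspots": _region_list(hot)}
            flagged["strain"] = _residues_of(hot)
            if outdir:
                import pandas as pd
                for s, prof in profiles.items():
                    pd.DataFrame({"residue": prof.residue_ids,
                                  "strain": prof.values}).to_csv(
                        f"{outdir}/strain_{s}.tsv", sep="\t", index=False,
                        float_format="%.12g")
            log.info("strain done in %.1fs", time.perf_counter() - t0)
        except (ConfigError, PipelineError):
            raise
        except Exception as exc:
            raise PipelineError("trajectory", exc) from exc

    # --- peak-table stages ----------------------------------------------
    if "apo_peaks" in inputs and "holo_peaks" in inputs:
        try:
            apo = read_peak_table(input_path(inputs["apo_peaks"]))
            holo = read_peak_table(input_path(inputs["holo_peaks"]))
            records = csp_significance(csp(apo, holo, alpha=p["alpha"]))
            sig = sorted(r.residue for r in records if r.significant)
            stages["csp"] = {
                "alpha": p["alpha"],
                "significant_residues": sig,
                "max_combined_ppm": round(max(r.combined for r in records), 9),
            }
            flagged["csp"] = set(sig)
            changes = intensity_change(apo, holo, up_thr=p["up_thr"],
                                       down_thr=p["down_thr"])
            moved = sorted(c.residue for c in changes
                           if c.category in ("increased", "decreased",
                                             "disappeared", "appeared"))
            stages["intensity"] = {
                "changed_residues": moved,
                "by_class": {
                    cls: sorted(c.residue for c in changes if c.category == cls)
                    for cls in ("increased", "decreased", "disappeared", "appeared")
                },
            }
            flagged["intensity"] = set(moved)
        except Exception as exc:
            raise PipelineError("peaks", exc) from exc

    # --- relaxation stages ----------------------------------------------
    if "apo_relaxation" in inputs or "holo_relaxation" in inputs:
        try:
            datasets = {}
            for state in ("apo", "holo"):
                key = f"{state}_relaxation"
                if key in inputs:
                    datasets[state] = read_relaxation_table(input_path(inputs[key]))
            ex_flags = {}
            for state, ds in datasets.items():
                if np.isfinite(ds.data["R1rho"]).any():
                    ex_flags[state] = {f.residue for f in exchange_flags(ds, k=p["k"])
                                       if f.flagged}
            if ex_flags:
                stages["exchange"] = {s: sorted(v) for s, v in ex_flags.items()}
                if len(ex_flags) == 2:
                    flagged["exchange"] = ex_flags["apo"] ^ ex_flags["holo"]
                else:
                    flagged["exchange"] = next(iter(ex_flags.values()))
            if rng is not None and len(datasets) == 2:
                fits = {s: fit_dataset(ds, rng, criterion=p["criterion"])
                        for s, ds in datasets.items()}
                common = sorted(
                    {f.residue for f in fits["apo"].residues if f.converged}
                    & {f.residue for f in fits["holo"].residues if f.converged})
                s2 = {s: {f.residue: f.params.S2 for f in fits[s].residues}
                      for s in fits}
                delta = np.array([s2["holo"][r] - s2["apo"][r] for r in common])
                thr = significance_threshold(delta, 1.0)
                moved = {r for r, d in zip(common, delta) if abs(d) > thr}
                stages["modelfree"] = {
                    s: {"tau_m_ns": round(fits[s].tau_m, 6),
                        "s2_mean": round(fits[s].s2_mean, 6),
                        "s2_sd": round(fits[s].s2_sd, 6),
                        "flexibility_threshold": round(fits[s].flexibility_threshold, 6),
                        "flexible_residues": fits[s].flexible_residues}
                    for s in fits}
                stages["modelfree"]["delta_s2_flagged"] = sorted(moved)
                flagged["modelfree"] = moved
            elif rng is not None and len(datasets) == 1:
                state, ds = next(iter(datasets.items()))
                fit = fit_dataset(ds, rng, criterion=p["criterion"])
                stages["modelfree"] = {
                    state: {"tau_m_ns": round(fit.tau_m, 6),
                            "s2_mean": round(fit.s2_mean, 6),
                            "s2_sd": round(fit.s2_sd, 6),
                            "flexibility_threshold": round(fit.flexibility_threshold, 6),
                            "flexible_residues": fit.flexible_residues}}
        except Exception as exc:
            raise PipelineError("relaxation", exc) from exc

    # --- hydration -------------------------------------------------------
    if "hydration" in inputs:
        try:
            h = inputs["hydration"]
            recs = ephogsy_classify(
                read_peak_table(h["apo_noe"]), read_peak_table(h["apo_roe"]),
                read_peak_table(h["holo_noe"]), read_peak_table(h["holo_roe"]))
            changed = sorted(r.residue for r in recs if r.noe_changed or r.roe_changed)
            stages["hydration"] = {
                "changed_residues": changed,
                "water_proximal": sorted(r.residue for r in recs if r.water_proximal),
            }
            flagged["hydration"] = set(changed)
        except Exception as exc:
            raise PipelineError("hydration", exc) from exc

    if not stages:
        raise ConfigError("inputs given but no runnable stage combination")

    counts: dict[int, int] = {}
    for residues in flagged.values():
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
    consensus = sorted(r for r, c in counts.items()
                       if c >= p["consensus_min_stages"])

    report = {
        "stages": stages,
        "per_residue_stage_counts": {str(r): c for r, c in sorted(counts.items())},
        "consensus_residues": consensus,
        "consensus_min_stages": p["consensus_min_stages"],
        "provenance": provenance,
    }
    if outdir:
        write_report(report, f"{outdir}/report.json")
    return report


def annotate_regions(report: dict, annotations: list[tuple[int, int, str]]) -> dict:
    """Attach labels like 'b10-b12 loop' to residue ranges in the report.

    `annotations` is a list of (first, last, label); overlapping ranges all
    contribute their labels.  Region entries of every stage gain a 'labels'
    list; the report itself gains an 'annotations' section.
    """
    out = dict(report)
    out["annotations"] = [
        {"first": int(a), "last": int(b), "label": str(lab)}
        for a, b, lab in annotations
    ]

    def labels_for(first: int, last: int) -> list[str]:
        return [lab for a, b, lab in annotations
                if int(a) <= last and first <= int(b)]

    stages = {}
    for name, stage in report.get("stages", {}).items():
        stage = dict(stage)
        for key in ("regions", "hotspots"):
            if key in stage:
                stage[key] = [
                    {**seg, "labels": labels_for(seg["first"], seg["last"])}
                    for seg in stage[key]
                ]
        stages[name] = stage
    out["stages"] = stages
    return out


def read_annotations(path: str) -> list[tuple[int, int, str]]:
    """TSV with columns first, last, label (header optional)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("first", "start"):
                continue
            if len(parts) < 3:
                raise ValueError(f"annotation line needs 'first<TAB>last<TAB>label': {line!r}")
            out.append((int(parts[0]), int(parts[1]), parts[2]))
    return out
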