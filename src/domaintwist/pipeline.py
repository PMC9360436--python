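"""End-to-end runs driven by a single YAML/JSON config.

Every command is a pure function of (config, input files): reruns with the
same inputs produce byte-identical outputs.  Each run writes its outputs
plus a JSON sidecar log recording the package version, a hash of the
resolved config, selection atom counts and per-stage wall times, and echoes
the resolved config into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import ContactCriteria, compare_networks, contacts_to_frame, find_contacts, residue_network
from .populations import DEFAULT_THRESHOLD_DEG, bootstrap_ci, population_fractions
from .rotation import AngleSeries, build_reference, trajectory_angles
from .structure import AtomSelection, read_pdb, resolve_selection, write_pdb
from .synthetic import (
    SyntheticConfig,
    build_two_domain_structure,
    domain_selections,
    make_reference_pair,
    simulate_trajectory,
)

__all__ = [
    "load_config",
    "run_simulate",
    "run_angle",
    "run_populations",
    "run_contacts",
    "run_compare_contacts",
]

DEFAULT_ROLLING_WINDOW = 51


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — YAML is a superset) run config."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return config


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _selection(config: dict, key: str) -> AtomSelection:
    try:
        block = config["selections"][key]
    except KeyError as exc:
        raise ValueError(f"config is missing selections.{key}") from exc
    return AtomSelection.from_dict(block)


def _criteria(config: dict) -> ContactCriteria:
    block = config.get("contact_criteria", {})
    return ContactCriteria(**block)


class _Log:
    def __init__(self, command: str, config: dict) -> None:
        self.data: dict[str, Any] = {
            "tool": "domaintwist",
            "version": __version__,
            "command": command,
            "config_hash": _config_hash(config),
            "stages": [],
        }
        self._t0 = time.perf_counter()

    def stage(self, name: str, **info: Any) -> None:
        now = time.perf_counter()
        self.data["stages"].append({"stage": name, "elapsed_s": round(now - self._t0, 4), **info})
        self._t0 = now

    def write(self, out_dir: Path, name: str) -> None:
        (out_dir / name).write_text(json.dumps(self.data, indent=2) + "\n")


def _out_dir(config: dict) -> Path:
    out = Path(config.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    return out


def _echo_config(config: dict, out_dir: Path, stem: str) -> None:
    (out_dir / f"{stem}.config.json").write_text(
        json.dumps(config, indent=2, sort_keys=True, default=str) + "\n"
    )


def run_simulate(config: dict) -> dict[str, Path]:
    """Generate a synthetic system: references, trajectory, ground truth.

    Writes ``inactive.pdb``, ``active.pdb``, ``trajectory.pdb``, a
    ground-truth TSV (``frame, state, theta_deg``) and a config echo.
    """
    out_dir = _out_dir(config)
    log = _Log("simulate", config)
    block = dict(config.get("simulate", {}))
    if "seed" in config and "seed" not in block:
        block["seed"] = int(config["seed"])
    schedule = block.pop("schedule", None)
    for tuple_key in ("axis", "basin_means_deg"):
        if tuple_key in block:
            block[tuple_key] = tuple(block[tuple_key])
    syn_cfg = SyntheticConfig(**block)
    structure = build_two_domain_structure(syn_cfg)
    inactive, active = make_reference_pair(structure, syn_cfg)
    ensemble, truth = simulate_trajectory((inactive, active), syn_cfg, schedule=schedule)
    log.stage("simulate", n_frames=ensemble.n_frames, n_atoms=ensemble.n_atoms)

    paths = {
        "inactive": out_dir / "inactive.pdb",
        "active": out_dir / "active.pdb",
        "trajectory": out_dir / "trajectory.pdb",
        "ground_truth": out_dir / "ground_truth.tsv",
    }
    write_pdb(inactive, paths["inactive"])
    write_pdb(active, paths["active"])
    write_pdb(ensemble, paths["trajectory"])
    pd.DataFrame(
        {"frame": np.arange(len(truth.theta_deg)), "state": truth.state, "theta_deg": truth.theta_deg}
    ).to_csv(paths["ground_truth"], sep="\t", index=False, float_format="%.6f")
    n_sel, c_sel = domain_selections(syn_cfg)
    config.setdefault("selections", {})
    config["selections"].setdefault(
        "n_domain", {"label": n_sel.label, "chain": "A", "ranges": [list(r) for r in n_sel.residue_ranges], "atoms": ["CA"]}
    )
    config["selections"].setdefault(
        "c_domain", {"label": c_sel.label, "chain": "A", "ranges": [list(r) for r in c_sel.residue_ranges], "atoms": ["CA"]}
    )
    _echo_config(config, out_dir, "simulate")
    log.stage("write", output_dir=str(out_dir))
    log.write(out_dir, "simulate.log.json")
    return paths


def _load_reference(config: dict):
    inactive = read_pdb(config["inactive"]).get_frame(0)
    active = read_pdb(config["active"]).get_frame(0)
    n_sel = _selection(config, "n_domain")
    c_sel = _selection(config, "c_domain")
    return build_reference(inactive, active, n_sel, c_sel)


def _trajectory_paths(config: dict) -> list[Path]:
    if "trajectories" in config:
        return [Path(p) for p in config["trajectories"]]
    if "trajectory" in config:
        return [Path(config["trajectory"])]
    raise ValueError("config needs a 'trajectory' path or a 'trajectories' list")


def run_angle(config: dict) -> list[AngleSeries]:
    """Compute per-frame twist angles for each configured trajectory.

    Writes one ``angles_<run>.csv`` per trajectory with columns
    ``run_id,frame,angle_deg,rmsd_A,angle_deg_rolling``.
    """
    out_dir = _out_dir(config)
    log = _Log("angle", config)
    for key in ("inactive", "active"):
        if key not in config:
            raise ValueError(f"config is missing the {key!r} structure path")
    reference = _load_reference(config)
    log.stage(
        "reference",
        theta_ref_deg=reference.theta_ref_deg,
        n_atoms_n_selection=int(len(resolve_selection(reference.inactive, reference.n_selection))),
        n_atoms_c_selection=int(len(resolve_selection(reference.inactive, reference.c_selection))),
    )
    window = int(config.get("rolling_window", DEFAULT_ROLLING_WINDOW))
    series_list = []
    for path in _trajectory_paths(config):
        ensemble = read_pdb(path)
        stride = int(config.get("stride", 1))
        if stride > 1:
            ensemble.frames = ensemble.frames[::stride]
        series = trajectory_angles(ensemble, reference)
        effective_window = min(window, len(series) if len(series) % 2 == 1 else len(series) - 1)
        df = series.to_frame(rolling_window=effective_window)
        csv_path = out_dir / f"angles_{path.stem}.csv"
        df.to_csv(csv_path, index=False, float_format="%.6f")
        series_list.append(series)
        log.stage("angles", run=path.stem, n_frames=len(series), csv=str(csv_path))
    _echo_config(config, out_dir, "angle")
    log.write(out_dir, "angle.log.json")
    return series_list


def _series_from_csvs(paths: list[Path]) -> list[AngleSeries]:
    out = []
    for p in paths:
        df = pd.read_csv(p)
        out.append(
            AngleSeries(
                run_id=str(df["run_id"].iloc[0]) if "run_id" in df else p.stem,
                angle_deg=df["angle_deg"].to_numpy(),
                alignment_rmsd_A=df["rmsd_A"].to_numpy() if "rmsd_A" in df else np.zeros(len(df)),
                frame_index=df["frame"].to_numpy() if "frame" in df else None,
            )
        )
    return out


def run_populations(config: dict) -> dict:
    """Classify frames and summarize populations; writes ``populations.json``.

    Angle series come from ``angle_csvs`` when present, else are computed
    inline by :func:`run_angle`.  Bootstrap CI parameters live under the
    ``bootstrap`` block (n_boot, block_len; seeded from the config seed).
    """
    out_dir = _out_dir(config)
    log = _Log("populations", config)
    if "angle_csvs" in config:
        series_list = _series_from_csvs([Path(p) for p in config["angle_csvs"]])
    else:
        series_list = run_angle(config)
    threshold = float(config.get("threshold_deg", DEFAULT_THRESHOLD_DEG))
    summary = population_fractions(series_list, threshold)
    boot = config.get("bootstrap", {})
    if boot.get("enabled", True):
        n_boot = int(boot.get("n_boot", 500))
        block_len = int(boot.get("block_len", min(100, min(len(s) for s in series_list))))
        seed = int(config.get("seed", 0))
        summary.ci95_inactive_like = bootstrap_ci(
            series_list, threshold, n_boot=n_boot, block_len=block_len, seed=seed
        )
    log.stage("populations", n_frames=summary.n_frames_total, n_runs=summary.n_runs)
    result = summary.to_dict(system=str(config.get("system", "")))
    (out_dir / "populations.json").write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
    _echo_config(config, out_dir, "populations")
    log.write(out_dir, "populations.log.json")
    return result


def run_contacts(config: dict) -> pd.DataFrame:
    """Enumerate contacts of one structure; writes ``contacts.csv``.

    With a ``focus: [chain, residue_number]`` key the output is restricted
    to that residue's network.
    """
    out_dir = _out_dir(config)
    log = _Log("contacts", config)
    structure = read_pdb(config["structure"]).get_frame(0)
    criteria = _criteria(config)
    if "focus" in config:
        chain, number = config["focus"]
        records = residue_network(structure, (str(chain), int(number)), criteria).contacts
    else:
        records = find_contacts(structure, criteria)
    df = contacts_to_frame(records)
    df.to_csv(out_dir / "contacts.csv", index=False)
    log.stage("contacts", n_atoms=structure.n_atoms, n_records=len(records))
    _echo_config(config, out_dir, "contacts")
    log.write(out_dir, "contacts.log.json")
    return df


def run_compare_contacts(config: dict) -> dict:
    """Diff a focus residue's network between two structures.

    Writes ``contact_diff.json`` with shared / only_a / only_b sections at
    the residue-pair level, atom-level distances per side.
    """
    out_dir = _out_dir(config)
    log = _Log("compare-contacts", config)
    structure_a = read_pdb(config["structure_a"]).get_frame(0)
    structure_b = read_pdb(config["structure_b"]).get_frame(0)
    chain, number = config["focus"]
    diff = compare_networks(structure_a, structure_b, (str(chain), int(number)), _criteria(config))

    def _records(recs):
        return [
            {"atom_a": r.atom_a, "atom_b": r.atom_b, "distance_A": r.distance_A} for r in recs
        ]

    def _key(k):
        (ca, na), (cb, nb), kind = k
        return {"residue_a": [ca, na], "residue_b": [cb, nb], "kind": kind}

    result = {
        "focus": [str(chain), int(number)],
        "shared": [
            {**_key(k), "a": _records(ra), "b": _records(rb)} for k, ra, rb in diff["shared"]
        ],
        "only_a": [{**_key(k), "a": _records(r)} for k, r in diff["only_a"]],
        "only_b": [{**_key(k), "b": _records(r)} for k, r in diff["only_b"]],
    }
    (out_dir / "contact_diff.json").write_text(json.dumps(result, indent=2) + "\n")
    log.stage("compare", shared=len(result["shared"]), only_a=len(result["only_a"]), only_b=len(result["only_b"]))
    _echo_config(config, out_dir, "compare_contacts")
    log.write(out_dir, "compare_contacts.log.json")
    return result
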