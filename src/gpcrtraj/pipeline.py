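"""Config-driven end-to-end analysis runner.

Takes a declarative YAML/dict config naming input trajectories (multi-model
PDB), a generic-numbering table, distance observables, hydrogen-bond group
pairs, pocket-zone parameters, threshold conditions and a PCA plan, and
emits machine-readable TSV/JSON reports: per-system occupancy tables,
distance histograms with conditional overlays, per-zone water-count
distributions, cation-coordination summaries and shared-space PCA
projections, plus a run manifest.  Everything is deterministic given the
config and inputs; any stage failure aborts the run with the stage name and
partial outputs are removed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bw import BWTable, load_bw_table
from .hbonds import HBCriterion, hbond_series, ionic_coordination, occupancy_percent
from .observables import (
    NamedObservableConfig,
    ZonePartition,
    conditional_histogram,
    count_waters,
    distance_series,
    histogram,
    threshold_condition,
    zone_anchor_from_residue,
)
from .pca import extracellular_half_selection, fit_pca, project, superpose
from .structure_io import Trajectory, read_pdb_models, select_atoms

__all__ = ["PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise PipelineError("config", "config must be a mapping")
    return cfg


def _write_hist_tsv(path: Path, hist, overlay=None, overlay_name="conditional_probability"):
    data = {
        "bin_lower": hist.bin_edges[:-1],
        "bin_upper": hist.bin_edges[1:],
        "probability": hist.probabilities,
    }
    if overlay is not None:
        data[overlay_name] = overlay
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run every configured stage; return a manifest dict.

    ``config`` is a mapping or a YAML path.  See the project README for the
    schema; all referenced paths must exist before any computation starts.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(output_dir or config.get("output_dir", "pipeline_out"))

    # -- validation before any computation --------------------------------
    traj_paths = config.get("trajectories", {})
    if not traj_paths:
        raise PipelineError("config", "no input trajectories configured")
    if len(set(traj_paths)) != len(traj_paths):
        raise PipelineError("config", "duplicate trajectory labels")
    missing = [str(p) for p in traj_paths.values() if not Path(p).exists()]
    if missing:
        raise PipelineError("config", f"missing trajectory files: {missing}")
    bw_path = config.get("bw_table")
    if bw_path is not None and not Path(bw_path).exists():
        raise PipelineError("config", f"missing BW table file: {bw_path}")

    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str) -> Path:
        p = out_dir / name
        written.append(p)
        return p

    try:
        table = load_bw_table(bw_path) if bw_path else None
        trajs: dict[str, Trajectory] = {}
        for label, path in traj_paths.items():
            try:
                trajs[label] = read_pdb_models(path)
            except Exception as exc:
                raise PipelineError("load", f"{label}: {exc}") from exc

        crit_cfg = config.get("hbond_criterion", {})
        criterion = HBCriterion(
            da_cutoff_A=crit_cfg.get("da_cutoff_A", 3.0),
            dha_angle_cutoff_deg=crit_cfg.get("dha_angle_cutoff_deg", 20.0),
            heavy_only_cutoff_A=crit_cfg.get("heavy_only_cutoff_A", 3.5),
            mode=crit_cfg.get("mode", "heavy_only"),
        )

        # -- hydrogen-bond occupancy table --------------------------------
        occ_rows = []
        for pair in config.get("hbond_pairs", []):
            for label, traj in trajs.items():
                try:
                    series = hbond_series(
                        traj, pair["group_a"], pair["group_b"],
                        criterion=criterion, pair_label=pair.get("label"),
                    )
                    occ_rows.append({
                        "system": label,
                        "pair_label": series.pair_label,
                        "occupancy_percent": round(occupancy_percent(series), 1),
                        "n_frames": len(series),
                    })
                except Exception as exc:
                    raise PipelineError("hbonds", f"{label}/{pair}: {exc}") from exc
        if occ_rows:
            pd.DataFrame(occ_rows).to_csv(
                _emit("occupancy.tsv"), sep="\t", index=False
            )

        # -- distance observables, histograms, conditional overlays -------
        series_by = {}  # (system, observable) -> DistanceSeries
        bin_width = float(config.get("bin_width_A", 0.2))
        for obs in config.get("observables", []):
            cfg = NamedObservableConfig(
                name=obs["name"],
                atom_a=(int(obs["atom_a"][0]), str(obs["atom_a"][1])),
                atom_b=(int(obs["atom_b"][0]), str(obs["atom_b"][1])),
                chain_a=obs.get("chain_a"),
                chain_b=obs.get("chain_b"),
            )
            for label, traj in trajs.items():
                try:
                    s = distance_series(traj, cfg)
                except Exception as exc:
                    raise PipelineError("observables", f"{label}/{cfg.name}: {exc}") from exc
                series_by[(label, cfg.name)] = s
                _write_hist_tsv(
                    _emit(f"hist_{cfg.name}_{label}.tsv"), histogram(s, bin_width)
                )
                pd.DataFrame({"frame": np.arange(len(s)), "value_A": s.values}).to_csv(
                    _emit(f"series_{cfg.name}_{label}.tsv"),
                    sep="\t", index=False, float_format="%.4f",
                )

        for cond in config.get("conditions", []):
            on, target = cond["condition_on"], cond["histogram_of"]
            for label in trajs:
                if (label, on) not in series_by or (label, target) not in series_by:
                    raise PipelineError(
                        "conditions",
                        f"{label}: condition needs observables {on!r} and {target!r}",
                    )
                mask = threshold_condition(
                    series_by[(label, on)], cond["predicate"], float(cond["value"])
                )
                hist, overlay = conditional_histogram(
                    series_by[(label, target)], mask, bin_width
                )
                _write_hist_tsv(
                    _emit(f"cond_{cond['name']}_{label}.tsv"), hist, overlay
                )

        # -- pocket zoning and water counts --------------------------------
        zones_cfg = config.get("zones")
        if zones_cfg:
            for label, traj in trajs.items():
                try:
                    anchor = zone_anchor_from_residue(
                        traj, int(zones_cfg["anchor_residue"]),
                        zones_cfg.get("anchor_atom", "CA"),
                    )
                    part = ZonePartition(
                        anchor_z=anchor,
                        zone_width_A=float(zones_cfg.get("zone_width_A", 8.0)),
                        n_zones=int(zones_cfg.get("n_zones", 3)),
                        lateral_radius_A=float(zones_cfg.get("lateral_radius_A", 8.0)),
                    )
                    axis_point = tuple(zones_cfg.get("bundle_axis_point", (0.0, 0.0)))
                    wc = count_waters(traj, part, axis_point)
                except Exception as exc:
                    raise PipelineError("zones", f"{label}: {exc}") from exc
                df = pd.DataFrame(
                    wc.counts, columns=[f"waters_{z}" for z in wc.zone_labels]
                )
                df.insert(0, "frame", np.arange(traj.n_frames))
                df.to_csv(_emit(f"waters_{label}.tsv"), sep="\t", index=False)
                for z in range(part.n_zones):
                    _write_hist_tsv(
                        _emit(f"hist_waters_{wc.zone_labels[z]}_{label}.tsv"),
                        histogram(wc.counts[:, z]),
                    )

        # -- cation coordination -------------------------------------------
        coord_cfg = config.get("coordination")
        if coord_cfg:
            rows = []
            for label, traj in trajs.items():
                try:
                    cat = select_atoms(
                        traj,
                        residue_id=int(coord_cfg["cation_residue"]),
                        atom_name=coord_cfg["cation_atom"],
                    )
                    if len(cat) != 1:
                        raise ValueError("cation atom not found")
                    partners = []
                    for rid, aname in coord_cfg["partners"]:
                        sel = select_atoms(traj, residue_id=int(rid), atom_name=aname)
                        if len(sel) != 1:
                            raise ValueError(f"partner atom {rid}/{aname} not found")
                        partners.append(sel.indices[0])
                    cs = ionic_coordination(
                        traj, cat.indices[0], partners,
                        cutoff_A=float(coord_cfg.get("cutoff_A", 3.0)),
                    )
                except Exception as exc:
                    raise PipelineError("coordination", f"{label}: {exc}") from exc
                rows.append({
                    "system": label,
                    "mean_coordination": float(np.mean(cs.counts)),
                    "min": int(cs.counts.min()),
                    "max": int(cs.counts.max()),
                    "n_frames": cs.counts.size,
                })
            pd.DataFrame(rows).to_csv(
                _emit("coordination.tsv"), sep="\t", index=False, float_format="%.4f"
            )

        # -- PCA in a shared component space --------------------------------
        pca_cfg = config.get("pca")
        if pca_cfg:
            if table is None:
                raise PipelineError("pca", "PCA requires a bw_table")
            fit_labels = pca_cfg.get("fit", list(trajs))
            project_labels = pca_cfg.get("project", list(trajs))
            helices = tuple(pca_cfg.get("helices", (2, 6, 7)))
            comp_ids = pca_cfg.get("components", [0, 1, 2])
            try:
                ref_traj = trajs[fit_labels[0]]
                fit_set = select_atoms(ref_traj, atom_name="CA", chain="A")
                reference = ref_traj.frame(0)
                aligned = {
                    lab: superpose(trajs[lab], reference, fit_set)
                    for lab in set(fit_labels) | set(project_labels)
                }
                ec_set = extracellular_half_selection(table, ref_traj, helices)
                from .structure_io import concat_trajectories

                fit_traj = concat_trajectories([aligned[l] for l in fit_labels])
                model = fit_pca(fit_traj, ec_set)
                for lab in project_labels:
                    proj = project(model, aligned[lab], comp_ids)
                    df = pd.DataFrame(
                        proj, columns=[f"pc{c + 1}" for c in comp_ids]
                    )
                    df.insert(0, "frame", np.arange(proj.shape[0]))
                    df.to_csv(
                        _emit(f"pca_projection_{lab}.tsv"),
                        sep="\t", index=False, float_format="%.5f",
                    )
                payload = {
                    "atom_indices": list(map(int, model.atom_set.indices)),
                    "eigenvalues_A2": model.eigenvalues.tolist(),
                    "mean_coords": model.mean_coords.tolist(),
                    "components": model.components[: max(comp_ids) + 1].tolist(),
                }
                _emit("pca_model.json").write_text(json.dumps(payload))
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("pca", str(exc)) from exc

        # -- manifest --------------------------------------------------------
        cfg_text = json.dumps(config, sort_keys=True, default=str)
        manifest = {
            "package_version": __version__,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "inputs": {
                lab: {"path": str(p), "n_frames": trajs[lab].n_frames}
                for lab, p in traj_paths.items()
            },
            "outputs": sorted([p.name for p in written] + ["manifest.json"]),
        }
        _emit("manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except Exception:
        for p in written:  # no partial report bundles
            p.unlink(missing_ok=True)
        raise
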