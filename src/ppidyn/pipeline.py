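"""Run configuration and the two-system comparison pipeline.

``run_compare`` executes the full analysis sequence — RMSD/RMSF → DCCM →
per-system and shared PCA → RMSIP/overlap → FEL → clusters → porcupine →
interface area and interaction occupancies → binding energetics → community
network — for two systems and emits a single paired-metric report plus every
per-stage file. All thresholds and seeds come from the RunConfig, which
round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ppidyn import correlation as _corr
from ppidyn import essential as _ess
from ppidyn import fitmetrics as _fit
from ppidyn import interactions as _ia
from ppidyn import network as _net
from ppidyn.energetics import (
    ForceFieldParameters,
    binding_energy,
    per_residue_decomposition,
    write_energy_tsv,
    write_residue_energy_tsv,
)
from ppidyn.structio import (
    StructureModel,
    TrajectoryEnsemble,
    apply_parameters,
    read_parameter_table,
    read_structure,
    read_trajectory,
    select,
)

__all__ = ["RunConfig", "run_compare", "run_system", "load_dataset"]


@dataclass
class RunConfig:
    """All knobs of one analysis run (defaults follow the study conditions:
    310 K, 4.5 Å contacts, 0.70 stable / 0.75 network persistence, minimum
    community size 3, five clusters)."""

    name: str = "system"
    structure_path: str | None = None
    trajectory_path: str | None = None
    parameter_path: str | None = None
    ligand_chains: list[str] = field(default_factory=lambda: ["M"])
    receptor_chains: list[str] = field(default_factory=lambda: ["P"])
    selection: str = "name CA"
    analysis_start: int = 0
    contact_cutoff: float = 4.5
    stable_threshold: float = 0.70
    network_persistence: float = 0.75
    min_community_size: int = 3
    hbond_d_max: float = 3.5
    hbond_angle_min: float = 135.0
    saltbridge_d_max: float = 4.0
    temperature: float = 310.0
    fel_bins: int = 100
    kmeans_k: int = 5
    kmeans_restarts: int = 50
    seed: int = 0
    energy_stride: int = 20
    interface_stride: int = 20
    decomposition_stride: int = 100
    sasa_points: int = 960
    max_communities: int = 30
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0 <= self.stable_threshold <= 1 and 0 <= self.network_persistence <= 1):
            raise ValueError("thresholds must be fractions in [0, 1]")
        if self.contact_cutoff <= 0 or self.temperature <= 0:
            raise ValueError("cutoff and temperature must be positive")
        if self.min_community_size < 1 or self.kmeans_k < 1:
            raise ValueError("counts must be ≥ 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def load_dataset(cfg: RunConfig) -> dict:
    """Load structure, parameters and trajectory named by a config."""
    model = read_structure(cfg.structure_path)
    if cfg.parameter_path:
        model = apply_parameters(model, read_parameter_table(cfg.parameter_path))
    traj = read_trajectory(
        cfg.trajectory_path, model, analysis_start=cfg.analysis_start
    )
    return {"model": model, "trajectory": traj}


def _ff_from(model: StructureModel) -> ForceFieldParameters:
    return ForceFieldParameters.from_model(model)


def run_system(
    name: str,
    model: StructureModel,
    traj: TrajectoryEnsemble,
    cfg: RunConfig,
    outdir: Path,
    ff: ForceFieldParameters | None = None,
    hub: str | None = None,
) -> tuple[dict, dict]:
    """All single-system stages; returns (metrics, artifacts).

    Artifacts carry in-memory stage outputs (PCA model, DCCM, network) that
    the comparison stage reuses; every number also lands in a TSV under
    ``outdir``.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    metrics: dict[str, float] = {}
    artifacts: dict = {}
    failed: list[str] = []
    ca = select(model, cfg.selection)

    def _stage(label, fn):
        try:
            fn()
        except Exception as exc:  # pragma: no cover - defensive
            failed.append(f"{label}: {exc}")

    def _fluctuations():
        rmsd = _fit.rmsd_series(traj, ca, reference_frame=0, fit=True)
        _fit.write_rmsd_tsv(rmsd, outdir / f"{name}_rmsd.tsv")
        post = rmsd[traj.analysis_start:]
        metrics["rmsd_mean_A"] = float(post.mean())
        metrics["rmsd_sd_A"] = float(post.std(ddof=0))
        vals = _fit.rmsf(traj, ca, reference="initial", fit=True)
        resnums = [model.atoms[i].residue_number for i in ca]
        _fit.write_rmsf_tsv(resnums, vals, outdir / f"{name}_rmsf.tsv")
        metrics["rmsf_mean_A"] = float(vals.mean())
        artifacts["rmsd"] = rmsd

    def _dccm_stage():
        mat = _corr.dccm(traj, ca, fit_reference="mean")
        _corr.write_dccm_tsv(mat, outdir / f"{name}_dccm.tsv")
        off = ~np.eye(mat.n, dtype=bool)
        with np.errstate(invalid="ignore"):
            metrics["dccm_mean_abs_offdiag"] = float(np.nanmean(np.abs(mat.C[off])))
        artifacts["dccm"] = mat

    def _pca_stage():
        pca = _ess.fit_pca(traj, ca)
        _ess.write_eigen_tsv(pca, outdir / f"{name}_eigen.tsv")
        fr = _ess.variance_fractions(pca)
        metrics["pc1_variance_fraction"] = float(fr[0])
        metrics["pc2_variance_fraction"] = float(fr[1])
        proj = _ess.project(pca, traj, components=(0, 1), selection=ca)
        _ess.write_projection_tsv(proj, outdir / f"{name}_projection.tsv")
        grid = _ess.fel_from_projection(proj, bins=cfg.fel_bins, temperature=cfg.temperature)
        _ess.write_fel_tsv(grid, outdir / f"{name}_fel.tsv")
        clusters = _ess.kmeans_representatives(
            proj, k=cfg.kmeans_k, seed=cfg.seed, restarts=cfg.kmeans_restarts
        )
        metrics["cluster1_occupancy_pct"] = float(clusters.occupancy_percent[0])
        _ess.porcupine(
            pca, 0, scale=1.0, topology=model, selection=ca,
            path=outdir / f"{name}_porcupine_pc1.pdb",
        )
        artifacts["pca"] = pca
        artifacts["projection"] = proj
        artifacts["clusters"] = clusters

    def _interface_stage():
        series = _ia.interface_area(
            traj, cfg.ligand_chains, cfg.receptor_chains,
            points=cfg.sasa_points, stride=cfg.interface_stride,
        )
        _ia.write_interface_tsv(series, outdir / f"{name}_interface_area.tsv")
        metrics["interface_area_mean_A2"] = float(series.areas.mean())
        metrics["interface_area_mode_A2"] = series.mode()
        artifacts["interface"] = series

    def _interactions_stage():
        records = _ia.classify_interface(
            traj, cfg.ligand_chains, cfg.receptor_chains,
            hbond_d_max=cfg.hbond_d_max, saltbridge_d_max=cfg.saltbridge_d_max,
            hydrophobic_d_max=cfg.contact_cutoff, stable_threshold=cfg.stable_threshold,
        )
        _ia.write_interactions_tsv(records, outdir / f"{name}_interactions.tsv")
        metrics["n_stable_interactions"] = float(sum(r.stable for r in records))
        salts = [r.occupancy for r in records if r.interaction_type == "saltbridge"]
        metrics["max_saltbridge_occupancy"] = float(max(salts)) if salts else 0.0
        artifacts["interactions"] = records

    def _energy_stage():
        ffp = ff if ff is not None else _ff_from(model)
        bd = binding_energy(
            traj, ffp, cfg.receptor_chains, cfg.ligand_chains,
            stride=cfg.energy_stride, points=cfg.sasa_points,
        )
        write_energy_tsv(bd, outdir / f"{name}_energy.tsv")
        metrics["dG_binding_mean"] = bd.g_binding[0]
        metrics["dG_binding_sd"] = bd.g_binding[1]
        metrics["dE_vdw_mean"] = bd.e_vdw[0]
        metrics["dE_ele_mean"] = bd.e_ele[0]
        decomp = per_residue_decomposition(
            traj, ffp, cfg.receptor_chains, cfg.ligand_chains,
            stride=cfg.decomposition_stride, points=cfg.sasa_points,
        )
        write_residue_energy_tsv(decomp, outdir / f"{name}_residue_energy.tsv")
        top = decomp.loc[decomp["total"].idxmin()]
        metrics["top_residue_dG"] = float(top["total"])
        artifacts["energy"] = bd
        artifacts["decomposition"] = decomp

    def _network_stage():
        mat = artifacts["dccm"]
        graph = _net.build_network(
            traj, mat, cutoff=cfg.contact_cutoff, persistence=cfg.network_persistence
        )
        _net.write_edge_list(graph, outdir / f"{name}_network_edges.tsv")
        part = _net.girvan_newman(
            graph, min_size=cfg.min_community_size, max_communities=cfg.max_communities
        )
        _net.write_communities_tsv(part, outdir / f"{name}_communities.tsv")
        strengths = _net.intercommunity_strength(graph, part)
        _net.write_coupling_tsv(strengths, outdir / f"{name}_coupling.tsv")
        metrics["n_communities_reported"] = float(len(part.reported))
        metrics["modularity"] = float(part.modularity)
        lig = set(cfg.ligand_chains)
        rec = set(cfg.receptor_chains)
        spanning = [
            c for c in part.reported
            if {n.split(":")[0] for n in c} & lig and {n.split(":")[0] for n in c} & rec
        ]
        metrics["has_interface_spanning_community"] = float(bool(spanning))
        hub_strength = 0.0
        hub_in_spanning = 0.0
        hub_label = hub
        if hub_label and hub_label in part.membership:
            hub_comm = part.membership[hub_label]
            hub_strength = sum(
                s for (a, b), s in strengths.items() if hub_comm in (a, b)
            )
            hub_in_spanning = float(any(hub_label in c for c in spanning))
        metrics["hub_community_crossing_strength"] = float(hub_strength)
        metrics["hub_in_interface_community"] = hub_in_spanning
        artifacts["network"] = graph
        artifacts["partition"] = part
        artifacts["coupling"] = strengths

    _stage("fluctuations", _fluctuations)
    _stage("dccm", _dccm_stage)
    _stage("pca", _pca_stage)
    _stage("interface", _interface_stage)
    _stage("interactions", _interactions_stage)
    _stage("energy", _energy_stage)
    if "dccm" in artifacts:
        _stage("network", _network_stage)
    else:
        failed.append("network: skipped (dccm unavailable)")
    artifacts["failed"] = failed
    return metrics, artifacts


def run_compare(
    config_a: RunConfig,
    config_b: RunConfig,
    dataset_a: dict | None = None,
    dataset_b: dict | None = None,
    hub: str | None = None,
) -> pd.DataFrame:
    """Full paired comparison of two systems.

    Datasets may be passed in memory (``{"model", "trajectory", optional
    "ff"}``); otherwise they are loaded from the config paths. Returns the
    report table (metric, value per system) and writes it, the per-stage
    files, and a text summary under each config's output directory.
    """
    ds_a = dataset_a or load_dataset(config_a)
    ds_b = dataset_b or load_dataset(config_b)
    out_a = Path(config_a.output_dir)
    out_b = Path(config_b.output_dir)

    arts = {}
    metrics = {}
    for cfg, ds, outdir, tag in (
        (config_a, ds_a, out_a, "a"), (config_b, ds_b, out_b, "b")
    ):
        m, art = run_system(
            cfg.name, ds["model"], ds["trajectory"], cfg, outdir,
            ff=ds.get("ff"), hub=hub,
        )
        metrics[tag] = m
        arts[tag] = art

    rows = []
    keys = sorted(set(metrics["a"]) | set(metrics["b"]))
    for k in keys:
        rows.append(
            {
                "metric": k,
                config_a.name: metrics["a"].get(k, np.nan),
                config_b.name: metrics["b"].get(k, np.nan),
            }
        )
    # cross-system metrics
    if "pca" in arts["a"] and "pca" in arts["b"]:
        k10 = min(10, arts["a"]["pca"].n_components, arts["b"]["pca"].n_components)
        val = _ess.rmsip(arts["a"]["pca"], arts["b"]["pca"], k=k10)
        rows.append({"metric": f"rmsip_first{k10}", config_a.name: val, config_b.name: val})
    report = pd.DataFrame(rows)
    for outdir in (out_a, out_b):
        report.to_csv(outdir / "compare_report.tsv", sep="\t", index=False, float_format="%.6f")
        with open(outdir / "compare_summary.txt", "w") as fh:
            fh.write(f"Paired comparison: {config_a.name} vs {config_b.name}\n")
            fh.write(report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
            fh.write("\n")
            for tag, cfg in (("a", config_a), ("b", config_b)):
                for f in arts[tag].get("failed", []):
                    fh.write(f"FAILED [{cfg.name}] {f}\n")
    report.attrs["failed"] = arts["a"].get("failed", []) + arts["b"].get("failed", [])
    return report


def scenario_contrasts(
    seed: int,
    frames: int = 500,
    stride: int = 25,
    energy_stride: int = 5,
    energy_points: int = 240,
) -> dict:
    """Paired wt-like vs mutant-like metrics on one generated scenario pair.

    A lean, file-free version of :func:`run_compare` computing exactly the
    quantities the two-system comparison turns on: mean RMSD, interface-area
    distribution peak, binding free energy, planted polar occupancies, PC1
    variance fraction, and the interface community (hub membership and its
    intercommunity coupling strength). The binding energy averages over a
    denser frame grid (``energy_stride``) than the interface-area series: the
    scheduled electrostatics toggle frame by frame, so the energy mean needs
    more samples, while a coarser quadrature (``energy_points``) keeps the
    per-frame surface term cheap.
    """
    from ppidyn.interactions import hydrogen_bonds, interface_area, salt_bridges
    from ppidyn.network import build_network, girvan_newman, intercommunity_strength
    from ppidyn.structio import apply_parameters
    from ppidyn.synthetic import make_scenario_pair

    pair = make_scenario_pair(seed=seed, frames=frames)
    out: dict[str, dict] = {}
    pca_models = {}
    for tag in ("wt", "mut"):
        d = pair[tag]
        model = apply_parameters(d["model"], d["params"])
        traj = d["trajectory"]
        truth = d["truth"]
        ff = ForceFieldParameters.from_model(model)
        ca = select(model, "name CA")
        m: dict = {}
        rmsd = _fit.rmsd_series(traj, ca, reference_frame=0, fit=True)
        m["rmsd_mean_A"] = float(rmsd.mean())
        series = interface_area(traj, ["M"], ["P"], stride=stride)
        m["interface_area_mode_A2"] = series.mode()
        bd = binding_energy(traj, ff, ["P"], ["M"], stride=energy_stride, points=energy_points)
        m["dG_binding_mean"] = bd.g_binding[0]
        sb = {((r.chain_a, r.resnum_a), (r.chain_b, r.resnum_b)): r.occupancy
              for r in salt_bridges(traj)}
        hb = {((r.chain_a, r.resnum_a), (r.chain_b, r.resnum_b)): r.occupancy
              for r in hydrogen_bonds(traj)}
        occ = {}
        for (a, b, kind), frac in truth.occupancies.items():
            if kind == "saltbridge":
                occ[(a, b, kind)] = sb.get((a, b), sb.get((b, a), 0.0))
            elif kind == "hbond":
                occ[(a, b, kind)] = hb.get((a, b), hb.get((b, a), 0.0))
        m["planted_polar_occupancies"] = occ
        pca = _ess.fit_pca(traj, ca)
        pca_models[tag] = pca
        m["pc1_variance_fraction"] = float(_ess.variance_fractions(pca)[0])
        mat = _corr.dccm(traj, ca, fit_reference="mean")
        graph = build_network(traj, mat)
        part = girvan_newman(graph, max_communities=30)
        strengths = intercommunity_strength(graph, part)
        hub = f"{truth.hub[0]}:{truth.hub[1]}" if truth.hub else None
        spanning = [
            c for c in part.reported
            if any(n.startswith("M:") for n in c) and any(n.startswith("P:") for n in c)
        ]
        m["hub_in_interface_community"] = bool(
            hub and any(hub in c for c in spanning)
        )
        hub_strength = 0.0
        if hub and hub in part.membership:
            hc = part.membership[hub]
            hub_strength = sum(s for (a, b), s in strengths.items() if hc in (a, b))
        m["hub_community_crossing_strength"] = float(hub_strength)
        out[tag] = m
    out["rmsip_first10"] = _ess.rmsip(pca_models["wt"], pca_models["mut"], k=10)
    return out
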