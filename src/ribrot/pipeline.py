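"""End-to-end pipelines and structured outputs.

Composes read → partition → match → superpose(reference) → plane → field →
center → angles → summary for each requested backbone atom class, and the
difference pipeline (profile → regions → composition). All numeric outputs
are plain TSV/JSON with a config-echo header so every summary number can be
recomputed from the per-atom table.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correspondence import (MatchedPairs, apply_transform, kabsch_superpose,
                             match_backbone)
from .diffreport import (call_difference_regions, compare_chain_composition,
                         residue_displacement_profile)
from .errors import ConfigError
from .rotation import (RotationConfig, RotationField, RotationSummary,
                       analyze_rotation)
from .structure_io import (ChainNameMap, StructureModel, SubunitPartition,
                           partition_chains, read_structure)

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    inputs: dict[str, dict[str, str]]
    id_scheme: str
    partition: dict
    config: dict
    superposition: dict
    outputs: list[str] = field(default_factory=list)
    tool_version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["timestamp"] = (self.timestamp or
                                datetime.datetime.now().isoformat(timespec="seconds"))
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def _checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def _header_lines(frame_note: str, id_scheme: str, config: dict) -> str:
    lines = [f"# frame: {frame_note}", f"# id_scheme: {id_scheme}"]
    lines += [f"# config.{k}: {v}" for k, v in sorted(config.items())]
    return "\n".join(lines) + "\n"


def field_table(fld: RotationField, summary: RotationSummary) -> pd.DataFrame:
    """Per-atom table: identity, projected coordinates, displacement,
    retention, and (for retained atoms) radius and chord angle."""
    radius = np.full(len(fld.keys), np.nan)
    angle = np.full(len(fld.keys), np.nan)
    key_to_row = {key: i for i, key in enumerate(fld.keys)}
    if summary.per_atom_radius is not None:
        for key, r, a in zip(summary.per_atom_keys, summary.per_atom_radius,
                             summary.per_atom_angle_deg):
            i = key_to_row[key]
            radius[i], angle[i] = r, a
    return pd.DataFrame({
        "chain": [k[0] for k in fld.keys],
        "residue": [k[1] for k in fld.keys],
        "icode": [k[2] for k in fld.keys],
        "atom": [k[3] for k in fld.keys],
        "u": fld.start_2d[:, 0],
        "v": fld.start_2d[:, 1],
        "du": fld.disp_2d[:, 0],
        "dv": fld.disp_2d[:, 1],
        "disp_3d": fld.disp_3d,
        "retained": fld.retained.astype(int),
        "radius": radius,
        "angle_deg": angle,
    })


def summary_payload(plane, summary: RotationSummary,
                    config: RotationConfig) -> dict:
    return {
        "plane": {
            "normal": plane.normal.tolist(),
            "origin": plane.origin.tolist(),
            "basis_u": plane.basis_u.tolist(),
            "basis_v": plane.basis_v.tolist(),
            "separation_score": plane.separation_score,
        },
        "center_2d": summary.center_2d.tolist(),
        "n_retained": summary.n_retained,
        "summary_angle_deg": summary.summary_angle_deg,
        "mean_angle_deg": summary.mean_angle_deg,
        "angle_dispersion_iqr_deg": summary.angle_dispersion,
        "sign": summary.sign,
        "objective_at_optimum": summary.objective_at_optimum,
        "config": asdict(config),
    }


def run_rotation_pipeline(model_a_path: str | Path, model_b_path: str | Path,
                          partition_config_path: str | Path,
                          config: RotationConfig | None = None,
                          out_prefix: str | Path = "rotation",
                          id_scheme: str = "auth",
                          atom_classes: tuple[str, ...] | None = None,
                          make_figures: bool = False) -> RunManifest:
    """Full rotation analysis for each requested atom class.

    Writes <prefix>.<class>.field.tsv, <prefix>.<class>.summary.json (and
    optionally a vector figure) per class, plus <prefix>.manifest.json.
    Plane and center are fitted independently per atom class.
    """
    config = config or RotationConfig()
    if atom_classes is None:
        atom_classes = (config.atom_class,)
    model_a = read_structure(model_a_path, id_scheme=id_scheme)
    model_b = read_structure(model_b_path, id_scheme=id_scheme)
    partition = SubunitPartition.from_yaml(partition_config_path)
    partition = partition_chains(model_a, partition)
    partition_b = partition_chains(model_b, SubunitPartition(
        reference_chains=partition.reference_chains,
        mobile_chains=partition.mobile_chains,
        excluded_chains=partition.excluded_chains & set(model_b.chain_index),
        mobile_body_ranges=partition.mobile_body_ranges))
    del partition_b  # validation only

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    superposition_info: dict = {}
    for atom_class in atom_classes:
        cfg = RotationConfig(**{**asdict(config), "atom_class": atom_class})
        pairs = match_backbone(model_a, model_b, partition, atom_class)
        transform = kabsch_superpose(pairs, fit_on="reference")
        aligned = apply_transform(pairs, transform)
        plane, fld, summary = analyze_rotation(aligned, cfg)

        frame_note = (f"model B superposed on model A reference-subunit "
                      f"backbone ({atom_class}); rmsd_after="
                      f"{transform.rmsd_after:.4f} A")
        table = field_table(fld, summary)
        tsv_path = Path(f"{out_prefix}.{atom_class}.field.tsv")
        with open(tsv_path, "w") as handle:
            handle.write(_header_lines(frame_note, id_scheme, asdict(cfg)))
            table.to_csv(handle, sep="\t", index=False, float_format="%.6f")
        payload = summary_payload(plane, summary, cfg)
        payload["superposition"] = {
            "fit_on": "reference",
            "rmsd_before": transform.rmsd_before,
            "rmsd_after": transform.rmsd_after,
            "n_atoms_fit": transform.n_atoms_fit,
        }
        json_path = Path(f"{out_prefix}.{atom_class}.summary.json")
        json_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        outputs += [str(tsv_path), str(json_path)]
        superposition_info[atom_class] = payload["superposition"]
        if make_figures:
            fig_path = Path(f"{out_prefix}.{atom_class}.vectors.png")
            export_vector_plot(fld, summary, fig_path)
            outputs += [str(fig_path), str(fig_path.with_suffix(".tsv"))]
        log.info("atom_class=%s: angle %.4f deg (median), %.4f (mean), "
                 "%d retained", atom_class, summary.summary_angle_deg,
                 summary.mean_angle_deg, summary.n_retained)

    manifest = RunManifest(
        inputs={
            "model_a": {"path": str(model_a_path),
                        "sha256": _checksum(model_a_path)},
            "model_b": {"path": str(model_b_path),
                        "sha256": _checksum(model_b_path)},
            "partition": {"path": str(partition_config_path),
                          "sha256": _checksum(partition_config_path)},
        },
        id_scheme=id_scheme,
        partition={
            "reference_chains": sorted(partition.reference_chains),
            "mobile_chains": sorted(partition.mobile_chains),
            "excluded_chains": sorted(partition.excluded_chains),
            "mobile_body_ranges": {c: [list(iv) for iv in ivs] for c, ivs
                                   in partition.mobile_body_ranges.items()},
        },
        config=asdict(config),
        superposition=superposition_info,
        outputs=outputs,
    )
    manifest_path = Path(f"{out_prefix}.manifest.json")
    manifest.write(manifest_path)
    manifest.outputs.append(str(manifest_path))
    return manifest


def run_difference_pipeline(model_a_path: str | Path, model_b_path: str | Path,
                            partition_config_path: str | Path,
                            name_map_path: str | Path | None = None,
                            threshold: float = 2.0, max_gap: int = 1,
                            representative: str = "auto",
                            fit_on_chains: set[str] | None = None,
                            out_prefix: str | Path = "diff",
                            id_scheme: str = "auth") -> RunManifest:
    """Displacement profile + difference regions (+ composition diff when a
    name map is given). The superposition frame is the reference-subunit
    backbone unless fit_on_chains overrides it."""
    model_a = read_structure(model_a_path, id_scheme=id_scheme)
    model_b = read_structure(model_b_path, id_scheme=id_scheme)
    partition = partition_chains(model_a,
                                 SubunitPartition.from_yaml(partition_config_path))
    pairs = match_backbone(model_a, model_b, partition, "both")
    if fit_on_chains:
        fit_mask = np.array([k[0] in fit_on_chains for k in pairs.keys])
        fit_note = f"chains {sorted(fit_on_chains)}"
        transform = kabsch_superpose(pairs.subset(fit_mask), fit_on="all")
    else:
        fit_note = "reference-subunit backbone"
        transform = kabsch_superpose(pairs, fit_on="reference")
    aligned = apply_transform(pairs, transform)

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    profiled_chains = partition.reference_chains | partition.mobile_chains
    profile = residue_displacement_profile(aligned, profiled_chains,
                                           representative)
    header = _header_lines(f"superposed on {fit_note}; rmsd_after="
                           f"{transform.rmsd_after:.4f} A", id_scheme,
                           {"threshold": threshold, "max_gap": max_gap,
                            "representative": representative})
    profile_path = Path(f"{out_prefix}.profile.tsv")
    with open(profile_path, "w") as handle:
        handle.write(header)
        profile.entries.to_csv(handle, sep="\t", index=False,
                               float_format="%.6f")
    outputs.append(str(profile_path))

    regions = call_difference_regions(profile, threshold, max_gap)
    regions_path = Path(f"{out_prefix}.regions.tsv")
    with open(regions_path, "w") as handle:
        handle.write(header)
        region_cols = ["chain_id", "start_residue", "end_residue",
                       "max_displacement", "mean_displacement", "n_residues"]
        pd.DataFrame([asdict(r) for r in regions],
                     columns=region_cols).to_csv(
            handle, sep="\t", index=False, float_format="%.6f")
    outputs.append(str(regions_path))

    composition = None
    if name_map_path is not None:
        name_map = ChainNameMap.from_yaml(name_map_path)
        composition = compare_chain_composition(model_a, model_b, name_map,
                                                "all")
        comp_path = Path(f"{out_prefix}.composition.json")
        comp_path.write_text(json.dumps({
            "shared": sorted(composition.shared),
            "only_a": sorted(composition.only_a),
            "only_b": sorted(composition.only_b),
        }, indent=1))
        outputs.append(str(comp_path))

    manifest = RunManifest(
        inputs={
            "model_a": {"path": str(model_a_path),
                        "sha256": _checksum(model_a_path)},
            "model_b": {"path": str(model_b_path),
                        "sha256": _checksum(model_b_path)},
        },
        id_scheme=id_scheme,
        partition={
            "reference_chains": sorted(partition.reference_chains),
            "mobile_chains": sorted(partition.mobile_chains),
            "excluded_chains": sorted(partition.excluded_chains),
        },
        config={"threshold": threshold, "max_gap": max_gap,
                "representative": representative, "frame": fit_note},
        superposition={"rmsd_before": transform.rmsd_before,
                       "rmsd_after": transform.rmsd_after,
                       "n_atoms_fit": transform.n_atoms_fit},
        outputs=outputs,
    )
    manifest_path = Path(f"{out_prefix}.manifest.json")
    manifest.write(manifest_path)
    manifest.outputs.append(str(manifest_path))
    return manifest


def export_vector_plot(fld: RotationField, summary: RotationSummary,
                       out_path: str | Path) -> Path:
    """In-plane vector-field figure: arrows from start_2d along disp_2d,
    colored by 3D displacement, fitted center marked; filtered atoms are
    drawn faded. A machine-readable TSV sidecar always accompanies it."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    if len(fld.keys) == 0:
        raise ConfigError("cannot plot an empty field")
    if fld.n_retained == 0:
        log.warning("no retained atoms: plotting unfiltered vectors only")

    fig, ax = plt.subplots(figsize=(7, 6))
    colors = fld.disp_3d
    vmin, vmax = float(colors.min()), float(colors.max())
    kept = fld.retained
    quiv = None
    for mask, alpha in ((~kept, 0.25), (kept, 1.0)):
        if not mask.any():
            continue
        quiv = ax.quiver(fld.start_2d[mask, 0], fld.start_2d[mask, 1],
                         fld.disp_2d[mask, 0], fld.disp_2d[mask, 1],
                         colors[mask], angles="xy", scale_units="xy", scale=1,
                         alpha=alpha, cmap="viridis",
                         clim=(vmin, vmax), width=0.003)
    if quiv is not None:
        fig.colorbar(quiv, ax=ax, label="3D displacement (Å)")
    ax.plot(*summary.center_2d, marker="x", color="red", markersize=12,
            markeredgewidth=2)
    ax.set_xlabel("u (Å)")
    ax.set_ylabel("v (Å)")
    ax.set_aspect("equal")
    ax.set_title(f"rotation field: {summary.summary_angle_deg:.2f}° "
                 f"({summary.sign}), {fld.n_retained} retained")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    sidecar = out_path.with_suffix(".tsv")
    field_table(fld, summary).to_csv(sidecar, sep="\t", index=False,
                                     float_format="%.6f")
    return out_path
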