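"""Readers/writers, run manifests, and the end-to-end pipeline.

All coordinates are continuous μm, 0-based at the ROI corner, with z
increasing with imaging depth; every module shares this convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .network import Segment, VesselNetwork, _SWC_TYPE_INV
from .synthdata import CELL_COLUMNS

logger = logging.getLogger("pemscope.io")

#: accepted aliases per canonical cell column (QuPath-style exports included)
COLUMN_ALIASES = {
    "cell_id": ["cell_id", "id", "object id", "object_id"],
    "cell_type": ["cell_type", "type", "class", "classification", "name"],
    "x_um": ["x_um", "x", "centroid x um", "centroid x µm", "centroid_x"],
    "y_um": ["y_um", "y", "centroid y um", "centroid y µm", "centroid_y"],
    "z_um": ["z_um", "z", "centroid z um", "centroid_z"],
}
MANDATORY = ["cell_id", "cell_type", "x_um", "y_um"]

#: coordinates beyond this are implausible as μm within one field of view
_UNIT_PLAUSIBILITY_UM = 50_000.0


def read_cells(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a cell table from CSV/TSV into the canonical schema.

    ``column_map`` maps canonical names to the file's column names and
    takes precedence over the built-in aliases.  Malformed rows
    (non-numeric coordinates, unknown cell type) are dropped with
    row-numbered diagnostics; a missing mandatory column raises
    :class:`SchemaError` listing the accepted aliases.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep)
    lower = {c.lower().strip(): c for c in raw.columns}

    resolved = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        if column_map and canonical in column_map:
            if column_map[canonical] in raw.columns:
                resolved[canonical] = column_map[canonical]
                continue
        for alias in aliases:
            if alias in lower:
                resolved[canonical] = lower[alias]
                break
    missing = [c for c in MANDATORY if c not in resolved]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s) {missing}; accepted "
            f"aliases: " + "; ".join(f"{m}: {COLUMN_ALIASES[m]}"
                                     for m in missing))

    df = pd.DataFrame()
    for canonical, src in resolved.items():
        df[canonical] = raw[src]
    for extra in CELL_COLUMNS:
        if extra not in df.columns and extra in raw.columns:
            df[extra] = raw[extra]

    bad_rows = []
    for col in ("x_um", "y_um", "z_um"):
        if col in df:
            coerced = pd.to_numeric(df[col], errors="coerce")
            newly_bad = coerced.isna() & df[col].notna()
            for i in df.index[newly_bad]:
                bad_rows.append((int(i) + 2,  # 1-based + header line
                                 f"non-numeric {col}: {df.at[i, col]!r}"))
            df[col] = coerced
    df["cell_type"] = df["cell_type"].astype(str).str.strip().str.lower()
    unknown = ~df.cell_type.isin(["microglia", "pericyte"])
    for i in df.index[unknown]:
        bad_rows.append((int(i) + 2, f"unknown cell_type "
                         f"{df.at[i, 'cell_type']!r}"))
    finite = df[["x_um", "y_um"]].notna().all(axis=1)
    keep = finite & ~unknown
    for line, why in sorted(set(bad_rows)):
        logger.warning("%s line %d rejected: %s", path.name, line, why)
    df = df[keep].reset_index(drop=True)

    coords = df[[c for c in ("x_um", "y_um", "z_um") if c in df]].to_numpy()
    if len(coords) and np.nanmax(np.abs(coords)) > _UNIT_PLAUSIBILITY_UM:
        logger.warning("%s: coordinate magnitudes exceed %g; are these "
                       "really μm?  No conversion applied.", path.name,
                       _UNIT_PLAUSIBILITY_UM)
    if "z_um" not in df:
        df["z_um"] = np.nan
    for soma, nuc in (("soma_x_um", "x_um"), ("soma_y_um", "y_um"),
                      ("soma_z_um", "z_um")):
        if soma not in df:
            df[soma] = df[nuc]
    return df


def write_cells(cells: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    cells.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# networks


def write_network(network: VesselNetwork, path, format: str | None = None
                  ) -> None:
    path = Path(path)
    fmt = format or ("swc" if path.suffix.lower() == ".swc" else "json")
    if fmt == "json":
        path.write_text(json.dumps(network.to_dict(), indent=1))
    elif fmt == "swc":
        path.write_text(network.to_swc())
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, format: str | None = None) -> VesselNetwork:
    path = Path(path)
    fmt = format or ("swc" if path.suffix.lower() == ".swc" else "json")
    if fmt == "json":
        return VesselNetwork.from_dict(json.loads(path.read_text()))
    if fmt == "swc":
        return _read_swc(path.read_text())
    raise ValueError(f"unknown network format {fmt!r}")


def _read_swc(text: str) -> VesselNetwork:
    """Rebuild a network from SWC samples.

    Chains are split at roots, branch points, type changes, and
    duplicate-coordinate boundary samples (the convention ``to_swc`` uses
    to preserve per-segment endpoint radii at shared junctions); radii
    become diameters.
    """
    samples = {}
    children: dict[int, list[int]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        n, t, x, y, z, r, parent = line.split()
        n, t, parent = int(n), int(t), int(parent)
        samples[n] = (t, np.array([float(x), float(y), float(z)]),
                      2.0 * float(r), parent)
        children.setdefault(parent, []).append(n)

    def is_break(n):
        t, xyz, _, parent = samples[n]
        kids = children.get(n, [])
        if parent == -1 or len(kids) != 1:
            return True
        kid = kids[0]
        return samples[kid][0] != t or \
            bool(np.array_equal(samples[kid][1], xyz))

    net = VesselNetwork()
    node_of: dict[int, int] = {}

    def node_for(n):
        if n not in node_of:
            nid = len(node_of)
            node_of[n] = nid
            net.nodes[nid] = samples[n][1].copy()
        return node_of[n]

    seg_id = iter(range(10 ** 6))
    for start in sorted(samples):
        t, xyz, _, parent = samples[start]
        # chains begin just after a break sample (roots are break samples)
        if parent == -1 or not is_break(parent):
            continue
        if np.array_equal(samples[parent][1], xyz):
            chain = [start]          # duplicate boundary sample: the
            start_key = parent       # junction node is the parent sample
        else:
            chain = [parent, start]
            start_key = parent
        while not is_break(chain[-1]):
            chain.append(children[chain[-1]][0])
        pts = np.array([samples[n][1] for n in chain])
        diams = np.array([samples[n][2] for n in chain])
        net.segments.append(Segment(
            next(seg_id), node_for(start_key), node_for(chain[-1]),
            pts, diams, order=None,
            vessel_class=_SWC_TYPE_INV.get(t, "capillary")))
    net.validate()
    return net


# ---------------------------------------------------------------------------
# manifest and pipeline


@dataclass
class RunManifest:
    command: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    inputs: dict = field(default_factory=dict)   # path -> sha256
    version: str = __version__
    timestamp: str = field(default_factory=lambda: datetime.now(
        timezone.utc).isoformat())
    warnings: list = field(default_factory=list)

    @staticmethod
    def digest(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(payload, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=1))


def run_pipeline(config=None, out_dir="pemscope_run", seed: int = 0,
                 chance_iterations: int = 300,
                 days=(0, 4, 7, 28)) -> Path:
    """Run the full desk-scale analysis on one synthetic scene.

    Generates a scene, labels CAM/PEM, runs the chance null, assigns branch
    orders and locates cells on the tree, measures widths, simulates and
    tracks the longitudinal series, quantifies marker intensity by PEM
    status, and writes tables, summary JSON and a manifest into
    ``out_dir``.
    """
    from . import associate, chance, intensity, synthdata, track, vasctree

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = synthdata.GeneratorConfig(seed=seed)
    rng = np.random.default_rng(seed)

    scene = synthdata.generate_scene(config, rng)
    write_network(scene.network, out / "network.json")
    write_network(scene.network, out / "network.swc")

    criteria = associate.AssociationCriteria()
    result = associate.classify(scene.cells, scene.network, criteria)
    write_cells(result.cells, out / "cells_labeled.csv")

    # prevalence and the chance null follow the fixed-tissue 2-D protocol:
    # full-thickness projection, then planar classification
    flat = synthdata.project_to_section(scene, config.roi_extent[2] + 1,
                                        config.roi_extent[2] / 2)
    result2d = associate.classify(flat.cells, flat.network, criteria)
    ch = chance.chance_for_scene(
        result2d.cells, config.roi_extent[:2], criteria,
        chance.ChanceModelConfig(n_iterations=chance_iterations), rng)

    vasctree.assign_branch_orders(scene.network)
    located = vasctree.locate_on_tree(result.cells, scene.network)
    dist = vasctree.order_distribution(located)
    dist.to_csv(out / "order_distribution.csv", index=False)

    widths = vasctree.measure_scene_widths(result.cells, scene.network,
                                           scene_id=seed)
    widths.to_csv(out / "widths.csv", index=False)
    contrast = vasctree.width_contrast_table(widths, min_per_group=1)

    series = synthdata.simulate_timepoints(scene, list(days), config, rng)
    retention = track.pem_retention(series)
    retention.to_csv(out / "retention.csv", index=False)
    events = track.gain_loss_events(series)
    events["events"].to_csv(out / "events.csv", index=False)
    width_change = vasctree.width_change_on_gain_loss(series)

    stack, truth = synthdata.render_intensity_stack(
        scene, synthdata.MarkerModel(), planes=8, rng=rng)
    try:
        import tifffile
        tifffile.imwrite(out / "stack.tif", stack.astype(np.float32))
    except ImportError:
        pass
    outlines = synthdata.pericyte_outlines(scene)
    meas = intensity.measure_pericyte_intensities(stack, outlines)
    has_pem = result.cells.set_index("cell_id")["has_pem"]
    meas["has_pem"] = meas.cell_id.map(has_pem).fillna(False)
    meas["scene_id"] = seed
    meas.to_csv(out / "pericyte_intensity.csv", index=False)
    pem_cmp = intensity.compare_by_pem_status(meas)

    summary = {
        "association": result2d.summary,
        "association_3d": result.summary,
        "chance": ch.as_dict(),
        "width_contrast": {"mean_pct_diff": contrast["mean_pct_diff"]},
        "width_change": width_change["summary"],
        "retention": retention.to_dict(orient="records"),
        "intensity_by_pem": {"mean_difference": pem_cmp["mean_difference"],
                             "paired_t_p": pem_cmp["paired_t_p"]},
    }
    write_json(summary, out / "summary.json")

    RunManifest(command="run", seed=seed,
                config={"roi_extent": list(config.roi_extent),
                        "seed": config.seed}).write(out / "manifest.json")

    report = [
        "pemscope pipeline report",
        f"microglia: {result2d.summary['n_microglia']}  "
        f"pericytes: {result2d.summary['n_pericytes']}",
        f"%CAM: {result2d.summary['pct_cam']:.1f}  "
        f"%PEM: {result2d.summary['pct_pem']:.1f}",
        f"chance %PEM: {ch.expected_pct:.2f} ± {ch.expected_sd:.2f}  "
        f"enrichment: {ch.enrichment_ratio:.2f}x"
        if ch.enrichment_ratio else "chance: undefined",
        f"day-28 PEM retention: "
        f"{retention.frac_any.iloc[-1] * 100:.0f}%",
    ]
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return out
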