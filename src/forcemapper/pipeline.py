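"""End-to-end analysis: curves -> events -> maps -> phase clusters.

`analyse_grid` runs detection and event extraction over every curve of a
grid; `run_analyse` adds artifact writing (events CSV, force/thickness
maps with flags, phase summary, figures) and a JSON session file that
lets maps and clusters be rebuilt without re-running detection.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import assign_phases, cluster_map, cluster_two, phase_summary
from .curve_io import ForceCurve, ForceGrid, grid_spacing
from .events import BreakthroughEvent, ThresholdConfig, extract_events, peak_statistics
from .kinks import DetectionConfig, detect_breakthrough_pairs
from .maps import ForceMap, assemble_map, map_to_image, save_map

__all__ = [
    "GridAnalysis",
    "analyse_curve",
    "analyse_grid",
    "run_analyse",
    "events_to_dataframe",
    "save_session",
    "load_session",
]


def analyse_curve(
    curve: ForceCurve,
    detection: DetectionConfig | None = None,
    thresholds: ThresholdConfig | None = None,
    curve_id: str | None = None,
) -> list[BreakthroughEvent]:
    """Detect, merge, pair and filter breakthrough events for one curve."""
    pairs, _ = detect_breakthrough_pairs(curve, detection)
    cid = curve_id if curve_id is not None else curve.source_id
    return extract_events(pairs, thresholds, curve_id=cid)


@dataclass
class GridAnalysis:
    """Per-cell events for a grid, plus the configs that produced them."""

    grid: ForceGrid
    events_by_cell: dict[tuple[int, int], list[BreakthroughEvent]]
    detection: DetectionConfig
    thresholds: ThresholdConfig

    def primary_points(self) -> tuple[list[tuple[int, int]], np.ndarray]:
        """Cells with a primary event and their (force, thickness) pairs."""
        cells, pts = [], []
        for cell in sorted(self.events_by_cell):
            primaries = [e for e in self.events_by_cell[cell] if e.rank == "primary"]
            if primaries:
                cells.append(cell)
                pts.append((primaries[0].force, primaries[0].thickness))
        return cells, np.array(pts, dtype=float).reshape(-1, 2)

    def events(self) -> list[BreakthroughEvent]:
        return [e for evs in self.events_by_cell.values() for e in evs]


def analyse_grid(
    grid: ForceGrid,
    detection: DetectionConfig | None = None,
    thresholds: ThresholdConfig | None = None,
) -> GridAnalysis:
    """Run per-curve breakthrough analysis over every populated cell."""
    detection = detection or DetectionConfig()
    thresholds = thresholds or ThresholdConfig()
    events_by_cell: dict[tuple[int, int], list[BreakthroughEvent]] = {}
    for cell, curve in sorted(grid.curves.items()):
        events_by_cell[cell] = analyse_curve(
            curve, detection, thresholds, curve_id=f"r{cell[0]:03d}_c{cell[1]:03d}"
        )
    return GridAnalysis(grid, events_by_cell, detection, thresholds)


def events_to_dataframe(analysis: GridAnalysis) -> pd.DataFrame:
    records = []
    for (r, c), events in sorted(analysis.events_by_cell.items()):
        for e in events:
            records.append(
                {
                    "curve_id": e.curve_id,
                    "row": r,
                    "col": c,
                    "rank": e.rank,
                    "force_nN": e.force,
                    "thickness_nm": e.thickness,
                    "z_start_nm": e.z_start,
                    "flags": ";".join(e.flags),
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["curve_id", "row", "col", "rank", "force_nN", "thickness_nm", "z_start_nm", "flags"],
    )


def save_session(analysis: GridAnalysis, path: str | Path) -> Path:
    """Persist detection results so maps can be rebuilt without re-detection."""
    path = Path(path)
    payload = {
        "grid": {
            "n_rows": analysis.grid.n_rows,
            "n_cols": analysis.grid.n_cols,
            "physical_size": list(analysis.grid.physical_size),
            "acquisition_order": analysis.grid.acquisition_order,
        },
        "detection": asdict(analysis.detection),
        "thresholds": asdict(analysis.thresholds),
        "events": [
            {
                "row": r,
                "col": c,
                "force": e.force,
                "thickness": e.thickness,
                "z_start": e.z_start,
                "rank": e.rank,
                "curve_id": e.curve_id,
                "flags": list(e.flags),
            }
            for (r, c), events in sorted(analysis.events_by_cell.items())
            for e in events
        ],
        "analysed_cells": [list(c) for c in sorted(analysis.events_by_cell)],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_session(path: str | Path) -> GridAnalysis:
    """Rebuild a :class:`GridAnalysis` from a session JSON (no curves)."""
    payload = json.loads(Path(path).read_text())
    g = payload["grid"]
    grid = ForceGrid(
        n_rows=g["n_rows"],
        n_cols=g["n_cols"],
        physical_size=tuple(g["physical_size"]),
        acquisition_order=g.get("acquisition_order", "raster"),
    )
    det = payload["detection"]
    det["angles"] = tuple(det["angles"])
    detection = DetectionConfig(**det)
    thresholds = ThresholdConfig(**payload["thresholds"])
    events_by_cell: dict[tuple[int, int], list[BreakthroughEvent]] = {
        tuple(c): [] for c in map(tuple, payload.get("analysed_cells", []))
    }
    for rec in payload["events"]:
        cell = (rec["row"], rec["col"])
        events_by_cell.setdefault(cell, []).append(
            BreakthroughEvent(
                force=rec["force"],
                thickness=rec["thickness"],
                z_start=rec["z_start"],
                rank=rec["rank"],
                curve_id=rec["curve_id"],
                flags=tuple(rec["flags"]),
            )
        )
    return GridAnalysis(grid, events_by_cell, detection, thresholds)


@dataclass
class RunConfig:
    """Everything one full analysis run needs."""

    output_dir: str = "forcemapper_out"
    input_dir: str | None = None  # directory of curve files (None = session)
    manifest: str | None = None
    session: str | None = None  # reload instead of detecting
    n_rows: int = 16
    n_cols: int = 16
    physical_size: float = 5.0
    acquisition_order: str = "raster"
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    rank: str = "primary"
    cluster_seed: int = 0
    cluster_features: str = "both"
    value_range: tuple[float, float] | None = None
    formats: tuple[str, ...] = ("png",)

    def __post_init__(self) -> None:
        bad = set(self.formats) - {"png", "pdf", "svg", "csv", "json"}
        if bad:
            raise ValueError(f"unsupported output formats: {sorted(bad)}")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in vars(config).items()
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_analyse(config: RunConfig, grid: ForceGrid | None = None) -> dict:
    """Execute the full pipeline and write all artifacts.

    Input priority: an in-memory ``grid`` argument, then
    ``config.session`` (reload, skipping detection), then
    ``config.input_dir``.  On failure all partial outputs of this run are
    removed.  Returns a dict of artifact paths plus summary objects.
    """
    from .curve_io import read_force_grid

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if grid is not None:
            analysis = analyse_grid(grid, config.detection, config.thresholds)
        elif config.session is not None:
            analysis = load_session(config.session)
        elif config.input_dir is not None:
            grid = read_force_grid(
                config.input_dir,
                n_rows=config.n_rows,
                n_cols=config.n_cols,
                physical_size=config.physical_size,
                acquisition_order=config.acquisition_order,
                manifest=config.manifest,
            )
            analysis = analyse_grid(grid, config.detection, config.thresholds)
        else:
            raise ValueError("no input: provide a grid, input_dir or session")

        result: dict = {"config_hash": _config_hash(config)}

        events_df = events_to_dataframe(analysis)
        events_path = outdir / "events.csv"
        events_df.to_csv(events_path, index=False)
        written.append(events_path)

        session_path = save_session(analysis, outdir / "session.json")
        written.append(session_path)

        figure_formats = tuple(f for f in config.formats if f in ("png", "pdf", "svg"))
        maps = {}
        for channel in ("force", "thickness"):
            fmap = assemble_map(
                analysis.grid, analysis.events_by_cell, channel=channel, rank_used=config.rank
            )
            written.extend(save_map(fmap, outdir / f"{channel}_map"))
            if figure_formats:
                vr = config.value_range if channel == "force" else None
                fig = map_to_image(
                    fmap, value_range=vr, path=outdir / f"{channel}_map", formats=figure_formats
                )
                written.extend(outdir / f"{channel}_map.{f}" for f in figure_formats)
                import matplotlib.pyplot as plt

                plt.close(fig)
            maps[channel] = fmap
        result["maps"] = maps

        cells, points = analysis.primary_points()
        if len(points) >= 2 and np.unique(points, axis=0).shape[0] >= 2:
            labels = cluster_two(points, seed=config.cluster_seed, features=config.cluster_features)
            phases = assign_phases(labels, points)
            summary = phase_summary(
                phases, points, seed=config.cluster_seed, features=config.cluster_features
            )
            phase_raster = cluster_map(analysis.grid.shape, dict(zip(cells, phases)))
            summary_df = pd.DataFrame(
                {
                    "phase": ["Ld", "Lo"],
                    "points_pct": [summary.point_fraction[p] for p in ("Ld", "Lo")],
                    "thickness_mean_nm": [summary.thickness_mean[p] for p in ("Ld", "Lo")],
                    "thickness_sd_nm": [summary.thickness_sd[p] for p in ("Ld", "Lo")],
                    "force_mean_nN": [summary.force_mean[p] for p in ("Ld", "Lo")],
                    "max_mismatch_nm": [summary.max_mismatch] * 2,
                }
            )
            summary_path = outdir / "phase_summary.csv"
            summary_df.to_csv(summary_path, index=False)
            written.append(summary_path)
            raster_path = outdir / "cluster_map.csv"
            np.savetxt(raster_path, phase_raster, delimiter=",", fmt="%s")
            written.append(raster_path)
            result["phase_summary"] = summary
            result["cluster_map"] = phase_raster
        else:
            result["phase_summary"] = None

        stats_path = outdir / "peak_statistics.json"
        stats_path.write_text(
            json.dumps(
                {
                    rank: peak_statistics(analysis.events(), rank=rank)
                    for rank in ("primary", "secondary")
                },
                indent=2,
            )
        )
        written.append(stats_path)

        meta_path = outdir / "run_meta.json"
        meta_path.write_text(
            json.dumps(
                {
                    "config_hash": result["config_hash"],
                    "rank": config.rank,
                    "cluster_seed": config.cluster_seed,
                    "cluster_features": config.cluster_features,
                    "spacing_um": grid_spacing(analysis.grid),
                    "n_cells_analysed": len(analysis.events_by_cell),
                },
                indent=2,
            )
        )
        written.append(meta_path)
        result["paths"] = [str(p) for p in written]
        result["analysis"] = analysis
        return result
    except Exception:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise
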