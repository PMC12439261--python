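"""End-to-end orchestration: movie → filtered stack → localizations →
tracks → super-resolution maps → subtypes → vascular parameters.

Every run resolves a full parameter set (defaults + overrides), writes it
to ``resolved-config.yaml`` before any stage executes, and records
per-stage counts in a machine-readable run log.  Outputs carry no
timestamps, so identical config + inputs reproduce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import io as lio
from .errors import HilumRequiredError, LnulmError
from .localize import PSFModel, localize_frames
from .mapping import RoiPolygon, accumulate_map, apply_roi
from .preprocess import (
    default_low_rank,
    reject_motion_frames,
    rigid_compensate,
    select_frames,
    svd_filter,
)
from .subtypes import (
    SubtypeResult,
    classify_tracks,
    compute_params,
    compute_velocity_threshold,
)
from .tracking import link_tracks


@dataclass
class PipelineConfig:
    """Fully explicit parameter set of one pipeline run."""

    # inputs (paths; may be left None when objects are passed to run_pipeline)
    movie: str | None = None
    roi: str | None = None
    out_dir: str = "lnulm-out"
    seed: int = 42

    # preprocess
    do_reject_frames: bool = True
    min_correlation: float = 0.9
    do_compensate: bool = True
    upsample: int = 10
    low_rank: int | None = None  # None -> ceil(0.05 * n_frames)
    high_rank: int | None = None

    # localize
    threshold_k: float = 5.0
    min_peak_factor: float = 1.3
    psf_fwhm_axial_um: float = 143.0
    psf_fwhm_lateral_um: float = 173.0
    area_bounds: tuple = (0.5, 3.0)
    min_shape_corr: float = 0.6
    min_peak: float = 0.0

    # track
    vmax_mm_s: float = 50.0
    min_track_length: int = 5

    # map / subtype
    sr_factor: int = 4

    # histology
    opening_radius: int = 1

    save_intermediate: bool = True

    def resolved(self, n_frames: int) -> dict:
        d = asdict(self)
        d["low_rank"] = self.low_rank if self.low_rank is not None else default_low_rank(n_frames)
        d["max_link_distance_um"] = self.max_link_distance_um(
            frame_rate_hz=None if "frame_rate_hz" not in d else d["frame_rate_hz"]
        )
        return d

    def max_link_distance_um(self, frame_rate_hz: float | None = None) -> float | None:
        if frame_rate_hz is None:
            return None
        return self.vmax_mm_s * 1000.0 / frame_rate_hz

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["area_bounds"] = list(self.area_bounds)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        d = {k: v for k, v in d.items() if k in known}
        if "area_bounds" in d and d["area_bounds"] is not None:
            d["area_bounds"] = tuple(d["area_bounds"])
        return cls(**d)


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def _save_grid(grid, out_dir: Path, stem: str):
    tifffile.imwrite(out_dir / f"{stem}_counts.tif", grid.counts.astype(np.uint16))
    tifffile.imwrite(out_dir / f"{stem}_velocity.tif", grid.velocity.astype(np.float32))
    tifffile.imwrite(out_dir / f"{stem}_direction.tif", grid.direction.astype(np.float32))
    meta = {
        "factor": int(grid.factor),
        "pixel_size_axial_um": grid.pixel_size_axial_um,
        "pixel_size_lateral_um": grid.pixel_size_lateral_um,
        "has_roi": grid.roi_mask is not None,
    }
    _write_json(meta, out_dir / f"{stem}_meta.json")
    if grid.roi_mask is not None:
        tifffile.imwrite(out_dir / f"{stem}_roi.tif", grid.roi_mask.astype(np.uint8))


def run_pipeline(
    config: PipelineConfig,
    movie=None,
    roi_vertices_um=None,
    hilum_um=None,
) -> dict:
    """Execute every stage and write the result bundle to ``config.out_dir``.

    Inputs may be given as in-memory objects (``movie`` a FrameSequence,
    ``roi_vertices_um`` a vertex list, ``hilum_um`` a point) or as the
    paths in the config.  Returns a dict with tracks, grids, subtype
    result, per-scope vascular parameters and the run log.  A missing
    hilum is not fatal: whole-node outputs complete and the subtype stage
    records the exclusion.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if movie is None:
        if config.movie is None:
            raise LnulmError("no movie supplied (neither object nor path)")
        movie = lio.read_movie(config.movie)
    if roi_vertices_um is None and config.roi is not None:
        roi_data = lio.read_roi(config.roi)
        roi_vertices_um = roi_data["vertices_um"]
        if hilum_um is None:
            hilum_um = roi_data.get("hilum_um")

    resolved = asdict(config)
    resolved["area_bounds"] = list(config.area_bounds)
    resolved["low_rank_resolved"] = (
        config.low_rank if config.low_rank is not None else default_low_rank(movie.n_frames)
    )
    resolved["max_link_distance_um"] = config.vmax_mm_s * 1000.0 / movie.frame_rate_hz
    (out_dir / "resolved-config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))

    log: dict = {"n_frames_in": int(movie.n_frames)}

    # --- preprocess -------------------------------------------------------
    seq = movie
    frame_indices = list(range(seq.n_frames))
    if config.do_reject_frames:
        rep = reject_motion_frames(seq, config.min_correlation)
        frame_indices = list(rep.kept_frames)
        seq = select_frames(seq, frame_indices)
        log["frames_kept"] = len(frame_indices)
    if config.do_compensate:
        seq, shift_rep = rigid_compensate(seq, reference_index=0, upsample=config.upsample)
        log["max_abs_shift_px"] = float(np.abs(shift_rep.shifts_px).max())
    filtered, svd_rep = svd_filter(
        seq, resolved["low_rank_resolved"], config.high_rank
    )
    _write_json(
        {
            "singular_values": [float(s) for s in svd_rep.singular_values],
            "band": list(svd_rep.band),
            "kept_frames": frame_indices,
        },
        out_dir / "filter-report.json",
    )

    # --- localize ---------------------------------------------------------
    model = PSFModel(
        fwhm_axial_um=config.psf_fwhm_axial_um,
        fwhm_lateral_um=config.psf_fwhm_lateral_um,
        area_bounds=config.area_bounds,
        min_shape_corr=config.min_shape_corr,
        min_peak=config.min_peak,
    )
    locs, loc_log = localize_frames(
        filtered.frames,
        model,
        movie.pixel_sizes,
        threshold_k=config.threshold_k,
        min_peak_factor=config.min_peak_factor,
        frame_indices=frame_indices,
    )
    log.update(loc_log)
    if config.save_intermediate:
        lio.localizations_to_csv(locs, out_dir / "localizations.csv")

    # --- track ------------------------------------------------------------
    gate = config.vmax_mm_s * 1000.0 / movie.frame_rate_hz
    tracks, track_log = link_tracks(
        locs, gate, config.min_track_length, movie.frame_rate_hz
    )
    log.update(track_log)
    lio.tracks_to_csv(tracks, out_dir / "tracks.csv", out_dir / "tracks-summary.csv")

    # --- map --------------------------------------------------------------
    grid = accumulate_map(tracks, config.sr_factor, movie.shape, movie.pixel_sizes)
    roi = None
    if roi_vertices_um is not None:
        roi = RoiPolygon(vertices_um=roi_vertices_um, hilum_um=hilum_um)
        grid = apply_roi(grid, roi)
    _save_grid(grid, out_dir, "map_whole")

    # --- subtype + parameters --------------------------------------------
    results: dict = {
        "tracks": tracks,
        "grid": grid,
        "log": log,
        "params": {},
        "subtypes": None,
    }
    params_rows = []
    whole = compute_params(tracks, grid)
    results["params"]["whole"] = whole
    params_rows.append({"scope": "whole", **whole.to_dict()})

    subtype_error = None
    if tracks:
        threshold, provenance = compute_velocity_threshold(grid)
        log["velocity_threshold_mm_s"] = threshold
        log["threshold_provenance"] = provenance
        try:
            sub = classify_tracks(
                tracks,
                threshold,
                hilum_um,
                threshold_provenance=provenance,
                map_spec={
                    "factor": config.sr_factor,
                    "fov_shape": movie.shape,
                    "pixel_sizes": movie.pixel_sizes,
                },
            )
            results["subtypes"] = sub
            log["type_counts"] = {str(k): v for k, v in sub.type_counts.items()}
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "track_id": t.track_id,
                        "label": sub.labels[t.track_id],
                        "mean_speed_mm_s": t.mean_speed_mm_s,
                        "radial_score": sub.radial_scores[t.track_id],
                    }
                    for t in tracks
                ]
            ).to_csv(out_dir / "subtypes.csv", index=False)
            for lab, name in ((1, "type1"), (2, "type2"), (3, "type3")):
                sel = sub.tracks_of_type(tracks, lab)
                g = sub.type_grids[lab]
                if roi is not None:
                    g = apply_roi(g, roi)
                _save_grid(g, out_dir, f"map_{name}")
                p = compute_params(sel, g)
                results["params"][name] = p
                params_rows.append({"scope": name, **p.to_dict()})
        except HilumRequiredError as e:
            subtype_error = str(e)
            log["subtype_excluded"] = subtype_error

    import pandas as pd

    pd.DataFrame(params_rows).to_csv(out_dir / "vascular-params.csv", index=False)
    _write_json(log, out_dir / "run-log.json")
    return results
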