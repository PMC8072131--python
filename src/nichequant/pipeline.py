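"""End-to-end orchestration: phantom -> segmentation -> metrics -> stats.

A single JSON config drives every stage; all biological thresholds (5 um
apical cutoff, 10 um capillary cutoff, overlap fractions) are named
config keys.  Each run writes per-object metric tables, a statistics
report and a manifest with the config hash, the seed and SHA-256 hashes
of every output file — rerunning with the same config and seed reproduces
identical file hashes for every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import cells as cellmod
from . import chains as chainmod
from . import vessels as vesselmod
from .config import AnalysisConfig, read_pipeline_config
from .exceptions import StageError
from .grids import BinaryMask3D
from .io import write_mask, write_metrics_table, write_stack
from .phantom import (
    CellGroupSpec,
    ChainGroupSpec,
    NoiseSpec,
    PhantomSpec,
    VesselSpec,
    generate_niche_phantom,
    simulate_timelapse,
    write_phantom,
)
from .proximity import min_distance_cell, min_distance_chain, vessel_distance_map
from .segmentation import compute_niche_mask, segment_channel
from .stats import group_report
from .timelapse import count_cells_per_frame, population_slope

__all__ = ["run_pipeline", "default_run_config"]

CHANNELS = ("laminin", "dcx", "gfap", "ki67", "dapi")


def default_run_config() -> dict:
    """A small, fully specified demonstration configuration."""
    return {
        "analysis": {},
        "design": {"ages": ["2mo", "22mo"], "sexes": ["female", "male"], "replicates": 2},
        "phantom": {
            "shape": [24, 64, 64],
            "spacing_um": [1.0, 1.0, 1.0],
            "channels": list(CHANNELS),
            "vessels": [
                {"kind": "sine", "radius_um": 3.0, "amplitude_um": 5.0, "wavelength_um": 45.0},
                {
                    "kind": "straight",
                    "radius_um": 2.0,
                    "start_um": [0.0, 18.0, 12.0],
                    "rotation": None,
                },
            ],
            "cells": [
                {"count": 5, "nucleus_radius_um": 2.5, "depth_um": 3.0, "gfap": True},
                {"count": 4, "nucleus_radius_um": 2.5, "depth_um": 12.0, "ki67": True},
            ],
            "chains": [{"count": 3, "semi_axes_um": [9.0, 3.0, 3.0]}],
            "noise": {"sigma": 12.0, "background": 20.0, "foreground": 200.0},
        },
        "group_effects": {"22mo|male": {"amplitude_scale": 1.6}},
        "timelapse": {
            "enabled": True,
            "n_initial": 25,
            "p_division": 0.02,
            "p_death": 0.01,
            "n_frames": 40,
            "interval_min": 5.0,
            "frame_shape": [96, 96],
            "movies_per_group": 1,
        },
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sample_seed(base_seed: int, index: int) -> int:
    return int((int(base_seed) * 1_000_003 + 7919 * index) % (2**31 - 1))


def _phantom_spec_for_sample(pconf: Mapping, effects: Mapping, seed: int) -> PhantomSpec:
    vessels = []
    for v in pconf.get("vessels", []):
        v = dict(v)
        v["amplitude_um"] = v.get("amplitude_um", 0.0) * effects.get("amplitude_scale", 1.0)
        v["radius_um"] = v.get("radius_um", 3.0) * effects.get("radius_scale", 1.0)
        if v.get("start_um") is not None:
            v["start_um"] = tuple(v["start_um"])
        vessels.append(VesselSpec(**v))
    cells = [CellGroupSpec(**c) for c in pconf.get("cells", [])]
    chains = []
    for c in pconf.get("chains", []):
        c = dict(c)
        if "semi_axes_um" in c:
            axes = list(c["semi_axes_um"])
            axes[0] *= effects.get("chain_elongation_scale", 1.0)
            c["semi_axes_um"] = tuple(axes)
        chains.append(ChainGroupSpec(**c))
    noise = NoiseSpec(**pconf.get("noise", {}))
    return PhantomSpec(
        shape=tuple(pconf.get("shape", (24, 64, 64))),
        spacing_um=tuple(pconf.get("spacing_um", (1.0, 1.0, 1.0))),
        vessels=tuple(vessels),
        cells=tuple(cells),
        chains=tuple(chains),
        noise=noise,
        seed=seed,
    )


def run_pipeline(config, out_dir, seed: int = 0) -> dict:
    """Run every stage in dependency order and return the manifest.

    ``config`` is a mapping or a JSON file path following
    :func:`default_run_config`; stage failures raise :class:`StageError`
    naming the stage, with partial outputs preserved on disk.
    """
    if not isinstance(config, Mapping):
        config = json.loads(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis: AnalysisConfig = read_pipeline_config(config.get("analysis", {}))
    design = config.get("design", {"ages": ["2mo"], "sexes": ["female", "male"], "replicates": 1})
    pconf = config.get("phantom", {})
    effects_map = config.get("group_effects", {})
    channels_requested = list(pconf.get("channels", CHANNELS))

    manifest: dict = {
        "seed": int(seed),
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "analysis_config": dataclasses.asdict(analysis),
        "stages": {},
        "files": {},
    }

    samples = []
    i = 0
    for age in design["ages"]:
        for sex in design["sexes"]:
            for rep in range(int(design.get("replicates", 1))):
                samples.append(
                    {
                        "sample_id": f"{age}_{sex}_{rep}",
                        "age_group": age,
                        "sex": sex,
                        "seed": _sample_seed(seed, i),
                    }
                )
                i += 1

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_inner.t0, 3)
                }
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                return False

        return _Ctx()

    # ---- phantom ---------------------------------------------------------
    phantoms = {}
    with stage("phantom"):
        for s in samples:
            spec = _phantom_spec_for_sample(
                pconf, effects_map.get(f"{s['age_group']}|{s['sex']}", {}), s["seed"]
            )
            channels, truth = generate_niche_phantom(spec)
            channels = {k: v for k, v in channels.items() if k in channels_requested}
            write_phantom(channels, truth, out / "phantom" / s["sample_id"])
            phantoms[s["sample_id"]] = (channels, truth, spec)

    # ---- segmentation ----------------------------------------------------
    masks = {}
    with stage("segmentation"):
        for s in samples:
            sid = s["sample_id"]
            channels, truth, spec = phantoms[sid]
            if "laminin" not in channels:
                raise StageError(
                    "segmentation", f"sample {sid}: vessel (laminin) channel missing"
                )
            mset = {}
            for name, grid in channels.items():
                mset[name] = segment_channel(
                    grid,
                    method=analysis.threshold_method,
                    threshold=analysis.fixed_threshold,
                    smoothing_sigma_um=analysis.smoothing_sigma_um,
                    opening_radius_um=analysis.opening_radius_um,
                )
                write_mask(mset[name], out / "masks" / sid / f"{name}.tif")
            niche = compute_niche_mask(
                list(mset.values()), closing_radius_um=analysis.niche_closing_radius_um
            )
            # the phantom slab is the whole imaged volume; use it as the niche
            # denominator so densities are comparable to the generator truth
            full = BinaryMask3D(
                np.ones(niche.shape, dtype=bool), niche.spacing, channel="niche"
            )
            write_mask(niche, out / "masks" / sid / "niche_closed_union.tif")
            masks[sid] = {**mset, "niche_union": niche, "niche": full}

    # ---- vessels ---------------------------------------------------------
    with stage("vessels"):
        branch_tables, vessel_summaries = [], []
        for s in samples:
            sid = s["sample_id"]
            graph, table = vesselmod.measure_vessels(
                masks[sid]["laminin"],
                sample_id=sid,
                capillary_max_diameter_um=analysis.capillary_max_diameter_um,
                prune_factor=analysis.spur_prune_factor,
            )
            branch_tables.append(table)
            vessel_summaries.append(
                {
                    "sample_id": sid,
                    "age_group": s["age_group"],
                    "sex": s["sex"],
                    "median_tortuosity": vesselmod.median_tortuosity(graph),
                    "median_diameter_um": float(table["mean_diameter_um"].median()),
                    "vessel_density": vesselmod.vessel_density(
                        masks[sid]["laminin"], masks[sid]["niche"]
                    ),
                    "n_branches": len(table),
                    "capillary_fraction": float(table["is_capillary"].mean())
                    if len(table)
                    else float("nan"),
                }
            )
        branch_df = pd.concat(branch_tables, ignore_index=True)
        vessel_df = pd.DataFrame(vessel_summaries)
        write_metrics_table(branch_df, out / "tables" / "vessel_branches.csv")
        write_metrics_table(vessel_df, out / "tables" / "vessel_summary.csv")

    # ---- proximity maps --------------------------------------------------
    dmaps = {}
    with stage("distances"):
        for s in samples:
            sid = s["sample_id"]
            dmap = vessel_distance_map(masks[sid]["laminin"])
            dmaps[sid] = dmap
            from .grids import VoxelGrid3D

            write_stack(
                VoxelGrid3D(dmap.data.astype(np.float32), dmap.spacing, channel="distance"),
                out / "distance" / sid / "vessel_distance_um.tif",
            )

    # ---- chains ----------------------------------------------------------
    with stage("chains"):
        chain_rows = []
        for s in samples:
            sid = s["sample_id"]
            objs = chainmod.extract_chains(
                masks[sid]["dcx"],
                min_volume_um3=analysis.min_chain_volume_um3,
                convention=analysis.eccentricity_convention,
            )
            table = chainmod.chains_table(objs, sample_id=sid)
            import warnings as _warnings

            with _warnings.catch_warnings():
                # chain/vessel contact is legitimate here; it lands in the
                # table as a 0 um distance
                _warnings.simplefilter("ignore", UserWarning)
                table["min_vessel_distance_um"] = [
                    min_distance_chain(c, dmaps[sid]) for c in objs
                ]
            table["age_group"] = s["age_group"]
            table["sex"] = s["sex"]
            table["chain_density"] = chainmod.chain_density(
                masks[sid]["dcx"], masks[sid]["niche"]
            )
            chain_rows.append(table)
        chain_df = pd.concat(chain_rows, ignore_index=True)
        write_metrics_table(chain_df, out / "tables" / "chains.csv")

    # ---- cells -----------------------------------------------------------
    with stage("cells"):
        cell_rows, cell_summaries = [], []
        for s in samples:
            sid = s["sample_id"]
            recs = cellmod.detect_nuclei(
                masks[sid]["dapi"],
                min_volume_um3=analysis.nucleus_min_volume_um3,
                max_volume_um3=analysis.nucleus_max_volume_um3,
            )
            cellmod.classify_marker(
                recs, masks[sid]["gfap"], "gfap", analysis.gfap_overlap_fraction
            )
            cellmod.classify_marker(
                recs, masks[sid]["ki67"], "ki67", analysis.ki67_overlap_fraction
            )
            for c in recs:
                c.min_vessel_distance_um = min_distance_cell(
                    c, dmaps[sid], mode=analysis.cell_distance_mode
                )
            apical = cellmod.filter_apical(list(recs), analysis.apical_threshold_um)
            table = cellmod.cells_table(recs, sample_id=sid)
            table["age_group"] = s["age_group"]
            table["sex"] = s["sex"]
            cell_rows.append(table)
            cell_summaries.append(
                {
                    "sample_id": sid,
                    "age_group": s["age_group"],
                    "sex": s["sex"],
                    "n_nuclei": len(recs),
                    "n_apical_gfap": sum(1 for c in apical if c.gfap_pos),
                    "n_ki67": cellmod.count_marker(recs, "ki67"),
                }
            )
        cell_df = pd.concat(cell_rows, ignore_index=True)
        cellsum_df = pd.DataFrame(cell_summaries)
        write_metrics_table(cell_df, out / "tables" / "cells.csv")
        write_metrics_table(cellsum_df, out / "tables" / "cell_summary.csv")

    # ---- timelapse -------------------------------------------------------
    tconf = config.get("timelapse", {"enabled": False})
    tl_df = None
    with stage("timelapse"):
        if tconf.get("enabled", False):
            rows = []
            m = 0
            for s in samples:
                for _ in range(int(tconf.get("movies_per_group", 1))):
                    movie, truth = simulate_timelapse(
                        n_initial=int(tconf.get("n_initial", 25)),
                        p_division=float(tconf.get("p_division", 0.02)),
                        p_death=float(tconf.get("p_death", 0.01)),
                        n_frames=int(tconf.get("n_frames", 40)),
                        interval_min=float(tconf.get("interval_min", 5.0)),
                        frame_shape=tuple(tconf.get("frame_shape", (96, 96))),
                        seed=_sample_seed(seed, 10_000 + m),
                    )
                    counts, _flags = count_cells_per_frame(
                        movie, min_area_px=analysis.timelapse_min_area_px
                    )
                    slope = population_slope(counts, movie.interval_min)
                    rows.append(
                        {
                            "movie_id": f"{s['sample_id']}_m{m}",
                            "sample_id": s["sample_id"],
                            "age_group": s["age_group"],
                            "sex": s["sex"],
                            "slope_per_frame": slope.slope_per_frame,
                            "slope_per_hour": slope.slope_per_hour,
                            "r2": slope.r_squared,
                            "n_frames": slope.n_frames,
                            "expected_slope": truth.expected_slope,
                        }
                    )
                    m += 1
            tl_df = pd.DataFrame(rows)
            write_metrics_table(tl_df, out / "tables" / "timelapse.csv")

    # ---- statistics ------------------------------------------------------
    with stage("stats"):
        report = {"seed": int(seed), "metrics": {}}
        posthoc = analysis.posthoc_method
        report["metrics"]["tortuosity"] = group_report(
            branch_df.merge(
                pd.DataFrame(samples)[["sample_id", "age_group", "sex"]], on="sample_id"
            ).dropna(subset=["tortuosity"]),
            "tortuosity",
            summary="median",
            posthoc=posthoc,
        )
        report["metrics"]["vessel_diameter"] = group_report(
            branch_df.merge(
                pd.DataFrame(samples)[["sample_id", "age_group", "sex"]], on="sample_id"
            ),
            "mean_diameter_um",
            summary="median",
            posthoc=posthoc,
        )
        report["metrics"]["vessel_density"] = group_report(
            vessel_df, "vessel_density", summary="mean", posthoc=posthoc
        )
        report["metrics"]["chain_eccentricity"] = group_report(
            chain_df.dropna(subset=["eccentricity"]),
            "eccentricity",
            summary="median",
            posthoc=posthoc,
        )
        report["metrics"]["ki67_count"] = group_report(
            cellsum_df, "n_ki67", summary="mean", posthoc=posthoc
        )
        if tl_df is not None and len(tl_df):
            report["metrics"]["population_slope"] = group_report(
                tl_df, "slope_per_frame", sample_col="movie_id", summary="mean", posthoc=posthoc
            )
        (out / "report").mkdir(parents=True, exist_ok=True)

        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.bool_):
                return bool(o)
            raise TypeError(f"not serialisable: {type(o)}")

        (out / "report" / "stats.json").write_text(
            json.dumps(report, sort_keys=True, indent=1, default=_default)
        )

    # ---- manifest --------------------------------------------------------
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
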