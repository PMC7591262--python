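"""Stage runner behind the command-line interface.

Each stage reads its inputs from a directory (written by the ``simulate``
stage or by the user in the documented formats), runs the corresponding
library module at the sizes given in the run configuration, and writes
CSV/JSON artifacts plus a machine-readable run log recording the seed,
package version, and parameters.  All randomness derives from
``RunConfig.seed``, so a stage rerun with the same seed writes identical
numbers.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coloc, frap, fret, morpho, screen, segtile, syndata
from .io_core import (
    RunConfig,
    read_image_stack,
    read_roi_set,
    write_image_stack,
    write_roi_set,
)
from .nnet import ModelConfig, TrainSchedule

STAGES = [
    "simulate",
    "coloc",
    "fret",
    "damfret",
    "frap",
    "morpho",
    "segtrain",
    "seginfer",
    "screen",
]

# Desk-scale fixture sizes for the simulate stage
SIM_N_COLOC_CELLS = 8
SIM_N_BLEACH_PAIRS = 20
SIM_N_FRAP_TRACES = 10
SIM_N_DAMFRET_EVENTS = 2000
SIM_N_NUCLEI_PER_GROUP = 20
SIM_N_SCREEN_STRAINS = 500
SIM_N_SCREEN_HITS = 12
SIM_N_BLOB_FRAMES = 8


def _write_log(out: Path, stage: str, config: RunConfig) -> None:
    log = {
        "stage": stage,
        "seed": config.seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "parameters": config.to_dict(),
    }
    with open(out / f"{stage}_runlog.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=1)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing input: {path}")
    return path


def run_stage(
    stage: str, config: RunConfig, out_dir: str | Path, in_dir: str | Path | None = None
) -> None:
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inp = Path(in_dir) if in_dir is not None else out
    getattr(_Stages, stage)(config, out, inp)
    _write_log(out, stage, config)


class _Stages:
    @staticmethod
    def simulate(config: RunConfig, out: Path, inp: Path) -> None:
        seed = config.seed
        # colocalization cells
        spec = syndata.CellSpec(coloc_fraction=0.5)
        images, roisets, gt = syndata.simulate_coloc_cells(
            SIM_N_COLOC_CELLS, spec, seed=seed
        )
        for i, (img, rs) in enumerate(zip(images, roisets)):
            write_image_stack(out / f"coloc_cell{i}.tif", img)
            write_roi_set(out / f"coloc_cell{i}.rois.json", rs)
        gt.to_json(out / "coloc_truth.json")
        # bleach pairs
        pairs, rois, gt = syndata.simulate_bleach_pairs(
            SIM_N_BLEACH_PAIRS, e_true=0.40, seed=seed + 1
        )
        for i, ((pre, post), rs) in enumerate(zip(pairs, rois)):
            write_image_stack(out / f"bleach_cell{i}_pre.tif", pre)
            write_image_stack(out / f"bleach_cell{i}_post.tif", post)
            write_roi_set(out / f"bleach_cell{i}.rois.json", rs)
        gt.to_json(out / "bleach_truth.json")
        # FRAP traces
        traces, gt = syndata.simulate_frap_series(
            SIM_N_FRAP_TRACES, m_true=0.0, seed=seed + 2
        )
        rows = []
        for tr in traces:
            for t, b, r in zip(tr.t, tr.bleached, tr.reference):
                rows.append(
                    {"trace": tr.label, "t": t, "bleached": b,
                     "reference": r, "pre": tr.pre}
                )
        pd.DataFrame(rows).to_csv(out / "frap_traces.csv", index=False)
        gt.to_json(out / "frap_truth.json")
        # nuclei
        nuclei, gt = syndata.simulate_nuclei(
            SIM_N_NUCLEI_PER_GROUP, sigmas=[10.0, 6.0], seed=seed + 3
        )
        for i, img in enumerate(nuclei):
            write_image_stack(out / f"nucleus{i}.tif", img)
        gt.to_json(out / "nuclei_truth.json")
        # EM sections
        stack, cells, gt = syndata.simulate_em_sections(
            n_cells=9,
            objects_per_cell={"vesicle": 3.0, "lipid_droplet": 2.0,
                              "mitochondrion": 2.0},
            seed=seed + 4,
        )
        write_image_stack(out / "em_sections.tif", stack)
        write_roi_set(out / "em_cells.rois.json", cells)
        gt.to_json(out / "em_truth.json")
        # DAmFRET events
        sample, control, gt = syndata.simulate_damfret_events(
            SIM_N_DAMFRET_EVENTS, model="always_assembled", seed=seed + 5
        )
        sample.to_csv(out / "damfret_sample.csv", index=False)
        control.to_csv(out / "damfret_control.csv", index=False)
        gt.to_json(out / "damfret_truth.json")
        # screen table
        table, gt = syndata.simulate_screen_table(
            SIM_N_SCREEN_STRAINS, n_hits=SIM_N_SCREEN_HITS, seed=seed + 6
        )
        table.to_csv(out / "screen_table.csv", index=False)
        gt.to_json(out / "screen_truth.json")
        # blob frames for segmentation
        frames, blob_rois, gt = syndata.simulate_blob_fields(
            SIM_N_BLOB_FRAMES, seed=seed + 7
        )
        for i, (frame, rs) in enumerate(zip(frames, blob_rois)):
            write_image_stack(
                out / f"blobs{i}.tif",
                syndata.ImageStack(frame[None, None], channel_names=["blobs"]),
            )
            write_roi_set(out / f"blobs{i}.rois.json", rs)
        gt.to_json(out / "blobs_truth.json")

    @staticmethod
    def coloc(config: RunConfig, out: Path, inp: Path) -> None:
        per_cell_rows = []
        curves = []
        i = 0
        while (inp / f"coloc_cell{i}.tif").exists():
            img = read_image_stack(inp / f"coloc_cell{i}.tif")
            rs = read_roi_set(_require(inp / f"coloc_cell{i}.rois.json"))
            profile = coloc.extract_profile(img, rs.rois[0], "ch1", "ch2")
            shifts, r, _ = coloc.shift_correlation(profile, config.max_shift)
            curves.append((shifts, r))
            for s, rv in zip(shifts, r):
                per_cell_rows.append({"cell": i, "shift": int(s), "r": rv})
            i += 1
        if i == 0:
            raise FileNotFoundError(f"missing input: {inp / 'coloc_cell0.tif'}")
        pd.DataFrame(per_cell_rows).to_csv(out / "coloc_per_cell.csv", index=False)
        curve = coloc.aggregate_curves(curves, min_cells=config.min_cells)
        pd.DataFrame(
            {"shift": curve.shifts, "mean_r": curve.r, "se": curve.se, "n": curve.n}
        ).to_csv(out / "coloc_aggregate.csv", index=False)

    @staticmethod
    def fret(config: RunConfig, out: Path, inp: Path) -> None:
        measurements = []
        i = 0
        while (inp / f"bleach_cell{i}_pre.tif").exists():
            pre = read_image_stack(inp / f"bleach_cell{i}_pre.tif")
            post = read_image_stack(_require(inp / f"bleach_cell{i}_post.tif"))
            rs = read_roi_set(_require(inp / f"bleach_cell{i}.rois.json"))
            measurements.append(
                fret.measure_bleach_pair(pre, post, rs.rois[0], cell_id=f"cell{i}")
            )
            i += 1
        if not measurements:
            raise FileNotFoundError(f"missing input: {inp / 'bleach_cell0_pre.tif'}")
        summary = fret.summarize_fret(
            measurements, min_bleach_depth=config.min_bleach_depth
        )
        summary.table.to_csv(out / "fret_per_cell.csv", index=False)
        summary.exclusions.to_csv(out / "fret_exclusions.csv", index=False)
        with open(out / "fret_summary.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "mean_e_percent": summary.mean_percent,
                    "se_percent": None if summary.se is None else 100 * summary.se,
                    "n": summary.n,
                },
                fh,
                indent=1,
            )

    @staticmethod
    def damfret(config: RunConfig, out: Path, inp: Path) -> None:
        sample = pd.read_csv(_require(inp / "damfret_sample.csv"))
        control = pd.read_csv(_require(inp / "damfret_control.csv"))
        sample = fret.compute_amfret(sample, min_acceptor=config.min_acceptor)
        control = fret.compute_amfret(control, min_acceptor=config.min_acceptor)
        sample.to_csv(out / "damfret_sample_amfret.csv", index=False)
        call = fret.detect_nucleation(
            sample,
            control,
            quantile=config.control_quantile,
            n_bins=config.n_expression_bins,
            min_events_per_bin=config.min_events_per_bin,
        )
        with open(out / "damfret_call.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "verdict": call.verdict,
                    "fraction_below_gate": call.fraction_below_gate,
                    "changepoint": call.changepoint,
                    "bin_edges": call.bin_edges.tolist(),
                    "bin_fraction_below": call.bin_fraction_below.tolist(),
                    "gate": call.gate.tolist(),
                },
                fh,
                indent=1,
            )

    @staticmethod
    def frap(config: RunConfig, out: Path, inp: Path) -> None:
        table = pd.read_csv(_require(inp / "frap_traces.csv"))
        rows = []
        for label, grp in table.groupby("trace"):
            trace = frap.FRAPTrace(
                t=grp["t"].to_numpy(),
                bleached=grp["bleached"].to_numpy(),
                reference=grp["reference"].to_numpy(),
                pre=float(grp["pre"].iloc[0]),
                label=str(label),
            )
            fit = frap.fit_recovery(
                trace, solid_like_threshold=config.solid_like_threshold
            )
            rows.append(
                {
                    "trace": label,
                    "mobile_fraction": fit.mobile_fraction,
                    "rate_per_s": fit.rate,
                    "f0": fit.f0,
                    "rss": fit.rss,
                    "converged": fit.converged,
                    "classification": fit.classification,
                }
            )
        pd.DataFrame(rows).to_csv(out / "frap_fits.csv", index=False)

    @staticmethod
    def morpho(config: RunConfig, out: Path, inp: Path) -> None:
        rows = []
        i = 0
        while (inp / f"nucleus{i}.tif").exists():
            img = read_image_stack(inp / f"nucleus{i}.tif")
            try:
                fit = morpho.fit_nucleus_2d(img, img.channel_names[0])
                rows.append(
                    {
                        "nucleus": i,
                        "group": img.meta.get("group"),
                        "sigma_px": fit.sigma,
                        "fwhm_px": fit.fwhm,
                        "converged": True,
                    }
                )
            except morpho.FitError:
                rows.append(
                    {"nucleus": i, "group": None, "sigma_px": np.nan,
                     "fwhm_px": np.nan, "converged": False}
                )
            i += 1
        if rows:
            pd.DataFrame(rows).to_csv(out / "nucleus_fits.csv", index=False)
        em_path = inp / "em_sections.tif"
        if em_path.exists():
            stack = read_image_stack(em_path)
            cells = read_roi_set(_require(inp / "em_cells.rois.json"))
            class_map = {v: k for k, v in syndata.EM_CLASS_CODES.items()}
            objects, counts = morpho.count_objects_per_cell(stack, cells, class_map)
            objects.to_csv(out / "em_objects.csv", index=False)
            counts.to_csv(out / "em_counts_per_cell.csv")
            volumes = morpho.volumes_3d(stack, class_map=class_map)
            volumes.to_csv(out / "em_volumes.csv", index=False)
        if not rows and not em_path.exists():
            raise FileNotFoundError(f"missing input: {inp / 'nucleus0.tif'}")

    @staticmethod
    def segtrain(config: RunConfig, out: Path, inp: Path) -> None:
        samples = _load_blob_samples(inp)
        if len(samples) < 2:
            raise FileNotFoundError(f"missing input: {inp / 'blobs0.tif'}")
        n_val = max(1, len(samples) // 5)  # one fifth of frames validate
        val_frames, train_frames = samples[:n_val], samples[n_val:]
        window = min(config.tile_window, 64)
        stride = int(window * (1 - config.tile_overlap)) or window // 2
        train_tiles = [
            t for s in train_frames for t in segtile.make_tiles(s, window, stride)[1]
        ]
        val_tiles = [
            t for s in val_frames for t in segtile.make_tiles(s, window, stride)[1]
        ]
        train_tiles += segtile.augment(
            train_tiles, n_out=len(train_tiles), seed=config.seed
        )
        schedule = TrainSchedule(
            max_iterations=config.max_iterations,
            validate_every=config.validate_every,
            learning_rate=config.learning_rate,
            lr_decay=config.lr_decay,
            batch_size=config.batch_size,
        )
        model_cfg = ModelConfig(
            depth=config.model_depth, base_channels=config.base_channels
        )
        model = segtile.train(
            train_tiles, val_tiles, schedule, model_cfg, seed=config.seed
        )
        model.save(out / "seg_model")
        model.log.to_csv(out / "training_log.csv", index=False)

    @staticmethod
    def seginfer(config: RunConfig, out: Path, inp: Path) -> None:
        model = segtile.TrainedModel.load(_require(inp / "seg_model.json").with_suffix(""))
        window = min(config.tile_window, 64)
        stride = int(window * (1 - config.tile_overlap)) or window // 2
        rows = []
        i = 0
        while (inp / f"blobs{i}.tif").exists():
            img = read_image_stack(inp / f"blobs{i}.tif")
            mask_prob, outline_prob = segtile.infer_and_stitch(
                img, model, window=window, stride=stride
            )
            labels, n = segtile.postprocess(
                mask_prob, outline_prob, threshold=config.seg_threshold
            )
            write_image_stack(
                out / f"blobs{i}_labels.tif",
                syndata.ImageStack(
                    labels[None, None].astype(float), channel_names=["labels"]
                ),
            )
            rows.append({"frame": i, "n_objects": n})
            i += 1
        if not rows:
            raise FileNotFoundError(f"missing input: {inp / 'blobs0.tif'}")
        pd.DataFrame(rows).to_csv(out / "seg_object_counts.csv", index=False)

    @staticmethod
    def screen(config: RunConfig, out: Path, inp: Path) -> None:
        table = pd.read_csv(_require(inp / "screen_table.csv"))
        table = screen.triage_stage1(table, fail_threshold=config.fail_threshold)
        table = screen.triage_stage2(table, fail_threshold=config.fail_threshold)
        table = screen.categorize_phenotypes(table)
        table.to_csv(out / "screen_triaged.csv", index=False)
        hits = table[table["confirmed_hit"]]
        summary = {
            "n_strains": int(len(table)),
            "n_stage1_fail": int(table["stage1_fail"].sum()),
            "n_confirmed_hits": int(len(hits)),
            "phenotype_counts": hits["phenotype"].value_counts().to_dict(),
        }
        with open(out / "screen_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1)


def _load_blob_samples(inp: Path) -> list[segtile.SegSample]:
    samples = []
    i = 0
    while (inp / f"blobs{i}.tif").exists():
        img = read_image_stack(inp / f"blobs{i}.tif")
        rs = read_roi_set(_require(inp / f"blobs{i}.rois.json"))
        samples.append(segtile.encode_rois(img, rs))
        i += 1
    return samples
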