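"""End-to-end assay orchestration: config in, tidy CSV + provenance out.

``run`` executes one assay (synthetic-scene generation, any of the five
quantification pipelines, or a condition comparison) from a :class:`RunConfig`
and writes per-image CSV tables plus a machine-readable provenance record
(effective parameters, package version, seed, input hashes). All randomness
descends from the single config seed through named per-stage substreams, so a
rerun with the same config is bit-identical.

``acceptance_suite`` runs a compact battery of ground-truth checks of every
pipeline at desk scale and reports pass/fail per check.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from stretchquant import (
    adhesions as adh,
    imgio,
    mitochondria as mito,
    orientation as ori,
    puncta,
    stats as st,
    synthetic as synth,
)

log = logging.getLogger(__name__)

ASSAYS = ("synth", "orient", "lc3b", "fa", "tomm20", "mitotracker", "jc1", "compare")

_SCENE_MAKERS = {
    "fiber": synth.make_fiber_scene,
    "puncta": synth.make_puncta_scene,
    "adhesion": synth.make_adhesion_scene,
    "mito": synth.make_mito_scene,
    "jc1": synth.make_jc1_scene,
    "cells": synth.make_cell_scene,
}


@dataclass
class RunConfig:
    """Declarative description of one assay run."""

    assay: str
    out_dir: str | Path
    seed: int = 0
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = dict(imgio.load_config(path))
        return cls(
            assay=cfg.pop("assay"),
            out_dir=cfg.pop("out_dir", "."),
            seed=int(cfg.pop("seed", 0)),
            params=cfg.pop("params", {}),
            inputs=cfg.pop("inputs", {}),
        )


def _stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _iter_stacks(config: RunConfig):
    """Yield (name, ImageStack, SceneTruth-or-None) from files or the generator."""
    if "images" in config.inputs:
        for i, rec in enumerate(config.inputs["images"]):
            stack = imgio.load_image(
                rec["path"],
                pixel_size_um=rec["pixel_size_um"],
                channel_map=rec["channel_map"],
                stretch_axis=rec.get("stretch_axis", "x"),
                z_layout=rec.get("z_layout", "pages_are_channels"),
            )
            yield Path(rec["path"]).stem, stack, None
        return
    gen = dict(config.inputs.get("synth", {}))
    if not gen:
        raise ValueError("config.inputs must provide 'images' or 'synth'")
    scene = gen.pop("scene")
    n_images = int(gen.pop("n_images", 1))
    noise = gen.pop("noise", None)
    maker = _SCENE_MAKERS[scene]
    for i in range(n_images):
        s = _stage_seed(config.seed, f"synth:{scene}", i)
        stack, truth = maker(**gen, seed=s)
        if noise:
            stack = synth.apply_noise(
                stack, seed=_stage_seed(config.seed, f"noise:{scene}", i), **noise
            )
        yield f"{scene}_{i:03d}", stack, truth


def _provenance(config: RunConfig, outputs: list[Path]) -> dict:
    from stretchquant import __version__

    hashes = {}
    for rec in config.inputs.get("images", []):
        p = Path(rec["path"])
        if p.exists():
            hashes[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    return {
        "assay": config.assay,
        "seed": config.seed,
        "params": config.params,
        "inputs": {k: v for k, v in config.inputs.items()},
        "input_hashes": hashes,
        "outputs": [str(p) for p in outputs],
        "version": __version__,
    }


def run(config: RunConfig) -> dict:
    """Execute one assay and write its CSV outputs plus provenance.json."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = {
        "synth": _run_synth,
        "orient": _run_orient,
        "lc3b": _run_lc3b,
        "fa": _run_fa,
        "tomm20": _run_tomm20,
        "mitotracker": _run_mitotracker,
        "jc1": _run_jc1,
        "compare": _run_compare,
    }[config.assay]
    try:
        outputs = handler(config, out)
    except Exception as exc:
        raise RuntimeError(f"assay {config.assay!r} failed: {exc}") from exc
    prov = _provenance(config, outputs)
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True, default=str))
    return prov


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def _run_synth(config: RunConfig, out: Path) -> list[Path]:
    outputs = []
    truth_rows = []
    for name, stack, truth in _iter_stacks(config):
        tif = out / f"{name}.tif"
        imgio.save_image(stack, tif)
        outputs.append(tif)
        if truth is not None:
            for obj in truth.objects:
                truth_rows.append({"image": name, "seed": truth.seed, **obj})
    if truth_rows:
        outputs.append(_write(pd.DataFrame(truth_rows), out / "truth.csv"))
    return outputs


def _run_orient(config: RunConfig, out: Path) -> list[Path]:
    p = config.params
    grid = tuple(p.get("grid", (5, 3)))
    channel = p.get("channel", "actin")
    sq_rows, img_rows = [], []
    for name, stack, _ in _iter_stacks(config):
        image = imgio.max_project(stack, channel)
        field = ori.orientation_field(image, smoothing_sigma=p.get("smoothing_sigma", 1.0))
        mains = ori.grid_main_orientations(field, grid, p.get("min_weight_fraction", 0.05))
        folded = [ori.fold_to_stretch(a, stack.stretch_axis) for a in mains]
        for k, ang in enumerate(folded):
            sq_rows.append({"image": name, "square": k, "angle_folded_deg": ang})
        img_rows.append(
            {
                "image": name,
                "mean_angle_deg": float(np.mean(folded)) if folded else np.nan,
                "n_squares": len(folded),
            }
        )
    return [
        _write(pd.DataFrame(sq_rows), out / "squares.csv"),
        _write(pd.DataFrame(img_rows), out / "images.csv"),
    ]


def _run_lc3b(config: RunConfig, out: Path) -> list[Path]:
    p = config.params
    rows = []
    manual = p.get("nuclei")  # scalar or per-image list
    for i, (name, stack, _) in enumerate(_iter_stacks(config)):
        image = imgio.max_project(stack, p.get("channel", "lc3b"))
        regs = puncta.segment_puncta(
            image,
            threshold=p.get("threshold", "auto"),
            min_area_px=p.get("min_area_px", puncta.MIN_SPOT_AREA_PX),
            pixel_size_um=stack.pixel_size_um,
        )
        regs = puncta.split_clusters(regs)
        if manual is not None:
            n_nuc = puncta.count_nuclei(
                manual_count=manual[i] if isinstance(manual, list) else manual
            )
        else:
            n_nuc = puncta.count_nuclei(imgio.max_project(stack, "dapi"))
        res = puncta.puncta_per_cell(regs, n_nuc, p.get("control_mean"))
        rows.append(
            {
                "image": name,
                "n_spots": res.n_spots,
                "n_nuclei": res.n_nuclei,
                "spots_per_cell": res.spots_per_cell,
                "normalized_to_control": res.normalized_to_control,
            }
        )
    return [_write(pd.DataFrame(rows), out / "spots.csv")]


def _run_fa(config: RunConfig, out: Path) -> list[Path]:
    p = config.params
    fa_rows, summary_rows = [], []
    for name, stack, _ in _iter_stacks(config):
        pxn = imgio.max_project(stack, p.get("pxn_channel", "pxn"))
        vcl = imgio.max_project(stack, p.get("vcl_channel", "vcl"))
        mask = adh.cell_mask(pxn)
        spots_a = adh.channel_spots(
            pxn, mask, min_area_px=p.get("min_area_px", 100),
            pixel_size_um=stack.pixel_size_um,
        )
        spots_b = adh.channel_spots(
            vcl, mask, min_area_px=p.get("min_area_px", 100),
            pixel_size_um=stack.pixel_size_um,
        )
        ra, rb = adh.mutual_overlap_filter(
            spots_a, spots_b, p.get("min_overlap_px", 5)
        )
        table = adh.build_adhesions(ra, rb, stack.pixel_size_um, stack.stretch_axis)
        for _, r in table.adhesions.iterrows():
            fa_rows.append({"image": name, **r.to_dict()})
        if len(table):
            summary, _dist = adh.adhesion_metrics(table, p.get("n_cells", 1))
            summary_rows.append({"image": name, **summary})
    return [
        _write(pd.DataFrame(fa_rows), out / "fa.csv"),
        _write(pd.DataFrame(summary_rows), out / "fa_summary.csv"),
    ]


def _run_tomm20(config: RunConfig, out: Path) -> list[Path]:
    p = config.params
    rows = []
    for name, stack, _ in _iter_stacks(config):
        actin = stack.channel("actin")
        masks = actin > p.get("cell_mask_threshold", 0.0)
        morph = mito.tomm20_stats(stack, masks, p.get("n_cells", 1))
        rows.append(
            {
                "image": name,
                "objects_per_cell": morph.objects_per_cell,
                "mean_area_normalized": morph.mean_area_normalized,
            }
        )
    return [_write(pd.DataFrame(rows), out / "tomm20.csv")]


def _run_mitotracker(config: RunConfig, out: Path) -> list[Path]:
    p = config.params
    rows = []
    for name, stack, _ in _iter_stacks(config):
        res = mito.mitotracker_intensity(stack, control_mean=p.get("control_mean"))
        rows.append(
            {
                "image": name,
                "mean_cell_intensity": res.mean_cell_intensity,
                "mean_background_intensity": res.mean_background_intensity,
                "corrected_intensity": res.corrected_intensity,
                "normalized": res.normalized,
            }
        )
    return [_write(pd.DataFrame(rows), out / "mitotracker.csv")]


def _run_jc1(config: RunConfig, out: Path) -> list[Path]:
    rows = []
    for name, stack, _ in _iter_stacks(config):
        res = mito.jc1_ratio(stack)
        rows.append({"image": name, "red_green_ratio": res.red_green_ratio})
    return [_write(pd.DataFrame(rows), out / "jc1.csv")]


def _run_compare(config: RunConfig, out: Path) -> list[Path]:
    p = config.params
    a = pd.read_csv(p["a_csv"])[p["column"]].dropna().to_numpy()
    b = pd.read_csv(p["b_csv"])[p["column"]].dropna().to_numpy()
    test = p.get("test", "ks")
    res = st.ks_two_sample(a, b) if test == "ks" else st.mann_whitney(a, b)
    row = {
        "test": res.method,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "n1": res.n1,
        "n2": res.n2,
        "column": p["column"],
    }
    if p.get("ci_boot"):
        band_a = st.bootstrap_ci95(a, n_boot=int(p["ci_boot"]), seed=_stage_seed(config.seed, "boot", 0))
        band_b = st.bootstrap_ci95(b, n_boot=int(p["ci_boot"]), seed=_stage_seed(config.seed, "boot", 1))
        row.update(
            a_ci_lower=band_a.lower, a_ci_upper=band_a.upper,
            b_ci_lower=band_b.lower, b_ci_upper=band_b.upper,
        )
    return [_write(pd.DataFrame([row]), out / "comparison.csv")]


# ---------------------------------------------------------------------------
# acceptance battery
# ---------------------------------------------------------------------------


@dataclass
class CheckResult:
    name: str
    passed: bool
    value: float
    tolerance: str


def acceptance_suite(seed: int = 0, min_area_px: int = puncta.MIN_SPOT_AREA_PX) -> list[CheckResult]:
    """Desk-scale ground-truth battery across all pipelines.

    Returns one :class:`CheckResult` per check; any failure means the
    installation or a parameter override (e.g. a perturbed ``min_area_px``)
    has broken a quantitative guarantee.
    """
    checks: list[CheckResult] = []

    # orientation: fixed-angle recovery
    stack, _ = synth.make_fiber_scene(
        120, ("fixed", 30.0), seed=_stage_seed(seed, "acc_orient")
    )
    mean_angle, _sq = ori.image_mean_orientation(imgio.max_project(stack, "actin"))
    checks.append(
        CheckResult("orientation_fixed_30deg", abs(mean_angle - 30.0) <= 2.0,
                    mean_angle, "30 +/- 2 deg")
    )

    # LC3B: exact counting with watershed splitting
    stack, truth = synth.make_puncta_scene(
        n_spots=12, cluster_pairs=3, n_small_spots=4,
        seed=_stage_seed(seed, "acc_lc3b"),
    )
    ref = truth.generative_params["reference_threshold"]
    regs = puncta.split_clusters(
        puncta.segment_puncta(
            imgio.max_project(stack, "lc3b"), threshold=ref, min_area_px=min_area_px
        )
    )
    checks.append(
        CheckResult("lc3b_exact_count", regs.count == 12, regs.count, "== 12")
    )

    # FA: colocalization boundary at 5 px, on render-threshold spot masks
    stack, truth = synth.make_adhesion_scene(
        n_pairs=6, overlap_px=5, seed=_stage_seed(seed, "acc_fa")
    )
    thr = truth.generative_params["render_threshold"]
    sa = adh.spots_from_binary(imgio.max_project(stack, "pxn") > thr)
    sb = adh.spots_from_binary(imgio.max_project(stack, "vcl") > thr)
    ra, rb = adh.mutual_overlap_filter(sa, sb, 5)
    table = adh.build_adhesions(ra, rb)
    checks.append(CheckResult("fa_overlap5_count", len(table) == 6, len(table), "== 6"))

    # JC-1 ratio recovery
    stack, _ = synth.make_jc1_scene(2.5, seed=_stage_seed(seed, "acc_jc1"))
    ratio = mito.jc1_ratio(stack).red_green_ratio
    checks.append(
        CheckResult("jc1_ratio_2.5", abs(ratio / 2.5 - 1) <= 0.02, ratio, "2.5 +/- 2%")
    )

    # MitoTracker corrected intensity
    stack, _ = synth.make_cell_scene(seed=_stage_seed(seed, "acc_mt"))
    corr = mito.mitotracker_intensity(stack).corrected_intensity
    checks.append(
        CheckResult("mitotracker_corrected", abs(corr / 250.0 - 1) <= 0.02,
                    corr, "250 +/- 2%")
    )
    return checks
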