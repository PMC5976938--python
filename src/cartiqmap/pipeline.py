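"""End-to-end orchestration: phantom -> geometry -> fitting -> model -> stats.

A run is fully described by a :class:`RunConfig` (serializable to YAML)
and a root seed; re-running the same configuration reproduces every
output byte for byte. Each stage writes its artifacts (NIfTI maps, CSV
tables, JSON summaries) under the configured output directory, and the
returned :class:`RunReport` carries the in-memory tables plus provenance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import assign_regions, assign_zones, compute_depth
from .io import save_curve_csv, save_nifti, save_protocol
from .phantom import LinkParams, PhantomSpec, make_geometry, make_ground_truth, simulate_stack
from .relaxometry import (
    default_t1_protocol,
    default_t1rho_protocol,
    default_t2star_protocol,
    filter_echoes,
    fit_map,
)
from .stats import (
    QMRI_PARAMS,
    compare_groups,
    correlation_table,
    fit_exponential,
    fit_sinusoidal,
    zonal_summary,
)
from .tissue_model import FiberModel, calibrate_default_profiles, evaluate_on_grid

logger = logging.getLogger("cartiqmap")

__all__ = ["RunConfig", "RunReport", "validate_config", "run"]


@dataclass
class RunConfig:
    """Every tunable of one pipeline run, with study-condition defaults."""

    # phantom geometry and acquisition
    width_mm: float = 15.0
    thickness_mm: float = 2.5
    curvature_per_m: float = 4.4
    pixel_spacing_mm: float = 0.1
    snr: float = 50.0
    # labelling
    zone_boundaries: tuple[float, float] = (0.15, 0.65)
    cr_width_mm: float = 6.0
    # fitting
    qc_threshold: float = 0.95
    max_te_ms: float = 60.0
    fit_noise_floor: bool = False
    # statistics
    posthoc_adjust: str = "bonferroni"
    # reproducibility / output
    seed: int = 0
    out_dir: str = "cartiqmap_run"

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(
            width_mm=self.width_mm,
            thickness_mm=self.thickness_mm,
            curvature_per_m=self.curvature_per_m,
            pixel_spacing_mm=self.pixel_spacing_mm,
            snr=self.snr,
            seed=self.seed,
            link_params=LinkParams(),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "zone_boundaries" in doc:
            doc["zone_boundaries"] = tuple(doc["zone_boundaries"])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        import yaml

        doc = asdict(self)
        doc["zone_boundaries"] = list(self.zone_boundaries)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def validate_config(config: RunConfig) -> list[str]:
    """Cross-field sanity checks; returns human-readable issues (may be empty)."""
    issues: list[str] = []
    if min(config.width_mm, config.thickness_mm, config.pixel_spacing_mm) <= 0:
        issues.append("phantom lengths must be positive")
    if config.curvature_per_m < 0:
        issues.append("curvature must be >= 0")
    if not config.snr > 0:
        issues.append("snr must be positive")
    b1, b2 = config.zone_boundaries
    if not (0.0 < b1 < b2 < 1.0):
        issues.append(f"zone boundaries {config.zone_boundaries} must be increasing in (0, 1)")
    if config.cr_width_mm > config.width_mm:
        issues.append(
            f"CR width {config.cr_width_mm} mm exceeds phantom width {config.width_mm} mm"
        )
    if not (0.0 < config.qc_threshold <= 1.0):
        issues.append("qc_threshold must lie in (0, 1]")
    if config.max_te_ms <= 0:
        issues.append("max_te_ms must be positive")
    if config.posthoc_adjust not in ("none", "bonferroni", "holm"):
        issues.append(f"unknown post-hoc adjustment {config.posthoc_adjust!r}")
    return issues


@dataclass
class RunReport:
    """Provenance and all result tables of one pipeline run."""

    config: RunConfig
    version: str
    qc_pass_rates: dict[str, float]
    zonal_qmri: pd.DataFrame
    zonal_model: pd.DataFrame
    correlations: pd.DataFrame
    curve_fits: dict
    group_comparisons: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run(config: RunConfig, write_outputs: bool = True) -> RunReport:
    """Execute the full pipeline described by ``config``.

    Stages: synthetic sample generation, depth/zone/region labelling,
    simulated acquisition and per-pixel fitting of the three sequences,
    model-map evaluation, and the statistical analysis (zonal summaries,
    region-wise correlation table, curve fits, group comparisons).
    """
    issues = validate_config(config)
    if issues:
        raise StageError("config: " + "; ".join(issues))

    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    timings: dict[str, float] = {}
    rng = np.random.default_rng(config.seed)

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = stage("phantom")
        spec = config.phantom_spec()
        model = calibrate_default_profiles()
        sample = make_geometry(spec)
        gt = make_ground_truth(sample, model, spec)
        protocols = {
            "T1": default_t1_protocol(),
            "T1RHO": default_t1rho_protocol(),
            "T2STAR": default_t2star_protocol(),
        }
        stacks = {
            kind: simulate_stack(gt, proto, spec, rng=rng)
            for kind, proto in protocols.items()
        }
        timings["phantom"] = time.perf_counter() - t0
    except Exception as exc:
        raise StageError(f"phantom: {exc}") from exc

    try:
        t0 = stage("geometry")
        depth = compute_depth(sample)
        zones = assign_zones(depth, config.zone_boundaries)
        regions = assign_regions(sample.mask, spec.pixel_spacing_mm, config.cr_width_mm)
        timings["geometry"] = time.perf_counter() - t0
    except Exception as exc:
        raise StageError(f"geometry: {exc}") from exc

    try:
        t0 = stage("relaxometry")
        pmaps = {}
        for kind, proto in protocols.items():
            stack = stacks[kind]
            if kind == "T2STAR":
                filtered = filter_echoes(proto, config.max_te_ms)
                keep = np.asarray(proto.times_ms) < config.max_te_ms
                stack = type(stack)(
                    data=stack.data[..., keep], kind=kind, mask=stack.mask
                )
                proto = filtered
            pmaps[kind] = fit_map(
                stack, proto, qc=config.qc_threshold, fit_floor=config.fit_noise_floor
            )
        timings["relaxometry"] = time.perf_counter() - t0
    except Exception as exc:
        raise StageError(f"relaxometry: {exc}") from exc

    try:
        t0 = stage("tissue_model")
        mmaps = evaluate_on_grid(depth, model, FiberModel(boundaries=config.zone_boundaries))
        timings["tissue_model"] = time.perf_counter() - t0
    except Exception as exc:
        raise StageError(f"tissue_model: {exc}") from exc

    try:
        t0 = stage("stats")
        qmaps, qc_masks, qc_rates = {}, {}, {}
        for kind in QMRI_PARAMS:
            pm = pmaps[kind]
            qmaps[kind] = pm.relax_ms
            qc_masks[kind] = pm.qc_pass
            qc_rates[kind] = pm.qc_pass_rate
            if pm.qc_pass_rate < 1.0:
                logger.warning("%s: %.1f%% of pixels passed QC", kind, 100 * pm.qc_pass_rate)

        zonal_q = pd.concat(
            [zonal_summary(qmaps[k], zones, regions, value_name=k) for k in QMRI_PARAMS],
            ignore_index=True,
        )
        zonal_m = pd.concat(
            [
                zonal_summary(arr, zones, regions, value_name=name)
                for name, arr in mmaps.as_dict().items()
            ],
            ignore_index=True,
        )
        corr = correlation_table(qmaps, mmaps, regions, qc_masks=qc_masks)

        curve_fits = {}
        for kind in QMRI_PARAMS:
            sel = qc_masks[kind] & np.isfinite(mmaps.ff)
            q = qmaps[kind][sel]
            curve_fits[kind] = {
                name: asdict(fit_exponential(mmaps.as_dict()[name][sel], q))
                for name in ("FF", "CO", "PG")
            }
            curve_fits[kind]["CFO"] = asdict(fit_sinusoidal(mmaps.cfo_deg[sel], q))

        comparisons = {}
        for kind in QMRI_PARAMS:
            vals = qmaps[kind][qc_masks[kind]]
            comparisons[kind] = {
                "regions": _comparison_dict(
                    compare_groups(vals, regions.labels[qc_masks[kind]], "regions")
                ),
                "zones": _comparison_dict(
                    compare_groups(
                        vals,
                        zones.labels[qc_masks[kind]],
                        "zones",
                        adjust=config.posthoc_adjust,
                    )
                ),
            }
        timings["stats"] = time.perf_counter() - t0
    except Exception as exc:
        raise StageError(f"stats: {exc}") from exc

    report = RunReport(
        config=config,
        version=__version__,
        qc_pass_rates=qc_rates,
        zonal_qmri=zonal_q,
        zonal_model=zonal_m,
        correlations=corr,
        curve_fits=curve_fits,
        group_comparisons=comparisons,
        stage_seconds=timings,
    )

    if write_outputs:
        try:
            dx = spec.pixel_spacing_mm
            save_nifti(out / "mask.nii.gz", sample.mask, dx)
            save_curve_csv(out / "surface_curve.csv", sample.surface_curve)
            save_curve_csv(out / "bone_curve.csv", sample.bone_curve)
            save_nifti(out / "depth.nii.gz", depth.z, dx)
            save_nifti(out / "zones.nii.gz", zones.labels, dx)
            save_nifti(out / "regions.nii.gz", regions.labels, dx)
            for kind in QMRI_PARAMS:
                save_protocol(out / f"protocol_{kind.lower()}.yaml", protocols[kind])
                save_nifti(out / f"stack_{kind.lower()}.nii.gz", stacks[kind].data, dx)
                save_nifti(out / f"map_{kind.lower()}.nii.gz", pmaps[kind].relax_ms, dx)
                save_nifti(out / f"r2adj_{kind.lower()}.nii.gz", pmaps[kind].r2_adj, dx)
            for name, arr in mmaps.as_dict().items():
                save_nifti(out / f"model_{name.lower()}.nii.gz", arr, dx)
            _float_csv(zonal_q, out / "zonal_qmri.csv")
            _float_csv(zonal_m, out / "zonal_model.csv")
            _float_csv(corr, out / "correlations.csv")
            (out / "curve_fits.json").write_text(json.dumps(curve_fits, indent=2))
            (out / "group_comparisons.json").write_text(
                json.dumps(comparisons, indent=2)
            )
            (out / "report.json").write_text(
                json.dumps(
                    {
                        "version": __version__,
                        "config": {**asdict(config), "zone_boundaries": list(config.zone_boundaries)},
                        "qc_pass_rates": qc_rates,
                        "stage_seconds": timings,
                    },
                    indent=2,
                )
            )
        except Exception as exc:
            raise StageError(f"output: {exc}") from exc
    return report


def _comparison_dict(comp) -> dict:
    d = {"test": comp.test, "statistic": comp.statistic, "p_value": comp.p_value}
    if comp.posthoc is not None:
        d["posthoc"] = comp.posthoc.to_dict(orient="records")
    return d
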