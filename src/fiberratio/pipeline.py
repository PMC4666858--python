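"""End-to-end workflow: simulate/load -> select SOIs -> R -> group statistics.

The pipeline consumes either a simulation specification (treatment groups
with true dislocation/wall ratios) or files on disk (stacks plus ROI
sidecars), computes per-fiber R values, applies the outlier policy, pools
washed/unwashed groups of the same enzyme when a two-sample test finds no
difference, and runs pooled-variance comparisons between enzyme groups.
Per-fiber failures (no usable SOI, degenerate denominator) are recorded
with their reason and skipped, not fatal — screening out unusable fibers is
part of the method.  Everything is deterministic given the configuration
and master seed, and the provenance record embeds the config hash, seed and
software version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .group_stats import (
    PoolingRefusal,
    RGroup,
    flag_outliers,
    pool_washed_unwashed,
    pooled_two_sample_test,
    sem_of_mean,
)
from .ratiometry import DegenerateDenominatorError, RatioResult, fiber_R
from .soi import NoUsableSoiError, SoiRules, select_sois
from .stack_io import FiberCube, read_rois, read_stack, write_results
from .synthetic import AcquisitionParams, FiberGeometry, GroupSpec, generate_cohort

logger = logging.getLogger("fiberratio")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one input source: ``simulate`` (list of group dicts) or
    ``inputs`` (list of {stack, rois, fiber_id, enzyme, washed} records).
    """

    simulate: list[dict] | None = None
    inputs: list[dict] | None = None
    seed: int | None = None
    acquisition: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    soi_rules: dict = field(default_factory=dict)
    roi_size_px: int = 9
    outlier_policy: str = "auto"  # auto | manual | none
    manual_outliers: dict = field(default_factory=dict)  # label -> [fiber_id]
    pooling_alpha: float = 0.05
    comparison_alpha: float = 0.05
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "configure exactly one input source: 'simulate' or 'inputs'"
            )
        if self.simulate is not None and self.seed is None:
            raise ValueError("a master seed is mandatory when simulating")
        if self.outlier_policy not in ("auto", "manual", "none"):
            raise ValueError(
                f"outlier_policy must be auto|manual|none, "
                f"got {self.outlier_policy!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Results bundle of one pipeline run."""

    fiber_results: list[RatioResult]
    failures: list[dict]
    groups: dict[str, RGroup]          # final (pooled) per-enzyme groups
    pooling_log: list[dict]
    comparisons: list[dict]
    provenance: dict


def _load_cubes(config: PipelineConfig) -> list[FiberCube]:
    cubes = []
    for rec in config.inputs:
        stack = read_stack(rec["stack"])
        rois = read_rois(rec["rois"])
        cubes.append(
            FiberCube(
                stack=stack,
                rois=rois,
                fiber_id=str(rec.get("fiber_id", Path(rec["stack"]).stem)),
                enzyme=str(rec.get("enzyme", "")),
                washed=bool(rec.get("washed", False)),
            )
        )
    return cubes


def _simulate_cubes(config: PipelineConfig) -> list[FiberCube]:
    groups = [GroupSpec(**g) for g in config.simulate]
    acq = AcquisitionParams(**config.acquisition)
    geometry = (
        FiberGeometry(**config.geometry) if config.geometry else FiberGeometry()
    )
    cohort = generate_cohort(
        groups, acq, config.seed, geometry=geometry,
        roi_size_px=config.roi_size_px,
    )
    return [cube for cube, _truth in cohort]


def measure_fibers(
    cubes: list[FiberCube], rules: SoiRules = SoiRules()
) -> tuple[list[RatioResult], list[dict]]:
    """Per-fiber SOI selection and R; failures recorded, not raised."""
    results: list[RatioResult] = []
    failures: list[dict] = []
    for cube in cubes:
        try:
            sois = select_sois(cube.stack, cube.rois, rules)
            for k, why in sorted(sois.rule_trace.items()):
                logger.info("%s: slice %d excluded (%s)", cube.fiber_id, k, why)
            res = fiber_R(
                cube.stack, cube.rois, sois,
                fiber_id=cube.fiber_id, enzyme=cube.enzyme, washed=cube.washed,
            )
            results.append(res)
        except (NoUsableSoiError, DegenerateDenominatorError) as exc:
            logger.warning("%s dropped: %s", cube.fiber_id, exc)
            failures.append({"fiber_id": cube.fiber_id, "reason": str(exc)})
    return results, failures


def _build_groups(
    results: list[RatioResult], config: PipelineConfig
) -> tuple[dict[str, RGroup], list[dict]]:
    """Treatment groups with outlier policy applied, then washed/unwashed
    pooling per enzyme."""
    by_treatment: dict[tuple[str, bool], list[RatioResult]] = {}
    for res in results:
        by_treatment.setdefault((res.enzyme, res.washed), []).append(res)

    raw_groups: dict[tuple[str, bool], RGroup] = {}
    for (enzyme, washed), members in sorted(by_treatment.items()):
        values = np.array([m.mean_R for m in members])
        ids = [m.fiber_id for m in members]
        if config.outlier_policy == "auto" and len(values) >= 4:
            flags = flag_outliers(values)
        elif config.outlier_policy == "manual":
            listed = set(config.manual_outliers.get(enzyme, []))
            flags = np.array([fid in listed for fid in ids])
        else:
            flags = np.zeros(len(values), dtype=bool)
        for fid, flagged in zip(ids, flags):
            if flagged:
                logger.info("outlier flagged: %s (enzyme %s)", fid, enzyme)
        raw_groups[(enzyme, washed)] = RGroup(
            label=enzyme, R_values=values, washed=washed, outlier_flags=flags
        )

    pooled: dict[str, RGroup] = {}
    pooling_log: list[dict] = []
    enzymes = sorted({e for e, _w in raw_groups})
    for enzyme in enzymes:
        gw = raw_groups.get((enzyme, True))
        gu = raw_groups.get((enzyme, False))
        if gw is not None and gu is not None:
            gw_clean = gw.without_outliers()
            gu_clean = gu.without_outliers()
            try:
                merged = pool_washed_unwashed(
                    gw_clean, gu_clean, config.pooling_alpha
                )
                pooled[enzyme] = merged
                pooling_log.append(
                    {"enzyme": enzyme, "pooled": True,
                     "n_washed": gw_clean.n, "n_unwashed": gu_clean.n}
                )
                logger.info("%s: washed/unwashed pooled (n=%d)", enzyme,
                            merged.n)
            except PoolingRefusal as refusal:
                # keep the larger arm so the enzyme still enters comparisons
                keep = gw_clean if gw_clean.n >= gu_clean.n else gu_clean
                pooled[enzyme] = keep
                pooling_log.append(
                    {"enzyme": enzyme, "pooled": False,
                     "mean_diff": refusal.test.mean_diff,
                     "ci_low": refusal.test.ci_low,
                     "ci_high": refusal.test.ci_high}
                )
                logger.warning("%s: pooling refused (%s)", enzyme, refusal)
        else:
            only = (gw or gu).without_outliers()
            pooled[enzyme] = only
            pooling_log.append(
                {"enzyme": enzyme, "pooled": False, "single_arm": True}
            )
    return pooled, pooling_log


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and return the results bundle."""
    rules = SoiRules(**config.soi_rules)
    cubes = (
        _simulate_cubes(config) if config.simulate is not None
        else _load_cubes(config)
    )
    results, failures = measure_fibers(cubes, rules)
    groups, pooling_log = _build_groups(results, config)

    comparisons: list[dict] = []
    for a, b in combinations(sorted(groups), 2):
        test = pooled_two_sample_test(
            groups[a], groups[b], config.comparison_alpha
        )
        comparisons.append({"group1": a, "group2": b, **test.as_dict()})

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_fibers_measured": len(results),
        "n_fibers_dropped": len(failures),
    }
    return PipelineResult(
        fiber_results=results,
        failures=failures,
        groups=groups,
        pooling_log=pooling_log,
        comparisons=comparisons,
        provenance=provenance,
    )


def write_bundle(bundle: PipelineResult, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the per-fiber and comparison tables; returns their paths."""
    paths = write_results(bundle.fiber_results, bundle.comparisons, out_dir)
    prov_path = Path(out_dir) / "provenance.json"
    prov_path.write_text(json.dumps(bundle.provenance, indent=2))
    return paths


def report(bundle: PipelineResult) -> str:
    """Human-readable summary: per-group scatter + mean ± SEM, then a
    comparison block per enzyme pair with the full pooled-test record."""
    lines: list[str] = []
    lines.append(f"fiberratio v{bundle.provenance['version']} — "
                 f"config {bundle.provenance['config_hash']}, "
                 f"seed {bundle.provenance['seed']}")
    lines.append(
        f"{bundle.provenance['n_fibers_measured']} fibers measured, "
        f"{bundle.provenance['n_fibers_dropped']} dropped"
    )
    for fail in bundle.failures:
        lines.append(f"  dropped {fail['fiber_id']}: {fail['reason']}")
    lines.append("")
    for label in sorted(bundle.groups):
        g = bundle.groups[label]
        values = ", ".join(f"{v:.3f}" for v in g.R_values)
        if g.n >= 2:
            lines.append(
                f"group {label} (n={g.n}): R = [{values}]; "
                f"mean R = {g.R_values.mean():.3f} ± "
                f"{sem_of_mean(g.R_values):.3f} (SEM)"
            )
        else:
            lines.append(
                f"group {label} (n={g.n}): R = [{values}]; "
                f"WARNING: too few fibers for a SEM"
            )
    if not bundle.groups:
        lines.append("WARNING: no groups survived measurement")
    if bundle.comparisons:
        lines.append("")
        lines.append("pairwise comparisons (pooled-variance t-test):")
        for cmp_row in bundle.comparisons:
            lines.append(
                f"  {cmp_row['group1']} vs {cmp_row['group2']}: "
                f"means {cmp_row['mean1']:.3f} / {cmp_row['mean2']:.3f}, "
                f"n {cmp_row['n1']} / {cmp_row['n2']}, "
                f"t_crit {cmp_row['t_crit']:.2f}, "
                f"SEM(diff) {cmp_row['sem']:.3f}, "
                f"mean diff {cmp_row['mean_diff']:.3f}, "
                f"95% CI [{cmp_row['ci_low']:.3f}, {cmp_row['ci_high']:.3f}], "
                f"{'significant' if cmp_row['significant'] else 'not significant'}"
            )
    return "\n".join(lines)
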