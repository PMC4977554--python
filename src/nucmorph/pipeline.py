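"""End-to-end study orchestration.

A study emulates the full experimental design: several cell-line ×
treatment conditions, each a cohort of synthetic single-cell volumes,
pushed through segmentation → morphometry → statistics; a dose-response
arm fitting the 4PL to simulated viability plates; and a FISH arm
measuring RRD and H3K9ac colocalization on simulated confocal stacks.
Everything is driven by one :class:`StudyConfig` (YAML/JSON-compatible
dict), is deterministic under its seeds, and writes a structured report
directory in which every number traces back to a stage output file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats_report
from .dose_response import FourParamLogistic
from .errors import ConfigError, NucmorphError
from .gene_position import measure_spots, pearson_colocalization
from .morphometry import run_morphometry
from .phantoms import (
    CellPhantomSpec,
    CohortSpec,
    iter_cohort,
    make_fish_phantom,
    make_viability_table,
    sample_cohort_specs,
)
from .segmentation import SegmentationParams, segment_nucleus_fluorescence
from .volume import FeatureTable, write_feature_table

logger = logging.getLogger(__name__)

_COHORT_KEYS = set(CohortSpec.__dataclass_fields__)
_MORPH_FEATURES = ("nuclear_volume", "nc_ratio", "concavity_pct", "clump_count")


@dataclass
class StudyConfig:
    """Configuration for one end-to-end study."""

    seed: int
    n_cells: int
    conditions: dict[str, dict]          # condition label -> CohortSpec overrides
    comparisons: list[tuple[str, str]]   # (treated, control) condition pairs
    segmentation: dict = field(default_factory=dict)
    clump_k_sigma: float = 2.0
    min_clump_volume_um3: float = 0.5
    ddr: dict[str, dict] = field(default_factory=dict)   # line -> 4PL params etc.
    fish: dict[str, dict] = field(default_factory=dict)  # condition -> FISH arm params

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        errors = validate_config(d)
        if errors:
            raise ConfigError("; ".join(errors))
        return cls(
            seed=int(d["seed"]),
            n_cells=int(d["n_cells"]),
            conditions={k: dict(v) for k, v in d["conditions"].items()},
            comparisons=[tuple(p) for p in d["comparisons"]],
            segmentation=dict(d.get("segmentation", {})),
            clump_k_sigma=float(d.get("clump_k_sigma", 2.0)),
            min_clump_volume_um3=float(d.get("min_clump_volume_um3", 0.5)),
            ddr={k: dict(v) for k, v in d.get("ddr", {}).items()},
            fish={k: dict(v) for k, v in d.get("fish", {}).items()},
        )


def validate_config(d: dict) -> list[str]:
    """Schema and cross-reference checks; returns a list of error strings."""
    errors: list[str] = []
    known_top = {"seed", "n_cells", "conditions", "comparisons", "segmentation",
                 "clump_k_sigma", "min_clump_volume_um3", "ddr", "fish"}
    for key in d:
        if key not in known_top:
            errors.append(f"unknown config key {key!r}")
    if "seed" not in d:
        errors.append("missing required key 'seed' (seeds must be explicit)")
    if "n_cells" not in d or int(d.get("n_cells", 0)) < 1:
        errors.append("n_cells must be >= 1")
    conditions = d.get("conditions")
    if not conditions:
        errors.append("no conditions defined")
        conditions = {}
    for name, params in conditions.items():
        for k, v in params.items():
            if k == "condition":
                errors.append(f"condition {name}: label is set by the key, not 'condition'")
            elif k not in _COHORT_KEYS:
                errors.append(f"condition {name}: unknown population key {k!r}")
            elif k == "voxel_size_um":
                if any(x <= 0 for x in v):
                    errors.append(f"condition {name}: voxel size must be positive")
    for pair in d.get("comparisons", []):
        if len(pair) != 2:
            errors.append(f"comparison {pair!r} is not a pair")
            continue
        for cond in pair:
            if cond not in conditions:
                errors.append(f"comparison references unknown condition {cond!r}")
    seg_keys = set(SegmentationParams.__dataclass_fields__)
    for k in d.get("segmentation", {}):
        if k not in seg_keys:
            errors.append(f"unknown segmentation key {k!r}")
    for line, arm in d.get("ddr", {}).items():
        for req in ("top", "bottom", "logic50", "hillslope"):
            if req not in arm:
                errors.append(f"ddr {line}: missing parameter {req!r}")
    for cond, arm in d.get("fish", {}).items():
        if "rrd_mean" not in arm:
            errors.append(f"fish {cond}: missing rrd_mean")
    return errors


def default_config(n_cells: int = 24, seed: int = 7) -> dict:
    """A complete scaled-down study: three lines × two treatments.

    Population parameters sit at the scale of the three esophageal lines
    (normal squamous, metaplastic, adenocarcinoma); the treated cancer
    condition carries the planted decreases in nuclear volume, NC ratio and
    clump count, the treated metaplastic condition the concavity increase.
    Cohort sizes default to 24 cells on compact grids so a full study runs
    on a laptop; pass a larger ``n_cells`` for full-scale runs.
    """
    small = {"voxel_size_um": (0.5, 0.5, 0.5), "noise_sd": 0.02, "margin_um": 1.0}
    return {
        "seed": seed,
        "n_cells": n_cells,
        "conditions": {
            "normal_DMSO": {"nuclear_volume_mean_um3": 180.0, "nuclear_volume_sd_um3": 40.0,
                            "nc_mean": 0.19, "nc_sd": 0.03, "clump_count_mean": 3.9,
                            "invagination_prob": 0.15, **small},
            "normal_vstat": {"nuclear_volume_mean_um3": 190.0, "nuclear_volume_sd_um3": 40.0,
                             "nc_mean": 0.22, "nc_sd": 0.03, "clump_count_mean": 4.5,
                             "invagination_prob": 0.15, **small},
            "metaplastic_DMSO": {"nuclear_volume_mean_um3": 300.0, "nuclear_volume_sd_um3": 60.0,
                                 "nc_mean": 0.52, "nc_sd": 0.05, "clump_count_mean": 6.1,
                                 "invagination_prob": 0.3, **small},
            "metaplastic_vstat": {"nuclear_volume_mean_um3": 295.0, "nuclear_volume_sd_um3": 60.0,
                                  "nc_mean": 0.26, "nc_sd": 0.04, "clump_count_mean": 5.8,
                                  "invagination_prob": 0.8, "n_invaginations": 3, **small},
            "cancer_DMSO": {"nuclear_volume_mean_um3": 280.0, "nuclear_volume_sd_um3": 45.0,
                            "nc_mean": 0.65, "nc_sd": 0.05, "clump_count_mean": 6.1,
                            "invagination_prob": 0.3, **small},
            "cancer_vstat": {"nuclear_volume_mean_um3": 230.0, "nuclear_volume_sd_um3": 45.0,
                             "nc_mean": 0.51, "nc_sd": 0.05, "clump_count_mean": 5.0,
                             "invagination_prob": 0.3, **small},
        },
        "comparisons": [("normal_vstat", "normal_DMSO"),
                        ("metaplastic_vstat", "metaplastic_DMSO"),
                        ("cancer_vstat", "cancer_DMSO")],
        "ddr": {
            "cancer": {"top": 100.0, "bottom": 0.0, "logic50": float(np.log10(0.94)),
                       "hillslope": -1.0, "noise_sd": 3.0, "n_reps": 6},
            "metaplastic": {"top": 100.0, "bottom": 0.0, "logic50": float(np.log10(11.19)),
                            "hillslope": -1.0, "noise_sd": 3.0, "n_reps": 6},
            "normal": {"top": 100.0, "bottom": 0.0, "logic50": float(np.log10(23.16)),
                       "hillslope": -1.0, "noise_sd": 3.0, "n_reps": 6},
        },
        "fish": {
            "cancer_DMSO": {"rrd_mean": 0.45, "rrd_sd": 0.15, "coloc_rho": 0.3,
                            "n_cells": 8, "n_spots": 2},
            "cancer_vstat": {"rrd_mean": 0.55, "rrd_sd": 0.2, "coloc_rho": 0.6,
                             "n_cells": 8, "n_spots": 2},
        },
    }


def _stage_seed(base: int, *idx: int) -> int:
    return int(np.random.SeedSequence([base, *idx]).generate_state(1)[0] % (2**31 - 1))


def run_study(config: StudyConfig | dict, out_dir: str | Path) -> Path:
    """Run the full study; returns the report directory.

    Emits ``features.csv``, ``ground_truth.csv``, ``summaries.csv``,
    ``comparisons.csv``, ``errors.csv`` (if any cell failed), ``ddr_fits.json``,
    ``fish_spots.csv`` / ``fish_coloc.csv`` and ``report.json``.
    """
    if isinstance(config, dict):
        config = StudyConfig.from_dict(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seg_params = SegmentationParams(**config.segmentation)

    # ---- morphometry arm -------------------------------------------------
    feature_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    error_frames: list[pd.DataFrame] = []
    for ci, (cond, overrides) in enumerate(sorted(config.conditions.items())):
        pop = CohortSpec(condition=cond, **overrides)
        seed = _stage_seed(config.seed, 0, ci)
        logger.info("cohort %s: n=%d seed=%d", cond, config.n_cells, seed)
        specs = sample_cohort_specs(config.n_cells, pop, seed)
        truths = []

        def cells():
            for cell_id, condition, vol, _cm, _nm, truth in iter_cohort(specs, cond):
                truths.append((cell_id, condition, truth))
                yield cell_id, condition, vol, None, None

        run = run_morphometry(cells(), seg_params=seg_params,
                              k_sigma=config.clump_k_sigma,
                              min_clump_volume_um3=config.min_clump_volume_um3)
        feature_rows.append(run.table.df)
        from .phantoms import _truth_rows
        truth_rows.append(pd.DataFrame(
            [row for cid, c, t in truths for row in _truth_rows(cid, c, t)]))
        if len(run.errors):
            error_frames.append(run.errors)

    features = FeatureTable(pd.concat(feature_rows, ignore_index=True))
    truth = FeatureTable(pd.concat(truth_rows, ignore_index=True))
    write_feature_table(features, out_dir / "features.csv")
    write_feature_table(truth, out_dir / "ground_truth.csv")
    if error_frames:
        pd.concat(error_frames, ignore_index=True).to_csv(out_dir / "errors.csv", index=False)

    stats_report.summarize_all(features).to_csv(out_dir / "summaries.csv", index=False)

    # ---- comparisons: Bonferroni within each pair's 4-feature family -----
    comp_rows = []
    for treated, control in config.comparisons:
        for test in ("mann-whitney", "ks"):
            family = []
            for feat in _MORPH_FEATURES:
                a = features.values(feat, treated)
                b = features.values(feat, control)
                family.append(stats_report.compare_groups(
                    a, b, test=test, feature=feat, group_a=treated, group_b=control))
            stats_report.bonferroni_adjust(family)
            comp_rows.extend(asdict(r) for r in family)
    comparisons = pd.DataFrame(comp_rows)
    comparisons.to_csv(out_dir / "comparisons.csv", index=False)

    # ---- dose-response arm ----------------------------------------------
    ddr_out: dict[str, dict] = {}
    for li, (line, arm) in enumerate(sorted(config.ddr.items())):
        params = (arm["top"], arm["bottom"], arm["logic50"], arm["hillslope"])
        table = make_viability_table(params, n_reps=int(arm.get("n_reps", 6)),
                                     noise_sd=float(arm.get("noise_sd", 3.0)),
                                     seed=_stage_seed(config.seed, 1, li))
        res = FourParamLogistic.from_dataframe(table).fit()
        ddr_out[line] = {"params": res.params, "bse": res.bse, "ic50_uM": res.ic50,
                         "ic50_se_uM": res.ic50_se, "converged": res.converged,
                         "planted_ic50_uM": float(10 ** arm["logic50"]), "n_obs": res.n_obs}
    if ddr_out:
        fits = {k: v for k, v in ddr_out.items()}
        lines = sorted(fits)
        ratios = {}
        for a in lines:
            for b in lines:
                if a != b:
                    ratios[f"{a}/{b}"] = fits[a]["ic50_uM"] / fits[b]["ic50_uM"]
        (out_dir / "ddr_fits.json").write_text(json.dumps(
            {"fits": fits, "ic50_ratios": ratios}, indent=1))

    # ---- FISH arm --------------------------------------------------------
    spot_rows, coloc_rows = [], []
    for fi, (cond, arm) in enumerate(sorted(config.fish.items())):
        rng = np.random.default_rng(_stage_seed(config.seed, 2, fi))
        for cell in range(int(arm.get("n_cells", 8))):
            rrds = np.clip(rng.normal(arm["rrd_mean"], arm.get("rrd_sd", 0.1),
                                      size=int(arm.get("n_spots", 2))), 0.0, 1.0)
            spec = CellPhantomSpec(voxel_size_um=(0.35, 0.35, 0.35),
                                   nucleus_semiaxes_um=(4.0, 4.0, 4.0),
                                   cell_semiaxes_um=(5.5, 5.5, 5.5),
                                   seed=int(rng.integers(0, 2**31 - 1)))
            channels, _nmask, _truth = make_fish_phantom(
                spec, list(rrds), coloc_rho=float(arm.get("coloc_rho", 0.5)),
                z_step_um=arm.get("z_step_um"))
            cell_id = f"fish_{cond}_{cell:03d}"
            nmask = segment_nucleus_fluorescence(channels["dapi"], seg_params)
            try:
                for m in measure_spots(channels["fish"], nmask, cell_id=cell_id):
                    z, y, x = m.centroid_um
                    spot_rows.append({"cell_id": cell_id, "condition": cond,
                                      "allele": m.allele, "z_um": z, "y_um": y,
                                      "x_um": x, "rrd": m.rrd})
                coloc = pearson_colocalization(channels["fish"], channels["h3k9ac"],
                                               nmask, cell_id=cell_id)
                coloc_rows.append({"cell_id": cell_id, "condition": cond,
                                   "pearson_r": coloc.pearson_r,
                                   "n_voxels": coloc.n_voxels})
            except NucmorphError as exc:
                logger.warning("FISH stage failed for %s: %s", cell_id, exc)
                error_frames.append(pd.DataFrame([{
                    "cell_id": cell_id, "condition": cond, "stage": "fish",
                    "error": str(exc)}]))
    if spot_rows:
        pd.DataFrame(spot_rows).to_csv(out_dir / "fish_spots.csv", index=False)
        pd.DataFrame(coloc_rows).to_csv(out_dir / "fish_coloc.csv", index=False)

    # ---- recovery deltas + report ---------------------------------------
    recovery = {}
    for feat in _MORPH_FEATURES:
        merged = features.df[features.df.feature == feat].merge(
            truth.df[truth.df.feature == feat], on=["cell_id", "condition"],
            suffixes=("_est", "_true"))
        if len(merged):
            err = (merged.value_est - merged.value_true).abs()
            recovery[feat] = {"mean_abs_error": float(err.mean()),
                              "n_cells": int(len(merged))}
    report = {
        "config": {"seed": config.seed, "n_cells": config.n_cells,
                   "conditions": config.conditions,
                   "comparisons": [list(p) for p in config.comparisons],
                   "segmentation": asdict(seg_params),
                   "clump_k_sigma": config.clump_k_sigma,
                   "min_clump_volume_um3": config.min_clump_volume_um3},
        "n_records": int(len(features.df)) // 4,
        "ground_truth_recovery": recovery,
        "alpha": stats_report.ALPHA,
        "significant": [
            {"feature": r["feature"], "treated": r["group_a"], "control": r["group_b"],
             "test": r["test"], "adjusted_p": r["adjusted_p"]}
            for r in comp_rows if r["adjusted_p"] is not None
            and r["adjusted_p"] < stats_report.ALPHA
        ],
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return out_dir


def flagged_conditions(comparisons: pd.DataFrame, test: str = "mann-whitney",
                       alpha: float = stats_report.ALPHA,
                       feature: str | None = None) -> set[str]:
    """Treated conditions with any (or one given) feature significant after
    adjustment."""
    sel = comparisons[comparisons.test == test]
    if feature is not None:
        sel = sel[sel.feature == feature]
    sig = sel[sel.adjusted_p < alpha]
    return set(sig.group_a.unique())
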