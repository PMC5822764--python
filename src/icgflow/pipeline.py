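"""End-to-end orchestration: QC -> region kinetics -> response -> stats.

``run_pipeline`` drives the full analysis over a manifest of
acquisitions: motion QC first (excluded stacks are recorded and carried
no further), per-region tracer-parameter extraction on the survivors,
rest/post stimulation pairing, and group statistics.  Every exclusion
and failure is logged in the results bundle — no record is silently
dropped: input keys always equal excluded keys plus analyzed keys plus
failed keys.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import __version__
from .io import FrameStack, read_stack
from .kinetics import DEFAULT_CONFIG, KineticsConfig, PARAM_NAMES
from .motion import estimate_displacement, movement_exclusion
from .regions import RegionSet, load_region_set, region_params
from .stats import GroupComparisonResult, anova_bonferroni
from .stimulation import pair_conditions, response_scatter

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stats_table"]

logger = logging.getLogger("icgflow")

STATS_PARAMS = ("bfi", "i_max", "mtt", "auc")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the end-to-end run."""

    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    run_qc: bool = True
    qc_window_s: float = 180.0
    qc_threshold_cm: float = 1.0
    stim_limbs: tuple[str, ...] = ("hand",)
    stim_region: str = "digits"
    min_valid_pixels: int = 10
    compute_dispersion: bool = False

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_loader(row: pd.Series) -> tuple[FrameStack, RegionSet]:
    """Load (stack, regions) from the path columns of a manifest row."""
    stack = read_stack(row["stack_path"], row.get("sidecar_path"))
    regions = load_region_set(
        row["labels_path"], limb=row.get("limb", "foot"), side=row.get("side", "left")
    )
    return stack, regions


@dataclass
class PipelineResult:
    """Bundle of every pipeline output table plus the run report."""

    limb_params: pd.DataFrame
    qc: pd.DataFrame
    responses: pd.DataFrame
    unpaired: pd.DataFrame
    scatter: pd.DataFrame
    stats: pd.DataFrame
    comparisons: list[GroupComparisonResult]
    report: dict

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.limb_params.to_csv(out_dir / "limb_params.csv", index=False)
        self.responses.to_csv(out_dir / "responses.csv", index=False)
        self.scatter.to_csv(out_dir / "response_scatter.csv", index=False)
        self.stats.to_csv(out_dir / "group_stats.csv", index=False)
        (out_dir / "qc_report.json").write_text(
            json.dumps(self.qc.to_dict(orient="records"), indent=2)
        )
        (out_dir / "run_report.json").write_text(json.dumps(self.report, indent=2))


def stats_table(
    limb_params: pd.DataFrame,
    parameters: tuple[str, ...] = STATS_PARAMS,
    condition: str = "rest",
) -> tuple[pd.DataFrame, list[GroupComparisonResult]]:
    """Group-comparison table (parameter x region) in the published
    layout: per-group mean +/- SD, omnibus F/p, and Bonferroni-adjusted
    pairwise p with significance stars against the control group."""
    df = limb_params[
        (limb_params["condition"] == condition) & limb_params["valid"]
    ]
    rows, results = [], []
    for region in sorted(df["region"].unique()):
        sub = df[df["region"] == region]
        groups = sorted(sub["group"].unique())
        if len(groups) < 2:
            continue
        for param in parameters:
            by_group = {g: sub.loc[sub["group"] == g, param].to_numpy() for g in groups}
            if any(v.size < 2 for v in by_group.values()):
                continue
            res = anova_bonferroni(by_group, parameter=param, region=region)
            results.append(res)
            row = {"parameter": param, "region": region, "f": res.f, "p": res.p}
            for g in groups:
                row[f"mean_{g}"] = res.means[g]
                row[f"sd_{g}"] = res.sds[g]
                row[f"n_{g}"] = res.ns[g]
            for (a, b), pw in res.pairwise.items():
                row[f"p_{a}_{b}"] = pw.adj_p
                if a == "C":
                    row[f"stars_{b}"] = res.stars((a, b))
            rows.append(row)
    return pd.DataFrame(rows), results


def run_pipeline(
    manifest: pd.DataFrame,
    loader: Callable[[pd.Series], tuple[FrameStack, RegionSet]] = default_loader,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis over a manifest.

    Parameters
    ----------
    manifest
        One row per acquisition with at least (subject, group, limb,
        side, condition); the default loader additionally needs
        ``stack_path`` / ``sidecar_path`` / ``labels_path`` columns.
    loader
        Callable mapping a manifest row to ``(FrameStack, RegionSet)``;
        swap in a closure over an in-memory cohort to avoid disk I/O.
    """
    if config is None:
        config = PipelineConfig()
    required = {"subject", "group", "limb", "side", "condition"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")

    qc_rows, param_rows, failed = [], [], []
    for _, row in manifest.iterrows():
        key = dict(
            subject=row["subject"], group=row["group"], limb=row["limb"],
            side=row["side"], condition=row["condition"],
        )
        try:
            stack, regions = loader(row)
        except Exception as exc:  # failing stack: logged and skipped
            logger.warning("failed to load %s: %s", key, exc)
            failed.append({**key, "error": str(exc)})
            qc_rows.append({**key, "decision": "load-failed"})
            continue

        if config.run_qc:
            profile = estimate_displacement(stack)
            decision = movement_exclusion(
                profile, window_s=config.qc_window_s, threshold_cm=config.qc_threshold_cm
            )
            qc_rows.append({**key, **decision.as_dict()})
            if decision.excluded:
                logger.info("excluded %s: drift %.2f cm", key, decision.max_drift_cm)
                continue
        else:
            qc_rows.append({**key, "decision": "skipped"})

        for name, mask in regions.regions():
            if not mask.any():
                continue
            res = region_params(
                stack, mask, config.kinetics,
                compute_dispersion=config.compute_dispersion,
                min_valid_pixels=config.min_valid_pixels,
            )
            param_rows.append(
                {
                    **key,
                    "region": name,
                    **res.params.as_dict(),
                    "n_pixels": res.n_pixels,
                    "flags": ";".join(res.flags),
                }
            )

    limb_params = pd.DataFrame(param_rows)
    qc = pd.DataFrame(qc_rows)

    if not limb_params.empty and limb_params["limb"].isin(config.stim_limbs).any():
        responses, unpaired = pair_conditions(
            limb_params[limb_params["valid"]],
            limbs=config.stim_limbs,
            region=config.stim_region,
        )
    else:
        responses = pd.DataFrame()
        unpaired = pd.DataFrame()
    scatter = response_scatter(responses) if not responses.empty else pd.DataFrame()

    if not limb_params.empty:
        stats_df, comparisons = stats_table(limb_params)
    else:
        stats_df, comparisons = pd.DataFrame(), []

    n_excluded = int((qc["decision"] == "exclude").sum()) if not qc.empty else 0
    report = {
        "version": __version__,
        "config_digest": config.digest(),
        "n_input": int(len(manifest)),
        "n_excluded": n_excluded,
        "n_failed": len(failed),
        "n_analyzed": int(len(manifest)) - n_excluded - len(failed),
        "failed": failed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    return PipelineResult(
        limb_params=limb_params,
        qc=qc,
        responses=responses,
        unpaired=unpaired,
        scatter=scatter,
        stats=stats_df,
        comparisons=comparisons,
        report=report,
    )
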