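"""Multi-stage trait table assembly, outlier-plot filtering, and the derived
growth traits AGRPH and CRPH.

AGRPH (average growth rate of plant height, cm/day) over the interval from
stage i to i+1 is (PH_{i+1} - PH_i) / (DAS_{i+1} - DAS_i).  CRPH
(contribution rate of plant height, %) is (PH_{i+1} - PH_i) / PH_final x 100,
the share of total stature gained in that interval; the three interval values
telescope to (PH_final - PH_first) / PH_final x 100.

Outlier plots are removed by two field-knowledge rules: a plant-height series
that decreases and later increases is a lodging signature (a plot knocked
down by wind and partially recovering), and an extremely low early-season
canopy cover indicates emergence failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGES = ("S1", "S2", "S3", "S4")
#: 2017 trial calendar, days after sowing
DEFAULT_CALENDAR = (("S1", 24), ("S2", 44), ("S3", 57), ("S4", 84))


@dataclass
class StageCalendar:
    """Ordered (stage, days-after-sowing) pairs."""

    entries: tuple = DEFAULT_CALENDAR

    def __post_init__(self) -> None:
        das = [d for _, d in self.entries]
        if any(b <= a for a, b in zip(das, das[1:])):
            raise ValueError("DAS must be strictly increasing across stages")

    @property
    def stages(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def das(self) -> dict[str, int]:
        return dict(self.entries)


def compute_agrph(ph: dict, calendar: StageCalendar | None = None) -> dict:
    """Per-interval growth rate (cm/day), keyed by the interval's start stage.

    ``ph`` maps stage -> height (cm); intervals with a missing endpoint get NaN.
    """
    calendar = calendar or StageCalendar()
    das = calendar.das
    out = {}
    stages = calendar.stages
    for s0, s1 in zip(stages, stages[1:]):
        p0, p1 = ph.get(s0, np.nan), ph.get(s1, np.nan)
        out[s0] = (p1 - p0) / (das[s1] - das[s0])
    return out


def compute_crph(ph: dict, calendar: StageCalendar | None = None) -> dict:
    """Per-interval contribution to final height (%), keyed by start stage."""
    calendar = calendar or StageCalendar()
    stages = calendar.stages
    final = ph.get(stages[-1], np.nan)
    if not np.isfinite(final) or final <= 0:
        return {s: np.nan for s in stages[:-1]}
    return {
        s0: (ph.get(s1, np.nan) - ph.get(s0, np.nan)) / final * 100.0
        for s0, s1 in zip(stages, stages[1:])
    }


def build_trait_table(
    stage_frames: dict, calendar: StageCalendar | None = None
) -> pd.DataFrame:
    """Join per-stage extraction frames into one long-form trait table.

    ``stage_frames`` maps stage -> DataFrame with columns plot_id, genotype,
    group, cc, ndvi, ph (the output of plot-trait extraction).  The result is
    long-form with one record per (plot, stage), DAS attached, and the derived
    agrph/crph columns populated on each interval's start-stage record.
    """
    calendar = calendar or StageCalendar()
    frames = []
    for stage in calendar.stages:
        if stage not in stage_frames:
            continue
        df = stage_frames[stage].copy()
        if df.duplicated("plot_id").any():
            dup = df.loc[df.duplicated("plot_id"), "plot_id"].iloc[0]
            raise ValueError(f"duplicate record for plot {dup} at stage {stage}")
        df["stage"] = stage
        df["das"] = calendar.das[stage]
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["plot_id", "das"]).reset_index(drop=True)

    agr = pd.Series(np.nan, index=table.index)
    crp = pd.Series(np.nan, index=table.index)
    for _, grp in table.groupby("plot_id"):
        ph = dict(zip(grp["stage"], grp["ph"]))
        a = compute_agrph(ph, calendar)
        c = compute_crph(ph, calendar)
        for idx, stage in zip(grp.index, grp["stage"]):
            if stage in a:
                agr[idx] = a[stage]
                crp[idx] = c[stage]
    table["agrph"] = agr
    table["crph"] = crp
    return table


@dataclass
class OutlierRules:
    """Thresholds of the plot-exclusion rules."""

    low_cc_threshold: float = 0.05  # absolute CC
    low_cc_stage: str = "S2"


def _is_lodging(ph_series: np.ndarray) -> bool:
    """Strict decrease between consecutive stages followed later by a strict increase."""
    diffs = np.diff(ph_series)
    for i, d in enumerate(diffs):
        if np.isfinite(d) and d < 0:
            later = diffs[i + 1 :]
            if np.any(later[np.isfinite(later)] > 0):
                return True
    return False


def filter_outlier_plots(
    table: pd.DataFrame, rules: OutlierRules | None = None,
    calendar: StageCalendar | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop lodging-pattern and low-emergence plots; log every exclusion.

    Returns (filtered table, exclusion log with plot_id / rule / values).
    """
    rules = rules or OutlierRules()
    calendar = calendar or StageCalendar()
    exclusions = []
    for pid, grp in table.groupby("plot_id"):
        grp = grp.sort_values("das")
        ph = grp["ph"].to_numpy()
        if _is_lodging(ph):
            exclusions.append(
                {"plot_id": pid, "rule": "lodging pattern",
                 "values": "/".join(f"{v:.1f}" for v in ph)}
            )
            continue
        early = grp.loc[grp["stage"] == rules.low_cc_stage, "cc"]
        if len(early) and np.isfinite(early.iloc[0]) and early.iloc[0] < rules.low_cc_threshold:
            exclusions.append(
                {"plot_id": pid, "rule": "low emergence",
                 "values": f"cc_{rules.low_cc_stage}={early.iloc[0]:.3f}"}
            )
    log = pd.DataFrame(exclusions, columns=["plot_id", "rule", "values"])
    keep = ~table["plot_id"].isin(set(log["plot_id"]))
    return table[keep].reset_index(drop=True), log


def trait_matrix_from_table(
    table: pd.DataFrame, trait: str, calendar: StageCalendar | None = None
):
    """Pivot one trait into a genotypes x stages matrix for clustering.

    For the interval traits agrph/crph the matrix has one column per interval
    (three for a four-stage calendar); rows with any missing entry are dropped.
    """
    from .shape_clustering import TraitMatrix

    calendar = calendar or StageCalendar()
    wide = table.pivot_table(index="plot_id", columns="stage", values=trait, aggfunc="first")
    stages = calendar.stages if trait not in ("agrph", "crph") else calendar.stages[:-1]
    wide = wide.reindex(columns=stages).dropna()
    meta = table.drop_duplicates("plot_id").set_index("plot_id")
    groups = meta.loc[wide.index, "group"].to_numpy() if "group" in meta else None
    return TraitMatrix(
        series=wide.to_numpy(), trait=trait, names=list(wide.index.astype(str)),
        groups=groups,
    )
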