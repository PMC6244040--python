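"""Typical growth curves: per-cluster stage means, confidence bands, and a
morphological naming convention.

A cluster's typical curve connects the member mean at each of the four growth
stages, with a 95% t-interval band.  Curves are named by two landmarks: the
*zenith* point (the stage of the maximum mean, "Z2" for a zenith at S2) and
its *adjacent* point, classified by where it sits relative to the straight
chord from the zenith to the far endpoint of the curve's longer arm:

* Z2 -> adjacent S3, chord Z2-P4;  Z3 -> adjacent S2, chord Z3-P1;
* Z4 -> adjacent S3, chord Z4-P1;  Z1 -> adjacent S2, chord Z1-P4.

The adjacent point is "A" (above the chord), "B" (below), or "O" (on it,
within a range-relative tolerance), giving names like "Z2A3", "Z3B2",
"Z4O3".  Naming is invariant to positive affine transforms of the curve.

Cluster interpretability is quantified by the *recognition rate* — the share
of a cluster's members carrying its most frequent genetic-background group —
and by the membership overlap between clusters from different traits.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: zenith stage (1-based) -> (adjacent stage, chord endpoint stage)
_ARM_RULE = {1: (2, 4), 2: (3, 4), 3: (2, 1), 4: (3, 1)}

_NAME_RE = re.compile(r"^Z[1-4][ABO][1-4]$")


@dataclass
class CurveName:
    zenith_stage: int
    relation: str  # "A" | "B" | "O"
    adjacent_stage: int
    endpoint_stage: int

    def __str__(self) -> str:
        return f"Z{self.zenith_stage}{self.relation}{self.adjacent_stage}"


@dataclass
class TypicalCurve:
    """Stage-mean trajectory of one cluster with 95% CI half-widths."""

    cluster_id: int
    trait: str
    means: np.ndarray
    ci_half_widths: np.ndarray
    n_members: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.name and not _NAME_RE.match(self.name):
            raise ValueError(f"malformed curve name {self.name!r}")


def build_typical_curve(
    members: np.ndarray, cluster_id: int = 0, trait: str = ""
) -> TypicalCurve:
    """Stage means and 95% t-interval half-widths over a cluster's members."""
    members = np.atleast_2d(np.asarray(members, dtype=float))
    n = len(members)
    if n == 0:
        raise ValueError("cannot build a typical curve from an empty cluster")
    means = members.mean(axis=0)
    if n >= 2:
        sd = members.std(axis=0, ddof=1)
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    else:
        half = np.full(members.shape[1], np.nan)
    return TypicalCurve(cluster_id, trait, means, half, n)


def name_typical_curve(
    curve: TypicalCurve | np.ndarray, o_tolerance: float = 0.02
) -> CurveName:
    """Classify a 4-stage curve into the Z/A/B/O naming space.

    ``o_tolerance`` is the on-the-chord band as a fraction of the curve's
    value range; it makes the visually judged "O" relation explicit.
    """
    means = curve.means if isinstance(curve, TypicalCurve) else np.asarray(curve, float)
    if means.shape != (4,):
        raise ValueError("naming requires exactly 4 stage means")
    zenith = int(np.argmax(means)) + 1  # ties break to the earliest stage
    adjacent, endpoint = _ARM_RULE[zenith]
    # chord through (zenith, m_z) and (endpoint, m_e), evaluated at the adjacent stage
    mz, me = means[zenith - 1], means[endpoint - 1]
    frac = (adjacent - zenith) / (endpoint - zenith)
    chord_at_adjacent = mz + frac * (me - mz)
    offset = means[adjacent - 1] - chord_at_adjacent
    band = o_tolerance * float(np.ptp(means))
    if offset > band:
        relation = "A"
    elif offset < -band:
        relation = "B"
    else:
        relation = "O"
    return CurveName(zenith, relation, adjacent, endpoint)


def curves_from_result(matrix, result, o_tolerance: float = 0.02) -> list[TypicalCurve]:
    """Named typical curves for every cluster of a k-Shape result.

    Means are taken on the original (un-normalized) trait scale, as plotted
    in grower-facing figures; the name depends only on the curve's shape.
    """
    curves = []
    for c in range(1, result.k + 1):
        members = matrix.series[result.assignments == c]
        curve = build_typical_curve(members, cluster_id=c, trait=matrix.trait)
        curve.name = str(name_typical_curve(curve, o_tolerance)) if members.shape[1] == 4 else ""
        curves.append(curve)
    return curves


def recognition_rate(
    assignments: np.ndarray, group_labels: np.ndarray, names: dict | None = None
) -> dict:
    """Dominant-group share per cluster (or per pooled name type).

    Returns scope -> {"dominant": group, "rate": %, "n": members}.  With
    ``names`` (cluster id -> type name), clusters sharing a name are pooled
    and keyed by the name.
    """
    assignments = np.asarray(assignments)
    group_labels = np.asarray(group_labels)
    if len(assignments) != len(group_labels):
        raise ValueError("assignments and group labels must align")
    scopes: dict = {}
    for c in np.unique(assignments):
        key = names.get(int(c), str(c)) if names else int(c)
        scopes.setdefault(key, []).extend(group_labels[assignments == c])
    out = {}
    for key, members in scopes.items():
        if not members:
            raise ValueError(f"empty scope {key}")
        dominant, count = Counter(members).most_common(1)[0]
        out[key] = {
            "dominant": dominant,
            "rate": 100.0 * count / len(members),
            "n": len(members),
        }
    return out


def membership_overlap(set_a, set_b) -> float:
    """Overlap (%) between two member-id sets: 100 * |A & B| / min(|A|, |B|)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap of an empty member set is undefined")
    return 100.0 * len(a & b) / min(len(a), len(b))


def plot_typical_curves(curves, stage_labels=None, path=None, title=""):
    """Typical curves with 95% CI bands, one panel; optionally saved to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        x = np.arange(1, len(curve.means) + 1)
        label = f"cluster {curve.cluster_id}" + (f" ({curve.name})" if curve.name else "")
        ax.plot(x, curve.means, marker="o", label=label)
        if np.isfinite(curve.ci_half_widths).all():
            ax.fill_between(
                x, curve.means - curve.ci_half_widths,
                curve.means + curve.ci_half_widths, alpha=0.2,
            )
    labels = stage_labels or [f"S{i}" for i in range(1, len(curves[0].means) + 1)]
    ax.set_xticks(np.arange(1, len(labels) + 1), labels)
    ax.set_xlabel("growth stage")
    ax.set_ylabel(curves[0].trait or "trait value")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
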