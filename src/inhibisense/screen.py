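"""Coarse screening: group centroids, 3D response plots, evaluation reports.

Before the network stage, a response triple can be screened into one of three
chemical groups (heavy metals / pesticides / petrochemicals) with a
nearest-centroid rule - the quantitative counterpart of eyeballing group
separation in a pseudo-3D scatter of the three channels.  The module also
renders those 3D scatters and scores full pipeline runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from .annet import PollutantCall, quantize_concentration
from .errors import DataError
from .registry import BACTERIA, GROUPS, POLLUTANTS, POLLUTANT_GROUP, group_of
from .types import LabeledSample, ResponseVector

__all__ = [
    "GroupModel",
    "EvaluationReport",
    "build_3d_figure",
    "classify_group",
    "evaluate",
    "fit_group_centroids",
    "plot_3d",
]

_GROUP_COLORS = {"heavy_metals": "tab:blue", "pesticides": "tab:green",
                 "petrochemicals": "tab:red"}

TOP_LEVEL_UM = 1000.0


@dataclass(frozen=True)
class GroupModel:
    """Per-group centroids in 3-channel response space."""

    centroids: dict  # group -> np.ndarray shape (3,)
    membership: dict  # pollutant -> group

    def __post_init__(self):
        missing = set(GROUPS) - set(self.centroids)
        if missing:
            raise DataError(f"missing centroids for groups {sorted(missing)}")


def fit_group_centroids(
    samples: Sequence[LabeledSample], exclude_top_level: bool = False
) -> GroupModel:
    """Per-group mean response; optionally drops the 1000 uM level first.

    The top level is excluded because the largest concentration affects all
    three bacteria strongly and smears the group separation.
    """
    kept = [
        s
        for s in samples
        if not (exclude_top_level and quantize_concentration(s.concentration_uM) == TOP_LEVEL_UM)
    ]
    buckets: dict[str, list[np.ndarray]] = {g: [] for g in GROUPS}
    for s in kept:
        buckets[group_of(s.pollutant)].append(s.response.as_array())
    empty = [g for g, rows in buckets.items() if not rows]
    if empty:
        raise DataError(f"no samples left for groups {empty}")
    centroids = {g: np.mean(rows, axis=0) for g, rows in buckets.items()}
    return GroupModel(centroids=centroids, membership=dict(POLLUTANT_GROUP))


def classify_group(model: GroupModel, response: ResponseVector | np.ndarray) -> str:
    """Nearest centroid by Euclidean distance; ties go to the earlier group."""
    x = response.as_array() if isinstance(response, ResponseVector) else np.asarray(response, float)
    dists = [np.linalg.norm(x - model.centroids[g]) for g in GROUPS]
    return GROUPS[int(np.argmin(dists))]


def build_3d_figure(samples: Sequence[LabeledSample]):
    """A 3-axis scatter (one axis per channel) colored by chemical group."""
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    labels = {"e_coli": "E. coli", "m_capsulatus": "M. capsulatus",
              "s_oneidensis": "S. oneidensis"}
    for group in GROUPS:
        pts = np.array(
            [s.response.as_array() for s in samples if group_of(s.pollutant) == group]
        )
        if pts.size:
            ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2],
                       color=_GROUP_COLORS[group], label=group.replace("_", " "),
                       depthshade=False)
    ax.set_xlabel(f"dI/I0 ({labels[BACTERIA[0]]})")
    ax.set_ylabel(f"dI/I0 ({labels[BACTERIA[1]]})")
    ax.set_zlabel(f"dI/I0 ({labels[BACTERIA[2]]})")
    ax.text2D(0.02, 0.98, "concentration increases outward from origin",
              transform=ax.transAxes, fontsize=8, va="top")
    if samples:
        ax.legend(loc="upper right", fontsize=8)
    return fig


def plot_3d(samples: Sequence[LabeledSample], path) -> Path:
    """Render the 3D scatter to a deterministic vector file (SVG or PDF)."""
    path = Path(path)
    fig = build_3d_figure(samples)
    metadata = {"Date": None} if path.suffix.lower() == ".svg" else {"CreationDate": None}
    with matplotlib.rc_context({"svg.hashsalt": "inhibisense"}):
        fig.savefig(path, format=path.suffix.lstrip(".").lower(), metadata=metadata)
    plt.close(fig)
    return path


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracies plus a 12x12 pollutant confusion table (rows = truth)."""

    n: int
    pollutant_accuracy: float
    group_accuracy: float
    level_accuracy: float
    confusion: pd.DataFrame

    def summary(self) -> str:
        return (
            f"samples: {self.n}\n"
            f"pollutant identity accuracy: {self.pollutant_accuracy:.4f}\n"
            f"group accuracy: {self.group_accuracy:.4f}\n"
            f"concentration level accuracy: {self.level_accuracy:.4f}\n"
        )

    def to_files(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.confusion.to_csv(out_dir / "confusion.csv")
        (out_dir / "summary.txt").write_text(self.summary())


def evaluate(
    calls: Sequence[PollutantCall], truth: Sequence[LabeledSample]
) -> EvaluationReport:
    """Score calls against ground truth; truth levels are quantized first."""
    if len(calls) != len(truth):
        raise DataError(f"{len(calls)} calls vs {len(truth)} truth records")
    if not calls:
        raise DataError("nothing to evaluate")
    confusion = pd.DataFrame(
        0, index=list(POLLUTANTS), columns=list(POLLUTANTS), dtype=int
    )
    ok_p = ok_g = ok_l = 0
    for call, t in zip(calls, truth):
        confusion.loc[t.pollutant, call.pollutant] += 1
        ok_p += call.pollutant == t.pollutant
        ok_g += call.group == group_of(t.pollutant)
        ok_l += call.level_uM == quantize_concentration(t.concentration_uM)
    n = len(calls)
    return EvaluationReport(
        n=n,
        pollutant_accuracy=ok_p / n,
        group_accuracy=ok_g / n,
        level_accuracy=ok_l / n,
        confusion=confusion,
    )
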