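"""Validation statistics and published-summary regression checks.

Provides the descriptive statistics used to validate appearance
classification (confusion matrices, accuracy, Cohen's kappa, AUROC) and
position detection (per-axis and absolute distance summaries with 95%
confidence intervals, Pearson correlation), plus
:func:`reproduce_paper_summaries`, which recomputes every summary number
of the published clinical validation that follows arithmetically from
its printed tables and reports pass/fail against the printed values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Appearance

__all__ = [
    "CLASS_ORDER",
    "ConfusionMatrix3",
    "DistanceSummary",
    "accuracy",
    "round_half_up",
    "cohens_kappa",
    "distance_summary",
    "pearson_r",
    "auroc",
    "load_fixture_confusion",
    "reproduce_paper_summaries",
]

CLASS_ORDER = (Appearance.NFD, Appearance.MFD, Appearance.AFD)
_CLASS_INDEX = {a: i for i, a in enumerate(CLASS_ORDER)}


def _fixture_path(name: str) -> Path:
    return Path(resources.files("foveafinder.fixtures") / name)


@dataclass
class ConfusionMatrix3:
    """3x3 confusion matrix; rows = system class, columns = ground-truth
    class, both in the order (NFD, MFD, AFD)."""

    counts: np.ndarray
    labels: tuple[str, str, str] = ("NFD", "MFD", "AFD")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("counts must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(cls, system: Sequence[Appearance],
                    truth: Sequence[Appearance]) -> "ConfusionMatrix3":
        if len(system) != len(truth):
            raise ValueError("system and truth must have equal length")
        counts = np.zeros((3, 3), dtype=int)
        for s, t in zip(system, truth):
            counts[_CLASS_INDEX[s], _CLASS_INDEX[t]] += 1
        return cls(counts=counts)


def accuracy(cm: ConfusionMatrix3) -> float:
    """Overall classification accuracy in percent (unrounded):
    ``100 * trace / total``."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (87.5 -> 88), matching how the
    published accuracies were rounded."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)


def cohens_kappa(cm: ConfusionMatrix3) -> float:
    """Cohen's kappa: ``(p_o - p_e) / (1 - p_e)`` with the expected
    agreement ``p_e = sum_i row_i * col_i / total^2``."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / n
    p_e = float((cm.counts.sum(axis=1) * cm.counts.sum(axis=0)).sum()) / (n * n)
    if p_e >= 1.0:
        raise ValueError("degenerate matrix: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class DistanceSummary:
    """Mean, sample SD, and normal-approximation 95% CI of the X, Y and
    absolute (Euclidean) distances between two sets of fovea positions."""

    mean_um: dict
    sd_um: dict
    ci95_lo_um: dict
    ci95_hi_um: dict
    n: int


def distance_summary(dx_um: Sequence[float], dy_um: Sequence[float]
                     ) -> DistanceSummary:
    """Summarise per-scan position differences.

    The absolute distance is ``sqrt(dx^2 + dy^2)`` per scan; SD is the
    sample standard deviation (n-1) and the 95% CI is the normal
    approximation ``mean +/- 1.96 * SD / sqrt(n)``.  At least two scans
    are required for the SD and CI.
    """
    dx = np.abs(np.asarray(dx_um, dtype=float))
    dy = np.abs(np.asarray(dy_um, dtype=float))
    if dx.size == 0 or dx.shape != dy.shape:
        raise ValueError("dx and dy must be equal-length non-empty vectors")
    if dx.size < 2:
        raise ValueError("n >= 2 required for SD and confidence intervals")
    absd = np.hypot(dx, dy)
    n = dx.size
    mean, sd, lo, hi = {}, {}, {}, {}
    for axis, v in (("X", dx), ("Y", dy), ("abs", absd)):
        m = float(v.mean())
        s = float(v.std(ddof=1))
        half = 1.96 * s / np.sqrt(n)
        mean[axis], sd[axis] = m, s
        lo[axis], hi[axis] = m - half, m + half
    return DistanceSummary(mean_um=mean, sd_um=sd, ci95_lo_um=lo,
                           ci95_hi_um=hi, n=n)


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or a.shape != b.shape:
        raise ValueError("n >= 3 equal-length vectors required")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve with midrank
    tie handling."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)  # midranks
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# Published-summary fixtures


def load_fixture_confusion(disease: str,
                           fixtures_dir: Optional[Path] = None
                           ) -> ConfusionMatrix3:
    """Load one cohort's published confusion matrix from the bundled
    fixtures ('bRVO', 'cRVO' or 'nAMD')."""
    path = (Path(fixtures_dir) / "confusion_matrices.csv") if fixtures_dir \
        else _fixture_path("confusion_matrices.csv")
    df = pd.read_csv(path, comment="#")
    sub = df[df["disease"] == disease]
    if sub.empty:
        raise ValueError(f"no confusion fixture for disease {disease!r}")
    order = ["NFD", "MFD", "AFD"]
    counts = np.zeros((3, 3), dtype=int)
    for _, row in sub.iterrows():
        counts[order.index(row["system"]), order.index(row["truth"])] = row["count"]
    return ConfusionMatrix3(counts=counts)


def reproduce_paper_summaries(fixtures_dir: Optional[Path] = None) -> dict:
    """Recompute the published validation arithmetic from bundled fixtures.

    Checks (a) per-cohort classification accuracy from the confusion
    matrices, (b) the unweighted mean of the three overall absolute
    position errors, (c) the case-weighted mean absolute error of the two
    cystoid-macular-edema cohorts (branch and central RVO), and (d) the
    dataset bookkeeping (Spectralis share of the test set, post-exclusion
    validation size).  Each entry reports the computed value, the printed
    value, and whether they agree at the printed precision.
    """
    fdir = Path(fixtures_dir) if fixtures_dir else None
    counts_path = (fdir / "dataset_counts.json") if fdir \
        else _fixture_path("dataset_counts.json")
    dist_path = (fdir / "position_distances.csv") if fdir \
        else _fixture_path("position_distances.csv")
    meta = json.loads(Path(counts_path).read_text())
    printed = meta["printed"]
    dist = pd.read_csv(dist_path, comment="#")

    report: dict = {}

    for disease in ("bRVO", "cRVO", "nAMD"):
        cm = load_fixture_confusion(disease, fixtures_dir=fdir)
        acc = accuracy(cm)
        rounded = round_half_up(acc)
        expected = float(printed["accuracy_pct"][disease])
        report[f"accuracy_{disease}"] = {
            "computed": acc, "rounded": rounded, "printed": expected,
            "pass": rounded == expected,
        }
        report[f"kappa_{disease}"] = {"computed": cohens_kappa(cm)}

    overall = dist[(dist["scope"] == "overall") & (dist["axis"] == "abs")]
    means = {row["disease"]: float(row["mean_um"]) for _, row in overall.iterrows()}
    unweighted = sum(means.values()) / len(means)
    report["mean_abs_distance_um"] = {
        "computed": unweighted, "printed": float(printed["mean_abs_distance_um"]),
        "pass": round_half_up(unweighted, 1) == float(printed["mean_abs_distance_um"]),
    }

    w = meta["validation_counts"]
    weighted = (w["bRVO"] * means["bRVO"] + w["cRVO"] * means["cRVO"]) \
        / (w["bRVO"] + w["cRVO"])
    report["cme_weighted_mean_um"] = {
        "computed": weighted, "printed": float(printed["cme_weighted_mean_um"]),
        "pass": round_half_up(weighted, 1) == float(printed["cme_weighted_mean_um"]),
    }

    spectralis = sum(d["spectralis"] for d in meta["device_counts"].values())
    report["spectralis_count"] = {
        "computed": spectralis, "printed": printed["spectralis_count"],
        "pass": spectralis == printed["spectralis_count"],
    }
    validation = meta["test_set_total"] - sum(meta["excluded"].values())
    report["validation_total"] = {
        "computed": validation, "printed": printed["validation_total"],
        "pass": validation == printed["validation_total"],
    }
    return report
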