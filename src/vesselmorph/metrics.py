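"""ROI-based SNR/CNR quality metrics and Student's t-tests.

SNR is defined as the mean intensity of a tissue ROI divided by the
noise level N; N is the sample standard deviation of a homogeneous
empty background region.  CNR between two tissues a and b is
``(mean_a - mean_b) / N``, so ``CNR(a, b) = SNR(a) - SNR(b)`` exactly
when the same N is shared.

Group comparisons use the unpaired two-tailed Student's t-test with
pooled variance (``df = n_a + n_b - 2``); a Welch variant is available
behind a flag, and summary-statistic input is supported so published
``mean +/- SD (n)`` tables can be tested directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ROI", "ROIStats", "TTestResult", "roi_mean", "noise_sd", "snr",
           "cnr", "roi_report", "ttest_unpaired", "ttest_from_summary",
           "ttest_table"]

ROLES = ("wall", "lumen", "parenchyma", "background")


@dataclass
class ROI:
    """Named voxel set, as a box (3 slices) or an explicit boolean mask."""

    name: str
    role: str
    box: tuple[slice, slice, slice] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown ROI role {self.role!r}")
        if (self.box is None) == (self.mask is None):
            raise ValueError("give exactly one of box or mask")

    def extract(self, volume: np.ndarray) -> np.ndarray:
        if self.box is not None:
            vals = np.asarray(volume)[self.box].ravel()
        else:
            vals = np.asarray(volume)[self.mask]
        if vals.size == 0:
            raise ValueError(f"ROI {self.name!r} is empty")
        return vals

    @classmethod
    def from_json_obj(cls, obj) -> "ROI":
        box = tuple(slice(a, b) for a, b in obj["box"])
        return cls(name=obj["name"], role=obj["role"], box=box)

    def to_json_obj(self):
        if self.box is None:
            raise ValueError("mask ROIs are not JSON-serializable; use a box")
        return {"name": self.name, "role": self.role,
                "box": [[s.start, s.stop] for s in self.box]}


@dataclass
class ROIStats:
    """Per-tissue means, background noise SD, and derived SNR/CNR."""

    means: dict
    noise: float
    snr: dict
    cnr: dict

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"quantity": f"S_{k}", "value": v}
                for k, v in self.means.items()]
        rows.append({"quantity": "N", "value": self.noise})
        rows += [{"quantity": f"SNR_{k}", "value": v}
                 for k, v in self.snr.items()]
        rows += [{"quantity": f"CNR_{a}_{b}", "value": v}
                 for (a, b), v in self.cnr.items()]
        return pd.DataFrame(rows)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def roi_mean(volume: np.ndarray, roi: ROI) -> float:
    """Arithmetic mean intensity over the ROI."""
    return float(roi.extract(volume).mean())


def noise_sd(volume: np.ndarray, roi: ROI) -> float:
    """Sample SD (n-1 denominator) of a background ROI."""
    if roi.role != "background":
        raise ValueError("noise ROI must have role 'background'")
    vals = roi.extract(volume)
    if vals.size < 2:
        raise ValueError("noise ROI needs at least 2 voxels")
    return float(vals.std(ddof=1))


def snr(volume: np.ndarray, signal_roi: ROI, noise_roi: ROI) -> float:
    n = noise_sd(volume, noise_roi)
    if n == 0:
        raise ZeroDivisionError(
            "background noise SD is zero; enlarge the background ROI or "
            "check that it lies outside the specimen")
    return roi_mean(volume, signal_roi) / n


def cnr(volume: np.ndarray, roi_a: ROI, roi_b: ROI, noise_roi: ROI) -> float:
    n = noise_sd(volume, noise_roi)
    if n == 0:
        raise ZeroDivisionError(
            "background noise SD is zero; enlarge the background ROI or "
            "check that it lies outside the specimen")
    return (roi_mean(volume, roi_a) - roi_mean(volume, roi_b)) / n


def roi_report(volume: np.ndarray, rois: list[ROI]) -> ROIStats:
    """Means, N, SNR per tissue ROI and CNR for every tissue pair."""
    noise_rois = [r for r in rois if r.role == "background"]
    if not noise_rois:
        raise ValueError("need one background ROI for the noise estimate")
    n = noise_sd(volume, noise_rois[0])
    tissue = [r for r in rois if r.role != "background"]
    means = {r.name: roi_mean(volume, r) for r in tissue}
    snrs = {k: v / n for k, v in means.items()}
    cnrs = {}
    names = list(means)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cnrs[(a, b)] = (means[a] - means[b]) / n
    return ROIStats(means=means, noise=n, snr=snrs, cnr=cnrs)


def _finish(t, df, mean_a, sd_a, n_a, mean_b, sd_b, n_b):
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TTestResult(t=float(t), df=float(df), p=p,
                       mean_a=float(mean_a), sd_a=float(sd_a), n_a=int(n_a),
                       mean_b=float(mean_b), sd_b=float(sd_b), n_b=int(n_b))


def ttest_from_summary(mean_a: float, sd_a: float, n_a: int,
                       mean_b: float, sd_b: float, n_b: int,
                       welch: bool = False) -> TTestResult:
    """Unpaired two-tailed t-test from group summary statistics.

    Pooled (Student) by default:
    ``s_p^2 = ((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a + n_b - 2)`` and
    ``t = (mean_a - mean_b) / (s_p sqrt(1/n_a + 1/n_b))``.

    Degenerate inputs: zero pooled variance gives t = 0, p = 1 for equal
    means and infinite t, p = 0 otherwise.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be >= 0")
    diff = mean_a - mean_b
    if welch:
        va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
        se2 = va + vb
        if se2 == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            return _finish(t, n_a + n_b - 2, mean_a, sd_a, n_a,
                           mean_b, sd_b, n_b)
        df = se2 ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
        t = diff / np.sqrt(se2)
        return _finish(t, df, mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2) / df
    if sp2 == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        if diff == 0:
            return TTestResult(0.0, df, 1.0, mean_a, sd_a, n_a,
                               mean_b, sd_b, n_b)
        return _finish(t, df, mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    t = diff / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return _finish(t, df, mean_a, sd_a, n_a, mean_b, sd_b, n_b)


def ttest_unpaired(samples_a, samples_b, welch: bool = False) -> TTestResult:
    """Unpaired two-tailed Student's t-test on raw samples."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    return ttest_from_summary(a.mean(), a.std(ddof=1), a.size,
                              b.mean(), b.std(ddof=1), b.size, welch=welch)


def ttest_table(rows: list[dict], alpha: float = 0.05,
                bonferroni: bool = False) -> pd.DataFrame:
    """Published-style comparison table from summary rows.

    Each row dict needs keys segment, mean_a, sd_a, n_a, mean_b, sd_b,
    n_b.  With ``bonferroni`` the significance threshold is divided by
    the number of rows (off by default).
    """
    thr = alpha / len(rows) if bonferroni else alpha
    out = []
    for r in rows:
        res = ttest_from_summary(r["mean_a"], r["sd_a"], r["n_a"],
                                 r["mean_b"], r["sd_b"], r["n_b"])
        out.append({
            "segment": r["segment"],
            "group_a": f"{r['mean_a']:.1f} ± {r['sd_a']:.1f}",
            "group_b": f"{r['mean_b']:.1f} ± {r['sd_b']:.1f}",
            "t": res.t, "df": res.df, "p": res.p,
            "significant": res.p < thr,
        })
    return pd.DataFrame(out)
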