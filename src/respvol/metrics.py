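"""Evaluation formulary for estimated vs reference volume waveforms.

Three agreement measures compare a depth-camera estimate against a
reference (typically a ventilator or spirometer):

* tidal volume error — mean over breaths of |VD_i - VV_i| / VV_i x 100;
* volume waveform error — sum_t |WD_t - WV_t| / sum_t |WV_t| x 100 on the
  time-aligned waveforms;
* ICC — intraclass correlation in the absolute-agreement single-measure
  form, from the two-way (time x waveform) ANOVA decomposition:

      ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

  with MS_R the between-time, MS_C the between-waveform and MS_E the
  residual mean squares, k waveforms and n time points.  Absolute
  agreement penalizes a constant bias between the waveforms, unlike a
  consistency ICC.

Method comparison uses the Kruskal-Wallis rank test (tie-corrected H,
chi-square p) over per-breath error samples, with Dunn's pairwise z tests
and Bonferroni adjustment as the post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .volume import Breath, VolumeWaveform


class AlignmentError(ValueError):
    """Waveforms cannot be placed on a common time base."""


@dataclass
class PairedWaveforms:
    """Reference and estimate resampled onto a common time base (mL)."""

    times: np.ndarray
    reference: np.ndarray
    estimate: np.ndarray

    def __post_init__(self):
        if not (len(self.times) == len(self.reference) == len(self.estimate)):
            raise ValueError("paired waveforms must have equal length")


def align(
    reference: VolumeWaveform,
    estimate: VolumeWaveform,
    offset: float = 0.0,
    use_cumulative: bool = True,
) -> PairedWaveforms:
    """Resample both waveforms onto their time overlap at the reference rate.

    ``offset`` (s) is added to the estimate's clock before alignment (the
    constant camera-vs-reference clock shift).  Values are linearly
    interpolated; the cumulative series is used by default.
    """
    rt = reference.times
    et = estimate.times + offset
    t0 = max(rt[0], et[0])
    t1 = min(rt[-1], et[-1])
    if t1 <= t0:
        raise AlignmentError("waveform time ranges do not overlap")
    sel = (rt >= t0) & (rt <= t1)
    times = rt[sel]
    rv = reference.cumulative if use_cumulative else reference.values
    ev = estimate.cumulative if use_cumulative else estimate.values
    return PairedWaveforms(
        times=times,
        reference=np.interp(times, rt, rv),
        estimate=np.interp(times, et, ev),
    )


def tidal_volume_error(VD, VV) -> tuple[float, np.ndarray]:
    """Mean per-breath relative tidal volume error in percent.

    Returns ``(mean_percent, per_breath_percent)``; breaths are matched
    by position in the two lists.
    """
    VD = np.asarray(VD, dtype=float)
    VV = np.asarray(VV, dtype=float)
    if VD.shape != VV.shape:
        raise ValueError(f"breath counts differ: {len(VD)} vs {len(VV)}")
    if len(VV) == 0:
        raise ValueError("no breaths to compare")
    if (VV <= 0).any():
        raise ValueError("reference tidal volumes must be positive")
    per_breath = np.abs(VD - VV) / VV * 100.0
    return float(per_breath.mean()), per_breath


def volume_waveform_error(pair: PairedWaveforms) -> float:
    """Summed absolute waveform discrepancy relative to the reference, percent."""
    denom = np.abs(pair.reference).sum()
    if denom <= 0:
        raise ValueError("reference waveform is identically zero")
    return float(np.abs(pair.estimate - pair.reference).sum() / denom * 100.0)


def icc(pair: PairedWaveforms) -> float:
    """Absolute-agreement single-measure ICC of the paired waveforms.

    Computed from the two-way ANOVA mean squares of the n x 2 data matrix
    (time points x waveforms).  Raises on constant waveforms, where the
    between-time variance that anchors the coefficient vanishes.
    """
    data = np.column_stack([pair.reference, pair.estimate])
    return icc_matrix(data)


def icc_matrix(data: np.ndarray) -> float:
    """Absolute-agreement single-measure ICC of an n x k data matrix."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 samples and 2 waveforms")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if abs(denom) < 1e-30 or ms_r < 1e-30:
        raise ValueError("ICC undefined: waveforms have no between-time variance")
    return float((ms_r - ms_e) / denom)


def match_breaths(
    reference: list[Breath], estimate: list[Breath]
) -> tuple[list[Breath], list[Breath], int]:
    """Pair breaths by greatest temporal overlap of their intervals.

    Falls back to index order when intervals carry no timing information.
    Returns matched reference and estimate lists plus the number of
    unmatched breaths (reported, never silently dropped).
    """
    if not reference or not estimate:
        return [], [], len(reference) + len(estimate)
    pairs: list[tuple[int, int]] = []
    used_e: set[int] = set()
    for i, rb in enumerate(reference):
        best_j, best_ov = -1, 0.0
        for j, eb in enumerate(estimate):
            if j in used_e:
                continue
            ov = min(rb.peak_time, eb.peak_time) - max(rb.valley_time, eb.valley_time)
            if ov > best_ov:
                best_j, best_ov = j, ov
        if best_j >= 0:
            pairs.append((i, best_j))
            used_e.add(best_j)
    if not pairs:  # no temporal overlap information; match by order
        m = min(len(reference), len(estimate))
        pairs = [(i, i) for i in range(m)]
    ref_m = [reference[i] for i, _ in pairs]
    est_m = [estimate[j] for _, j in pairs]
    unmatched = (len(reference) - len(pairs)) + (len(estimate) - len(pairs))
    return ref_m, est_m, unmatched


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    offsets = np.cumsum([0] + [len(g) for g in groups[:-1]])
    h = 0.0
    for g, off in zip(groups, offsets):
        r_mean = ranks[off : off + len(g)].mean()
        h += len(g) * (r_mean - (N + 1) / 2.0) ** 2
    h *= 12.0 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    if tie_corr <= 0:
        return 0.0, 1.0
    h /= tie_corr
    p = float(stats.chi2.sf(h, len(groups) - 1))
    return float(h), p


def dunn_test(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons with Bonferroni adjustment."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(g) for g in groups[:-1]])
    r_means = [ranks[o : o + len(g)].mean() for g, o in zip(groups, offsets)]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (r_means[i] - r_means[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": float(z),
                "p_raw": float(p_raw),
                "p_adjusted": float(min(1.0, p_raw * m)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MethodComparison:
    h: float
    p_value: float
    pairwise: pd.DataFrame


def compare_methods(
    errors_by_method: dict[str, np.ndarray] | list[np.ndarray],
) -> MethodComparison:
    """Kruskal-Wallis omnibus test plus Dunn's post hoc over error samples.

    Each entry is the list of per-breath tidal volume errors of one
    method.  Identical values across all groups give H = 0, p = 1.
    """
    if isinstance(errors_by_method, dict):
        labels = list(errors_by_method)
        groups = [np.asarray(errors_by_method[k], dtype=float) for k in labels]
    else:
        groups = [np.asarray(g, dtype=float) for g in errors_by_method]
        labels = [f"group{i}" for i in range(len(groups))]
    h, p = kruskal_wallis(groups)
    return MethodComparison(h=h, p_value=p, pairwise=dunn_test(groups, labels))


@dataclass
class MetricsReport:
    """Flat summary of the agreement between estimate and reference."""

    tidal_volume_error_pct: float
    volume_waveform_error_pct: float
    icc: float
    per_breath_error_pct: np.ndarray = field(default_factory=lambda: np.array([]))
    n_breaths_reference: int = 0
    n_breaths_estimate: int = 0
    n_unmatched: int = 0

    def __post_init__(self):
        if self.tidal_volume_error_pct < 0 or self.volume_waveform_error_pct < 0:
            raise ValueError("errors must be non-negative")
        if self.icc > 1.0 + 1e-12:
            raise ValueError("icc cannot exceed 1")

    def to_text(self) -> str:
        lines = [
            f"tidal_volume_error_pct = {self.tidal_volume_error_pct:.4f}",
            f"volume_waveform_error_pct = {self.volume_waveform_error_pct:.4f}",
            f"icc = {self.icc:.6f}",
            f"n_breaths_reference = {self.n_breaths_reference}",
            f"n_breaths_estimate = {self.n_breaths_estimate}",
            f"n_unmatched = {self.n_unmatched}",
        ]
        return "\n".join(lines) + "\n"


def evaluate_waveforms(
    reference: VolumeWaveform,
    estimate: VolumeWaveform,
    offset: float = 0.0,
) -> MetricsReport:
    """Full agreement report between an estimate and a reference waveform."""
    pair = align(reference, estimate, offset)
    ref_b, est_b, unmatched = match_breaths(reference.breaths, estimate.breaths)
    if ref_b:
        tve, per_breath = tidal_volume_error(
            [b.tidal_ml for b in est_b], [b.tidal_ml for b in ref_b]
        )
    else:
        tve, per_breath = float("nan"), np.array([])
    return MetricsReport(
        tidal_volume_error_pct=tve,
        volume_waveform_error_pct=volume_waveform_error(pair),
        icc=icc(pair),
        per_breath_error_pct=per_breath,
        n_breaths_reference=len(reference.breaths),
        n_breaths_estimate=len(estimate.breaths),
        n_unmatched=unmatched,
    )
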