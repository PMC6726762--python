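"""Biophysical quantities derived from the raw per-object measurements.

The chain from pixels to biology:

* tip-broadening correction — the apparent nucleosome radius r is roughly
  twice the crystallographic 5.5 nm, and the protruding arms lose the
  difference, so each arm gains (r − 5.5 nm);
* wrapping length l_w [bp] — free-DNA mean contour minus both corrected
  arms, divided by the nm/bp calibration;
* positioning — the corrected short-arm ratio sa-ratio_c = s/(s+l),
  0.5 for a perfectly centered nucleosome, → 0 toward the fragment end.

Group comparisons follow the usual decision tree: Shapiro–Wilk per group,
then t-test/ANOVA + Tukey when all groups pass normality, otherwise
Mann–Whitney U or Kruskal–Wallis with Dunn's post test
(Bonferroni-adjusted).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .afm_io import PipelineConfig, QuantRecord

#: Histogram specifications (bin width, range) per parameter.
HISTOGRAM_SPECS = {
    "theta_deg": (15.0, (0.0, 180.0)),
    "lw_bp": (15.0, (60.0, 225.0)),
    "sa_ratio_c": (0.01, (0.0, 0.5)),
    "arm_nm": (10.0, (0.0, 120.0)),
}


def nm_per_bp(mean_contour_nm: float, fragment_bp: int) -> float:
    """Rise per base pair from the mean free-DNA contour length."""
    if mean_contour_nm <= 0 or fragment_bp <= 0:
        raise ValueError("mean contour length and fragment size must be positive")
    return mean_contour_nm / fragment_bp


def correct_arm_length(arm_nm: float, radius_nm: float,
                       known_radius_nm: float = 5.5) -> float:
    """Tip-broadening correction: add (apparent − known) radius to the arm."""
    if arm_nm < 0 or radius_nm <= 0:
        raise ValueError("arm_nm must be >= 0 and radius_nm > 0")
    return arm_nm + (radius_nm - known_radius_nm)


def wrapping_length(short_corr_nm: float, long_corr_nm: float,
                    free_dna_mean_nm: float, nm_per_bp: float) -> float:
    """DNA wrapping length l_w in bp (unrounded; round only when reporting)."""
    if min(short_corr_nm, long_corr_nm, free_dna_mean_nm, nm_per_bp) <= 0:
        raise ValueError("all inputs must be positive")
    return (free_dna_mean_nm - short_corr_nm - long_corr_nm) / nm_per_bp


def sa_ratio(short_corr_nm: float, long_corr_nm: float) -> float:
    """Corrected short-arm ratio s/(s+l) in [0, 0.5]."""
    if short_corr_nm <= 0 or long_corr_nm <= 0:
        raise ValueError("arm lengths must be positive")
    if short_corr_nm > long_corr_nm:
        short_corr_nm, long_corr_nm = long_corr_nm, short_corr_nm
    return short_corr_nm / (short_corr_nm + long_corr_nm)


def normalize_angle(theta_deg: float, inverted_flag: bool) -> float:
    """Resolve the 180° − θ orientation ambiguity when flagged."""
    if not (0 <= theta_deg <= 180):
        raise ValueError("theta_deg must lie in [0, 180]")
    return 180.0 - theta_deg if inverted_flag else theta_deg


#: qc flags that mark an object as structurally unreliable
_ABNORMAL_FLAGS = {"ambiguous", "branched", "border", "circular", "fragmented",
                   "single_arm", "unmeasurable"}


def filter_valid(records: list[QuantRecord], cfg: PipelineConfig,
                 for_positioning: bool = False) -> list[QuantRecord]:
    """Apply the validity windows and abnormality filters.

    Nucleosome records must have an arm-sum contour inside
    ``cfg.length_window_nm`` and carry none of the structural-abnormality
    flags.  With ``for_positioning=True`` the additional
    sa-ratio_c ≥ ``cfg.sa_ratio_min`` cut used for positioning analyses is
    applied.
    """
    lo, hi = cfg.length_window_nm
    kept = []
    for r in records:
        if set(r.qc_flags) & _ABNORMAL_FLAGS:
            continue
        if r.object_kind == "nucleosome":
            arm_sum = r.short_arm_nm + r.long_arm_nm
            if not (lo <= arm_sum <= hi):
                continue
            if for_positioning and not (r.sa_ratio_c >= cfg.sa_ratio_min):
                continue
        kept.append(r)
    return kept


def quantify_record(record: QuantRecord, cfg: PipelineConfig) -> QuantRecord:
    """Fill the derived fields of a nucleosome record in place."""
    if record.object_kind != "nucleosome":
        return record
    flags = list(record.qc_flags)
    s = correct_arm_length(record.short_arm_nm, record.radius_nm, cfg.known_radius_nm)
    l = correct_arm_length(record.long_arm_nm, record.radius_nm, cfg.known_radius_nm)
    if record.radius_nm < cfg.known_radius_nm:
        flags.append("negative_radius_correction")
    if s > l:
        s, l = l, s
        flags.append("arms_swapped")
    record.short_arm_corr_nm, record.long_arm_corr_nm = s, l
    record.lw_bp = wrapping_length(s, l, cfg.free_dna_mean_nm, cfg.nm_per_bp)
    if record.lw_bp < 0:
        flags.append("over_extended")
    record.sa_ratio_c = sa_ratio(s, l)
    if not np.isnan(record.theta_deg):
        record.theta_deg = normalize_angle(
            record.theta_deg, "theta_inverted" in flags
        )
    record.qc_flags = tuple(flags)
    return record


def median_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI for the median via binomial order statistics."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    alpha = 1.0 - level
    lo_rank = int(stats.binom.ppf(alpha / 2, n, 0.5))        # 0-based lower index
    hi_rank = int(stats.binom.isf(alpha / 2, n, 0.5))        # 0-based upper index
    lo_rank = max(lo_rank, 0)
    hi_rank = min(hi_rank, n - 1)
    return float(x[lo_rank]), float(x[hi_rank])


@dataclass
class ClassSummary:
    label: str
    n: int
    stats: pd.DataFrame  # index: parameter; columns: mean, sd, median, ci_lo, ci_hi
    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def _histogram(values: np.ndarray, bin_width: float,
               rng: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Probability-normalized histogram; final bin right-closed."""
    edges = np.arange(rng[0], rng[1] + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    # np.histogram already closes the last bin on the right
    probs = counts / max(len(values), 1)
    return probs, edges


def summarize_class(records: list[QuantRecord], label: str) -> ClassSummary:
    """Per-class mean ± sd, median with 95% CI, and standard histograms."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to summarize a class")
    params = ["total_length_nm", "radius_nm", "theta_deg", "short_arm_nm",
              "long_arm_nm", "short_arm_corr_nm", "long_arm_corr_nm",
              "lw_bp", "sa_ratio_c"]
    rows = {}
    for p in params:
        vals = np.array([getattr(r, p) for r in records], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            continue
        lo, hi = median_ci(vals)
        rows[p] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "median": float(np.median(vals)),
            "ci_lo": lo,
            "ci_hi": hi,
            "n": len(vals),
        }
    hists = {}
    for key, (width, rng) in HISTOGRAM_SPECS.items():
        if key == "arm_nm":
            vals = np.array(
                [getattr(r, p) for r in records for p in ("short_arm_nm", "long_arm_nm")],
                dtype=float,
            )
        else:
            vals = np.array([getattr(r, key) for r in records], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals):
            hists[key] = _histogram(vals, width, rng)
    return ClassSummary(label, len(records), pd.DataFrame(rows).T, hists)


def dunn_posthoc(groups: list[np.ndarray]) -> np.ndarray:
    """Dunn's rank-based multiple comparison, Bonferroni-adjusted.

    Returns the symmetric matrix of adjusted two-sided p-values.  The z
    statistic for groups i, j uses the pooled-rank means and the
    tie-corrected variance N(N+1)/12 − Σ(t³−t)/(12(N−1)).
    """
    k = len(groups)
    all_vals = np.concatenate(groups)
    n_total = len(all_vals)
    ranks = stats.rankdata(all_vals)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = k * (k - 1) // 2
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p[i, j] = p[j, i] = min(p_raw * m, 1.0)
    return p


@dataclass
class ComparisonReport:
    branch: str                    # which test family was used
    normality_p: list[float]
    statistic: float
    p_value: float
    posthoc: np.ndarray | None     # pairwise adjusted p-values (k > 2)


def compare_classes(groups: list[np.ndarray],
                    alpha: float = 0.05) -> ComparisonReport:
    """Normality-gated two-or-more-group comparison.

    All groups normal (Shapiro–Wilk, p > alpha) → t-test (2 groups) or
    one-way ANOVA + Tukey HSD; otherwise Mann–Whitney U (2 groups) or
    Kruskal–Wallis + Dunn (Bonferroni).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 3:
            raise ValueError("each group needs n >= 3")
        if np.ptp(g) == 0:
            raise ValueError("constant group has degenerate variance")
    normality = [float(stats.shapiro(g).pvalue) for g in groups]
    all_normal = all(p > alpha for p in normality)
    posthoc = None
    if len(groups) == 2:
        if all_normal:
            res = stats.ttest_ind(groups[0], groups[1])
            branch = "t-test"
        else:
            res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            branch = "mann-whitney"
        statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        if all_normal:
            res = stats.f_oneway(*groups)
            branch = "anova+tukey"
            tk = stats.tukey_hsd(*groups)
            posthoc = np.asarray(tk.pvalue)
        else:
            res = stats.kruskal(*groups)
            branch = "kruskal-wallis+dunn"
            posthoc = dunn_posthoc(groups)
        statistic, p_value = float(res.statistic), float(res.pvalue)
    return ComparisonReport(branch, normality, statistic, p_value, posthoc)
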