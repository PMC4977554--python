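"""Statistical reporting: summaries, group comparisons, normality, qPCR.

Per-condition features are summarized as mean ± SEM.  Treated-vs-control
distributions are compared with the two-sided Mann-Whitney U test (the
morphometric features are typically non-Gaussian) and the two-sample
Kolmogorov-Smirnov test, with Bonferroni adjustment across the family of
four morphometric features within a cell line.  Normality is assessed with
the Anderson-Darling test for the composite normal hypothesis (mean and
variance estimated), using the small-sample-corrected statistic
A* = A²(1 + 0.75/n + 2.25/n²) and the standard piecewise-exponential
p-value approximation — the same convention as R's ``nortest::ad.test``.

Relative qPCR expression uses the efficiency-corrected ratio

    fold change = E_target^ΔCt_target / E_ref^ΔCt_ref

with ΔCt = Ct(control) − Ct(treated) and efficiencies in (1, 2].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NucmorphError
from .volume import FeatureTable

ALPHA = 0.05  # study-wide significance threshold


@dataclass
class ComparisonResult:
    """One two-group distribution comparison."""

    feature: str
    group_a: str
    group_b: str
    test: str  # mann-whitney | ks
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")
        if min(self.n_a, self.n_b) < 3:
            raise ValueError("each group needs n >= 3")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


@dataclass
class PfafflResult:
    """Efficiency-corrected relative expression of one target gene."""

    target_gene: str
    e_target: float
    e_ref: float
    dct_target: float
    dct_ref: float
    ratio: float


def summarize(table: FeatureTable, feature: str, condition: str) -> tuple[float, float, int]:
    """Mean, SEM (sd/√n, ddof=1) and n for one feature in one condition."""
    vals = table.values(feature, condition)
    n = vals.size
    if n < 2:
        raise NucmorphError(f"need n >= 2 to summarize, got {n} for {feature}/{condition}")
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n)), int(n)


def summarize_all(table: FeatureTable) -> pd.DataFrame:
    """Mean ± SEM for every (feature, condition) pair."""
    rows = []
    for feature in table.features():
        for condition in table.conditions():
            if table.values(feature, condition).size >= 2:
                mean, sem, n = summarize(table, feature, condition)
                rows.append({"feature": feature, "condition": condition,
                             "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)


def compare_groups(a, b, test: str = "mann-whitney",
                   feature: str = "", group_a: str = "a", group_b: str = "b") -> ComparisonResult:
    """Two-sided two-sample comparison.

    Mann-Whitney uses the exact null distribution for n ≤ 20 per group
    (no ties) and the normal approximation with tie and continuity
    correction otherwise; ties get mid-ranks.  Identical samples short-cut
    to p = 1.  KS is the two-sample Kolmogorov-Smirnov D.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 3:
        raise NucmorphError("each group needs n >= 3")
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        stat = float(a.size * b.size / 2) if test == "mann-whitney" else 0.0
        return ComparisonResult(feature, group_a, group_b, test, stat, 1.0,
                                int(a.size), int(b.size))
    if test == "mann-whitney":
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    elif test == "ks":
        res = stats.ks_2samp(a, b, alternative="two-sided")
    else:
        raise NucmorphError(f"unknown two-sample test {test!r}")
    return ComparisonResult(feature, group_a, group_b, test,
                            float(res.statistic), float(min(res.pvalue, 1.0)),
                            int(a.size), int(b.size))


def bonferroni_adjust(results: list[ComparisonResult]) -> list[ComparisonResult]:
    """Bonferroni adjustment across one family of comparisons (in place)."""
    m = len(results)
    for r in results:
        r.adjusted_p = min(1.0, r.p_value * m)
    return results


def normality(a) -> tuple[float, float]:
    """Anderson-Darling test of composite normality: returns (A², p).

    A² uses estimated mean and variance; p comes from the corrected
    statistic A* = A²(1 + 0.75/n + 2.25/n²) via the piecewise-exponential
    approximation.  Requires n ≥ 8 and a non-constant sample.
    """
    x = np.sort(np.asarray(a, dtype=float))
    n = x.size
    if n < 8:
        raise NucmorphError(f"Anderson-Darling needs n >= 8, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise NucmorphError("constant sample: normality test undefined")
    z = (x - x.mean()) / sd
    logp = stats.norm.logcdf(z)
    logsf = stats.norm.logsf(z)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (logp + logsf[::-1]))
    a_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a_star >= 0.6:
        p = np.exp(1.2937 - 5.709 * a_star + 0.0186 * a_star**2)
    elif a_star >= 0.34:
        p = np.exp(0.9177 - 4.279 * a_star - 1.38 * a_star**2)
    elif a_star >= 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * a_star - 59.938 * a_star**2)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * a_star - 223.73 * a_star**2)
    return float(a2), float(min(max(p, 0.0), 1.0))


def pfaffl_ratio(e_target: float, e_ref: float, dct_target: float, dct_ref: float) -> float:
    """Efficiency-corrected fold change E_t^ΔCt_t / E_ref^ΔCt_ref.

    ΔCt is control − treated in cycles.  Efficiencies must lie in (1, 2]
    (2 = perfect doubling per cycle).
    """
    for name, e in (("target", e_target), ("reference", e_ref)):
        if not 1.0 < e <= 2.0:
            raise NucmorphError(f"{name} efficiency must lie in (1, 2], got {e}")
    return float(e_target**dct_target / e_ref**dct_ref)


def analyze_qpcr(ct_table: pd.DataFrame, efficiencies: dict[str, float],
                 ref_gene: str = "ACTB") -> list[PfafflResult]:
    """Pfaffl analysis of a Ct table (columns gene, condition, replicate, ct).

    ΔCt per gene = mean Ct(control) − mean Ct(treated); every non-reference
    gene is reported relative to ``ref_gene``.
    """
    def dct(gene: str) -> float:
        g = ct_table[ct_table["gene"] == gene]
        ctrl = g.loc[g["condition"] == "control", "ct"]
        trt = g.loc[g["condition"] == "treated", "ct"]
        if ctrl.empty or trt.empty:
            raise NucmorphError(f"gene {gene}: missing control or treated Ct values")
        return float(ctrl.mean() - trt.mean())

    dct_ref = dct(ref_gene)
    out = []
    for gene in sorted(ct_table["gene"].unique()):
        if gene == ref_gene:
            continue
        d = dct(gene)
        out.append(PfafflResult(
            target_gene=gene, e_target=efficiencies[gene], e_ref=efficiencies[ref_gene],
            dct_target=d, dct_ref=dct_ref,
            ratio=pfaffl_ratio(efficiencies[gene], efficiencies[ref_gene], d, dct_ref),
        ))
    return out


# ---------------------------------------------------------------------------
# Figure + binned-data exports (tests consume the CSVs, not the images)


def export_histograms(table: FeatureTable, out_dir: str | Path, bins: int = 20) -> pd.DataFrame:
    """Per-feature, per-condition histograms: PNG plus a binned-counts CSV.

    Bin edges are shared across conditions within a feature so overlays are
    comparable; counts conserve n exactly.  Returns the binned table.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for feature in table.features():
        all_vals = table.values(feature)
        if all_vals.size == 0:
            continue
        edges = np.histogram_bin_edges(all_vals, bins=bins)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for condition in table.conditions():
            vals = table.values(feature, condition)
            if vals.size == 0:
                continue
            counts, _ = np.histogram(vals, bins=edges)
            ax.stairs(counts, edges, label=condition)
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                rows.append({"feature": feature, "condition": condition,
                             "bin_left": lo, "bin_right": hi, "count": int(c)})
        ax.set_xlabel(feature)
        ax.set_ylabel("cells")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / f"hist_{feature}.png", dpi=120)
        plt.close(fig)
    binned = pd.DataFrame(rows)
    binned.to_csv(out_dir / "histograms.csv", index=False)
    return binned


def export_boxplots(table: FeatureTable, out_dir: str | Path) -> pd.DataFrame:
    """Per-feature box plots (median/IQR, whiskers at 1.5·IQR) + stats CSV."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for feature in table.features():
        conds = [c for c in table.conditions() if table.values(feature, c).size > 0]
        data = [table.values(feature, c) for c in conds]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.boxplot(data, tick_labels=conds, whis=1.5)
        ax.set_ylabel(feature)
        fig.tight_layout()
        fig.savefig(out_dir / f"box_{feature}.png", dpi=120)
        plt.close(fig)
        for cond, vals in zip(conds, data):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = vals[vals >= q1 - 1.5 * iqr].min()
            hi = vals[vals <= q3 + 1.5 * iqr].max()
            rows.append({"feature": feature, "condition": cond, "median": med,
                         "q1": q1, "q3": q3, "whisker_low": lo, "whisker_high": hi,
                         "n": int(vals.size)})
    boxstats = pd.DataFrame(rows)
    boxstats.to_csv(out_dir / "boxplots.csv", index=False)
    return boxstats
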