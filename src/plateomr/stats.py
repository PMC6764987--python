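"""Group-level statistics: binning, chi-squared tests, Bonferroni
thresholds, the median-p convention, and small unit helpers.

Activity and E-O scores are not normally distributed across larvae, so
group comparisons are nonparametric throughout: scores are binned (activity
into quartile bands, E-O into the three bands <0%, 0-10%, >10%) and groups
are compared with a Pearson chi-squared test.  Repeat experiments run on
separate days are summarized by the median of the per-experiment p-values;
multiple comparisons within a figure family use the Bonferroni-corrected
thresholds 0.05/n and 0.01/n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

log = logging.getLogger(__name__)


class StatsError(ValueError):
    """Invalid statistical input (empty group, out-of-domain value, ...)."""


ACTIVITY_QUARTILE_LABELS = ("0-25%", "25-50%", "50-75%", "75-100%")
EO_TERCILE_LABELS = ("<0%", "0-10%", ">10%")
SIGN_LABELS = ("positive", "non-positive")


@dataclass(frozen=True)
class BinnedCounts:
    """Counts of larvae per score bin under a named binning scheme."""

    scheme: str
    labels: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise StatsError("labels and counts must align")
        if any(c < 0 for c in self.counts):
            raise StatsError("counts must be >= 0")

    @property
    def n(self) -> int:
        return int(sum(self.counts))


def bin_scores(values: Sequence[float], scheme: str = "activity_quartiles") -> BinnedCounts:
    """Bin scores under one of the standard schemes.

    activity_quartiles: [0,25), [25,50), [50,75), [75,100] — boundaries
    close upward except the last bin.  eo_terciles: (-inf,0), [0,10],
    (10,inf) — an E-O of exactly 0 or exactly 10 falls in the middle band.
    sign: >0 vs <=0.
    """
    v = np.asarray(values, dtype=float)
    if v.size and not np.isfinite(v).all():
        raise StatsError("scores must be finite")
    if scheme == "activity_quartiles":
        if v.size and (v.min() < 0 or v.max() > 100):
            raise StatsError("activity must be within [0, 100]")
        counts = (
            int(((v >= 0) & (v < 25)).sum()),
            int(((v >= 25) & (v < 50)).sum()),
            int(((v >= 50) & (v < 75)).sum()),
            int(((v >= 75) & (v <= 100)).sum()),
        )
        return BinnedCounts(scheme, ACTIVITY_QUARTILE_LABELS, counts)
    if scheme == "eo_terciles":
        counts = (
            int((v < 0).sum()),
            int(((v >= 0) & (v <= 10)).sum()),
            int((v > 10).sum()),
        )
        return BinnedCounts(scheme, EO_TERCILE_LABELS, counts)
    if scheme == "sign":
        counts = (int((v > 0).sum()), int((v <= 0).sum()))
        return BinnedCounts(scheme, SIGN_LABELS, counts)
    raise StatsError(f"unknown binning scheme {scheme!r}")


@dataclass(frozen=True)
class GroupComparison:
    """Result of one chi-squared comparison with its Bonferroni context."""

    chi2: float
    dof: int
    p: float
    n_comparisons: int = 1

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not 0 <= self.p <= 1 or self.n_comparisons < 1:
            raise StatsError("invalid test result")

    def bonferroni_alpha(self, alpha: float = 0.05) -> float:
        return bonferroni(alpha, self.n_comparisons)

    @property
    def significant_at(self) -> str:
        """'**' below 0.01/n, '*' below 0.05/n, '' otherwise."""
        if self.p < bonferroni(0.01, self.n_comparisons):
            return "**"
        if self.p < bonferroni(0.05, self.n_comparisons):
            return "*"
        return ""


def _pearson(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-squared statistic and dof of an r x k contingency table,
    expected counts from the pooled margins."""
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row * col / total
    chi2 = float(((table - expected) ** 2 / expected).sum())
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, dof


def chi2_homogeneity(
    counts_a: BinnedCounts | Sequence[int],
    counts_b: BinnedCounts | Sequence[int],
    n_comparisons: int = 1,
) -> GroupComparison:
    """Pearson chi-squared homogeneity test on a 2 x k table of binned
    counts (no continuity correction).

    Bins empty in *both* groups are pruned first (they carry no information
    and would give 0/0 expected counts); a bin empty in only one group is
    kept.  dof = k - 1 after pruning.
    """
    a = np.asarray(
        counts_a.counts if isinstance(counts_a, BinnedCounts) else counts_a, dtype=float
    )
    b = np.asarray(
        counts_b.counts if isinstance(counts_b, BinnedCounts) else counts_b, dtype=float
    )
    if a.shape != b.shape:
        raise StatsError("groups must be binned with the same scheme")
    if a.sum() == 0 or b.sum() == 0:
        raise StatsError("each group needs at least one larva")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise StatsError("need at least 2 non-empty bins")
    table = np.vstack([a, b])
    chi2, dof = _pearson(table)
    p = float(_chi2_dist.sf(chi2, dof))
    return GroupComparison(chi2=chi2, dof=dof, p=p, n_comparisons=n_comparisons)


def chi2_5050(eo_values: Sequence[float], n_comparisons: int = 1) -> GroupComparison:
    """Goodness-of-fit of the positive/non-positive E-O split against the
    50-50 distribution expected when larvae ignore the visual stimulus.

    An E-O of exactly 0 counts as non-positive.  1 dof.
    """
    v = np.asarray(eo_values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 1:
        raise StatsError("need at least one valid E-O value")
    pos = int((v > 0).sum())
    observed = np.array([pos, n - pos], dtype=float)
    expected = np.array([n / 2.0, n / 2.0])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(_chi2_dist.sf(chi2, 1))
    return GroupComparison(chi2=chi2, dof=1, p=p, n_comparisons=n_comparisons)


def bonferroni(alpha: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted threshold alpha / n."""
    if n_comparisons < 1:
        raise StatsError(f"n_comparisons must be >= 1, got {n_comparisons}")
    if not 0 < alpha <= 1:
        raise StatsError(f"alpha must be in (0, 1], got {alpha}")
    return alpha / n_comparisons


def median_p(p_values: Sequence[float | None]) -> float:
    """Median p-value across repeat experiments; missing entries (None/NaN,
    e.g. a day on which the test was not available) are dropped.  NaN when
    nothing remains."""
    vals = np.asarray(
        [p for p in p_values if p is not None], dtype=float
    )
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(np.median(vals))


def molar_from_mass(mass_conc_mg_per_l: float, formula_weight: float) -> float:
    """Convert mg/L to µM given the formula weight in g/mol
    (e.g. 160 mg/L tricaine at 261.3 g/mol -> 612 µM)."""
    if mass_conc_mg_per_l <= 0 or formula_weight <= 0:
        raise StatsError("mass concentration and formula weight must be > 0")
    return 1000.0 * mass_conc_mg_per_l / formula_weight


def compare_groups(
    scores: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]],
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Chi-squared contrasts of treatment groups against their controls.

    ``scores`` must carry a 'group' column (see scoring.assign_groups).
    Each (treatment, control) contrast is tested on activity quartile counts
    and — over larvae with a valid E-O — on E-O tercile counts.
    ``n_comparisons`` defaults to the number of contrasts.  Output rows:
    contrast, metric, n_treatment, n_control, chi2, dof, p,
    bonferroni_alpha_05, significant.
    """
    if "group" not in scores.columns:
        raise StatsError("scores must carry a 'group' column")
    n_cmp = n_comparisons or max(len(contrasts), 1)
    rows = []
    for treat, ctrl in contrasts:
        for metric, scheme, valid_only in (
            ("activity", "activity_quartiles", False),
            ("eo", "eo_terciles", True),
        ):
            col = "activity_pct" if metric == "activity" else "eo"
            sub_t = scores[scores["group"] == treat]
            sub_c = scores[scores["group"] == ctrl]
            if valid_only:
                sub_t = sub_t[sub_t["eo_valid"]]
                sub_c = sub_c[sub_c["eo_valid"]]
            row = {
                "contrast": f"{treat} vs {ctrl}",
                "metric": metric,
                "n_treatment": len(sub_t),
                "n_control": len(sub_c),
            }
            try:
                cmp = chi2_homogeneity(
                    bin_scores(sub_t[col], scheme),
                    bin_scores(sub_c[col], scheme),
                    n_comparisons=n_cmp,
                )
                row.update(
                    chi2=cmp.chi2, dof=cmp.dof, p=cmp.p,
                    bonferroni_alpha_05=cmp.bonferroni_alpha(0.05),
                    significant=cmp.significant_at,
                )
            except StatsError as exc:
                log.warning("contrast %s (%s) not testable: %s", row["contrast"], metric, exc)
                row.update(
                    chi2=np.nan, dof=0, p=np.nan,
                    bonferroni_alpha_05=bonferroni(0.05, n_cmp), significant="",
                )
            rows.append(row)
    return pd.DataFrame(rows)


def experiment_set_summary(
    p_values_per_contrast: Mapping[str, Sequence[float | None]],
) -> pd.DataFrame:
    """Median-p summary over repeat experiments, one row per contrast."""
    rows = []
    for contrast, ps in p_values_per_contrast.items():
        finite = [p for p in ps if p is not None and np.isfinite(p)]
        rows.append(
            {
                "contrast": contrast,
                "n_experiments": len(finite),
                "median_p": median_p(ps),
            }
        )
    return pd.DataFrame(rows)
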