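"""Group-specific differential expression from RNA-seq gene counts.

The analysis contrasts four sample cohorts (benign breast lesions and ER+,
triple-negative, and HER2-positive tumors).  Counts are mode-normalized,
low-expression genes are removed by a per-group median threshold, and each
gene is tested with all-pairwise Dunnett-Tukey-Kramer (DTK) comparisons —
a studentized-range procedure with Welch-type degrees of freedom that is
valid under unequal variances and unequal sample sizes.  A gene is called
group-specific when the target group's mean log2(count+1) differs from every
other group at the chosen alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("benign", "ER+", "TN", "HER2")

#: genes must exceed this many reads (per-group median) in at least one group
LOW_EXPRESSION_THRESHOLD = 16


class NormalizationError(ValueError):
    """A sample cannot be normalized (e.g. all counts zero)."""


@dataclass
class NormalizedMatrix:
    """Mode-normalized expression values.

    values
        genes x samples DataFrame of normalized (linear-scale) abundances.
    scale_factors
        per-sample positive scale factor; ``values = raw / factor``.
    """

    values: pd.DataFrame
    scale_factors: pd.Series
    log_base: int = 2
    offset: int = 1

    def log_values(self) -> pd.DataFrame:
        """log2(value + 1), the scale on which group means are compared."""
        return np.log2(self.values + self.offset)


@dataclass
class DTKResult:
    """All-pairwise DTK comparison results for one feature.

    ``pairs`` maps (group_i, group_j) to a dict with keys
    diff, se, df, q_stat, p, ci_low, ci_high.  p is symmetric under pair
    swap; diff is mean(i) - mean(j).
    """

    pairs: dict[tuple[str, str], dict[str, float]]
    k: int
    alpha: float
    group_means: dict[str, float] = field(default_factory=dict)

    def p_value(self, a: str, b: str) -> float:
        if (a, b) in self.pairs:
            return self.pairs[(a, b)]["p"]
        return self.pairs[(b, a)]["p"]

    def diff(self, a: str, b: str) -> float:
        if (a, b) in self.pairs:
            return self.pairs[(a, b)]["diff"]
        return -self.pairs[(b, a)]["diff"]


def mode_normalize(counts: pd.DataFrame, reference: str = "pseudo") -> NormalizedMatrix:
    """Scale samples so the modal log2 ratio to a reference is zero.

    The per-sample factor is 2**mode where the mode is the kernel-density
    argmax (Gaussian KDE, Silverman bandwidth) of log2(sample/reference)
    over genes nonzero in both.  The reference is the per-gene geometric
    mean across samples (``reference="pseudo"``) or a named sample column.

    Most genes in a cohort are not perturbed, so the mode of the ratio
    distribution estimates the technical scale difference while ignoring
    the differentially expressed tail.
    """
    counts = counts.astype(float)
    zero_samples = counts.columns[(counts <= 0).all(axis=0)]
    if len(zero_samples):
        raise NormalizationError(
            f"sample(s) with all-zero counts cannot be normalized: {list(zero_samples)}"
        )
    if reference == "pseudo":
        logref = np.log2(counts.where(counts > 0)).mean(axis=1, skipna=True)
        ref = np.exp2(logref)
    else:
        if reference not in counts.columns:
            raise KeyError(f"reference sample {reference!r} not in matrix")
        ref = counts[reference]

    factors = {}
    for sample in counts.columns:
        both = (counts[sample] > 0) & (ref > 0)
        ratios = np.log2(counts.loc[both, sample] / ref[both]).to_numpy()
        if ratios.size < 2 or np.allclose(ratios, ratios[0]):
            factors[sample] = float(np.exp2(ratios[0])) if ratios.size else 1.0
            continue
        kde = stats.gaussian_kde(ratios, bw_method="silverman")
        grid = np.linspace(ratios.min(), ratios.max(), 512)
        factors[sample] = float(np.exp2(grid[np.argmax(kde(grid))]))

    scale = pd.Series(factors, name="scale_factor")
    return NormalizedMatrix(values=counts / scale, scale_factors=scale)


def filter_low_expression(
    counts: pd.DataFrame,
    groups: pd.Series,
    threshold: float = LOW_EXPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Keep genes whose per-group median count is strictly > ``threshold``
    in at least one group; everything else is below the detection limit."""
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    group_medians = counts.T.groupby(groups).median().T
    keep = (group_medians > threshold).any(axis=1)
    return counts.loc[keep]


def _welch_df(s2i: float, ni: int, s2j: float, nj: int) -> float:
    num = (s2i / ni + s2j / nj) ** 2
    den = (s2i / ni) ** 2 / (ni - 1) + (s2j / nj) ** 2 / (nj - 1)
    if den == 0:
        return float(ni + nj - 2)
    return num / den


def dtk_pairwise(
    values: dict[str, np.ndarray],
    alpha: float = 0.05,
    equal_var: bool = False,
    compute_ci: bool = True,
) -> DTKResult:
    """All-pairwise Dunnett-Tukey-Kramer comparisons of k group means.

    For each pair (i, j): se = sqrt(s_i^2/n_i + s_j^2/n_j), Welch-
    Satterthwaite degrees of freedom, q = sqrt(2)|m_i - m_j|/se, and the
    p-value is the upper tail of the studentized range with k groups.  The
    confidence half-width is q(alpha, k, df)/sqrt(2) * se.

    With ``equal_var=True`` the classical Tukey-Kramer special case is used
    instead: a pooled variance with df = N - k.

    Zero variance in both groups is degenerate for the studentized-range
    statistic; by convention equal means give p = 1 and unequal means p = 0.

    ``compute_ci=False`` skips the studentized-range quantile (the slowest
    part, needed only for intervals) and reports NaN CI bounds; genome-wide
    screens use this since calling is driven by the p-values alone.
    """
    names = list(values.keys())
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    arrs = {g: np.asarray(values[g], dtype=float) for g in names}
    for g, a in arrs.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    means = {g: a.mean() for g, a in arrs.items()}
    variances = {g: a.var(ddof=1) for g, a in arrs.items()}
    sizes = {g: a.size for g, a in arrs.items()}

    if equal_var:
        n_total = sum(sizes.values())
        pooled = sum(variances[g] * (sizes[g] - 1) for g in names) / (n_total - k)
        df_pooled = float(n_total - k)

    pairs: dict[tuple[str, str], dict[str, float]] = {}
    for gi, gj in itertools.combinations(names, 2):
        diff = means[gi] - means[gj]
        if equal_var:
            se = np.sqrt(pooled * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            df = df_pooled
        else:
            se = np.sqrt(variances[gi] / sizes[gi] + variances[gj] / sizes[gj])
            df = _welch_df(variances[gi], sizes[gi], variances[gj], sizes[gj])
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
            q_stat = 0.0 if diff == 0 else np.inf
            half = 0.0
        else:
            q_stat = np.sqrt(2.0) * abs(diff) / se
            p = float(stats.studentized_range.sf(q_stat, k, df))
            if compute_ci:
                q_crit = stats.studentized_range.ppf(1.0 - alpha, k, df)
                half = q_crit / np.sqrt(2.0) * se
            else:
                half = np.nan
        pairs[(gi, gj)] = {
            "diff": float(diff),
            "se": float(se),
            "df": float(df),
            "q_stat": float(q_stat),
            "p": min(max(p, 0.0), 1.0),
            "ci_low": float(diff - half),
            "ci_high": float(diff + half),
        }
    return DTKResult(pairs=pairs, k=k, alpha=alpha, group_means=means)


def call_group_specific(
    dtk_by_feature: dict[str, DTKResult],
    target_group: str = "HER2",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag features whose target-group mean differs from every other group.

    A feature is called iff all (k-1) target-vs-other DTK p-values are
    < alpha.  Direction is the sign of target mean minus the pooled mean of
    the other groups.  Returns a DataFrame indexed by feature with columns
    is_DE, direction, p_max and the individual pairwise p-values.
    """
    records = {}
    for feat, res in dtk_by_feature.items():
        others = [g for g in res.group_means if g != target_group]
        if not others:
            raise ValueError(f"target group {target_group!r} missing for {feat!r}")
        try:
            ps = {g: res.p_value(target_group, g) for g in others}
        except KeyError as exc:
            raise ValueError(f"missing pair for feature {feat!r}") from exc
        p_max = max(ps.values())
        pooled_other = float(np.mean([res.group_means[g] for g in others]))
        direction = int(np.sign(res.group_means[target_group] - pooled_other))
        rec = {"is_DE": p_max < alpha, "direction": direction, "p_max": p_max}
        rec.update({f"p_vs_{g}": p for g, p in ps.items()})
        records[feat] = rec
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "feature"
    return table


def differential_expression(
    counts: pd.DataFrame,
    groups: pd.Series,
    target_group: str = "HER2",
    alpha: float = 0.05,
    normalize: bool = True,
) -> pd.DataFrame:
    """Full expression pipeline: normalize, filter, DTK, group-specific call.

    ``counts`` is genes x samples (raw integers); ``groups`` maps sample to
    cohort label.  Returns the call table of :func:`call_group_specific`
    restricted to the expressed genes.
    """
    filtered = filter_low_expression(counts, groups)
    if normalize:
        norm = mode_normalize(filtered)
        logvals = norm.log_values()
    else:
        logvals = np.log2(filtered + 1)
    groups = groups.reindex(logvals.columns)
    sample_sets = {g: logvals.columns[groups == g] for g in groups.unique()}
    results = {}
    for gene in logvals.index:
        row = logvals.loc[gene]
        results[gene] = dtk_pairwise(
            {g: row[cols].to_numpy() for g, cols in sample_sets.items()},
            alpha=alpha,
            compute_ci=False,
        )
    return call_group_specific(results, target_group=target_group, alpha=alpha)
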