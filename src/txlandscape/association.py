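"""Linking network genes to drug response and clinical outcome.

Two association layers:

* drug response — Spearman rank correlation between a gene's expression and
  EC50 across cell lines (rank-based, so correlating against log EC50 is
  equivalent), with a Monte-Carlo random-panel simulation to judge whether a
  cluster of correlated genes sharing one biological process could arise by
  chance;
* time-to-event — a univariable Cox proportional-hazards score statistic
  per gene (partial-likelihood score test at beta = 0, Breslow tie
  handling), aggregated over gene sets with the maxmean statistic of gene
  set analysis (GSA): per set, the mean positive part and mean negative
  part of the gene scores compete and the larger magnitude wins; inference
  is by permutation of the patient outcome vector with restandardization
  of each permuted score catalog.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Spearman vs drug response


def p_from_spearman_rho(rho: float, n: int) -> float:
    """Two-sided p for a Spearman coefficient via the t approximation:
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom."""
    if not -1.0 < rho < 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman_vs_response(
    expr: np.ndarray, ec50: np.ndarray, exact: bool = False
) -> tuple[float, float]:
    """Spearman rank correlation of one gene's expression against EC50.

    Midranks handle ties; p is two-sided from the t approximation, or by
    exhaustive permutation when ``exact`` (n <= 8 only).  Constant input is
    an error — the correlation is undefined.
    """
    expr = np.asarray(expr, dtype=float)
    ec50 = np.asarray(ec50, dtype=float)
    if expr.size != ec50.size or expr.size < 5:
        raise ValueError("need >=5 paired observations")
    if np.ptp(expr) == 0 or np.ptp(ec50) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rx = stats.rankdata(expr)
    ry = stats.rankdata(ec50)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if expr.size > 8:
            raise ValueError("exact permutation p limited to n <= 8")
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    return rho, p_from_spearman_rho(rho, expr.size)


def correlate_panel(
    expr: pd.DataFrame, ec50: pd.Series, genes: set[str] | None = None
) -> pd.DataFrame:
    """Per-gene Spearman correlation against EC50 over shared cell lines."""
    lines = expr.columns.intersection(ec50.index)
    rows = []
    for gene in expr.index if genes is None else expr.index.intersection(sorted(genes)):
        x = expr.loc[gene, lines].to_numpy()
        if np.ptp(x) == 0:
            continue
        rho, p = spearman_vs_response(x, ec50[lines].to_numpy())
        rows.append({"gene": gene, "rho": rho, "p": p})
    return pd.DataFrame(rows, columns=["gene", "rho", "p"]).set_index("gene")


def random_panel_simulation(
    expr: pd.DataFrame,
    response: pd.Series,
    annotation: dict[str, set[str]],
    panel_size: int = 244,
    n_sims: int = 1000,
    min_shared: int = 6,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> float:
    """Probability that a random gene panel shows the observed clustering.

    Per simulation: draw ``panel_size`` genes at random, correlate each
    against the response, and count the largest number of significant
    (p < alpha) genes that share a single annotation term.  Returns the
    empirical probability that this count reaches ``min_shared``.
    """
    if panel_size > len(expr.index):
        raise ValueError("panel_size exceeds expression universe")
    rng = np.random.default_rng(seed)
    genes = np.asarray(expr.index)
    hits = 0
    for _ in range(n_sims):
        panel = rng.choice(genes, size=panel_size, replace=False)
        corr = correlate_panel(expr.loc[panel], response)
        sig = set(corr.index[corr["p"] < alpha])
        best = 0
        term_counts: dict[str, int] = {}
        for g in sig:
            for term in annotation.get(g, ()):
                term_counts[term] = term_counts.get(term, 0) + 1
        if term_counts:
            best = max(term_counts.values())
        hits += best >= min_shared
    return hits / n_sims


# ---------------------------------------------------------------------------
# Cox score statistic


def cox_score(
    expr: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float | np.ndarray:
    """Univariable Cox partial-likelihood score test statistic at beta = 0.

    U/sqrt(I) with Breslow handling of tied event times (every tied event
    uses the full risk set).  Positive values mean higher expression goes
    with higher hazard.  ``expr`` may be one gene (1-D over samples) or a
    genes x samples matrix, in which case a vector of statistics returns.
    """
    orig_ndim = np.asarray(expr).ndim
    expr = np.atleast_2d(np.asarray(expr, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events: Cox score undefined")
    order = np.argsort(time, kind="stable")
    t_s, e_s, x_s = time[order], event[order], expr[:, order]
    n = t_s.size
    # suffix sums over the risk set {l: t_l >= t_j}
    s1 = np.cumsum(x_s[:, ::-1], axis=1)[:, ::-1]
    s2 = np.cumsum((x_s**2)[:, ::-1], axis=1)[:, ::-1]
    U = np.zeros(expr.shape[0])
    I = np.zeros(expr.shape[0])
    j = 0
    while j < n:
        k = j
        while k < n and t_s[k] == t_s[j]:
            k += 1
        d_idx = [i for i in range(j, k) if e_s[i]]
        d = len(d_idx)
        if d:
            n_risk = n - j
            xbar = s1[:, j] / n_risk
            U += x_s[:, d_idx].sum(axis=1) - d * xbar
            I += d * (s2[:, j] / n_risk - xbar**2)
        j = k
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(I > 0, U / np.sqrt(np.maximum(I, 1e-300)), 0.0)
    return float(z[0]) if orig_ndim == 1 else z


# ---------------------------------------------------------------------------
# maxmean gene set analysis


@dataclass
class GeneSetResult:
    name: str
    score: float
    p: float
    fdr: float
    direction: str
    n_genes: int


def _maxmean(scores: np.ndarray) -> float:
    s_pos = np.maximum(scores, 0.0).mean()
    s_neg = np.maximum(-scores, 0.0).mean()
    return float(s_pos if s_pos >= s_neg else -s_neg)


def _restandardize(scores: np.ndarray) -> np.ndarray:
    sd = scores.std(ddof=0)
    if sd == 0:
        return scores - scores.mean()
    return (scores - scores.mean()) / sd


def gsa_maxmean(
    gene_scores: pd.Series,
    gene_sets: dict[str, set[str]],
    score_fn=None,
    n_perms: int = 1000,
    seed: int | np.random.Generator = 0,
    min_set_size: int = 2,
) -> list[GeneSetResult]:
    """Maxmean gene-set analysis with permutation inference.

    ``gene_scores`` are the observed per-gene statistics.  ``score_fn``,
    when given, is called with a permutation RNG and must return a
    recomputed score Series under one relabeling of the outcome (the
    permutation unit is the patient outcome vector, propagated through the
    per-gene score); otherwise gene labels themselves are permuted, which
    is only appropriate for independent gene scores.  Each score catalog —
    observed and permuted — is restandardized (centered and scaled by the
    catalog mean and sd) before the maxmean statistic is formed, so shifts
    of the whole score distribution under relabeling do not masquerade as
    set-level signal.  p-values are two-sided permutation tails; FDR is the
    permutation-based plug-in estimate.  Sets with fewer than
    ``min_set_size`` scored genes are skipped.
    """
    import warnings

    rng = np.random.default_rng(seed)
    genes = gene_scores.index
    obs_std = pd.Series(_restandardize(gene_scores.to_numpy(dtype=float)), index=genes)

    members: dict[str, list[str]] = {}
    for name, gs in gene_sets.items():
        hit = [g for g in gs if g in obs_std.index]
        if len(hit) < min_set_size:
            warnings.warn(f"gene set {name!r} has <{min_set_size} scored genes; skipped")
            continue
        members[name] = hit
    if not members:
        return []

    names = list(members)
    obs_stat = np.array([_maxmean(obs_std[members[nm]].to_numpy()) for nm in names])

    perm_stats = np.empty((n_perms, len(names)))
    for b in range(n_perms):
        if score_fn is not None:
            perm_scores = score_fn(rng)
            perm_scores = perm_scores.reindex(genes)
        else:
            perm_scores = pd.Series(
                rng.permutation(gene_scores.to_numpy(dtype=float)), index=genes
            )
        perm_std = pd.Series(_restandardize(perm_scores.to_numpy(dtype=float)), index=genes)
        for i, nm in enumerate(names):
            perm_stats[b, i] = _maxmean(perm_std[members[nm]].to_numpy())

    results = []
    abs_obs = np.abs(obs_stat)
    abs_perm = np.abs(perm_stats)
    for i, nm in enumerate(names):
        p = (1.0 + np.sum(abs_perm[:, i] >= abs_obs[i])) / (n_perms + 1.0)
        # permutation plug-in FDR: expected false positives at this
        # threshold over observed positives
        expected = np.mean(np.sum(abs_perm >= abs_obs[i], axis=1))
        observed = np.sum(abs_obs >= abs_obs[i])
        fdr = min(1.0, expected / observed) if observed else 1.0
        results.append(
            GeneSetResult(
                name=nm,
                score=float(obs_stat[i]),
                p=float(p),
                fdr=float(fdr),
                direction="positive" if obs_stat[i] >= 0 else "negative",
                n_genes=len(members[nm]),
            )
        )
    return results


def gsa_survival(
    expr: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    gene_sets: dict[str, set[str]],
    n_perms: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[GeneSetResult]:
    """Maxmean GSA of gene sets against time-to-event outcome.

    Gene scores are the negated Cox score statistics, so a negative set
    score indicates association with increased risk of relapse and a
    positive one with decreased risk (the published sign convention).
    Permutations shuffle the (time, event) outcome vector across patients
    and propagate through the Cox scores.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = expr.to_numpy(dtype=float)
    observed = pd.Series(-np.atleast_1d(cox_score(X, time, event)), index=expr.index)

    def score_fn(rng: np.random.Generator) -> pd.Series:
        perm = rng.permutation(time.size)
        return pd.Series(
            -np.atleast_1d(cox_score(X, time[perm], event[perm])), index=expr.index
        )

    return gsa_maxmean(
        observed, gene_sets, score_fn=score_fn, n_perms=n_perms, seed=seed
    )
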