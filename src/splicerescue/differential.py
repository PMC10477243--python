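"""Differential splicing and expression tests with knockdown-rescue meta-analysis.

The per-event splicing test is a negative-binomial interaction GLM standing
in for a DESeq2-style spliced:unspliced ratio test: counts y (spliced and
unspliced across replicates of two conditions) are modelled with a log link,

    log mu = b0 + b1*read_class + b2*condition + b3*read_class*condition,

with fixed per-event dispersion (method of moments, floored). The
interaction b3 is the change in log spliced:unspliced odds between
conditions; significance comes from the likelihood-ratio test of b3. Because
the dispersion is estimated from the same few replicates, the LR statistic
is referred to an F(1, d) distribution with d the residual degrees of
freedom behind the dispersion estimate (quasi-likelihood small-sample
correction) rather than to chi-square; with many replicates the two
coincide. The full model is saturated in the four cell means, so only the
reduced model needs the IRLS fit.

Evidence from the knockdown-vs-control and rescue-vs-knockdown comparisons
is combined with Fisher's method, and an event among the most significant
is called rescued when its rescue-comparison change is significant and
opposite in sign to the knockdown change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DISPERSION_FLOOR",
    "nb_ratio_test",
    "gene_de_test",
    "size_factors",
    "bh_adjust",
    "meta_p",
    "classify_rescue",
    "ir_difftest",
    "RescueSummary",
]

DISPERSION_FLOOR = 1e-8
_LN2 = float(np.log(2.0))
_MU_FLOOR = 1e-8


def _nb_loglik(y, mu, alpha):
    """NB log-likelihood with Var = mu + alpha*mu^2 at fixed alpha."""
    mu = np.maximum(mu, _MU_FLOOR)
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _moment_dispersion(cells) -> float:
    """Pooled method-of-moments NB dispersion across condition/class cells."""
    num = 0.0
    den = 0.0
    for y in cells:
        y = np.asarray(y, dtype=float)
        if len(y) < 2:
            continue
        m = y.mean()
        if m <= 0:
            continue
        v = y.var(ddof=1)
        w = len(y) - 1
        num += w * (v - m)
        den += w * m * m
    if den == 0:
        return DISPERSION_FLOOR
    return max(num / den, DISPERSION_FLOOR)


def _irls_nb(y, X, alpha, offset=None, max_iter=100, tol=1e-8):
    """IRLS for an NB GLM with log link and fixed dispersion.

    Returns (beta, mu, converged). Convergence on relative deviance change.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if offset is None:
        offset = np.zeros(len(y))
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), _MU_FLOOR)) - offset.mean()
    prev_ll = -np.inf
    mu = np.exp(X @ beta + offset)
    for _ in range(max_iter):
        mu = np.clip(mu, _MU_FLOOR, 1e12)
        w = mu / (1.0 + alpha * mu)
        eta = X @ beta + offset
        z = eta + (y - mu) / mu - offset
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        mu = np.exp(np.clip(X @ beta + offset, -50, 50))
        ll = _nb_loglik(y, mu, alpha)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0):
            return beta, mu, True
        prev_ll = ll
    return beta, mu, False


def nb_ratio_test(
    spliced_a, unspliced_a, spliced_b, unspliced_b
) -> tuple[float, float]:
    """Interaction LRT for a change in spliced:unspliced odds between conditions.

    Returns (log2_effect, p_value); log2_effect > 0 means higher
    spliced:unspliced odds in condition b. All-zero events are untestable
    and return (0.0, 1.0).
    """
    cells = [
        np.asarray(v, dtype=float)
        for v in (unspliced_a, spliced_a, unspliced_b, spliced_b)
    ]
    if any(len(c) < 2 for c in cells):
        raise ValueError("need >= 2 replicates per condition")
    if all(np.all(c == 0) for c in cells):
        return 0.0, 1.0

    alpha = _moment_dispersion(cells)
    y = np.concatenate(cells)
    n_rep = [len(c) for c in cells]
    read_class = np.concatenate(
        [np.full(n, k % 2) for k, n in enumerate(n_rep)]
    ).astype(float)
    condition = np.concatenate(
        [np.full(n, k // 2) for k, n in enumerate(n_rep)]
    ).astype(float)

    # full model is saturated in the 4 cells: MLE means are the cell means
    mu_full = np.concatenate(
        [np.full(len(c), max(c.mean(), _MU_FLOOR)) for c in cells]
    )
    ll_full = _nb_loglik(y, mu_full, alpha)

    X_reduced = np.column_stack([np.ones_like(y), read_class, condition])
    _, mu_reduced, _ = _irls_nb(y, X_reduced, alpha, tol=1e-12)
    ll_reduced = _nb_loglik(y, mu_reduced, alpha)

    stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    if stat < 1e-8:  # numerically zero: the reduced model fits exactly
        stat = 0.0
    df_resid = sum(len(c) - 1 for c in cells)
    p = float(stats.f.sf(stat, 1, df_resid))

    # interaction coefficient from saturated cell means (log odds change)
    m = [max(c.mean(), _MU_FLOOR) for c in cells]
    log_effect = (np.log(m[3]) - np.log(m[2])) - (np.log(m[1]) - np.log(m[0]))
    return float(log_effect / _LN2), p


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Genes with a zero count in any sample are excluded from the reference
    (DESeq convention); at least one all-positive gene is required.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be a 2-D gene x sample matrix")
    positive = np.all(mat > 0, axis=1)
    if not np.any(positive):
        raise ValueError("no gene expressed in all samples; size factors undefined")
    logs = np.log(mat[positive])
    log_ref = logs.mean(axis=1)
    log_sf = np.median(logs - log_ref[:, None], axis=0)
    log_sf = log_sf - log_sf.mean()
    return np.exp(log_sf)


def gene_de_test(counts: pd.DataFrame, condition_labels) -> pd.DataFrame:
    """Size-factor-normalised NB Wald test per gene between two conditions.

    ``counts`` is a gene x sample frame (or array) of raw counts and
    ``condition_labels`` assigns each column to one of exactly two groups.
    Returns a frame with gene_id, log2_effect, p_value, padj.
    """
    labels = np.asarray(condition_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two conditions required")
    for g in groups:
        if np.sum(labels == g) < 2:
            raise ValueError("need >= 2 replicates per condition")
    mat = np.asarray(counts, dtype=float)
    gene_ids = (
        list(counts.index)
        if isinstance(counts, pd.DataFrame)
        else [f"g{i}" for i in range(mat.shape[0])]
    )
    sf = size_factors(mat)
    offset = np.log(sf)
    design = np.column_stack(
        [np.ones(mat.shape[1]), (labels == groups[1]).astype(float)]
    )
    norm = mat / sf

    rows = []
    for gid, y, ynorm in zip(gene_ids, mat, norm):
        if np.all(y == 0):
            rows.append((gid, 0.0, 1.0))
            continue
        alpha = _moment_dispersion(
            [ynorm[labels == g] for g in groups]
        )
        beta, mu, _ = _irls_nb(y, design, alpha, offset=offset)
        w = mu / (1.0 + alpha * mu)
        info = design.T @ (design * w[:, None])
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(max(cov[1, 1], 0.0))
        except np.linalg.LinAlgError:
            se = np.inf
        wald = beta[1] / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(wald)))
        rows.append((gid, float(beta[1] / _LN2), p))
    out = pd.DataFrame(rows, columns=["gene_id", "log2_effect", "p_value"])
    out["padj"] = bh_adjust(out["p_value"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meta_p(p1, p2) -> np.ndarray | float:
    """Fisher's method across the two comparisons: chi-square with 4 df.

    Zero p-values are clamped to the smallest positive float.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    x = -2.0 * (np.log(np.maximum(p1, tiny)) + np.log(np.maximum(p2, tiny)))
    out = stats.chi2.sf(x, df=4)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RescueSummary:
    n_events: int
    top_n: int
    n_significant: int
    n_rescued: int
    n_down: int
    n_up: int

    @property
    def frac_rescued(self) -> float:
        return self.n_rescued / self.top_n if self.top_n else float("nan")

    @property
    def frac_down(self) -> float:
        return self.n_down / self.n_significant if self.n_significant else float("nan")

    @property
    def frac_up(self) -> float:
        return self.n_up / self.n_significant if self.n_significant else float("nan")


def classify_rescue(
    results_kd: pd.DataFrame,
    results_rescue: pd.DataFrame,
    top_n: int = 1000,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, RescueSummary]:
    """Rank events by meta-p and call rescue/directionality among the top.

    Both frames need columns event_id, log2_effect, p_value, padj and the
    same event set. Events are ranked by Fisher meta-p of the two
    comparisons (ties by |knockdown effect| descending, then event_id).
    Among the ``top_n``, an event is *rescued* when its knockdown change is
    significant (padj < alpha), its rescue-comparison change is significant,
    and the two effects have opposite signs; *direction* is the sign of the
    knockdown effect for significant events.
    """
    kd = results_kd.set_index("event_id")
    rescue = results_rescue.set_index("event_id")
    missing = kd.index.symmetric_difference(rescue.index)
    if len(missing):
        raise ValueError(
            f"unmatched event ids between comparisons: {sorted(missing)[:10]}"
        )
    if top_n > len(kd):
        raise ValueError("top_n exceeds the number of events")
    rescue = rescue.loc[kd.index]

    table = pd.DataFrame(
        {
            "event_id": kd.index,
            "kd_log2_effect": kd["log2_effect"].to_numpy(),
            "kd_padj": kd["padj"].to_numpy(),
            "rescue_log2_effect": rescue["log2_effect"].to_numpy(),
            "rescue_padj": rescue["padj"].to_numpy(),
            "meta_p": meta_p(kd["p_value"].to_numpy(), rescue["p_value"].to_numpy()),
        }
    )
    table = table.sort_values(
        by=["meta_p", "kd_log2_effect", "event_id"],
        ascending=[True, True, True],
        key=lambda col: -col.abs() if col.name == "kd_log2_effect" else col,
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["in_top"] = table["rank"] <= top_n
    table["significant"] = table["kd_padj"] < alpha
    opposite = np.sign(table["rescue_log2_effect"]) == -np.sign(
        table["kd_log2_effect"]
    )
    table["rescued"] = (
        table["in_top"]
        & table["significant"]
        & (table["rescue_padj"] < alpha)
        & opposite
    )
    table["direction"] = np.where(
        table["significant"],
        np.where(table["kd_log2_effect"] < 0, "down", "up"),
        "",
    )

    top = table[table["in_top"]]
    sig = top[top["significant"]]
    summary = RescueSummary(
        n_events=len(table),
        top_n=top_n,
        n_significant=len(sig),
        n_rescued=int(top["rescued"].sum()),
        n_down=int((sig["direction"] == "down").sum()),
        n_up=int((sig["direction"] == "up").sum()),
    )
    return table, summary


def ir_difftest(
    counts: pd.DataFrame, condition_a: str, condition_b: str
) -> pd.DataFrame:
    """Run nb_ratio_test for every event in a long count table.

    ``counts`` has columns event_id, condition, replicate, spliced,
    unspliced. Returns event_id, log2_effect, p_value, padj (BH across
    events), with effects oriented condition_a -> condition_b.
    """
    required = {"event_id", "condition", "spliced", "unspliced"}
    if not required.issubset(counts.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    rows = []
    for event_id, group in counts.groupby("event_id", sort=True):
        sub_a = group[group["condition"] == condition_a]
        sub_b = group[group["condition"] == condition_b]
        effect, p = nb_ratio_test(
            sub_a["spliced"].to_numpy(),
            sub_a["unspliced"].to_numpy(),
            sub_b["spliced"].to_numpy(),
            sub_b["unspliced"].to_numpy(),
        )
        rows.append((event_id, effect, p))
    out = pd.DataFrame(rows, columns=["event_id", "log2_effect", "p_value"])
    out["padj"] = bh_adjust(out["p_value"].to_numpy())
    return out
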