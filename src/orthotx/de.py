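"""Two-factor negative-binomial differential expression.

The model
---------
Counts ``K_ij`` for feature i in sample j follow a negative binomial with
mean ``mu_ij = exp(x_j' beta_i + o_ij)`` and variance
``mu + alpha_i * mu^2``, where ``x_j`` encodes
``species + structure + species:structure`` (treatment coding, reference
levels species A and structure bud) and the offset
``o_ij = log(size_factor_j) + log(length_i / 1000)`` carries library-size
and transcript-length normalization (miRNA features omit the length term).

Per feature the dispersion ``alpha_i`` is estimated by Cox-Reid-adjusted
profile likelihood on a grid and shrunk toward a mean-dispersion trend.
Two significance engines share the fitted models:

* engine "lrt": likelihood-ratio test of the interaction (full vs reduced
  model, 2 df) and Wald tests for the 7 pairwise contrasts;
* engine "ql": quasi-likelihood F-tests using a moderated per-feature
  quasi-dispersion (deviance / residual df, squeezed toward its trend).

A feature is called only when BOTH engines reach adjusted p <= alpha and
the |log2 fold change| exceeds the threshold — the consensus analogue of
intersecting two independent DE programs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .design import build_design_matrices, contrast_vectors, FULL_COLUMNS
from .simulate import CountExperiment

__all__ = [
    "normalize_counts",
    "filter_low_expression",
    "estimate_dispersion",
    "fit_nb_glm",
    "NBFit",
    "test_interaction",
    "test_contrasts",
    "ql_test_interaction",
    "ql_test_contrasts",
    "quasi_dispersion",
    "bh_adjust",
    "call_significant",
    "fisher_enrichment",
    "pca_profile",
    "run_de",
    "DEAnalysis",
]

log = logging.getLogger(__name__)

_MIN_ALPHA = 1e-8
_ETA_CLIP = 50.0


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------


@dataclass
class Normalization:
    size_factors: pd.Series          # per sample
    offsets: np.ndarray              # features x samples, natural log
    normalized: pd.DataFrame         # counts / (size factor * length/1000)


def normalize_counts(exp: CountExperiment) -> Normalization:
    """Median-of-ratios size factors plus per-kilobase length normalization.

    Size factors are the median, over features with all-positive counts, of
    each sample's ratio to the feature-wise geometric mean.  Normalized
    counts divide by ``size_factor * length/1000`` for transcripts and by
    the size factor alone for miRNAs; the same terms enter the GLM as
    log offsets.
    """
    counts = exp.counts.to_numpy(dtype=float)
    empty_samples = exp.counts.columns[counts.sum(axis=0) == 0]
    if len(empty_samples):
        raise ValueError(
            f"sample(s) with all-zero counts: {list(empty_samples)}"
        )
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has nonzero counts in every sample; "
                         "cannot estimate size factors")
    log_geo = np.log(counts[positive]).mean(axis=1)
    ratios = np.log(counts[positive]) - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    size_factors = pd.Series(sf, index=exp.counts.columns, name="size_factor")
    if exp.feature_kind == "transcript":
        len_kb = exp.feature_lengths.to_numpy(dtype=float) / 1000.0
    else:
        len_kb = np.ones(exp.counts.shape[0])
    offsets = np.log(sf)[None, :] + np.log(len_kb)[:, None]
    normalized = pd.DataFrame(
        counts / (sf[None, :] * len_kb[:, None]),
        index=exp.counts.index, columns=exp.counts.columns,
    )
    return Normalization(size_factors, offsets, normalized)


def filter_low_expression(
    exp: CountExperiment,
    normalized: pd.DataFrame | None = None,
    threshold: float = 19.0,
    aggregate: str = "sum",
) -> CountExperiment:
    """Discard lowly expressed features.

    Transcripts are judged on length-normalized counts, miRNA groups on raw
    counts; a feature is discarded when the aggregate (default: sum across
    samples) is strictly below ``threshold``.
    """
    if aggregate not in ("sum", "mean", "max"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if exp.feature_kind == "transcript":
        if normalized is None:
            normalized = normalize_counts(exp).normalized
        basis = normalized
    else:
        basis = exp.counts
    agg = getattr(basis, aggregate)(axis=1)
    keep = agg.index[agg >= threshold]
    return exp.subset(keep)


# ---------------------------------------------------------------------------
# NB likelihood and vectorized IRLS fitting
# ---------------------------------------------------------------------------


def nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-feature NB log-likelihood summed over samples.

    ``alpha`` below 1e-6 switches to the Poisson limit with a first-order
    1/r correction, avoiding catastrophic cancellation in the gamma terms.
    """
    alpha = np.maximum(np.asarray(alpha, dtype=float), _MIN_ALPHA)
    mu = np.maximum(mu, 1e-12)
    out = np.empty(Y.shape[0])
    small = alpha < 1e-6
    if small.any():
        Ys, mus = Y[small], mu[small]
        r = 1.0 / alpha[small]
        pois = Ys * np.log(mus) - mus - gammaln(Ys + 1.0)
        corr = (Ys * (Ys - 1.0) / 2.0 - Ys * mus + mus**2 / 2.0) / r[:, None]
        out[small] = (pois + corr).sum(axis=1)
    big = ~small
    if big.any():
        Yb, mub = Y[big], mu[big]
        r = (1.0 / alpha[big])[:, None]
        ll = (gammaln(Yb + r) - gammaln(r) - gammaln(Yb + 1.0)
              + r * np.log(r / (r + mub)) + Yb * np.log(mub / (r + mub)))
        out[big] = ll.sum(axis=1)
    return out


@dataclass
class NBFit:
    """Fitted NB GLMs for a block of features sharing one design."""

    design: pd.DataFrame                  # samples x P
    beta: np.ndarray                      # features x P, natural log
    mu: np.ndarray                        # features x samples
    loglik: np.ndarray                    # features
    deviance: np.ndarray                  # features
    alpha: np.ndarray                     # dispersions used
    offsets: np.ndarray                   # features x samples
    xtwx: np.ndarray                      # features x P x P at convergence
    converged: np.ndarray                 # bool per feature
    feature_ids: pd.Index


def fit_nb_glm(
    counts: pd.DataFrame | np.ndarray,
    design: pd.DataFrame,
    offsets: np.ndarray,
    alpha: np.ndarray | float,
    max_iter: int = 80,
    tol: float = 1e-8,
    beta_init: np.ndarray | None = None,
) -> NBFit:
    """Vectorized IRLS (Fisher scoring) for NB GLMs with log link.

    All features are iterated simultaneously; each step solves a batch of
    P x P weighted least-squares systems.  Convergence is declared when a
    feature's deviance changes by less than ``tol`` (relative, floored at
    ``tol`` absolute).
    """
    if isinstance(counts, pd.DataFrame):
        fids = counts.index
        Y = counts.to_numpy(dtype=float)
    else:
        Y = np.asarray(counts, dtype=float)
        fids = pd.RangeIndex(Y.shape[0])
    X = design.to_numpy(dtype=float)
    n, S = Y.shape
    P = X.shape[1]
    if np.linalg.matrix_rank(X) < P:
        raise ValueError("design matrix is rank deficient")
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (n,)).copy()
    alpha = np.maximum(alpha, _MIN_ALPHA)
    O = np.broadcast_to(offsets, (n, S))

    if beta_init is None:
        Z0 = np.log(Y + 0.5) - O
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ Z0.T).T
    else:
        beta = beta_init.copy()
    eta = np.clip(beta @ X.T + O, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = nb_loglik(Y, mu, alpha)
    active = np.ones(n, dtype=bool)
    converged = np.zeros(n, dtype=bool)
    eye = np.eye(P) * 1e-10
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        mu_a = mu[idx]
        W = mu_a / (1.0 + alpha[idx, None] * mu_a)
        z = (beta[idx] @ X.T) + (Y[idx] - mu_a) / mu_a
        WX = W[:, :, None] * X[None, :, :]
        A = np.einsum("nsp,sq->npq", WX, X) + eye
        b = np.einsum("ns,sp->np", W * z, X)
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        eta_new = np.clip(beta_new @ X.T + O[idx], -_ETA_CLIP, _ETA_CLIP)
        mu_new = np.exp(eta_new)
        ll_new = nb_loglik(Y[idx], mu_new, alpha[idx])
        # step-halving where the likelihood worsened
        worse = ll_new < ll[idx] - 1e-10
        tries = 0
        while worse.any() and tries < 10:
            beta_new[worse] = 0.5 * (beta_new[worse] + beta[idx][worse])
            eta_w = np.clip(beta_new[worse] @ X.T + O[idx][worse],
                            -_ETA_CLIP, _ETA_CLIP)
            mu_new[worse] = np.exp(eta_w)
            ll_new[worse] = nb_loglik(Y[idx][worse], mu_new[worse],
                                      alpha[idx][worse])
            worse = ll_new < ll[idx] - 1e-10
            tries += 1
        delta = np.abs(ll_new - ll[idx])
        done = delta < tol * (np.abs(ll_new) + 1.0)
        beta[idx] = beta_new
        mu[idx] = mu_new
        ll[idx] = ll_new
        converged[idx[done]] = True
        active[idx[done]] = False
    # saturated log-likelihood for the deviance
    ll_sat = nb_loglik(Y, np.maximum(Y, 1e-8), alpha)
    deviance = 2.0 * (ll_sat - ll)
    W = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("ns,sp,sq->npq", W, X, X)
    return NBFit(design=design, beta=beta, mu=mu, loglik=ll,
                 deviance=deviance, alpha=alpha, offsets=np.asarray(O),
                 xtwx=xtwx, converged=converged, feature_ids=fids)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    offsets: np.ndarray,
    prior_df: float = 10.0,
    grid: tuple[float, float, int] = (1e-8, 10.0, 25),
    n_bins: int = 8,
) -> pd.DataFrame:
    """Per-feature NB dispersions with trend shrinkage.

    For each grid dispersion the GLM is refitted (warm-started) and the
    Cox-Reid adjusted profile log-likelihood
    ``APL = loglik - 0.5 * logdet(X'WX)`` is recorded.  The per-feature
    maximizer (with quadratic interpolation in log-dispersion) is shrunk in
    log space toward a mean-dispersion trend, weighting the trend by
    ``prior_df`` against the residual degrees of freedom.

    Returns a DataFrame with columns ``alpha`` (final), ``alpha_mle`` and
    ``alpha_trend``.
    """
    Y = counts.to_numpy(dtype=float)
    n, S = Y.shape
    P = design.shape[1]
    resid_df = max(S - P, 1)
    alphas = np.logspace(np.log10(grid[0]), np.log10(grid[1]), grid[2])
    apl = np.empty((n, len(alphas)))
    beta = None
    for k, a in enumerate(alphas):
        fit = fit_nb_glm(counts, design, offsets, a, beta_init=beta)
        beta = fit.beta
        sign, logdet = np.linalg.slogdet(fit.xtwx)
        apl[:, k] = fit.loglik - 0.5 * logdet

    log_a = np.log(alphas)

    def _argmax_interp(curves: np.ndarray) -> np.ndarray:
        k = np.argmax(curves, axis=-1)
        k = np.clip(k, 1, len(alphas) - 2)
        y0 = np.take_along_axis(curves, (k - 1)[..., None], -1)[..., 0]
        y1 = np.take_along_axis(curves, k[..., None], -1)[..., 0]
        y2 = np.take_along_axis(curves, (k + 1)[..., None], -1)[..., 0]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12,
                         0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        step = log_a[1] - log_a[0]
        best = log_a[k] + shift * step
        # boundary maxima stay at the boundary
        kraw = np.argmax(curves, axis=-1)
        best = np.where(kraw == 0, log_a[0], best)
        best = np.where(kraw == len(alphas) - 1, log_a[-1], best)
        return best

    log_mle = _argmax_interp(apl)

    # mean-dispersion trend from binned common dispersions
    mean_norm = np.exp(np.log(Y + 0.5).mean(axis=1)
                       - offsets.mean(axis=1))
    if n >= 10 * n_bins:
        qs = np.quantile(mean_norm, np.linspace(0, 1, n_bins + 1))
        qs[-1] += 1.0
        which = np.clip(np.searchsorted(qs, mean_norm, side="right") - 1,
                        0, n_bins - 1)
        centers = []
        log_common = []
        for b in range(n_bins):
            mask = which == b
            if mask.sum() < 5:
                continue
            centers.append(np.log(mean_norm[mask]).mean())
            log_common.append(float(_argmax_interp(apl[mask].sum(axis=0))))
        if len(centers) >= 2:
            order = np.argsort(centers)
            log_trend = np.interp(np.log(mean_norm),
                                  np.array(centers)[order],
                                  np.array(log_common)[order])
        else:
            log_trend = np.full(n, float(_argmax_interp(apl.sum(axis=0))))
    else:
        log_trend = np.full(n, float(_argmax_interp(apl.sum(axis=0))))

    w = prior_df / (prior_df + resid_df)
    log_final = w * log_trend + (1.0 - w) * log_mle
    out = pd.DataFrame(
        {
            "alpha": np.maximum(np.exp(log_final), _MIN_ALPHA),
            "alpha_mle": np.maximum(np.exp(log_mle), _MIN_ALPHA),
            "alpha_trend": np.maximum(np.exp(log_trend), _MIN_ALPHA),
        },
        index=counts.index,
    )
    return out


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

_LN2 = np.log(2.0)


def test_interaction(fit_full: NBFit, fit_reduced: NBFit) -> pd.DataFrame:
    """Likelihood-ratio test of the species:structure interaction (2 df).

    Reports the two interaction contrasts on the log2 scale: how much the
    flower-bud and fruit-flower transitions differ between species.
    """
    df = fit_full.design.shape[1] - fit_reduced.design.shape[1]
    stat = np.maximum(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    # identical models (0 df) carry no evidence against the null
    p = stats.chi2.sf(stat, df) if df > 0 else np.ones_like(stat)
    ok = fit_full.converged & fit_reduced.converged
    p = np.where(ok, p, np.nan)
    i_fl = FULL_COLUMNS.index("species[B]:structure[flower]")
    i_fr = FULL_COLUMNS.index("species[B]:structure[fruit]")
    lfc_fl = fit_full.beta[:, i_fl] / _LN2
    lfc_fr = (fit_full.beta[:, i_fr] - fit_full.beta[:, i_fl]) / _LN2
    return pd.DataFrame(
        {
            "stat": stat,
            "df": df,
            "pvalue": p,
            "log2fc_int_flower_vs_bud": lfc_fl,
            "log2fc_int_fruit_vs_flower": lfc_fr,
        },
        index=fit_full.feature_ids,
    )


def _wald(fit: NBFit, cvec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cov = np.linalg.inv(fit.xtwx)
    est = fit.beta @ cvec
    var = np.einsum("p,npq,q->n", cvec, cov, cvec)
    se = np.sqrt(np.maximum(var, 1e-300))
    return est, se


def test_contrasts(fit_full: NBFit) -> dict[str, pd.DataFrame]:
    """Wald tests for the 7 pairwise contrasts of the comparison scheme."""
    out: dict[str, pd.DataFrame] = {}
    ok = fit_full.converged
    for name, cvec in contrast_vectors().items():
        est, se = _wald(fit_full, cvec)
        z = est / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.where(ok, p, np.nan)
        out[name] = pd.DataFrame(
            {"log2fc": est / _LN2, "stat": z, "pvalue": p},
            index=fit_full.feature_ids,
        )
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    from scipy.special import polygamma

    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def quasi_dispersion(
    fit_full: NBFit, prior_df: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes moderated quasi-dispersions.

    Per-feature quasi-dispersion is the full-model deviance over its
    residual df, squeezed toward the prior location with a prior df
    estimated by moment matching on the log scale (variance of log s^2
    against its chi-square expectation); pass ``prior_df`` to fix it
    instead.  Returns (posterior s^2, residual df, total denominator df).
    """
    from scipy.special import polygamma, psi

    S = fit_full.mu.shape[1]
    d = max(S - fit_full.design.shape[1], 1)
    s2 = np.maximum(fit_full.deviance / d, 1e-10)
    z = np.log(s2)
    if prior_df is None:
        if len(s2) >= 10:
            evar = float(np.var(z, ddof=1)) - float(polygamma(1, d / 2.0))
            if evar > 1e-8:
                prior_df = min(2.0 * _trigamma_inverse(evar), 1e6)
            else:
                prior_df = 1e6
        else:
            prior_df = 10.0
    if prior_df >= 1e6:
        s2_0 = float(np.exp(np.mean(z) - psi(d / 2.0) + np.log(d / 2.0)))
        s2_post = np.full_like(s2, s2_0)
        return s2_post, float(d), float(prior_df + d)
    s2_0 = float(
        np.exp(np.mean(z) - psi(d / 2.0) + np.log(d / 2.0)
               + psi(prior_df / 2.0) - np.log(prior_df / 2.0))
    )
    s2_post = (prior_df * s2_0 + d * s2) / (prior_df + d)
    return s2_post, float(d), float(prior_df + d)


def ql_test_interaction(
    fit_full: NBFit, fit_reduced: NBFit, prior_df: float | None = None
) -> pd.DataFrame:
    """Quasi-likelihood F-test of the interaction (2 numerator df)."""
    df_test = fit_full.design.shape[1] - fit_reduced.design.shape[1]
    s2_post, _, df_total = quasi_dispersion(fit_full, prior_df)
    num = np.maximum(fit_reduced.deviance - fit_full.deviance, 0.0) / df_test
    F = num / s2_post
    p = stats.f.sf(F, df_test, df_total)
    ok = fit_full.converged & fit_reduced.converged
    return pd.DataFrame(
        {"stat": F, "pvalue": np.where(ok, p, np.nan)},
        index=fit_full.feature_ids,
    )


def ql_test_contrasts(
    fit_full: NBFit, prior_df: float | None = None
) -> dict[str, pd.DataFrame]:
    """Quasi-likelihood F-tests (1 numerator df) for the 7 contrasts."""
    s2_post, _, df_total = quasi_dispersion(fit_full, prior_df)
    out: dict[str, pd.DataFrame] = {}
    ok = fit_full.converged
    for name, cvec in contrast_vectors().items():
        est, se = _wald(fit_full, cvec)
        F = (est / se) ** 2 / s2_post
        p = stats.f.sf(F, 1, df_total)
        out[name] = pd.DataFrame(
            {"log2fc": est / _LN2, "stat": F,
             "pvalue": np.where(ok, p, np.nan)},
            index=fit_full.feature_ids,
        )
    return out


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(pvalues, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=1.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


def call_significant(
    table: pd.DataFrame,
    alpha: float = 0.001,
    lfc_threshold: float = 1.0,
    lfc_columns: tuple[str, ...] = ("log2fc",),
) -> pd.DataFrame:
    """Consensus calls: both engines' padj <= alpha AND |log2FC| > threshold.

    ``table`` must carry ``padj_lrt`` and ``padj_ql`` columns plus the
    log2FC column(s); for multi-contrast tests (the interaction) the
    largest-magnitude log2FC decides both the threshold and the direction.
    """
    lfc = table[list(lfc_columns)].to_numpy(dtype=float)
    best = lfc[np.arange(len(table)), np.argmax(np.abs(lfc), axis=1)]
    called = (
        (table["padj_lrt"].to_numpy() <= alpha)
        & (table["padj_ql"].to_numpy() <= alpha)
        & (np.abs(best) > lfc_threshold)
    )
    called &= ~np.isnan(table["padj_lrt"].to_numpy())
    called &= ~np.isnan(table["padj_ql"].to_numpy())
    out = table.copy()
    out["called"] = called
    out["direction"] = np.where(~called, "",
                                np.where(best > 0, "up", "down"))
    return out


# ---------------------------------------------------------------------------
# enrichment and PCA
# ---------------------------------------------------------------------------


def fisher_enrichment(
    called: set[str] | list[str],
    universe: set[str] | list[str],
    term_map: dict[str, set[str] | list[str]],
) -> pd.DataFrame:
    """Per-term two-sided Fisher exact test of over/under-representation.

    Fold enrichment is (overlap/|called|) / (|term|/|universe|); values
    below 1 indicate under-representation and are reported too.  BH FDR is
    applied across terms.
    """
    called_set = set(called)
    universe_set = set(universe)
    if not called_set <= universe_set:
        raise ValueError("called features must be a subset of the universe")
    rows = []
    for term in sorted(term_map):
        members = set(term_map[term]) & universe_set
        if not members:
            continue
        overlap = len(members & called_set)
        a = overlap
        b = len(called_set) - overlap
        c = len(members) - overlap
        d = len(universe_set) - len(called_set) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        fold = ((overlap / len(called_set)) / (len(members) / len(universe_set))
                if called_set else np.nan)
        rows.append((term, len(members), overlap, fold, p))
    out = pd.DataFrame(
        rows, columns=["term", "n_term", "overlap", "fold_enrichment",
                       "pvalue"]
    ).set_index("term")
    out["padj"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    return out


def pca_profile(
    normalized: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of log2(normalized + 1) expression profiles, feature-centered.

    Returns sample coordinates (samples x components) and the percentage of
    variance per component (non-negative, non-increasing, summing to <= 100).
    """
    if normalized.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    mat = np.log2(normalized.to_numpy(dtype=float) + 1.0)
    mat = mat - mat.mean(axis=1, keepdims=True)  # center each feature
    data = mat.T  # samples x features
    from sklearn.decomposition import PCA

    k = min(data.shape[0], data.shape[1])
    if n_components is not None:
        k = min(k, n_components)
    total_var = data.var(axis=0, ddof=1).sum()
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(data)
    if total_var <= 0:
        log.warning("constant expression matrix; PCA variance is zero")
        pct = np.zeros(k)
    else:
        pct = 100.0 * pca.explained_variance_ / total_var
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=normalized.columns, columns=cols), pct


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class DEAnalysis:
    """Full differential-expression result bundle."""

    experiment: CountExperiment          # after filtering
    size_factors: pd.Series
    normalized: pd.DataFrame
    dispersion: pd.DataFrame
    interaction: pd.DataFrame            # DDEG table with consensus calls
    contrasts: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary_counts(self) -> pd.DataFrame:
        rows = []
        tab = self.interaction
        rows.append(("interaction", int(tab["called"].sum()),
                     int((tab["direction"] == "up").sum()),
                     int((tab["direction"] == "down").sum())))
        for name, tab in self.contrasts.items():
            rows.append((name, int(tab["called"].sum()),
                         int((tab["direction"] == "up").sum()),
                         int((tab["direction"] == "down").sum())))
        return pd.DataFrame(rows, columns=["test", "called", "up",
                                           "down"]).set_index("test")


def run_de(
    exp: CountExperiment,
    alpha: float = 0.001,
    lfc_threshold: float = 1.0,
    low_count_threshold: float = 19.0,
    prior_df: float = 10.0,
    aggregate: str = "sum",
) -> DEAnalysis:
    """Normalize, filter, fit both engines, and produce consensus calls."""
    norm0 = normalize_counts(exp)
    filtered = filter_low_expression(exp, norm0.normalized,
                                     low_count_threshold, aggregate)
    if filtered.counts.shape[0] == 0:
        raise ValueError("no features left after low-expression filtering")
    norm = Normalization(
        norm0.size_factors,
        norm0.offsets[exp.counts.index.get_indexer(filtered.counts.index)],
        norm0.normalized.loc[filtered.counts.index],
    )
    X_full, X_red = build_design_matrices(exp.sample_meta)
    disp = estimate_dispersion(filtered.counts, X_full, norm.offsets,
                               prior_df=prior_df)
    alpha_vec = disp["alpha"].to_numpy()
    fit_full = fit_nb_glm(filtered.counts, X_full, norm.offsets, alpha_vec)
    fit_red = fit_nb_glm(filtered.counts, X_red, norm.offsets, alpha_vec)

    inter = test_interaction(fit_full, fit_red)
    inter = inter.rename(columns={"stat": "stat_lrt", "pvalue": "pvalue_lrt"})
    inter["padj_lrt"] = bh_adjust(inter["pvalue_lrt"])
    ql_int = ql_test_interaction(fit_full, fit_red)
    inter["stat_ql"] = ql_int["stat"]
    inter["pvalue_ql"] = ql_int["pvalue"]
    inter["padj_ql"] = bh_adjust(inter["pvalue_ql"])
    inter = call_significant(
        inter, alpha, lfc_threshold,
        lfc_columns=("log2fc_int_flower_vs_bud",
                     "log2fc_int_fruit_vs_flower"),
    )

    wald = test_contrasts(fit_full)
    ql = ql_test_contrasts(fit_full)
    contrasts: dict[str, pd.DataFrame] = {}
    for name in wald:
        tab = wald[name].rename(columns={"stat": "stat_lrt",
                                         "pvalue": "pvalue_lrt"})
        tab["padj_lrt"] = bh_adjust(tab["pvalue_lrt"])
        tab["stat_ql"] = ql[name]["stat"]
        tab["pvalue_ql"] = ql[name]["pvalue"]
        tab["padj_ql"] = bh_adjust(tab["pvalue_ql"])
        contrasts[name] = call_significant(tab, alpha, lfc_threshold)
    return DEAnalysis(
        experiment=filtered,
        size_factors=norm.size_factors,
        normalized=norm.normalized,
        dispersion=disp,
        interaction=inter,
        contrasts=contrasts,
    )
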