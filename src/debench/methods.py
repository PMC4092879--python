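"""Reference implementations of six count-based differential-expression tests.

Each function takes a gene x sample count matrix and a two-group design and
returns a :class:`MethodResult` with per-gene p-values (or one minus a
posterior probability for the empirical-Bayes method), BH-adjusted values,
and a shared normalized fold-change estimate.  The families implemented,
each at the level of its statistical principle:

``poisson_ma_test``
    Poisson-model test on pooled counts (conditional binomial with a
    normal approximation); over-sensitive on overdispersed data.
``nb_exact_test``
    Exact conditional NB test with empirical-Bayes (weighted-likelihood)
    shrinkage of per-gene dispersions toward a common value.
``nb_pooled_test``
    Exact conditional NB test with a parametric mean-dispersion trend
    phi(mu) = a1 + a0/mu and the conservative max(gene-wise, trend)
    working dispersion.
``nbp_test``
    Exact conditional NB test under the NBP power-dispersion model
    phi(mu) = phi0 * mu**(alpha - 2) with global ML (phi0, alpha).
``two_stage_poisson``
    Per-gene overdispersion score test, then a Poisson likelihood-ratio
    test or a quasi-likelihood F test depending on the flag.
``eb_nb_posterior``
    Empirical-Bayes posterior probability of differential expression from
    Poisson-gamma marginal likelihoods with hyperparameters sampled from
    the data (deliberately randomized unless seeded).

Policy for degenerate genes: an all-zero gene gets p = 1 and fold change 1
so downstream BH adjustment never sees missing values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from . import dispersion as disp
from .evaluate import bh_adjust

__all__ = [
    "MethodResult",
    "normalize_total_count",
    "compute_rpkm",
    "fold_change_estimate",
    "nb_conditional_pvalues",
    "poisson_ma_test",
    "nb_exact_test",
    "nb_pooled_test",
    "nbp_test",
    "two_stage_poisson",
    "eb_nb_posterior",
    "METHODS",
    "run_method",
]

logger = logging.getLogger(__name__)

_LOG_REL_TOL = 1e-9  # two-sided inclusion tolerance on log-pmf comparisons


@dataclass
class MethodResult:
    """Per-gene output of one DE method on one dataset."""

    method: str
    gene_id: np.ndarray
    p: np.ndarray
    p_adjusted: np.ndarray
    fc_estimate: np.ndarray
    norm_factors: np.ndarray
    direction: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.p)) or np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values must be finite and in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "p": self.p,
                "p_adj": self.p_adjusted,
                "fc": self.fc_estimate,
            }
        )
        df["direction"] = (
            self.direction if self.direction is not None else np.nan
        )
        return df


def _split_groups(group) -> tuple[np.ndarray, list[np.ndarray]]:
    labels = np.asarray(list(group))
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    return uniq, [np.flatnonzero(labels == u) for u in uniq]


def _as_matrix(counts) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), counts.index.to_numpy(dtype=object)
    mat = np.asarray(counts, dtype=float)
    gene_id = np.array([f"g{i}" for i in range(mat.shape[0])], dtype=object)
    return mat, gene_id


def normalize_total_count(counts) -> np.ndarray:
    """Per-sample total-count scaling factors, geometric-mean centered.

    ``factor_j = total_j / geometric_mean(totals)``; dividing a sample's
    counts by its factor puts all samples on a common library scale.  The
    factors multiply to 1.
    """
    mat, _ = _as_matrix(counts)
    totals = mat.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every sample needs a positive total count")
    return totals / np.exp(np.mean(np.log(totals)))


def compute_rpkm(C, N, L):
    """Reads per kilobase per million mapped reads: 1e9 * C / (N * L)."""
    C = np.asarray(C, dtype=float)
    N = np.asarray(N, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(N <= 0) or np.any(L <= 0):
        raise ValueError("N and L must be positive")
    if np.any(C < 0):
        raise ValueError("C must be non-negative")
    out = 1e9 * C / (N * L)
    return float(out) if out.ndim == 0 else out


def fold_change_estimate(
    counts, group, norm_factors=None, pseudocount: float = 0.5
) -> np.ndarray:
    """Normalized group-2 over group-1 mean fold change, shared by all methods.

    A single estimator across methods so that cross-method fold-change
    concordance reflects only normalization, not test internals.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mat, _ = _as_matrix(counts)
    _, (g1, g2) = _split_groups(group)
    if norm_factors is None:
        norm_factors = normalize_total_count(mat)
    q = mat / norm_factors
    m1 = q[:, g1].mean(axis=1) + pseudocount
    m2 = q[:, g2].mean(axis=1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = m2 / m1
    return np.where((m1 == 0) & (m2 == 0), 1.0, fc)


def _direction(fc: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.sign(np.log(np.where(fc > 0, fc, 1.0))).astype(np.int8)


def _build_result(method, gene_id, p, counts, group, norm_factors,
                  directional=True, extra=None) -> MethodResult:
    p = np.clip(p, 0.0, 1.0)
    fc = fold_change_estimate(counts, group, norm_factors)
    return MethodResult(
        method=method,
        gene_id=gene_id,
        p=p,
        p_adjusted=bh_adjust(p),
        fc_estimate=fc,
        norm_factors=np.asarray(norm_factors, dtype=float),
        direction=_direction(fc) if directional else None,
        extra=extra or {},
    )


# ---------------------------------------------------------------------------
# Exact conditional NB test core
# ---------------------------------------------------------------------------

def nb_conditional_pvalues(
    s1,
    s2,
    n1: int,
    n2: int,
    phi,
    batch_points: int = 4_000_000,
) -> np.ndarray:
    """Two-sided exact conditional NB p-values for per-group count sums.

    Under the null each of the ``n1 + n2`` samples of gene g is
    NB(mu_g, phi_g), so the group sums are NB with sizes ``n1/phi`` and
    ``n2/phi`` and a shared success probability that cancels on
    conditioning: given the total ``s = s1 + s2``, the group-1 sum follows
    a negative hypergeometric law

        P(k | s) ∝ C(k + n1/phi - 1, k) * C(s - k + n2/phi - 1, s - k).

    The two-sided p-value sums the probabilities of every split of ``s``
    no more likely than the observed one.  For small totals the full
    conditional support is enumerated (exact, matching brute-force
    enumeration); for large totals the support is sampled on a uniform
    stride of at most 1/128 of the conditional standard deviation, a
    midpoint-rule quadrature whose stride cancels in the normalized
    ratio and whose relative error is far below the scale at which
    p-values are used.  Genes with ``s = 0`` get p = 1.
    """
    s1 = np.asarray(np.round(s1), dtype=np.int64)
    s2 = np.asarray(np.round(s2), dtype=np.int64)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), s1.shape).copy()
    phi = np.maximum(phi, 1e-6)
    s = s1 + s2
    G = len(s1)
    pvals = np.ones(G)
    active = np.flatnonzero(s > 0)
    if len(active) == 0:
        return pvals

    r1 = n1 / phi
    r2 = n2 / phi
    lgt = gammaln(np.arange(int(s.max()) + 2, dtype=np.float64))

    def log_weight(k, sg, rr1, rr2):
        return (
            gammaln(k + rr1)
            - lgt[k + 1]
            + gammaln(sg - k + rr2)
            - lgt[sg - k + 1]
        )

    lw_obs = log_weight(s1[active], s[active], r1[active], r2[active])

    # per-gene stride: 1 (exact) for small totals, else conditional-sd based
    r_tot = r1[active] + r2[active]
    cond_var = (
        s[active] * r1[active] * r2[active] * (r_tot + s[active])
        / (r_tot**2 * (r_tot + 1.0))
    )
    stride = np.maximum(1, (np.sqrt(cond_var) / 128.0).astype(np.int64))

    # process genes in batches bounded by total evaluation points
    sizes = s[active] // stride + 1
    bounds = np.searchsorted(np.cumsum(sizes), np.arange(0, sizes.sum(),
                                                         batch_points))
    bounds = np.unique(np.append(bounds, len(active)))
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        gidx = active[b0:b1]
        sz = sizes[b0:b1]
        offsets = np.concatenate([[0], np.cumsum(sz)[:-1]])
        rep = lambda v: np.repeat(v, sz)
        k = (np.arange(sz.sum()) - rep(offsets)) * rep(stride[b0:b1])
        lw = log_weight(k, rep(s[gidx]), rep(r1[gidx]), rep(r2[gidx]))
        lw_max = np.maximum.reduceat(lw, offsets)
        w = np.exp(lw - np.repeat(lw_max, sz))
        tot = np.add.reduceat(w, offsets)
        thresh = lw_obs[b0:b1] + np.maximum(np.abs(lw_obs[b0:b1]), 1.0) * _LOG_REL_TOL
        hit = np.where(lw <= np.repeat(thresh, sz), w, 0.0)
        num = np.add.reduceat(hit, offsets)
        pvals[gidx] = np.minimum(num / tot, 1.0)
    return pvals


def _normalized(counts, group):
    mat, gene_id = _as_matrix(counts)
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    labels, group_idx = _split_groups(group)
    factors = normalize_total_count(mat)
    return mat, gene_id, labels, group_idx, factors, mat / factors


# ---------------------------------------------------------------------------
# Poisson-family pooled test
# ---------------------------------------------------------------------------

def poisson_ma_test(counts, group) -> MethodResult:
    """Poisson-model test on pooled group counts (conditional binomial z).

    Under a per-gene Poisson model the group-1 pooled count given the
    gene's total is binomial with success probability equal to group 1's
    share of the total library size; the two-sided p-value uses the
    normal approximation to that binomial.  On overdispersed (NB) data
    the binomial variance is far too small, making the test
    over-sensitive -- the behaviour this family is known for.
    """
    mat, gene_id, _, (g1, g2), factors, _ = _normalized(counts, group)
    k1 = mat[:, g1].sum(axis=1)
    k2 = mat[:, g2].sum(axis=1)
    N1 = mat[:, g1].sum()
    N2 = mat[:, g2].sum()
    prob = N1 / (N1 + N2)
    n = k1 + k2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (k1 - n * prob) / np.sqrt(n * prob * (1 - prob))
    p = np.where(n > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return _build_result("poisson_ma", gene_id, p, mat, group, factors)


# ---------------------------------------------------------------------------
# NB-family exact tests
# ---------------------------------------------------------------------------

def nb_exact_test(
    counts, group, shrinkage_weight: float = 20.0, dispersion=None
) -> MethodResult:
    """Exact conditional NB test with empirical-Bayes dispersion shrinkage.

    A common dispersion is estimated by profile likelihood on
    library-size-normalized counts; per-gene dispersions are shrunk
    toward it by maximizing the weighted likelihood with
    ``shrinkage_weight`` prior degrees of freedom.  Passing
    ``dispersion`` (scalar or per-gene vector) skips estimation and runs
    the exact test at that fixed value.
    """
    mat, gene_id, _, group_idx, factors, q = _normalized(counts, group)
    g1, g2 = group_idx
    if dispersion is not None:
        phi = np.broadcast_to(np.asarray(dispersion, float), (mat.shape[0],))
        extra = {"dispersion": "fixed"}
    elif min(len(g1), len(g2)) < 2:
        logger.warning(
            "nb_exact_test: a group has a single sample; using the pooled "
            "one-group common dispersion only (no per-gene shrinkage)"
        )
        pooled = [np.arange(mat.shape[1])]
        common = disp.common_dispersion(q, pooled)
        phi = np.full(mat.shape[0], common)
        extra = {"common_dispersion": common, "dispersion": "common-only"}
    else:
        ll = disp.loglik_profile(q, group_idx)
        common = disp.common_dispersion(q, group_idx, ll=ll)
        phi = disp.tagwise_dispersion(
            q, group_idx, prior_df=shrinkage_weight, ll=ll
        )
        extra = {"common_dispersion": common, "dispersion": "tagwise"}
    p = nb_conditional_pvalues(
        q[:, g1].sum(axis=1), q[:, g2].sum(axis=1), len(g1), len(g2), phi
    )
    extra["phi"] = np.asarray(phi, dtype=float)
    return _build_result("nb_exact", gene_id, p, mat, group, factors, extra=extra)


def nb_pooled_test(counts, group, trend: str = "parametric",
                   dispersion=None) -> MethodResult:
    """Exact conditional NB test with a parametric mean-dispersion trend.

    Per-gene ML dispersions are regressed on the parametric trend
    ``phi(mu) = a1 + a0 / mu``; each gene's working dispersion is the
    maximum of its own estimate and the trend value (conservative).  If
    the trend regression is degenerate, or ``trend='common'`` is
    requested, the common profile-likelihood dispersion is used for every
    gene instead.
    """
    mat, gene_id, _, group_idx, factors, q = _normalized(counts, group)
    g1, g2 = group_idx
    extra: dict = {}
    if dispersion is not None:
        phi = np.broadcast_to(np.asarray(dispersion, float), (mat.shape[0],))
        extra["dispersion"] = "fixed"
    else:
        ll = disp.loglik_profile(q, group_idx)
        common = disp.common_dispersion(q, group_idx, ll=ll)
        extra["common_dispersion"] = common
        coefs = None
        if trend == "parametric":
            genewise = disp.genewise_dispersion(q, group_idx, ll=ll)
            mu = q.mean(axis=1)
            coefs = disp.fit_dispersion_trend(mu, genewise)
        if coefs is None:
            if trend == "parametric":
                logger.warning(
                    "nb_pooled_test: trend regression degenerate; falling "
                    "back to the common dispersion"
                )
            phi = np.full(mat.shape[0], common)
            extra["dispersion"] = "common"
        else:
            a0, a1 = coefs
            trend_phi = a1 + a0 / np.maximum(q.mean(axis=1), 1e-8)
            phi = np.maximum(genewise, trend_phi)
            extra.update(dispersion="trend", trend_a0=a0, trend_a1=a1)
    p = nb_conditional_pvalues(
        q[:, g1].sum(axis=1), q[:, g2].sum(axis=1), len(g1), len(g2), phi
    )
    extra["phi"] = np.asarray(phi, dtype=float)
    return _build_result("nb_pooled", gene_id, p, mat, group, factors, extra=extra)


def nbp_test(counts, group, dispersion_params=None) -> MethodResult:
    """Exact conditional NB test under the NBP power-dispersion model.

    The dispersion is modeled globally as ``phi(mu) = phi0 * mu**(alpha-2)``
    with ``(phi0, alpha)`` fitted by maximum likelihood (``alpha = 2`` is
    constant dispersion).  ``dispersion_params=(phi0, alpha)`` fixes the
    model instead of fitting it.
    """
    mat, gene_id, _, group_idx, factors, q = _normalized(counts, group)
    g1, g2 = group_idx
    if dispersion_params is not None:
        phi0, alpha = map(float, dispersion_params)
        converged = True
    else:
        phi0, alpha, converged = disp.fit_nbp_dispersion(q, group_idx)
        if not converged:
            logger.warning(
                "nbp_test: dispersion ML did not converge; using alpha = 2 "
                "(constant dispersion)"
            )
    mu = q.mean(axis=1)
    phi = phi0 * np.where(mu > 0, mu, 1.0) ** (alpha - 2.0)
    phi = np.clip(phi, 1e-6, 1e4)
    p = nb_conditional_pvalues(
        q[:, g1].sum(axis=1), q[:, g2].sum(axis=1), len(g1), len(g2), phi
    )
    extra = {"phi0": phi0, "alpha": alpha, "converged": converged,
             "phi": np.asarray(phi, dtype=float)}
    return _build_result("nbp", gene_id, p, mat, group, factors, extra=extra)


# ---------------------------------------------------------------------------
# Two-stage Poisson test
# ---------------------------------------------------------------------------

def two_stage_poisson(counts, group, overdispersion_level: float = 0.05
                      ) -> MethodResult:
    """Two-stage Poisson test with a per-gene overdispersion triage.

    Stage 1 applies an adjusted score test of NB-type overdispersion
    against the Poisson two-group model.  Stage 2 tests the group effect
    with a Poisson likelihood-ratio test for genes that pass as Poisson
    and a quasi-likelihood F test (Pearson-scale dispersion) for flagged
    genes.  The two p-value families are BH-adjusted separately and
    merged, with the flag recorded per gene.
    """
    mat, gene_id, _, (g1, g2), factors, q = _normalized(counts, group)
    if min(len(g1), len(g2)) < 2:
        raise ValueError("two_stage_poisson requires >= 2 samples per group")
    N = mat.shape[1]
    m1 = q[:, g1].mean(axis=1)
    m2 = q[:, g2].mean(axis=1)
    m0 = q.mean(axis=1)
    mu = np.empty_like(q)
    mu[:, g1] = m1[:, None]
    mu[:, g2] = m2[:, None]
    h = np.empty(N)
    h[g1] = 1.0 / len(g1)
    h[g2] = 1.0 / len(g2)

    ok = m0 > 0
    # stage 1: adjusted overdispersion score statistic, one-sided
    resid = (q - mu) ** 2 - q + h[None, :] * mu
    denom = np.sqrt(2.0 * (mu**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        T = resid.sum(axis=1) / denom
    p_od = np.where(ok & (denom > 0), stats.norm.sf(T), 1.0)
    flagged = ok & (p_od < overdispersion_level)

    # stage 2: Poisson LRT for the group effect (factorial terms cancel)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = q * np.log(np.where(mu > 0, mu, 1.0) / np.where(ok, m0, 1.0)[:, None])
    lrt = 2.0 * np.where(mu > 0, term, 0.0).sum(axis=1)
    lrt = np.maximum(lrt, 0.0)

    p = np.ones(mat.shape[0])
    plain = ok & ~flagged
    p[plain] = stats.chi2.sf(lrt[plain], df=1)
    if flagged.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            pearson = np.where(mu > 0, (q - mu) ** 2 / np.where(mu > 0, mu, 1.0), 0.0)
        scale = pearson.sum(axis=1) / (N - 2)
        scale = np.maximum(scale, 1e-8)
        F = lrt[flagged] / scale[flagged]
        p[flagged] = stats.f.sf(F, 1, N - 2)

    # BH within each stage-2 family, merged afterwards
    p_adj = np.ones_like(p)
    for mask in (plain, flagged):
        if mask.any():
            p_adj[mask] = bh_adjust(p[mask])
    res = _build_result("tspm", gene_id, p, mat, group, factors,
                        extra={"overdispersed": flagged,
                               "p_overdispersion": p_od})
    res.p_adjusted = p_adj
    return res


# ---------------------------------------------------------------------------
# Empirical-Bayes posterior method
# ---------------------------------------------------------------------------

def eb_nb_posterior(
    counts,
    group,
    n_hyper_samples: int = 100,
    seed: int | None = None,
    max_em_iter: int = 200,
) -> MethodResult:
    """Empirical-Bayes posterior probability of differential expression.

    Models each count as Poisson with its own gamma-distributed rate, so
    counts are marginally negative binomial with per-gene mean mu and
    dispersion phi.  Hyperparameter pairs (mu, phi) are sampled from
    method-of-moments estimates of a random subset of genes -- the
    intentional randomization that makes unseeded runs differ.  Marginal
    likelihoods are averaged over the sampled hyperparameters under
    "equivalent expression" (one (mu, phi) for all samples) and
    "different expression" (an independent (mu, phi) per group); the
    prior DE proportion is estimated by EM.  Returns ``1 -
    posterior(DE)`` in the p slot and no direction (the posterior
    carries no sign).
    """
    if n_hyper_samples < 1:
        raise ValueError("n_hyper_samples must be >= 1")
    mat, gene_id, _, (g1, g2), factors, q = _normalized(counts, group)
    rng = np.random.default_rng(seed)
    S = q.sum(axis=1)
    n_tot = mat.shape[1]

    candidates = np.flatnonzero(S > 0)
    if len(candidates) == 0:
        p = np.ones(mat.shape[0])
        return _build_result("eb_nb", gene_id, p, mat, group, factors,
                             directional=False)
    pick = rng.choice(candidates, size=n_hyper_samples, replace=True)
    # each hyper pair comes from a sampled gene's pooled or per-group
    # moment estimates, so group-level expression states are represented
    # in the empirical prior
    cols = [np.arange(n_tot), g1, g2]
    source = rng.integers(0, 3, size=n_hyper_samples)
    mu_h = np.empty(n_hyper_samples)
    var_h = np.empty(n_hyper_samples)
    for si, idx in enumerate(cols):
        sel = source == si
        sub = q[np.ix_(pick[sel], idx)]
        mu_h[sel] = sub.mean(axis=1)
        var_h[sel] = sub.var(axis=1, ddof=1) if len(idx) > 1 else sub.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_h = (var_h - mu_h) / mu_h**2
    phi_h = np.clip(np.nan_to_num(phi_h, nan=0.1), 1e-3, 50.0)
    mu_h = np.maximum(mu_h, 1e-8)

    lgt_y = gammaln(q + 1.0)
    l_g1 = np.empty((mat.shape[0], n_hyper_samples))
    l_g2 = np.empty_like(l_g1)
    for i, (m, ph) in enumerate(zip(mu_h, phi_h)):
        r = 1.0 / ph
        ll = (
            gammaln(q + r)
            - gammaln(r)
            - lgt_y
            + r * np.log(r / (r + m))
            + q * np.log(m / (r + m))
        )
        l_g1[:, i] = ll[:, g1].sum(axis=1)
        l_g2[:, i] = ll[:, g2].sum(axis=1)

    log_nh = np.log(n_hyper_samples)
    l_ee = logsumexp(l_g1 + l_g2, axis=1) - log_nh
    l_de = (logsumexp(l_g1, axis=1) - log_nh) + (logsumexp(l_g2, axis=1) - log_nh)

    pi = 0.1
    log_post = None
    for _ in range(max_em_iter):
        log_num = np.log(pi) + l_de
        log_den = np.logaddexp(log_num, np.log1p(-pi) + l_ee)
        log_post = log_num - log_den
        new_pi = float(np.clip(np.exp(logsumexp(log_post)) / len(log_post),
                               1e-10, 1 - 1e-10))
        if abs(new_pi - pi) < 1e-10:
            pi = new_pi
            break
        pi = new_pi
    posterior = np.exp(log_post)
    p = np.clip(1.0 - posterior, 0.0, 1.0)
    p[S == 0] = 1.0
    res = _build_result(
        "eb_nb", gene_id, p, mat, group, factors, directional=False,
        extra={"posterior_de": posterior, "prior_de": pi},
    )
    # Bayesian FDR: mean local false-discovery odds among the genes ranked
    # at or above each gene -- the canonical cutoff rule for posteriors
    # (BH on 1 - posterior would correct twice).
    order = np.argsort(p, kind="stable")
    bayes_fdr = np.cumsum(p[order]) / np.arange(1, len(p) + 1)
    res.p_adjusted = np.empty_like(p)
    res.p_adjusted[order] = np.minimum(bayes_fdr, 1.0)
    return res


#: Uniform-interface registry of the six method families.
METHODS = {
    "poisson_ma": poisson_ma_test,
    "nb_exact": nb_exact_test,
    "nb_pooled": nb_pooled_test,
    "nbp": nbp_test,
    "tspm": two_stage_poisson,
    "eb_nb": eb_nb_posterior,
}

#: Methods that accept (and honour) a random seed.
_SEEDED = {"eb_nb"}


def run_method(name: str, counts, group, seed: int | None = None,
               **kwargs) -> MethodResult:
    """Run one registered method by name with a uniform interface."""
    if name not in METHODS:
        raise KeyError(f"unknown method {name!r}; choices: {sorted(METHODS)}")
    if name in _SEEDED:
        kwargs.setdefault("seed", seed)
    return METHODS[name](counts, group, **kwargs)
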