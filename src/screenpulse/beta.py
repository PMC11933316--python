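"""Gene-level β-score estimation by negative-binomial maximum likelihood.

Model
-----
For sgRNA *i* of a gene observed in sample *r* with size factor
:math:`s_r`, counts follow :math:`K_{ir} \\sim \\mathrm{NB}(\\mu_{ir},
\\alpha_i)` with ``Var = mu + alpha*mu**2`` and a log-linear mean

.. math:: \\log \\mu_{ir} = \\log s_r + \\log b_i + \\sum_c D_{rc}\\,\\beta_{gc},

where :math:`b_i` is the guide's baseline abundance, :math:`D` a 0/1
design matrix with one column per (condition, day) contrast (Day-0
baseline samples have all-zero rows), and :math:`\\beta_{gc}` the gene's
log-scale selection coefficient in contrast *c*: positive β means
enrichment relative to baseline, negative means depletion.

The likelihood is maximized by blockwise Newton ascent — a simultaneous
Newton step on every :math:`\\log b_i` and every :math:`\\beta_c` (the
contrast blocks are mutually orthogonal because each sample belongs to at
most one contrast), globalized with step halving on the log-likelihood.
Standard errors come from the observed-information matrix over the full
parameter vector; Wald z = β/se.

Per-guide dispersions are method-of-moments estimates on size-factor
normalized counts within replicate groups (samples sharing condition and
day), pooled by a count-weighted average and clipped to ``[alpha_min,
alpha_max]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigError, ConsistencyError, FitError
from .library import CountMatrix, SgRNALibrary
from .counts import design_from_samples, size_factors_control

__all__ = [
    "nb_loglik", "estimate_dispersion", "fit_gene", "fit_screen",
    "cellcycle_normalize", "BetaTable", "GeneFit",
    "ALPHA_MIN", "ALPHA_MAX",
]

ALPHA_MIN = 0.01
ALPHA_MAX = 10.0

#: |beta| cap; the MLE diverges when a contrast has zero reads for every
#: guide, and the cap stands in for "fully depleted/enriched"
BETA_BOUND = 10.0

_POISSON_ALPHA = 1e-12


def nb_loglik(k, mu, alpha):
    """Log-pmf of NB(mu, alpha) with Var = mu + alpha*mu^2, elementwise.

    alpha → 0 reduces continuously to the Poisson log-pmf.
    """
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if np.any(alpha < 0):
        raise ValueError("alpha must be non-negative")
    k, mu, alpha = np.broadcast_arrays(k, mu, alpha)
    out = np.empty(k.shape, dtype=float)
    pois = alpha < _POISSON_ALPHA
    if pois.any():
        kk, mm = k[pois], mu[pois]
        out[pois] = kk * np.log(mm) - mm - gammaln(kk + 1)
    nb = ~pois
    if nb.any():
        kk, mm, aa = k[nb], mu[nb], alpha[nb]
        r = 1.0 / aa
        out[nb] = (gammaln(kk + r) - gammaln(r) - gammaln(kk + 1)
                   + r * np.log(r / (r + mm)) + kk * np.log(mm / (r + mm)))
    return out if out.ndim else float(out)


def estimate_dispersion(cm: CountMatrix, size_factors: pd.Series | None = None,
                        alpha_min: float = ALPHA_MIN,
                        alpha_max: float = ALPHA_MAX) -> pd.Series:
    """Per-sgRNA method-of-moments overdispersion on normalized counts.

    Within each replicate group (samples sharing condition and day),
    ``alpha = (s^2 - m) / m^2`` with the n−1 variance; group estimates are
    pooled by a count-weighted average and clipped to [alpha_min, alpha_max].
    """
    sf = size_factors if size_factors is not None else cm.size_factors
    if sf is None:
        raise ConsistencyError("size factors required for dispersion estimation")
    norm = (cm.counts / sf.reindex(cm.counts.columns)).to_numpy(dtype=float)
    groups = cm.samples.groupby(["condition", "day"]).groups
    pos = [cm.counts.columns.get_indexer(list(idx)) for idx in groups.values()]
    pos = [p for p in pos if len(p) >= 2]
    n_sg = cm.counts.shape[0]
    if not pos:
        warnings.warn("no replicate group with >= 2 samples; "
                      "using global alpha_min for every sgRNA")
        return pd.Series(alpha_min, index=cm.counts.index, dtype=float)

    num = np.zeros(n_sg)
    wsum = np.zeros(n_sg)
    for p in pos:
        sub = norm[:, p]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        a = np.zeros(n_sg)
        a[ok] = (v[ok] - m[ok]) / m[ok] ** 2
        w = np.where(ok, m * len(p), 0.0)
        num += w * a
        wsum += w
    alpha = np.full(n_sg, alpha_min)
    seen = wsum > 0
    alpha[seen] = num[seen] / wsum[seen]
    alpha = np.clip(alpha, alpha_min, alpha_max)
    return pd.Series(alpha, index=cm.counts.index, dtype=float)


@dataclass
class GeneFit:
    beta: pd.Series
    se: pd.Series
    z: pd.Series
    baselines: pd.Series
    converged: bool
    loglik: float
    n_iter: int


def _loglik_value(K, s, D, alpha, logb, beta):
    eta = logb[:, None] + (D @ beta)[None, :] + np.log(s)[None, :]
    mu = np.exp(np.clip(eta, -300.0, 300.0))
    return float(nb_loglik(K, mu, alpha[:, None]).sum()), mu


def fit_gene(gene_counts: pd.DataFrame, design: pd.DataFrame,
             size_factors: pd.Series, dispersions: pd.Series, *,
             tol: float = 1e-6, max_iter: int = 100) -> GeneFit:
    """Fit one gene's β per contrast jointly with per-guide baselines.

    ``gene_counts``: sgRNA × sample counts for the gene's guides.
    Guides whose total count is zero are dropped; an all-zero gene raises
    :class:`FitError` (callers skip it with a warning).
    """
    samples = list(gene_counts.columns)
    K = gene_counts.to_numpy(dtype=float)
    keep = K.sum(axis=1) > 0
    if not keep.any():
        raise FitError("gene has no sgRNA with positive total count")
    K = K[keep]
    sg_ids = list(gene_counts.index[keep])
    s = size_factors.reindex(samples).to_numpy(dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ConsistencyError("missing or non-positive size factor")
    D = design.reindex(samples).to_numpy(dtype=float)
    if np.any(np.isnan(D)):
        raise ConsistencyError("design does not cover all samples")
    alpha = np.clip(dispersions.reindex(sg_ids).to_numpy(dtype=float), 0.0, None)
    conds = list(design.columns)
    n_i, n_c = K.shape[0], len(conds)
    base = D.sum(axis=1) == 0
    cond_masks = [D[:, c] == 1 for c in range(n_c)]

    # init: baselines from Day-0 samples, betas from pooled ratios
    Kn = K / s[None, :]
    if base.any():
        b0 = Kn[:, base].mean(axis=1)
    else:
        b0 = Kn.mean(axis=1)
    logb = np.log(np.maximum(b0, 0.25))
    beta = np.zeros(n_c)
    bsum = max(np.exp(logb).sum(), 1e-9)
    for c, m in enumerate(cond_masks):
        if m.any():
            beta[c] = np.log((Kn[:, m].sum() / m.sum() + 0.5) / (bsum + 0.5))

    def _score_info(mu):
        """Gradient and observed information over theta = (log b, beta)."""
        a = alpha[:, None]
        u = (1.0 + a * K) / (1.0 + a * mu)
        score = K - mu * u
        w = mu * u / (1.0 + a * mu)
        grad = np.empty(n_i + n_c)
        grad[:n_i] = score.sum(axis=1)
        info = np.zeros((n_i + n_c, n_i + n_c))
        info[np.arange(n_i), np.arange(n_i)] = w.sum(axis=1)
        for c, m in enumerate(cond_masks):
            grad[n_i + c] = score[:, m].sum()
            wc = w[:, m].sum(axis=1)
            info[:n_i, n_i + c] = wc
            info[n_i + c, :n_i] = wc
            info[n_i + c, n_i + c] = wc.sum()
        return grad, info

    ll, mu = _loglik_value(K, s, D, alpha, logb, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, info = _score_info(mu)
        # Newton direction on the joint parameter vector, ridge-guarded
        try:
            delta = np.linalg.solve(
                info + 1e-10 * np.eye(n_i + n_c), grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.pinv(info) @ grad
        delta = np.clip(delta, -5.0, 5.0)
        step = 1.0
        for _ in range(40):
            ll_new, mu_new = _loglik_value(
                K, s, D, alpha,
                logb + step * delta[:n_i], beta + step * delta[n_i:])
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        # bound parameters: a condition with no reads drives beta to -inf;
        # the boundary value stands in for "fully depleted"
        new_logb = np.clip(logb + step * delta[:n_i], -30.0, 30.0)
        new_beta = np.clip(beta + step * delta[n_i:], -BETA_BOUND, BETA_BOUND)
        change = max(np.abs(new_logb - logb).max(),
                     np.abs(new_beta - beta).max())
        logb, beta = new_logb, new_beta
        ll, mu = _loglik_value(K, s, D, alpha, logb, beta)
        if change < tol:
            converged = True
            break

    # observed information at the optimum; se from inverse diagonal
    _, info = _score_info(mu)
    cov = np.linalg.pinv(info)
    var = np.clip(np.diag(cov)[n_i:], 1e-12, None)
    se = np.sqrt(var)

    idx = pd.Index(conds, name="condition")
    return GeneFit(
        beta=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        z=pd.Series(beta / se, index=idx),
        baselines=pd.Series(np.exp(logb), index=pd.Index(sg_ids, name="sgRNA")),
        converged=converged,
        loglik=ll,
        n_iter=it,
    )


@dataclass
class BetaTable:
    """Long-format per-gene, per-contrast fit results.

    ``table`` columns: ``gene, condition, beta, se, z, converged``.
    Contrast names follow ``{COND}_D{day}``.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def wide(self, value: str = "beta") -> pd.DataFrame:
        return self.table.pivot(index="gene", columns="condition", values=value)

    def by_day(self, condition: str, value: str = "beta") -> pd.DataFrame:
        """gene × day matrix for one condition (columns sorted by day)."""
        sub = self.table[self.table["condition"].str.startswith(condition + "_D")].copy()
        if sub.empty:
            raise ConsistencyError(f"no contrasts for condition {condition!r}")
        sub["day"] = sub["condition"].str.rsplit("_D", n=1).str[1].astype(int)
        wide = sub.pivot(index="gene", columns="day", values=value)
        return wide[sorted(wide.columns)]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BetaTable":
        return cls(pd.read_csv(path, sep="\t"))


def fit_screen(cm: CountMatrix, library: SgRNALibrary,
               design: pd.DataFrame | None = None, *,
               per_replicate: bool = True,
               size_factors: pd.Series | None = None,
               dispersions: pd.Series | None = None,
               tol: float = 1e-6, max_iter: int = 100):
    """Fit every targeting gene; returns ``{replicate: BetaTable}`` when
    ``per_replicate`` (default, replicates then averaged downstream) or a
    single BetaTable for a joint fit across replicates."""
    if size_factors is None:
        size_factors = cm.size_factors
    if size_factors is None:
        ntc = [i for i in library.ntc_ids if i in cm.counts.index]
        size_factors = size_factors_control(cm, ntc if ntc else list(cm.counts.index))
    if dispersions is None:
        dispersions = estimate_dispersion(cm, size_factors)
    if design is None:
        design = design_from_samples(cm.samples)
    extra = set(cm.samples.index[cm.samples["condition"] != "BASE"]) - set(design.index)
    if extra:
        raise ConsistencyError(
            f"design does not cover sample {sorted(extra)[0]!r}")
    design = design.reindex(cm.counts.columns, fill_value=0)

    if per_replicate:
        out = {}
        for rep in cm.replicates():
            names = list(cm.samples.index[cm.samples["replicate"] == rep])
            sub = cm.subset_samples(names)
            subD = design.loc[names]
            subD = subD.loc[:, subD.sum(axis=0) > 0]
            out[rep] = _fit_all_genes(sub, library, subD, size_factors,
                                      dispersions, tol, max_iter)
        return out
    return _fit_all_genes(cm, library, design, size_factors, dispersions,
                          tol, max_iter)


def _fit_all_genes(cm, library, design, size_factors, dispersions, tol, max_iter):
    rows = []
    skipped = []
    gene_groups = library.targeting.groupby("gene")["sgRNA"]
    for gene, ids in gene_groups:
        ids = [i for i in ids if i in cm.counts.index]
        if not ids:
            skipped.append(gene)
            continue
        sub = cm.counts.loc[ids]
        try:
            fit = fit_gene(sub, design, size_factors, dispersions,
                           tol=tol, max_iter=max_iter)
        except FitError:
            skipped.append(gene)
            continue
        for cond in design.columns:
            rows.append((gene, cond, fit.beta[cond], fit.se[cond],
                         fit.z[cond], fit.converged))
    if skipped:
        warnings.warn(f"skipped {len(skipped)} gene(s) with no usable counts "
                      f"(first: {skipped[0]})")
    table = pd.DataFrame(rows, columns=["gene", "condition", "beta", "se",
                                        "z", "converged"])
    n_nc = int((~table["converged"]).sum())
    if n_nc:
        warnings.warn(f"{n_nc} gene-condition fits did not converge "
                      f"(last iterate reported)")
    return BetaTable(table, metadata={"skipped_genes": skipped})


def cellcycle_normalize(bt: BetaTable,
                        reference_genes: list[str] | None = None) -> BetaTable:
    """Rescale each contrast so β values are comparable across conditions.

    The per-contrast scale κ_c is the median |β| over a reference gene set
    (default: all fitted genes); β and se are divided by κ_c.  This makes
    the spread of growth-driven β uniform across sampling days, the role
    the upstream tooling's "cell cycle normalization" plays.
    """
    if reference_genes is not None and len(reference_genes) == 0:
        raise ConfigError("reference gene set is empty")
    table = bt.table.copy()
    if reference_genes is None:
        ref_mask = pd.Series(True, index=table.index)
    else:
        present = set(reference_genes) & set(table["gene"])
        if not present:
            raise ConfigError("no reference gene present in the beta table")
        ref_mask = table["gene"].isin(present)
    kappa = {}
    for cond, sub in table[ref_mask].groupby("condition"):
        k = float(sub["beta"].abs().median())
        if k == 0.0 or not np.isfinite(k):
            warnings.warn(f"reference median |beta| is zero for {cond}; "
                          f"scale left at 1")
            k = 1.0
        kappa[cond] = k
    scale = table["condition"].map(kappa)
    table["beta"] = table["beta"] / scale
    table["se"] = table["se"] / scale
    table["z"] = table["beta"] / table["se"]
    meta = dict(bt.metadata)
    meta["kappa"] = kappa
    return BetaTable(table, metadata=meta)
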