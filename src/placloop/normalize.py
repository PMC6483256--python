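"""Zero-truncated Poisson (ZTP) background normalization of bin-pair counts.

Only bin pairs with a non-zero count are observed at kilobase resolution,
so the raw count ``x_ij`` is modeled as a Poisson variable conditioned on
being at least 1, with a log-linear model on the underlying Poisson rate::

    log lambda_ij = b0 + b_f log(f_i f_j) + b_gc log(gc_i gc_j)
                  + b_m log(m_i m_j) + b_IP log(IP_i IP_j) + b_d log(d_ij)

The model is fitted by maximum likelihood per chromosome, separately for
the AND and XOR sets. The fitted rate is the expected background contact
frequency ``e_ij``; significance of an observed count is the ZTP tail
probability ``p_ij = P(X > x_ij | X >= 1)`` at rate ``e_ij``. Bin pairs
with extremely small first-pass p-values (< 1/N, N the number of non-zero
bin pairs in the group) are treated as signal outliers and excluded from a
single re-fit, which yields the recalibrated background ``e~_ij`` and
p-value ``p~_ij``; Benjamini-Hochberg FDR ``q_ij`` is then computed within
each (chromosome, set) group.

Records with any non-positive covariate product (a bin with no fragment
end, zero ChIP signal, or undefined GC/mappability) are invisible to the
assay and are excluded from both fitting and scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .errors import ConvergenceError, DegenerateDataError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Names of the model terms, in design-matrix order.
MODEL_TERMS = ("intercept", "log_ff", "log_gcgc", "log_mm", "log_ipip", "log_d")

_MAX_ITER = 100
_LL_RTOL = 1e-8

NORMALIZED_COLUMNS = [
    "chrom", "bin1", "bin2", "set", "x", "d",
    "e", "p", "e_tilde", "p_tilde", "q", "fold",
]


@dataclass
class ZtpFit:
    """Fitted ZTP regression coefficients for one (chromosome, set) group."""

    chrom: str
    set_label: str
    beta: np.ndarray
    n_obs: int
    converged: bool
    loglik: float = field(default=float("nan"))

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta_f(self) -> float:
        return float(self.beta[1])

    @property
    def beta_gc(self) -> float:
        return float(self.beta[2])

    @property
    def beta_m(self) -> float:
        return float(self.beta[3])

    @property
    def beta_ip(self) -> float:
        return float(self.beta[4])

    @property
    def beta_d(self) -> float:
        return float(self.beta[5])


def ztp_tail_prob(x, lam):
    """Upper tail P(X > x) of a zero-truncated Poisson with rate ``lam``.

    For X ~ Poisson(lam) conditioned on X >= 1 this is
    ``P(X > x) / (1 - exp(-lam))``; ``-expm1`` keeps the denominator
    accurate for tiny rates and the scipy survival function handles rates
    well past 1e3. Accepts scalars or arrays.
    """
    x_arr = np.asarray(x)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(x_arr < 1):
        raise ValueError("observed count must be >= 1 on the truncated support")
    if np.any(lam_arr <= 0):
        raise ValueError("rate parameter must be positive")
    out = poisson.sf(x_arr, lam_arr) / (-np.expm1(-lam_arr))
    if np.isscalar(x) and np.isscalar(lam):
        return float(out)
    return out


def _infer_resolution(features: pd.DataFrame) -> int:
    diffs = features.groupby("chrom")["start"].diff().dropna()
    if diffs.empty:
        return int(features["end"].iloc[0] - features["start"].iloc[0])
    return int(diffs.iloc[0])


def design_matrix(
    records: pd.DataFrame, features: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the ZTP design matrix for bin-pair records.

    Returns ``(X, y, valid)`` where ``valid`` marks rows whose covariate
    products are all strictly positive and finite.
    """
    res = _infer_resolution(features)
    feats = features.copy()
    feats["bin"] = feats["start"] // res
    feats = feats.set_index(["chrom", "bin"])
    left = feats.reindex(
        pd.MultiIndex.from_arrays([records["chrom"], records["bin1"]])
    )
    right = feats.reindex(
        pd.MultiIndex.from_arrays([records["chrom"], records["bin2"]])
    )

    prods = np.column_stack(
        [
            left["f"].to_numpy() * right["f"].to_numpy(),
            left["gc"].to_numpy() * right["gc"].to_numpy(),
            left["m"].to_numpy() * right["m"].to_numpy(),
            left["IP"].to_numpy(float) * right["IP"].to_numpy(float),
            records["d"].to_numpy(float),
        ]
    )
    valid = np.all(np.isfinite(prods) & (prods > 0), axis=1)
    X = np.empty((len(records), 6))
    X[:, 0] = 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        X[:, 1:] = np.log(prods)
    y = records["x"].to_numpy(float)
    return X, y, valid


def _ztp_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = np.clip(X @ beta, -300, 300)
    lam = np.exp(eta)
    return float(np.sum(y * eta - lam - np.log(-np.expm1(-lam)) - gammaln(y + 1)))


def fit_ztp(
    records: pd.DataFrame,
    features: pd.DataFrame,
    chrom: str | None = None,
    set_label: str | None = None,
) -> ZtpFit:
    """Maximum-likelihood fit of the ZTP regression for one group of records.

    Newton iterations on the ZTP log-likelihood, initialized from an
    ordinary Poisson GLM; the score of the log link is ``x - mu`` with
    ``mu = lambda / (1 - exp(-lambda))`` the ZTP mean, and the observed
    information uses the weight ``mu (1 - mu exp(-lambda))``. Convergence
    is declared when the relative log-likelihood change drops below 1e-8.
    """
    if chrom is None:
        chroms = records["chrom"].unique()
        chrom = chroms[0] if len(chroms) == 1 else "*"
    if set_label is None and "set" in records:
        labels = records["set"].unique()
        set_label = labels[0] if len(labels) == 1 else "*"

    X, y, valid = design_matrix(records, features)
    X, y = X[valid], y[valid]
    n = len(y)
    if np.any(y < 1):
        raise ValueError("ZTP regression requires all counts >= 1")
    if n <= X.shape[1]:
        raise InsufficientDataError(
            f"{n} usable records for {X.shape[1]} coefficients in "
            f"({chrom}, {set_label})"
        )

    # center covariates for conditioning; un-center the intercept afterwards
    means = X[:, 1:].mean(axis=0)
    Xc = X.copy()
    Xc[:, 1:] -= means

    # a covariate constant within the group is indistinguishable from the
    # intercept; pin its coefficient at 0 and let the intercept absorb it
    spread = np.abs(Xc[:, 1:]).max(axis=0)
    active = np.concatenate(([True], spread > 1e-12))
    Xc = Xc[:, active]

    init = sm.GLM(y, Xc, family=sm.families.Poisson()).fit()
    beta = np.asarray(init.params, dtype=float)

    ll = _ztp_loglik(beta, Xc, y)
    converged = False
    for _ in range(_MAX_ITER):
        eta = np.clip(Xc @ beta, -300, 300)
        lam = np.exp(eta)
        q = -np.expm1(-lam)
        mu = lam / q
        score = Xc.T @ (y - mu)
        w = mu * (1.0 - mu * np.exp(-lam))
        hess = (Xc * w[:, None]).T @ Xc
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix in ({chrom}, {set_label})"
            ) from exc
        # damped Newton: halve the step until the likelihood improves
        new_ll = ll
        for _half in range(30):
            cand = beta + step
            cand_ll = _ztp_loglik(cand, Xc, y)
            if cand_ll >= ll - 1e-12:
                beta, new_ll = cand, cand_ll
                break
            step = step / 2.0
        else:
            raise ConvergenceError(
                f"line search failed in ({chrom}, {set_label})"
            )
        if abs(new_ll - ll) <= _LL_RTOL * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged:
        raise ConvergenceError(
            f"no convergence after {_MAX_ITER} iterations in ({chrom}, {set_label})"
        )

    beta_full = np.zeros(X.shape[1])
    beta_full[active] = beta
    beta_out = beta_full
    beta_out[0] = beta_full[0] - beta_full[1:] @ means
    return ZtpFit(
        chrom=str(chrom),
        set_label=str(set_label),
        beta=beta_out,
        n_obs=n,
        converged=True,
        loglik=ll,
    )


def expected_and_pvalue(
    fit: ZtpFit, records: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Score records under a fitted model: expected count ``e`` and p-value.

    Records with a non-positive covariate product cannot be scored; they
    are dropped from the output and counted in a log message.
    """
    if not fit.converged:
        raise ValueError("cannot score records with a non-converged fit")
    X, y, valid = design_matrix(records, features)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info(
            "excluded %d record(s) with non-positive covariates in (%s, %s)",
            n_skipped, fit.chrom, fit.set_label,
        )
    out = records.loc[valid].copy()
    e = np.exp(np.clip(X[valid] @ fit.beta, -300, 300))
    out["e"] = e
    out["p"] = ztp_tail_prob(y[valid], e)
    return out


def refit_without_outliers(
    scored: pd.DataFrame, features: pd.DataFrame, fit: ZtpFit
) -> tuple[pd.DataFrame, ZtpFit]:
    """Remove signal outliers, re-fit once, and re-score every record.

    Outliers are records with first-pass ``p < 1/N`` where N is the number
    of non-zero bin pairs in this group. The re-fitted background yields
    ``e_tilde`` and ``p_tilde`` for all records, outliers included.
    """
    n_total = len(scored)
    if n_total == 0:
        raise DegenerateDataError("no scored records to re-fit")
    keep = scored["p"] >= 1.0 / n_total
    if not keep.any():
        raise DegenerateDataError(
            f"all {n_total} records flagged as outliers in "
            f"({fit.chrom}, {fit.set_label})"
        )
    if keep.all():
        refit = fit
    else:
        refit = fit_ztp(
            scored.loc[keep], features, chrom=fit.chrom, set_label=fit.set_label
        )
    out = scored.copy()
    X, y, valid = design_matrix(out, features)
    e_tilde = np.exp(np.clip(X @ refit.beta, -300, 300))
    out["e_tilde"] = e_tilde
    out["p_tilde"] = ztp_tail_prob(y, e_tilde)
    return out, refit


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normalize_bin_pairs(
    binpairs: pd.DataFrame,
    features: pd.DataFrame,
    sets: tuple[str, ...] = ("AND", "XOR"),
    fdr_scope: str = "chromosome",
) -> pd.DataFrame:
    """Fit, score, re-fit and FDR-adjust all (chromosome, set) groups.

    ``fdr_scope`` is ``"chromosome"`` (adjust within each (chromosome, set)
    group, the default) or ``"genome"`` (adjust per set across chromosomes).
    NOT-set records are never scored. Returns the normalized table with
    columns chrom, bin1, bin2, set, x, d, e, p, e_tilde, p_tilde, q, fold.
    """
    if fdr_scope not in ("chromosome", "genome"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    groups = []
    for chrom in sorted(binpairs["chrom"].unique()):
        for set_label in sets:
            sub = binpairs[
                (binpairs["chrom"] == chrom) & (binpairs["set"] == set_label)
            ]
            if sub.empty:
                continue
            fit = fit_ztp(sub, features, chrom=chrom, set_label=set_label)
            scored = expected_and_pvalue(fit, sub, features)
            scored, _ = refit_without_outliers(scored, features, fit)
            if fdr_scope == "chromosome":
                scored["q"] = bh_fdr(scored["p_tilde"])
            groups.append(scored)
    if not groups:
        return pd.DataFrame(columns=NORMALIZED_COLUMNS)
    out = pd.concat(groups, ignore_index=True)
    if fdr_scope == "genome":
        for set_label in sets:
            mask = out["set"] == set_label
            if mask.any():
                out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p_tilde"])
    out["fold"] = out["x"] / out["e_tilde"]
    return out[NORMALIZED_COLUMNS]
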