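"""Differential relative abundance tests and the method registry.

Built-in methods (all two-sided, per OTU):

``ttest``
    Welch t-test on relative abundances.
``log_ttest``
    Welch t-test on log(count + 1) values.
``wilcoxon``
    Mann-Whitney rank-sum test on relative abundances; exact null
    distribution for small tie-free groups, tie-corrected normal
    approximation otherwise.
``nb_glm``
    Per-OTU negative binomial regression on raw counts with
    log(library size) offset, case status as the only covariate, ML
    dispersion, Wald p on the group coefficient.
``permutation``
    Seeded label-permutation test on relative abundances with statistic
    S = log(mean cases / mean controls)²; p is the proportion of
    permuted statistics >= the observed one.

External methods plug in as subprocesses via :class:`MethodSpec`.  The
universal missing-p rule applies everywhere: an OTU for which a method
produces no p-value (degenerate input, non-convergence, plugin failure)
gets p = 1, never NaN and never a silently dropped row.
"""

from __future__ import annotations

import itertools
import logging
import math
import subprocess
import tempfile
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountTable, library_sizes, to_relative_abundance, write_count_table
from .spike import LabelAssignment

logger = logging.getLogger(__name__)


@dataclass
class DAResult:
    """Per-OTU p-values (and statistics) from one method on one labeled table."""

    method_name: str
    otu_ids: list[str] | None
    p: np.ndarray
    statistic: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.otu_ids is not None and len(self.p) != len(self.otu_ids):
            raise ValueError("p length does not match otu_ids")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values outside [0, 1]")
        if np.any(np.isnan(self.p)):
            raise ValueError("NaN p-values; apply the missing-p rule first")


def _fill_missing(p: np.ndarray) -> np.ndarray:
    """The universal missing-p rule: absent/NaN p-values become 1."""
    p = np.asarray(p, dtype=float).copy()
    p[~np.isfinite(p)] = 1.0
    return np.clip(p, 0.0, 1.0)


def _split(values: np.ndarray, labels: LabelAssignment):
    status = labels.status
    return values[:, status], values[:, ~status]


# ---------------------------------------------------------------------------
# Built-in tests


def t_test_relative(t: CountTable, labels: LabelAssignment) -> DAResult:
    """Welch t-test per OTU on relative abundances."""
    rel = to_relative_abundance(t).counts if t.is_raw else t.counts
    return _welch(rel, labels, "ttest")


def t_test_log(t: CountTable, labels: LabelAssignment, pseudocount: float = 1.0) -> DAResult:
    """Welch t-test per OTU on log(count + pseudocount) values."""
    vals = np.log(t.counts.astype(float) + pseudocount)
    return _welch(vals, labels, "log_ttest")


def _welch(values: np.ndarray, labels: LabelAssignment, name: str) -> DAResult:
    cases, controls = _split(values, labels)
    if cases.shape[1] < 2 or controls.shape[1] < 2:
        # t-test undefined with fewer than 2 observations per group
        return DAResult(name, None, np.ones(values.shape[0]))
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.ttest_ind(cases, controls, axis=1, equal_var=False)
    # both groups constant: the reference implementation errors out
    # ("data essentially constant") -> missing-p rule
    degenerate = (cases.var(axis=1) == 0) & (controls.var(axis=1) == 0)
    p = np.where(degenerate, 1.0, p)
    stat = np.where(degenerate, np.nan, stat)
    return DAResult(name, None, _fill_missing(p), stat)


def wilcoxon_relative(t: CountTable, labels: LabelAssignment,
                      exact_max_n: int = 12) -> DAResult:
    """Mann-Whitney rank-sum test per OTU on relative abundances.

    Exact null distribution when both groups have <= *exact_max_n*
    observations and the OTU has no ties; otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    rel = to_relative_abundance(t).counts if t.is_raw else t.counts
    cases, controls = _split(rel, labels)
    n1, n2 = cases.shape[1], controls.shape[1]
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(cases, controls, axis=1, method="asymptotic",
                                 use_continuity=True, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    stat = np.asarray(res.statistic, dtype=float)
    all_tied = (rel.max(axis=1) == rel.min(axis=1))
    if max(n1, n2) <= exact_max_n:
        for i in range(rel.shape[0]):
            row = np.concatenate([cases[i], controls[i]])
            if all_tied[i] or len(np.unique(row)) < len(row):
                continue  # ties: keep the corrected approximation
            ex = stats.mannwhitneyu(cases[i], controls[i], method="exact",
                                    alternative="two-sided")
            p[i], stat[i] = ex.pvalue, ex.statistic
    p[all_tied] = 1.0
    return DAResult("wilcoxon", None, _fill_missing(p), stat)


_LOG_ALPHA_BOUNDS = (np.log(1e-8), np.log(1e4))


def _nb2_negloglik_grad(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                        offset: np.ndarray):
    """NB2 negative log-likelihood and gradient in (beta, log alpha)."""
    from scipy.special import gammaln, digamma

    beta, la = theta[:-1], theta[-1]
    alpha = np.exp(la)
    inv_a = 1.0 / alpha
    eta = X @ beta + offset
    mu = np.exp(np.clip(eta, -500, 500))
    denom = 1.0 + alpha * mu
    ll = (gammaln(y + inv_a) - gammaln(inv_a) - gammaln(y + 1)
          + y * (np.log(alpha) + eta) - (y + inv_a) * np.log(denom))
    g_beta = X.T @ ((y - mu) / denom)
    dll_dalpha = (inv_a ** 2 * (np.log(denom) - digamma(y + inv_a) + digamma(inv_a))
                  + (y - mu) / (alpha * denom))
    g_la = float(dll_dalpha.sum() * alpha)
    return -float(ll.sum()), -np.r_[g_beta, g_la]


def _nb_fit_one(y: np.ndarray, X: np.ndarray, offset: np.ndarray):
    """Fit one NB regression; return (p, beta1) or None on failure.

    Direct NB2 maximum likelihood in (beta, log alpha) with analytic
    gradient (L-BFGS-B), Wald p for the group coefficient from the
    inverse observed information.  A GLM with the moment-estimated
    dispersion held fixed serves as fallback when ML fails.
    """
    from scipy import optimize
    from scipy.stats import norm
    import statsmodels.tools.numdiff as nd

    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        # moment start: group-wise rates relative to depth
        L = np.exp(offset)
        case = X[:, 1] > 0
        r_ctrl = max(y[~case].sum() / L[~case].sum(), 1e-12)
        r_case = max(y[case].sum() / L[case].sum(), 1e-12)
        b0 = np.log(r_ctrl)
        b1 = np.log(r_case) - b0
        mu0 = np.where(case, r_case, r_ctrl) * L
        alpha0 = float(np.clip(np.sum((y - mu0) ** 2 - mu0) / np.sum(mu0 ** 2),
                               1e-6, 100.0))
        start = np.r_[b0, b1, np.log(alpha0)]
        bounds = [(-50, 50), (-50, 50), _LOG_ALPHA_BOUNDS]
        try:
            res = optimize.minimize(
                _nb2_negloglik_grad, start, args=(y, X, offset), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8})
            if res.success and abs(res.x[1]) < 49:
                hess = nd.approx_hess2(
                    res.x, lambda th: _nb2_negloglik_grad(th, y, X, offset)[0])
                cov = np.linalg.inv(hess)
                se1 = np.sqrt(cov[1, 1])
                if np.isfinite(se1) and se1 > 0:
                    z = res.x[1] / se1
                    return float(2 * norm.sf(abs(z))), float(res.x[1])
        except Exception:
            pass
        # fallback: dispersion held at the moment estimate
        try:
            import statsmodels.api as sm
            res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha0),
                         offset=offset).fit()
            if np.isfinite(res.pvalues[1]) and np.isfinite(res.params[1]):
                return float(res.pvalues[1]), float(res.params[1])
        except Exception:
            pass
    return None


def nb_glm(t: CountTable, labels: LabelAssignment) -> DAResult:
    """Negative binomial GLM per OTU: log mu = b0 + b1·case + log(depth).

    Wald p on b1; per-OTU ML dispersion with a method-of-moments
    fallback; all-zero OTUs and non-convergent fits get p = 1.
    """
    if not t.is_raw:
        raise ValueError("nb_glm requires raw counts")
    L = library_sizes(t).astype(float)
    offset = np.log(L)
    X = np.column_stack([np.ones(t.n_samples), labels.status.astype(float)])
    p = np.ones(t.n_otus)
    beta = np.full(t.n_otus, np.nan)
    n_failed = 0
    for i in range(t.n_otus):
        y = t.counts[i].astype(float)
        if y.sum() == 0:
            continue
        out = _nb_fit_one(y, X, offset)
        if out is None:
            n_failed += 1
            logger.warning("nb_glm: no convergence for OTU %s; p set to 1",
                           t.otu_ids[i])
            continue
        p[i], beta[i] = out
    return DAResult("nb_glm", list(t.otu_ids), _fill_missing(p), beta,
                    meta={"n_failed": n_failed})


def _perm_case_masks(n: int, n_cases: int, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    masks = np.zeros((n_perm, n), dtype=bool)
    for k in range(n_perm):
        masks[k, rng.choice(n, size=n_cases, replace=False)] = True
    return masks


def _log_ratio_sq(case_mean: np.ndarray, ctrl_mean: np.ndarray) -> np.ndarray:
    """S = log(mean cases / mean controls)²; one zero mean -> +inf, both -> 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.log(case_mean / ctrl_mean) ** 2
    s = np.where((case_mean == 0) & (ctrl_mean == 0), 0.0, s)
    s = np.where((case_mean == 0) ^ (ctrl_mean == 0), np.inf, s)
    return s


def permutation_test(t: CountTable, labels: LabelAssignment,
                     n_perm: int = 10_000, seed: int = 0,
                     exhaustive: bool = False) -> DAResult:
    """Label-permutation test on relative abundances.

    The statistic S = log(mean cases / mean controls)² is recomputed
    under random case/control relabelings (the same permutation set is
    reused across all OTUs); p = proportion of permuted S >= observed S.
    With ``exhaustive=True`` every distinct case subset is enumerated
    instead of sampling, giving exact permutation p-values.
    """
    rel = to_relative_abundance(t).counts if t.is_raw else t.counts
    n, n_cases = t.n_samples, labels.n_cases
    if exhaustive:
        combos = list(itertools.combinations(range(n), n_cases))
        masks = np.zeros((len(combos), n), dtype=bool)
        for k, idx in enumerate(combos):
            masks[k, list(idx)] = True
        obs_col = combos.index(tuple(np.flatnonzero(labels.status)))
        perm_cols = slice(None)
    else:
        sampled = _perm_case_masks(n, n_cases, n_perm,
                                   np.random.default_rng(seed))
        # observed labels share the matrix path of the permutations so
        # that S_perm == S_obs comparisons are float-exact
        masks = np.vstack([labels.status, sampled])
        obs_col, perm_cols = 0, slice(1, None)
    w_case = masks.T / n_cases           # (samples, perms)
    w_ctrl = (~masks).T / (n - n_cases)
    s_all = _log_ratio_sq(rel @ w_case, rel @ w_ctrl)  # (otus, perms)
    obs = s_all[:, obs_col]
    s_perm = s_all[:, perm_cols]
    # ">= observed" with float-noise-tolerant tie detection: symmetric
    # label splits produce mathematically identical statistics that can
    # differ in the last ulp
    with np.errstate(invalid="ignore"):
        ge = (s_perm > obs[:, None]) | np.isclose(s_perm, obs[:, None],
                                                  rtol=1e-9, atol=1e-12)
    ge |= np.isposinf(s_perm) & np.isposinf(obs)[:, None]
    p = ge.mean(axis=1)
    stat = np.where(np.isfinite(obs), obs, np.nan)
    return DAResult("permutation", list(t.otu_ids), _fill_missing(p), stat,
                    meta={"n_perm": s_perm.shape[1], "exhaustive": exhaustive,
                          "seed": seed})


# ---------------------------------------------------------------------------
# Registry and dispatch


@dataclass
class MethodSpec:
    """A registered DA method.

    Built-in methods carry a callable ``(table, labels, **kw) -> DAResult``;
    external methods carry a subprocess ``command`` following the plugin
    protocol (argv gets the count-table TSV and labels TSV paths appended;
    stdout must be a two-column TSV ``otu_id<TAB>p``).
    """

    name: str
    input_scale: str = "raw"  # raw | relative | log_relative
    func: Callable | None = None
    command: list[str] | None = None
    is_builtin: bool = True


_REGISTRY: dict[str, MethodSpec] = {}


def register_method(spec: MethodSpec, overwrite: bool = False):
    if spec.name in _REGISTRY and not overwrite:
        raise ValueError(f"method {spec.name!r} already registered")
    _REGISTRY[spec.name] = spec


def get_method(name: str) -> MethodSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown method {name!r}; registered: {sorted(_REGISTRY)}") from None


def list_methods() -> list[str]:
    return sorted(_REGISTRY)


def run_method(spec: MethodSpec | str, t: CountTable, labels: LabelAssignment,
               **kwargs) -> DAResult:
    """Dispatch a method and enforce the missing-p rule and shape contract."""
    if isinstance(spec, str):
        spec = get_method(spec)
    t0 = time.perf_counter()
    error = None
    if spec.func is not None:
        try:
            result = spec.func(t, labels, **kwargs)
        except Exception as exc:  # a failed run is recorded, not dropped
            logger.warning("method %s failed: %s", spec.name, exc)
            result, error = None, str(exc)
    else:
        result, error = _run_plugin(spec, t, labels)
    if result is None:
        p = np.ones(t.n_otus)
        result = DAResult(spec.name, list(t.otu_ids), p)
        result.meta["error"] = error
    # align to the table's OTU set; absent OTUs get p = 1
    if result.otu_ids is None:
        result.otu_ids = list(t.otu_ids)
    elif list(result.otu_ids) != list(t.otu_ids):
        lookup = dict(zip(result.otu_ids, result.p))
        result.p = np.array([lookup.get(o, np.nan) for o in t.otu_ids])
        result.otu_ids = list(t.otu_ids)
        result.statistic = None
    result.p = _fill_missing(result.p)
    result.method_name = spec.name
    result.meta.setdefault("runtime_s", time.perf_counter() - t0)
    if error:
        result.meta["error"] = error
    return result


def _run_plugin(spec: MethodSpec, t: CountTable, labels: LabelAssignment):
    """Invoke an external method subprocess per the plugin protocol."""
    with tempfile.TemporaryDirectory() as tmp:
        tdir = Path(tmp)
        table_path = tdir / "table.tsv"
        labels_path = tdir / "labels.tsv"
        write_count_table(t, table_path)
        pd.DataFrame({
            "sample_id": labels.sample_ids,
            "status": ["case" if c else "control" for c in labels.status],
        }).to_csv(labels_path, sep="\t", index=False)
        try:
            proc = subprocess.run(
                list(spec.command) + [str(table_path), str(labels_path)],
                capture_output=True, text=True, check=True)
            rows = [ln.split("\t") for ln in proc.stdout.splitlines() if ln.strip()]
            otu_ids = [r[0] for r in rows]
            p = np.array([float(r[1]) for r in rows])
            return DAResult(spec.name, otu_ids, _fill_missing(p)), None
        except Exception as exc:
            logger.warning("plugin %s failed: %s", spec.name, exc)
            return None, str(exc)


for _spec in [
    MethodSpec("ttest", "relative", func=t_test_relative),
    MethodSpec("log_ttest", "log_relative", func=t_test_log),
    MethodSpec("wilcoxon", "relative", func=wilcoxon_relative),
    MethodSpec("nb_glm", "raw", func=nb_glm),
    MethodSpec("permutation", "relative", func=permutation_test),
]:
    register_method(_spec)

#: The full 13-variant method roster of the benchmark design: 5
#: built-ins plus 8 external (plugin) methods.  Used for grid
#: bookkeeping; the external entries require registered plugin commands
#: to actually run.
FULL_METHOD_ROSTER = (
    "metagenomeseq_zig", "metagenomeseq_zig_filtered", "metagenomeseq_feature",
    "bayseq", "deseq2", "edger", "nb_glm", "ttest", "log_ttest", "wilcoxon",
    "permutation", "aldex2_welch", "aldex2_wilcoxon",
)
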