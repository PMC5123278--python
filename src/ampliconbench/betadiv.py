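"""Beta-diversity optimization grid.

Pipeline per grid cell: library-size normalization → count
transformation → distance metric → PERMANOVA, scored by the model R²
for a chosen design variable (optionally with permutations restricted
within strata for repeated-measures designs).

Normalizations: none, TSS (relative abundance), CSS (cumulative sum
scaling with a data-driven quantile), TMM (trimmed mean of M-values)
and median-of-ratios size factors — the latter three implemented here
from their published procedures, since they are part of the grid under
study.  CSS and size factors are per-sample divisors that carry depth;
TMM factors follow the effective-library-size convention (the table is
divided by the relative effective library size L_j·f_j, normalized to
geometric mean 1), because pure TMM factors have geometric mean one and
deliberately exclude depth.

Transformations: natural log with pseudocount (values corrected by
−log(c) for c < 1 so zeros map to zero), square root, cubic root.

Distances: Bray-Curtis, Euclidean, Jensen-Shannon divergence (natural
log, no square root), unweighted UniFrac and normalized weighted
UniFrac (both require a rooted tree covering the OTUs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

from .core import CountTable, PhyloTree, SampleMetadata, library_sizes

NORMALIZATIONS = ("none", "tss", "css", "tmm", "deseq")
TRANSFORMS = ("identity", "log_pseudo", "sqrt", "cbrt")
METRICS = ("bray", "euclidean", "jsd", "unifrac", "wunifrac")
#: Metrics that are independent of library-size normalization by design.
NORMALIZATION_INVARIANT = frozenset({"jsd", "unifrac", "wunifrac"})

#: Pseudocount presets for the log transform.  The grid accepts
#: arbitrary pseudocounts; both published sets are shipped.
LOG_PSEUDOCOUNTS = (1.0, 0.01, 1e-4)
LOG_PSEUDOCOUNTS_EXTENDED = (1.0, 0.01, 1e-4, 1e-5)


class NormalizationError(ValueError):
    """Raised when a normalization is infeasible on the given table."""


@dataclass(frozen=True)
class NormalizationSpec:
    kind: str = "none"
    css_quantile: float | None = None   # override the data-driven choice
    tmm_logratio_trim: float = 0.3
    tmm_sum_trim: float = 0.05

    def __post_init__(self):
        if self.kind not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.kind!r}")
        if self.css_quantile is not None and not 0 < self.css_quantile < 1:
            raise ValueError("css_quantile must be in (0, 1)")


@dataclass(frozen=True)
class TransformSpec:
    kind: str = "identity"
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.kind not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.kind!r}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    def label(self) -> str:
        if self.kind == "log_pseudo":
            return f"log_pseudo:{self.pseudocount:g}"
        return self.kind


# ---------------------------------------------------------------------------
# Scaling factors


def deseq_size_factors(t: CountTable) -> np.ndarray:
    """Median-of-ratios size factors (sparse-data variant).

    The per-OTU reference is the geometric mean over *nonzero* counts
    only; each sample's factor is the median count/reference ratio over
    OTUs with positive reference and positive count in that sample.
    Factors are scaled to geometric mean 1.
    """
    counts = t.counts.astype(float)
    with np.errstate(divide="ignore"):
        logc = np.where(counts > 0, np.log(counts), np.nan)
    n_nonzero = (counts > 0).sum(axis=1)
    ref = np.where(n_nonzero > 0, np.exp(np.nanmean(np.where(
        counts > 0, logc, np.nan), axis=1)), 0.0)
    factors = np.empty(t.n_samples)
    for j in range(t.n_samples):
        usable = (ref > 0) & (counts[:, j] > 0)
        if not usable.any():
            raise NormalizationError(
                f"sample {t.sample_ids[j]!r} shares no nonzero OTU with the reference")
        # median on the log scale (reference-implementation convention:
        # even-length medians average log-ratios, not ratios)
        factors[j] = np.exp(np.median(np.log(counts[usable, j] / ref[usable])))
    return factors / np.exp(np.mean(np.log(factors)))


def tmm_factors(t: CountTable, logratio_trim: float = 0.3,
                sum_trim: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors.

    Reference sample = the one whose 0.75-quantile/library-size ratio is
    closest to the mean such ratio.  Per sample, the weighted trimmed
    mean of per-OTU log2 ratios (M) against the reference — trimming
    ``logratio_trim`` from each M tail and ``sum_trim`` from each
    absolute-intensity (A) tail, weighting by inverse asymptotic
    variance — gives the log2 factor.  Factors are scaled to geometric
    mean 1.  Raises :class:`NormalizationError` when extreme sparsity
    leaves no overlapping nonzero OTUs to compare.
    """
    counts = t.counts.astype(float)
    lib = library_sizes(t).astype(float)
    if np.any(lib == 0):
        raise NormalizationError("zero-depth sample")
    f75 = np.quantile(counts, 0.75, axis=0) / lib
    if np.median(f75) < 1e-20:
        ref_j = int(np.argmax(np.sqrt(counts).sum(axis=0)))
    else:
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    ref, n_r = counts[:, ref_j], lib[ref_j]

    log2f = np.zeros(t.n_samples)
    for j in range(t.n_samples):
        if j == ref_j:
            continue
        obs, n_o = counts[:, j], lib[j]
        both = (obs > 0) & (ref > 0)
        if not both.any():
            raise NormalizationError(
                f"TMM infeasible: sample {t.sample_ids[j]!r} shares no nonzero "
                f"OTU with reference {t.sample_ids[ref_j]!r}")
        o, r = obs[both], ref[both]
        m = np.log2((o / n_o) / (r / n_r))
        a = 0.5 * (np.log2(o / n_o) + np.log2(r / n_r))
        v = (n_o - o) / (n_o * o) + (n_r - r) / (n_r * r)
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = len(m)
        lo_l = np.floor(n * logratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * sum_trim) + 1
        hi_s = n + 1 - lo_s
        rm, ra = rankdata(m), rankdata(a)
        keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        if not keep.any():
            raise NormalizationError(
                f"TMM infeasible: no OTUs left after trimming for sample "
                f"{t.sample_ids[j]!r}")
        w = 1.0 / v[keep]
        f = np.sum(w * m[keep]) / np.sum(w)
        log2f[j] = f if np.isfinite(f) else 0.0
    factors = 2.0 ** log2f
    return factors / np.exp(np.mean(np.log(factors)))


def css_quantile(t: CountTable, rel: float = 0.1) -> float:
    """Data-driven CSS quantile.

    Follows the published procedure: compare each sample's nonzero-count
    quantile profile against the mean sorted-count profile and pick the
    smallest quantile at which the median absolute deviation starts
    changing by more than ``rel`` relatively, with a floor of 0.5.
    """
    counts = t.counts.astype(float)
    if np.any(counts.sum(axis=0) == 0):
        raise NormalizationError("zero-depth sample")
    smat = np.sort(counts, axis=0)
    ref = smat.mean(axis=1)  # nondecreasing
    pos = ref > 0
    if pos.sum() < 3:
        raise NormalizationError("degenerate table: reference profile nearly empty")
    ref_pos = ref[pos]
    lo = len(ref_pos)
    probs = np.linspace(0, 1, lo)
    diffs = np.empty((lo, t.n_samples))
    for j in range(t.n_samples):
        nz = counts[counts[:, j] > 0, j]
        if nz.size == 0:
            raise NormalizationError(f"sample {t.sample_ids[j]!r} is all zero")
        diffs[:, j] = ref_pos - np.quantile(nz, probs)
    diffr2 = np.median(np.abs(diffs), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        relchange = np.abs(np.diff(diffr2)) / diffr2[1:]
    hits = np.flatnonzero(relchange > rel)
    x = (hits[0] + 1) / len(diffr2) if hits.size else 0.5
    return max(float(x), 0.5)


def css_factors(t: CountTable, quantile: float | None = None,
                scaling_constant: float = 1000.0) -> np.ndarray:
    """Cumulative-sum-scaling divisors.

    factor_j = (sum of sample j's nonzero counts ≤ the *quantile*-th
    quantile of its nonzero counts) / *scaling_constant*.  The quantile
    defaults to the data-driven :func:`css_quantile` choice.
    """
    if quantile is None:
        quantile = css_quantile(t)
    counts = t.counts.astype(float)
    factors = np.empty(t.n_samples)
    for j in range(t.n_samples):
        nz = counts[counts[:, j] > 0, j]
        if nz.size == 0:
            raise NormalizationError(f"sample {t.sample_ids[j]!r} is all zero")
        qs = np.quantile(nz, quantile)
        factors[j] = nz[nz <= qs].sum() / scaling_constant
    if np.any(factors == 0):
        raise NormalizationError("CSS produced a zero scaling factor")
    return factors


def normalize(t: CountTable, spec: NormalizationSpec | str) -> CountTable:
    """Apply a library-size normalization; output carries is_raw=False."""
    if isinstance(spec, str):
        spec = NormalizationSpec(spec)
    if not t.is_raw:
        raise ValueError("normalize expects a raw count table")
    counts = t.counts.astype(float)
    lib = library_sizes(t).astype(float)
    if np.any(lib == 0):
        raise NormalizationError("zero-depth sample")
    if spec.kind == "none":
        out = counts
    elif spec.kind == "tss":
        out = counts / lib
    elif spec.kind == "css":
        out = counts / css_factors(t, quantile=spec.css_quantile)
    elif spec.kind == "tmm":
        f = tmm_factors(t, spec.tmm_logratio_trim, spec.tmm_sum_trim)
        eff = lib * f
        out = counts / (eff / np.exp(np.mean(np.log(eff))))
    elif spec.kind == "deseq":
        out = counts / deseq_size_factors(t)
    return CountTable(list(t.otu_ids), list(t.sample_ids), out, is_raw=False,
                      provenance={**t.provenance, "normalization": spec.kind})


# ---------------------------------------------------------------------------
# Transformations


def transform(t: CountTable, spec: TransformSpec | str) -> CountTable:
    """Apply a count transformation cell-wise.

    ``log_pseudo``: log(x + c); for c < 1 all values are corrected by
    subtracting log(c) so that zeros map to zero; for c = 1, log(0+1)=0
    already.  ``sqrt``/``cbrt``: fractional powers.  Negative input is
    an error.
    """
    if isinstance(spec, str):
        spec = TransformSpec(spec)
    x = t.counts.astype(float)
    if np.any(x < 0):
        raise ValueError("transform requires non-negative values")
    if spec.kind == "identity":
        y = x
    elif spec.kind == "log_pseudo":
        c = spec.pseudocount
        y = np.log(x + c)
        if c < 1:
            y = y - np.log(c)
    elif spec.kind == "sqrt":
        y = np.sqrt(x)
    elif spec.kind == "cbrt":
        y = np.cbrt(x)
    return CountTable(list(t.otu_ids), list(t.sample_ids), y, is_raw=False,
                      provenance={**t.provenance, "transform": spec.label()})


# ---------------------------------------------------------------------------
# Distances


def distance(t: CountTable, metric: str, tree: PhyloTree | None = None,
             weighted_normalized: bool = True) -> skbio.DistanceMatrix:
    """Pairwise sample distances under one metric.

    ``bray``, ``euclidean``: on the table's values as given.  ``jsd``:
    samples converted to probability vectors, Jensen-Shannon divergence
    with natural log (not its square-root metric).  ``unifrac`` /
    ``wunifrac``: phylogenetic; require a rooted tree whose tips cover
    every OTU with a nonzero count.  Weighted UniFrac defaults to the
    normalized ([0, 1]-bounded) variant.
    """
    X = t.counts.T.astype(float)  # samples × OTUs
    ids = list(t.sample_ids)
    if metric in ("bray", "euclidean"):
        cond = pdist(X, "braycurtis" if metric == "bray" else "euclidean")
    elif metric == "jsd":
        totals = X.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("all-zero sample; JSD undefined")
        cond = pdist(X / totals, "jensenshannon") ** 2  # scipy: sqrt(JSD), base e
    elif metric in ("unifrac", "wunifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a phylogenetic tree")
        present = X.sum(axis=0) > 0
        tree.require_tips(np.array(t.otu_ids)[present])
        skmetric = "unweighted_unifrac" if metric == "unifrac" else "weighted_unifrac"
        kwargs = {"normalized": weighted_normalized} if metric == "wunifrac" else {}
        dm = skbio.diversity.beta_diversity(
            skmetric, X[:, present], ids=ids,
            taxa=[o for o, keep in zip(t.otu_ids, present) if keep],
            tree=tree.tree, validate=True, **kwargs)
        return dm
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return skbio.DistanceMatrix(squareform(cond), ids=ids)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    r_squared: float
    p: float
    pseudo_f: float
    n_permutations: int


def _ss_decomposition(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(d: skbio.DistanceMatrix, groups, strata=None,
              n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA with optional strata-restricted permutations.

    R² = SS_among / SS_total from the distance decomposition (SS_total =
    Σd²/n over all pairs, SS_within pooled over groups); the p-value
    comes from pseudo-F under label permutations, shuffled only within
    strata when given.  R² is deterministic — it does not depend on the
    seed; only the p-value carries Monte-Carlo error.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    n = len(groups)
    if n != d.shape[0]:
        raise ValueError("groups length does not match distance matrix")
    d2 = np.asarray(d.data) ** 2
    a = len(uniq)

    def stats_for(g):
        ss_t, ss_w = _ss_decomposition(d2, g)
        ss_a = ss_t - ss_w
        f = (ss_a / (a - 1)) / (ss_w / (n - a)) if ss_w > 0 else np.inf
        return ss_a / ss_t if ss_t > 0 else 0.0, f

    r2, f_obs = stats_for(groups)
    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        if len(strata) != n:
            raise ValueError("strata length does not match distance matrix")
        blocks = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    exceed = 0
    for _ in range(n_perm):
        g = groups.copy()
        if strata is None:
            rng.shuffle(g)
        else:
            for idx in blocks:
                g[idx] = g[idx[rng.permutation(len(idx))]]
        _, f = stats_for(g)
        if f >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermanovaResult(float(r2), float(p), float(f_obs), n_perm)


# ---------------------------------------------------------------------------
# The grid


def beta_grid(t: CountTable, metadata: SampleMetadata, design_variable: str,
              normalizations=NORMALIZATIONS,
              transformations=None,
              metrics=METRICS,
              tree: PhyloTree | None = None,
              strata_variable: str | None = None,
              n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Full factorial sweep normalizations × transformations × metrics.

    Normalization-invariant metrics (JSD and both UniFracs) are computed
    once per transformation (on the un-normalized branch) and their rows
    replicated across normalizations, flagged ``shared=True``.  A
    failing cell (e.g. TMM infeasible at extreme sparsity) is recorded
    with an error status, never dropped silently.
    """
    if transformations is None:
        transformations = [TransformSpec("identity")] + \
            [TransformSpec("log_pseudo", c) for c in LOG_PSEUDOCOUNTS] + \
            [TransformSpec("sqrt"), TransformSpec("cbrt")]
    groups = metadata.column(design_variable, t.sample_ids)
    strata = (metadata.column(strata_variable, t.sample_ids)
              if strata_variable else None)

    normalized: dict[str, CountTable | Exception] = {}
    for norm in normalizations:
        spec = norm if isinstance(norm, NormalizationSpec) else NormalizationSpec(norm)
        try:
            normalized[spec.kind] = normalize(t, spec)
        except Exception as exc:
            normalized[spec.kind] = exc

    rows = []
    for tr in transformations:
        tr = tr if isinstance(tr, TransformSpec) else TransformSpec(tr)
        shared_cache: dict[str, tuple] = {}
        for norm_kind, nt in normalized.items():
            for metric in metrics:
                row = dict(normalization=norm_kind, transformation=tr.label(),
                           metric=metric, r2=np.nan, p=np.nan,
                           n_permutations=n_perm, status="ok",
                           shared=metric in NORMALIZATION_INVARIANT)
                if isinstance(nt, Exception) and metric not in NORMALIZATION_INVARIANT:
                    row["status"] = f"error: {nt}"
                    rows.append(row)
                    continue
                try:
                    if metric in NORMALIZATION_INVARIANT:
                        if metric not in shared_cache:
                            base = transform(normalize(t, "none"), tr)
                            dm = distance(base, metric, tree=tree)
                            res = permanova(dm, groups, strata, n_perm, seed)
                            shared_cache[metric] = (res.r_squared, res.p)
                        row["r2"], row["p"] = shared_cache[metric]
                    else:
                        dm = distance(transform(nt, tr), metric, tree=tree)
                        res = permanova(dm, groups, strata, n_perm, seed)
                        row["r2"], row["p"] = res.r_squared, res.p
                except Exception as exc:
                    row["status"] = f"error: {exc}"
                rows.append(row)
    return pd.DataFrame(rows)


def best_cell(grid: pd.DataFrame) -> pd.Series:
    """The grid row with the highest R² among successful cells."""
    ok = grid[grid["status"] == "ok"]
    if ok.empty:
        raise ValueError("no successful grid cells")
    return ok.loc[ok["r2"].idxmax()]


# ---------------------------------------------------------------------------
# Phylogenetic agglomeration


def agglomerate_otus(t: CountTable, tree: PhyloTree, quantile: float = 0.001):
    """Merge OTUs closer (cophenetic distance) than a distance quantile.

    Clusters are connected components of the under-threshold graph
    (single-linkage closure); member counts are summed; the cluster id
    is the member with the highest total count (ties broken
    lexicographically).  Returns ``(table, merge_map)`` with merge_map:
    archetype id -> list of merged member ids.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    tree.require_tips(t.otu_ids)
    dm = tree.tip_distances().filter(t.otu_ids)
    order = [dm.index(o) for o in t.otu_ids]
    d = np.asarray(dm.data)[np.ix_(order, order)]
    cond = d[np.triu_indices(t.n_otus, 1)]
    # "lower" order statistic: a vanishing quantile gives the minimum
    # distance, which under the strict < rule merges nothing
    threshold = np.quantile(cond, quantile, method="lower")
    adj = csr_matrix(d < threshold)
    n_comp, labels = connected_components(adj, directed=False)

    totals = t.counts.sum(axis=1)
    merged_counts, archetype_rows, merge_map = [], [], {}
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        # archetype: highest total count, then lexicographic id
        best = min(members, key=lambda i: (-totals[i], t.otu_ids[i]))
        merged_counts.append(t.counts[members].sum(axis=0))
        archetype_rows.append(best)
        merge_map[t.otu_ids[best]] = [t.otu_ids[i] for i in members]
    # preserve original row order of archetypes
    row_order = np.argsort(archetype_rows)
    counts = np.array(merged_counts)[row_order]
    ids = [t.otu_ids[archetype_rows[k]] for k in row_order]
    out = CountTable(ids, list(t.sample_ids), counts, is_raw=t.is_raw,
                     provenance={**t.provenance, "agglomeration_quantile": quantile})
    return out, merge_map
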