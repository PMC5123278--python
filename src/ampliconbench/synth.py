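"""Synthetic OTU tables with realistic marker-gene survey pathologies.

The generator emulates the three characteristics that make 16S count
data hard to analyse: high sparsity (typically 80–95% zeros), library
sizes varying by orders of magnitude, and an overdispersed
mean-variance relationship.  Counts follow a gamma-Poisson (negative
binomial) model per OTU: OTU mean proportions decay as a power law in
abundance rank, per-sample depths are log-normal, and a per-cell gamma
multiplier with dispersion ``phi`` produces variance ``mu + phi*mu^2``
conditional on depth.  Sparsity arises from small means plus
overdispersion, not from an explicit zero-inflation knob: the power-law
exponent is tempered by root-finding on the closed-form negative
binomial zero probability until the expected zero fraction matches
``target_sparsity`` given the drawn depths.

Also provides the within-OTU permutation null (each OTU row permuted
independently across samples, preserving all OTU-marginal statistics
while destroying within-sample structure) and seeded sample subsetting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize

from .core import CountTable


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the gamma-Poisson table generator.

    Defaults produce a 1000 OTU × 100 sample table at ~85% sparsity with
    log-normal depths around 3×10⁴ reads (sd of log depth = 1, so depths
    span roughly two orders of magnitude) and dispersion 0.5.
    """

    n_otus: int = 1000
    n_samples: int = 100
    target_sparsity: float = 0.85
    library_size_log_mean: float = float(np.log(3e4))
    library_size_log_sd: float = 1.0
    otu_mean_tail_exponent: float = 1.5
    dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_otus < 3:
            raise ValueError("n_otus must be >= 3 (tertiles must be formable)")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0 < self.target_sparsity < 1:
            raise ValueError("target_sparsity must be in (0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.otu_mean_tail_exponent <= 0:
            raise ValueError("otu_mean_tail_exponent must be > 0")

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _expected_sparsity(gamma: float, base_exponent: float, n_otus: int,
                       libsizes: np.ndarray, phi: float) -> float:
    """Closed-form expected zero fraction at tempering *gamma*.

    Conditional on each OTU row being non-empty (the generator redraws
    all-zero rows, since a real OTU table never contains an OTU with no
    observed reads): with NB zero probability p0_ij and row-empty
    probability Pall_i = prod_j p0_ij, the expected zero count of row i
    is (sum_j p0_ij - n·Pall_i)/(1 - Pall_i).
    """
    n = len(libsizes)
    ranks = np.arange(1, n_otus + 1, dtype=float)
    q = ranks ** (-base_exponent * gamma)
    q /= q.sum()
    mu = np.outer(q, libsizes)  # (otus, samples)
    logp0 = (-1.0 / phi) * np.log1p(phi * mu)
    s = (-np.expm1(logp0)).sum(axis=1)        # expected nonzero cells per row
    one_minus_pall = -np.expm1(logp0.sum(axis=1))
    # zeros_i | row non-empty = n - s_i / (1 - Pall_i), numerically stable
    zeros = n - s / np.maximum(one_minus_pall, 1e-300)
    return float(zeros.sum() / (n * n_otus))


def generate_table(cfg: SynthConfig) -> CountTable:
    """Generate a raw integer CountTable under *cfg*; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    libsizes = np.round(
        rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd, cfg.n_samples)
    ).astype(np.int64)
    libsizes = np.maximum(libsizes, 1)

    # temper the power-law exponent so the expected NB zero fraction hits target
    f = lambda g: _expected_sparsity(g, cfg.otu_mean_tail_exponent, cfg.n_otus,
                                     libsizes.astype(float), cfg.dispersion) - cfg.target_sparsity
    lo, hi = 0.05, 6.0
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            "infeasible config: target_sparsity %.3f not reachable "
            "(attainable range [%.3f, %.3f])"
            % (cfg.target_sparsity, flo + cfg.target_sparsity, fhi + cfg.target_sparsity)
        )
    gamma = optimize.brentq(f, lo, hi, xtol=1e-4)

    ranks = np.arange(1, cfg.n_otus + 1, dtype=float)
    q = ranks ** (-cfg.otu_mean_tail_exponent * gamma)
    q /= q.sum()
    # feasibility of the non-empty-row condition: the rarest OTU must
    # have a workable chance of being observed at all
    mu_all = np.outer(q, libsizes.astype(float))
    log_pall = ((-1.0 / cfg.dispersion) * np.log1p(cfg.dispersion * mu_all)).sum(axis=1)
    if (-np.expm1(log_pall)).min() < 1e-2:
        raise ValueError(
            "infeasible config: target_sparsity %.3f would require OTUs too "
            "rare to ever be observed; lower the target or enlarge the table"
            % cfg.target_sparsity)
    rng.shuffle(q)  # abundance rank decoupled from row order

    shape = 1.0 / cfg.dispersion
    g = rng.gamma(shape, cfg.dispersion, size=(cfg.n_otus, cfg.n_samples))
    mu = np.outer(q, libsizes.astype(float))
    counts = rng.poisson(mu * g)
    # every OTU of a real table is observed at least once: redraw empty rows
    for _ in range(1000):
        empty = np.flatnonzero(counts.sum(axis=1) == 0)
        if empty.size == 0:
            break
        g_new = rng.gamma(shape, cfg.dispersion, size=(empty.size, cfg.n_samples))
        counts[empty] = rng.poisson(mu[empty] * g_new)
    else:
        raise ValueError("infeasible config: could not populate all OTU rows")

    otu_ids = [f"OTU_{i:04d}" for i in range(1, cfg.n_otus + 1)]
    sample_ids = [f"S{j:03d}" for j in range(1, cfg.n_samples + 1)]
    return CountTable(
        otu_ids, sample_ids, counts, is_raw=True,
        provenance={"generator": "gamma-poisson", "seed": cfg.seed,
                    "config": asdict(cfg), "config_hash": cfg.digest(),
                    "tempering_exponent": round(gamma, 6)},
    )


def estimate_dispersion(t: CountTable, max_share: float = 0.02,
                        min_mean: float = 1.0) -> float:
    """Method-of-moments estimate of the gamma-Poisson dispersion.

    Per OTU, fitted means given depth are mu_ij = q_i * L_j (q_i the
    OTU's pooled proportion) and phi_i = sum((c-mu)^2 - mu)/sum(mu^2);
    the estimate is the median phi_i over informative OTUs.  OTUs whose
    mean relative abundance exceeds ``max_share`` are excluded because
    their relative-abundance fluctuations are compositionally coupled
    to the library size itself; OTUs with depth-standardized mean below
    ``min_mean`` carry almost no variance information.
    """
    L = t.counts.sum(axis=0).astype(float)
    c = t.counts.astype(float)
    q = c.sum(axis=1) / L.sum()
    mu = np.outer(q, L)
    with np.errstate(invalid="ignore"):
        phi_i = ((c - mu) ** 2 - mu).sum(axis=1) / np.maximum((mu ** 2).sum(axis=1), 1e-12)
    m = (c / L * L.mean()).mean(axis=1)
    keep = (q < max_share) & (m > min_mean)
    if not keep.any():
        raise ValueError("no informative OTUs for dispersion estimation")
    return float(np.median(phi_i[keep]))


def permute_within_otus(t: CountTable, seed: int) -> CountTable:
    """Independently permute each OTU row across samples (null dataset).

    Preserves every OTU-marginal statistic exactly (per-OTU mean,
    variance, sparsity) while breaking within-sample structure, so any
    case/control split of the result satisfies the null hypothesis.
    """
    if not t.is_raw:
        raise ValueError("within-OTU permutation requires a raw table")
    rng = np.random.default_rng(seed)
    order = rng.random(t.counts.shape).argsort(axis=1)
    permuted = np.take_along_axis(t.counts, order, axis=1)
    return t.copy(counts=permuted,
                  provenance={**t.provenance, "within_otu_permutation_seed": seed})


def subset_samples(t: CountTable, n: int, seed: int, drop_empty: bool = False) -> CountTable:
    """Select *n* distinct samples uniformly without replacement.

    Column order follows the original table.  All-zero OTU rows are kept
    unless ``drop_empty``; the seed is recorded in output provenance.
    """
    if n > t.n_samples:
        raise ValueError(f"cannot subset {n} samples from {t.n_samples}")
    if n < 2:
        raise ValueError("subset must keep at least 2 samples")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(t.n_samples, size=n, replace=False))
    counts = t.counts[:, idx]
    otu_ids = list(t.otu_ids)
    if drop_empty:
        keep = counts.sum(axis=1) > 0
        counts = counts[keep]
        otu_ids = [o for o, k in zip(otu_ids, keep) if k]
    return CountTable(
        otu_ids, [t.sample_ids[j] for j in idx], counts, is_raw=t.is_raw,
        provenance={**t.provenance, "subset_seed": seed, "subset_n": n},
    )
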