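"""Evaluation statistics and experiment grid runners.

Two experiment arms share a contract: within an iteration of a grid
cell, every method sees the identical label assignment (and, for the
spike arm, the identical spiked table and truth set), so method
comparisons are paired.  Per-iteration seeds are derived from the
master seed via ``numpy.random.SeedSequence`` spawn keys indexed by
(dataset, case proportion, iteration[, spike config]), never from
global state, so any single record can be reproduced in isolation.

Metrics:

* FPR — fraction of OTUs with crude p < 0.05 under null (permuted)
  labels;
* spike-retrieval AUC — the Mann-Whitney probability that a spiked OTU
  receives a lower p-value than a non-spiked one (ties count 1/2);
* spiked-OTU p-value quantile and the sparsity-vs-p diagnostic table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import CountTable, sparsity
from .da import DAResult, run_method
from .spike import SpikeConfig, assign_labels, run_spike

ALPHA = 0.05  # fixed by definition of the FPR; do not tune


def fpr(p: np.ndarray, alpha: float = ALPHA) -> float:
    """Fraction of OTUs with p strictly below *alpha*."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return float((p < alpha).mean())


def auc_spike(p: np.ndarray, truth: np.ndarray) -> float:
    """ROC AUC for retrieving spiked OTUs from p-values.

    Orientation: lower p = spiked.  Equals the Mann-Whitney probability
    that a random spiked OTU has lower p than a random non-spiked OTU,
    with ties counted 1/2 (mid-rank).
    """
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if p.shape != truth.shape:
        raise ValueError("p and truth shapes differ")
    n1, n0 = int(truth.sum()), int((~truth).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("truth must contain both spiked and non-spiked OTUs")
    ranks = rankdata(p)  # mid-ranks
    r_spiked = ranks[truth].sum()
    u = n1 * n0 + n1 * (n1 + 1) / 2 - r_spiked  # #(p_spiked < p_non) + ties/2
    return float(u / (n1 * n0))


def spike_quantile(p: np.ndarray, otu_index: int) -> float:
    """p-value quantile of one OTU within all OTUs (mean rank for ties)."""
    p = np.asarray(p, dtype=float)
    ranks = rankdata(p)
    return float(ranks[otu_index] / len(p))


def sparsity_p_table(result: DAResult, t: CountTable) -> pd.DataFrame:
    """Join per-OTU sparsity with p-values (the sparsity-bias diagnostic)."""
    if list(result.otu_ids) != list(t.otu_ids):
        raise ValueError("otu_ids of result and table do not match")
    return pd.DataFrame({
        "otu_id": t.otu_ids,
        "sparsity": sparsity(t, "per_otu"),
        "p": result.p,
    })


# ---------------------------------------------------------------------------
# Experiment grids


@dataclass
class ExperimentGrid:
    """A factorial benchmark design.

    ``datasets`` maps dataset id -> CountTable (or is just a list of ids
    for dry-run bookkeeping).  For the spike arm, ``spike_configs``
    holds one :class:`SpikeConfig` per configuration cell.
    """

    datasets: dict | list
    case_proportions: tuple[float, ...] = (0.10, 0.25, 0.50)
    n_iterations: int = 150
    methods: tuple[str, ...] = ("ttest", "wilcoxon", "permutation")
    spike_configs: tuple[SpikeConfig, ...] | None = None
    master_seed: int = 0
    method_kwargs: dict = field(default_factory=dict)

    @property
    def dataset_ids(self) -> list[str]:
        if isinstance(self.datasets, dict):
            return list(self.datasets)
        return list(self.datasets)

    def iteration_seed(self, d: int, prop_i: int, it: int, extra: int | None = None) -> int:
        """Derive a per-iteration seed; independent of method by design."""
        key = (d, prop_i, it) if extra is None else (d, prop_i, it, extra)
        ss = np.random.SeedSequence(self.master_seed, spawn_key=key)
        return int(ss.generate_state(1)[0] % (2**31))


def grid_size(grid: ExperimentGrid) -> int:
    """Number of planned DA runs, without executing anything."""
    n = (len(grid.dataset_ids) * len(grid.case_proportions)
         * grid.n_iterations * len(grid.methods))
    if grid.spike_configs is not None:
        n *= len(grid.spike_configs)
    return n


def default_spike_configs(otus_per_tertile: int = 5) -> tuple[SpikeConfig, ...]:
    """The 10 spike configurations of the reference design: five
    multiplicative magnitudes, four additive, one mixed."""
    from .spike import MULTIPLICATIVE_MAGNITUDES, ADDITIVE_MAGNITUDES
    cfgs = [SpikeConfig("multiplicative", m, otus_per_tertile=otus_per_tertile)
            for m in MULTIPLICATIVE_MAGNITUDES]
    cfgs += [SpikeConfig("additive", m, otus_per_tertile=otus_per_tertile)
             for m in ADDITIVE_MAGNITUDES]
    cfgs.append(SpikeConfig("mixed", otus_per_tertile=otus_per_tertile))
    return tuple(cfgs)


def _method_kwargs(grid: ExperimentGrid, method: str, seed: int) -> dict:
    kw = dict(grid.method_kwargs.get(method, {}))
    if method == "permutation":
        kw.setdefault("seed", seed)
    return kw


def _fpr_cell(grid: ExperimentGrid, ds_id: str, d: int, pi: int, it: int) -> list[dict]:
    """One (dataset × proportion × iteration) cell of the FPR arm.

    Pure function of the grid and indices, so cells can run in any
    order or in parallel with identical results.
    """
    table = grid.datasets[ds_id]
    prop = grid.case_proportions[pi]
    seed = grid.iteration_seed(d, pi, it)
    labels = assign_labels(table, prop, seed)
    rows = []
    for method in grid.methods:
        row = dict(dataset=ds_id, method=method, proportion=prop,
                   iteration=it, seed=seed, metric="fpr",
                   value=np.nan, status="ok")
        try:
            res = run_method(method, table, labels,
                             **_method_kwargs(grid, method, seed))
            if res.meta.get("error"):
                row["status"] = f"error: {res.meta['error']}"
            else:
                row["value"] = fpr(res.p)
        except Exception as exc:
            row["status"] = f"error: {exc}"
        rows.append(row)
    return rows


def _spike_cell(grid: ExperimentGrid, ds_id: str, d: int, pi: int, it: int,
                strict: bool) -> list[dict]:
    """One (dataset × proportion × iteration) cell of the spike arm,
    covering every spike configuration and method."""
    table = grid.datasets[ds_id]
    prop = grid.case_proportions[pi]
    label_seed = grid.iteration_seed(d, pi, it)
    labels = assign_labels(table, prop, label_seed)
    rows = []
    for ci, cfg in enumerate(grid.spike_configs):
        spike_seed = grid.iteration_seed(d, pi, it, extra=ci)
        cfg_seeded = SpikeConfig(cfg.scheme, cfg.magnitude, cfg.magnitude_set,
                                 cfg.otus_per_tertile, spike_seed)
        base = dict(dataset=ds_id, proportion=prop, scheme=cfg.scheme,
                    magnitude=cfg.magnitude, iteration=it, seed=label_seed,
                    metric="auc")
        try:
            sp = run_spike(table, labels, cfg_seeded, strict=strict)
        except Exception as exc:
            rows.extend(dict(base, method=m, value=np.nan,
                             status=f"error: {exc}") for m in grid.methods)
            continue
        truth = sp.truth_mask()
        for method in grid.methods:
            row = dict(base, method=method, value=np.nan, status="ok")
            try:
                res = run_method(method, sp.table, labels,
                                 **_method_kwargs(grid, method, label_seed))
                if res.meta.get("error"):
                    row["status"] = f"error: {res.meta['error']}"
                else:
                    row["value"] = auc_spike(res.p, truth)
            except Exception as exc:
                row["status"] = f"error: {exc}"
            rows.append(row)
    return rows


def _run_cells(cell_fn, cells, n_jobs: int) -> pd.DataFrame:
    if n_jobs == 1:
        chunks = [cell_fn(*c) for c in cells]
    else:
        from joblib import Parallel, delayed
        chunks = Parallel(n_jobs=n_jobs)(delayed(cell_fn)(*c) for c in cells)
    return pd.DataFrame([row for chunk in chunks for row in chunk])


def run_fpr_experiment(grid: ExperimentGrid, n_jobs: int = 1) -> pd.DataFrame:
    """Null-label FPR experiment: one shared random label assignment per
    (dataset × proportion × iteration), every method run on it."""
    cells = [(grid, ds_id, d, pi, it)
             for d, ds_id in enumerate(grid.dataset_ids)
             for pi in range(len(grid.case_proportions))
             for it in range(grid.n_iterations)]
    return _run_cells(_fpr_cell, cells, n_jobs)


def run_spike_experiment(grid: ExperimentGrid, strict: bool = True,
                         n_jobs: int = 1) -> pd.DataFrame:
    """Spike-retrieval experiment: label + spike between randomization and
    testing; AUC per (method × spike config × proportion × iteration).

    Truth sets differ across iterations but are identical across
    methods within an iteration.
    """
    if grid.spike_configs is None:
        raise ValueError("grid.spike_configs is required for the spike arm")
    cells = [(grid, ds_id, d, pi, it, strict)
             for d, ds_id in enumerate(grid.dataset_ids)
             for pi in range(len(grid.case_proportions))
             for it in range(grid.n_iterations)]
    return _run_cells(_spike_cell, cells, n_jobs)


def summarize(records: pd.DataFrame, by=("dataset", "method", "proportion")) -> pd.DataFrame:
    """Median metric per group, skipping errored rows (count reported)."""
    ok = records[records["status"] == "ok"]
    by = [b for b in by if b in records.columns]
    agg = ok.groupby(by, dropna=False)["value"].median().rename("median_value").reset_index()
    n_err = (records["status"] != "ok").groupby(
        [records[b] for b in by]).sum().rename("n_errored").reset_index()
    return agg.merge(n_err, on=by, how="left")
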