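"""In-silico spike-in engine with exact truth tracking.

Case/control labels are drawn at random (so, before spiking, the null
hypothesis holds by construction).  Selected OTUs — drawn from the low,
mid and high tertiles of overall mean relative abundance, restricted to
OTUs present in at least one case sample — are then inflated in case
samples only, by one of three schemes:

multiplicative
    counts × magnitude;
additive
    each nonzero case count gains round(m · magnitude · depth), where m
    is the OTU's mean relative abundance over its nonzero samples
    (zeros stay zero);
mixed
    multiplicative with a per-OTU magnitude cycled from a shuffled
    magnitude set.

After spiking, every case sample is rescaled to its original sequencing
depth with largest-remainder integer apportionment, so library sizes
are conserved exactly and control samples are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CountTable, library_sizes, to_relative_abundance

MULTIPLICATIVE_MAGNITUDES = (0.5, 2.0, 5.0, 10.0, 20.0)
ADDITIVE_MAGNITUDES = (0.5, 2.0, 5.0, 10.0)
TERTILES = ("low", "mid", "high")


@dataclass
class LabelAssignment:
    """Case/control status per sample, plus the seed that produced it."""

    sample_ids: list[str]
    status: np.ndarray  # bool, True = case
    case_proportion: float
    seed: int

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=bool)
        if self.status.sum() < 1 or (~self.status).sum() < 1:
            raise ValueError("need at least one case and one control")

    @property
    def case_ids(self) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.status) if c]

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())


@dataclass(frozen=True)
class SpikeConfig:
    """One spike-in configuration cell of the experiment grid."""

    scheme: str  # multiplicative | additive | mixed
    magnitude: float | None = None
    magnitude_set: tuple[float, ...] = MULTIPLICATIVE_MAGNITUDES[1:]
    otus_per_tertile: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("multiplicative", "additive", "mixed"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme != "mixed" and (self.magnitude is None or self.magnitude <= 0):
            raise ValueError("magnitude must be a positive number")
        if self.scheme == "mixed" and not self.magnitude_set:
            raise ValueError("magnitude_set must be non-empty")
        if self.otus_per_tertile < 1:
            raise ValueError("otus_per_tertile must be >= 1")

    def label(self) -> str:
        if self.scheme == "mixed":
            return "mixed"
        return f"{self.scheme}:{self.magnitude:g}"


@dataclass
class SpikeResult:
    """Spiked table plus the exact truth set.

    ``truth`` maps otu_id -> (tertile, applied magnitude).  Library
    sizes of the spiked table equal ``original_library_sizes`` exactly.
    """

    table: CountTable
    truth: dict[str, tuple[str, float]]
    labels: LabelAssignment
    original_library_sizes: np.ndarray
    lenient_shortfall: bool = False

    def truth_mask(self) -> np.ndarray:
        spiked = set(self.truth)
        return np.array([o in spiked for o in self.table.otu_ids])


def assign_labels(t: CountTable, case_proportion: float, seed: int) -> LabelAssignment:
    """Randomly select ``max(1, round(p·n))`` samples as cases."""
    if not 0 < case_proportion < 1:
        raise ValueError("case_proportion must be in (0, 1)")
    n = t.n_samples
    n_cases = max(1, int(np.floor(case_proportion * n + 0.5)))
    if n_cases >= n:
        raise ValueError("rounding leaves no control samples")
    rng = np.random.default_rng(seed)
    case_idx = rng.choice(n, size=n_cases, replace=False)
    status = np.zeros(n, dtype=bool)
    status[case_idx] = True
    return LabelAssignment(list(t.sample_ids), status, case_proportion, seed)


def _tertile_slices(order: np.ndarray) -> dict[str, np.ndarray]:
    """Split OTU indices (ascending mean relative abundance) into tertiles.

    When n % 3 != 0 the remainder goes to the lower tertiles.
    """
    n = len(order)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if k < rem else 0) for k in range(3)]
    out, start = {}, 0
    for name, size in zip(TERTILES, sizes):
        out[name] = order[start:start + size]
        start += size
    return out


def select_spike_targets(t: CountTable, labels: LabelAssignment,
                         otus_per_tertile: int = 5, seed: int = 0,
                         strict: bool = True) -> list[tuple[str, str]]:
    """Draw spike targets: *otus_per_tertile* eligible OTUs per tertile.

    OTUs are ranked by overall mean relative abundance (ties broken by
    lexicographic OTU id) and split low/mid/high; only OTUs present in
    at least one case sample are eligible.  In strict mode a tertile
    with too few eligible OTUs raises; in lenient mode all its eligible
    OTUs are taken.
    """
    rel = to_relative_abundance(t).counts
    mean_rel = rel.mean(axis=1)
    ids = np.array(t.otu_ids)
    order = np.lexsort((ids, mean_rel))  # ascending abundance, id tiebreak
    eligible = (t.counts[:, labels.status] > 0).any(axis=1)
    rng = np.random.default_rng(seed)
    targets: list[tuple[str, str]] = []
    for tertile, idx in _tertile_slices(order).items():
        pool = idx[eligible[idx]]
        if len(pool) < otus_per_tertile:
            if strict:
                raise ValueError(
                    f"tertile {tertile!r} has only {len(pool)} eligible OTUs "
                    f"(requested {otus_per_tertile})"
                )
            chosen = pool
        else:
            chosen = rng.choice(pool, size=otus_per_tertile, replace=False)
        targets.extend((t.otu_ids[i], tertile) for i in sorted(chosen))
    return targets


def rescale_to_depth(sample_counts: np.ndarray, original_depth: int) -> np.ndarray:
    """Rescale a count vector to sum exactly to *original_depth*.

    Proportional up to integer rounding, using largest-remainder
    apportionment (remainder ties broken by lower index).  Zeros map to
    zeros.
    """
    v = np.asarray(sample_counts, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot rescale an all-zero sample")
    if original_depth <= 0:
        raise ValueError("original_depth must be positive")
    scaled = v * (original_depth / total)
    floor = np.floor(scaled).astype(np.int64)
    short = int(original_depth - floor.sum())
    if short:
        remainder = scaled - floor
        # stable sort on negated remainder: ties resolved by lower index
        order = np.argsort(-remainder, kind="stable")
        floor[order[:short]] += 1
    return floor


def _finalize(t: CountTable, raw: np.ndarray, labels: LabelAssignment,
              truth: dict, depths: np.ndarray, lenient=False) -> SpikeResult:
    counts = raw.copy()
    for j in np.flatnonzero(labels.status):
        counts[:, j] = rescale_to_depth(counts[:, j], int(depths[j]))
    spiked = t.copy(counts=counts.astype(np.int64),
                    provenance={**t.provenance, "spiked": sorted(truth)})
    return SpikeResult(spiked, truth, labels, depths, lenient)


def spike_multiplicative(t: CountTable, labels: LabelAssignment,
                         targets: list[tuple[str, str]],
                         magnitude: float) -> SpikeResult:
    """Multiply target OTU counts in case samples by *magnitude*, then
    rescale case samples to original depth."""
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    depths = library_sizes(t)
    work = t.counts.astype(float)
    row = {o: i for i, o in enumerate(t.otu_ids)}
    truth = {}
    for otu, tertile in targets:
        work[row[otu], labels.status] *= magnitude
        truth[otu] = (tertile, magnitude)
    return _finalize(t, work, labels, truth, depths)


def spike_additive(t: CountTable, labels: LabelAssignment,
                   targets: list[tuple[str, str]], magnitude: float) -> SpikeResult:
    """Add round(m·magnitude·depth) to each nonzero case count of each
    target OTU, with m the OTU's mean relative abundance over its
    nonzero samples (table-wide); zeros remain zero."""
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    depths = library_sizes(t)
    rel = t.counts / depths.astype(float)
    work = t.counts.astype(float)
    row = {o: i for i, o in enumerate(t.otu_ids)}
    truth = {}
    for otu, tertile in targets:
        i = row[otu]
        nonzero = t.counts[i] > 0
        if not nonzero.any():
            raise RuntimeError(f"target OTU {otu!r} is entirely zero")
        m = rel[i, nonzero].mean()
        sel = labels.status & nonzero
        work[i, sel] += np.round(m * magnitude * depths[sel].astype(float))
        truth[otu] = (tertile, magnitude)
    return _finalize(t, work, labels, truth, depths)


def spike_mixed(t: CountTable, labels: LabelAssignment,
                targets: list[tuple[str, str]],
                magnitude_set: tuple[float, ...], seed: int) -> SpikeResult:
    """Multiplicative spiking with per-OTU magnitudes cycled from a
    seeded shuffle of *magnitude_set*."""
    if not magnitude_set:
        raise ValueError("magnitude_set must be non-empty")
    rng = np.random.default_rng(seed)
    mags = list(magnitude_set)
    rng.shuffle(mags)
    depths = library_sizes(t)
    work = t.counts.astype(float)
    row = {o: i for i, o in enumerate(t.otu_ids)}
    truth = {}
    for k, (otu, tertile) in enumerate(targets):
        mag = mags[k % len(mags)]
        work[row[otu], labels.status] *= mag
        truth[otu] = (tertile, mag)
    return _finalize(t, work, labels, truth, depths)


def run_spike(t: CountTable, labels: LabelAssignment, cfg: SpikeConfig,
              strict: bool = True) -> SpikeResult:
    """Select targets and apply the configured scheme (one grid cell)."""
    targets = select_spike_targets(t, labels, cfg.otus_per_tertile,
                                   seed=cfg.seed, strict=strict)
    if cfg.scheme == "multiplicative":
        return spike_multiplicative(t, labels, targets, cfg.magnitude)
    if cfg.scheme == "additive":
        return spike_additive(t, labels, targets, cfg.magnitude)
    return spike_mixed(t, labels, targets, cfg.magnitude_set, cfg.seed)
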