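"""Splat-style scRNA-seq simulation, pseudobulk aggregation and kappa scoring.

The generator emulates group-structured differential expression: gamma
base gene means, per-group log-normal DE multipliers, log-normal library
sizes, gamma-Poisson counts, and optional experiment-wide logistic
dropout whose midpoint can be calibrated to hit a target global dropout
fraction.  Population/eQTL machinery of the original model is abstracted
into the group DE factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .templates import BulkDataset, MarkerSet, PipetError, build_templates, select_markers

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "KappaResult",
    "GROUP_PROBS",
    "simulate_sc",
    "stratified_split",
    "make_pseudobulk",
    "cohens_kappa",
    "run_consistency_experiment",
]

# grouping probabilities used throughout the simulation study
GROUP_PROBS = {
    2: (0.6, 0.4),
    3: (0.4, 0.4, 0.2),
    4: (0.2, 0.4, 0.2, 0.2),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic scRNA-seq generator."""

    n_genes: int = 5000
    n_cells: int = 5000
    group_probs: tuple[float, ...] = (0.6, 0.4)
    de_prob: float = 0.2
    de_facloc: float = 0.3
    de_facscale: float = 0.7
    de_down_prob: float = 0.5
    # each DE effect applies to a random non-empty subset of groups (every
    # group joins with this probability); subsets of size > 1 yield partially
    # shared signatures, the analogue of condition effects shared across
    # conditions, and are what makes classes confusable for k > 2
    de_condition_prob: float = 0.45
    # per-gene fraction of cells actually carrying the effect, drawn uniformly
    # from this range (the analogue of genotype dosage: a group's bulk profile
    # shows the averaged effect while only carrier cells express it)
    de_carrier_range: tuple[float, float] = (1.0, 1.0)
    # if set, DE effects land only on the top fraction of genes by base mean,
    # so markers are well expressed and nearly every cell clears the
    # permutation gate even when its class margin is ambiguous
    de_high_expr_frac: float | None = None
    # cells belong to simulated individuals; each individual scales its
    # group's log DE effects by a penetrance drawn from Beta(shape, 1), so a
    # weakly penetrant individual's cells sit near the decision boundary
    n_donors_per_group: int = 50
    donor_strength_beta: float | None = 1.15
    mean_shape: float = 8.0
    mean_rate: float = 0.3
    libsize_loc: float = 9.0
    libsize_scale: float = 0.2
    bcv_dispersion: float = 0.1
    dropout_mid: float | None = None
    dropout_shape: float = -0.2
    dropout_target: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.group_probs, dtype=float)
        if probs.ndim != 1 or len(probs) < 1:
            raise PipetError("group_probs must be a non-empty vector")
        if np.any(probs <= 0) or abs(probs.sum() - 1.0) > 1e-8:
            raise PipetError("group_probs must be positive and sum to 1")
        for name in ("de_facscale", "mean_shape", "mean_rate", "libsize_scale"):
            if getattr(self, name) <= 0:
                raise PipetError(f"{name} must be positive")
        if not 0 <= self.de_prob <= 1:
            raise PipetError("de_prob must be in [0, 1]")
        if self.dropout_target is not None and not 0 <= self.dropout_target < 1:
            raise PipetError("dropout_target must be in [0, 1)")
        if self.de_prob > 0 and self.de_facscale < 1e-12 and self.de_facloc == 0:
            warnings.warn("DE requested but factor distribution is degenerate")


@dataclass
class SimulatedDataset:
    """Synthetic counts with ground-truth group labels."""

    counts: np.ndarray  # genes x cells, non-negative integers
    gene_ids: list[str]
    cell_ids: list[str]
    true_group: np.ndarray  # per-cell class name
    split_assignment: np.ndarray | None = None  # "bulk_pool" | "test"
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def class_names(self) -> list[str]:
        return sorted(set(map(str, self.true_group)))

    def subset_cells(self, mask: np.ndarray) -> "SimulatedDataset":
        mask = np.asarray(mask)
        return SimulatedDataset(
            counts=self.counts[:, mask],
            gene_ids=list(self.gene_ids),
            cell_ids=[c for c, m in zip(self.cell_ids, mask) if m],
            true_group=np.asarray(self.true_group)[mask],
            split_assignment=None
            if self.split_assignment is None
            else np.asarray(self.split_assignment)[mask],
            params=dict(self.params),
        )


@dataclass
class KappaResult:
    """Cohen's kappa with its ingredients."""

    kappa: float
    p0: float
    pe: float
    table: pd.DataFrame  # truth rows x prediction columns
    n: int
    n_excluded: int = 0


def _dropout_prob(lam: np.ndarray, mid: float, shape: float) -> np.ndarray:
    """Logistic dropout probability as a function of the true mean."""
    with np.errstate(divide="ignore"):
        loglam = np.log(lam, where=lam > 0, out=np.full(lam.shape, -np.inf))
    return expit(shape * (loglam - mid))


def calibrate_dropout_mid(
    lam: np.ndarray, target: float, shape: float, tol: float = 1e-4
) -> float:
    """Bisection on the logistic midpoint so the expected fraction of
    entries hit by dropout equals ``target``."""
    if target <= 0:
        return -np.inf
    sample = lam.ravel()
    if sample.size > 2_000_000:
        step = sample.size // 2_000_000 + 1
        sample = sample[::step]
    lo, hi = -30.0, 30.0
    # shape < 0: dropout increases with mid
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        frac = float(_dropout_prob(sample, mid, shape).mean())
        if abs(frac - target) < tol:
            return mid
        if frac < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_sc(config: SimConfig) -> SimulatedDataset:
    """Generate a synthetic group-structured scRNA-seq count matrix."""
    rng = np.random.default_rng(config.seed)
    k = len(config.group_probs)
    n_genes, n_cells = config.n_genes, config.n_cells

    groups = rng.choice(k, size=n_cells, p=np.asarray(config.group_probs))
    base = rng.gamma(config.mean_shape, 1.0 / config.mean_rate, size=n_genes)
    base = np.maximum(base, 1e-10)

    if not 0 < config.de_condition_prob <= 1:
        raise PipetError("de_condition_prob must be in (0, 1]")
    if config.de_high_expr_frac is not None:
        if not 0 < config.de_high_expr_frac <= 1:
            raise PipetError("de_high_expr_frac must be in (0, 1]")
        n_top = max(1, int(round(config.de_high_expr_frac * n_genes)))
        eligible = np.argsort(base)[::-1][:n_top]
        p_in_pool = min(1.0, config.de_prob * n_genes / n_top)
        de_genes = eligible[rng.random(n_top) < p_in_pool]
    else:
        de_genes = np.flatnonzero(rng.random(n_genes) < config.de_prob)
    fac = np.exp(rng.normal(config.de_facloc, config.de_facscale, size=de_genes.size))
    down = rng.random(de_genes.size) < config.de_down_prob
    fac = np.where(down, 1.0 / fac, fac)
    hit = rng.random((de_genes.size, k)) < config.de_condition_prob
    empty = ~hit.any(axis=1)
    hit[empty, rng.integers(0, k, size=int(empty.sum()))] = True

    lo, hi = config.de_carrier_range
    if not 0 < lo <= hi <= 1:
        raise PipetError("de_carrier_range must satisfy 0 < low <= high <= 1")
    lib = rng.lognormal(config.libsize_loc, config.libsize_scale, size=n_cells)

    # individuals: every cell belongs to a donor of its own group; donor
    # penetrance scales the group's log effects for all of that donor's cells
    donor_of_cell = rng.integers(0, config.n_donors_per_group, size=n_cells)
    donor_of_cell += groups * config.n_donors_per_group
    if config.donor_strength_beta is not None:
        strength = rng.beta(
            config.donor_strength_beta, 1.0, size=config.n_donors_per_group * k
        )
        cell_strength = strength[donor_of_cell]
    else:
        cell_strength = np.ones(n_cells)

    mu = np.broadcast_to(base[:, None], (n_genes, n_cells)).copy()
    if de_genes.size:
        carrier_p = rng.uniform(lo, hi, size=de_genes.size)
        active = hit[:, groups]
        if hi < 1 or lo < 1:
            active = active & (
                rng.random((de_genes.size, n_cells)) < carrier_p[:, None]
            )
        log_eff = np.where(active, np.log(fac)[:, None] * cell_strength[None, :], 0.0)
        mu[de_genes] *= np.exp(log_eff)
        del active, log_eff
    mu *= lib / mu.sum(axis=0, keepdims=True)
    if config.bcv_dispersion > 0:
        # trended biological CV: common BCV plus a 1/sqrt(mean) term so that
        # weakly expressed genes are much noisier than strong ones
        bcv = config.bcv_dispersion + 1.0 / np.sqrt(np.maximum(mu, 1e-12))
        shape = 1.0 / bcv**2
        lam = rng.gamma(shape, 1.0) * mu / shape  # mean-1 gamma noise, CV = bcv
        del bcv, shape
    else:
        lam = mu
    counts = rng.poisson(lam)

    dropout_mid = config.dropout_mid
    realized_dropout = 0.0
    if config.dropout_target is not None and config.dropout_target > 0:
        dropout_mid = calibrate_dropout_mid(
            lam, config.dropout_target, config.dropout_shape
        )
    if dropout_mid is not None and np.isfinite(dropout_mid):
        p_drop = _dropout_prob(lam, dropout_mid, config.dropout_shape)
        dropped = rng.random(size=counts.shape) < p_drop
        realized_dropout = float(dropped.mean())
        counts[dropped] = 0
        del p_drop, dropped
    del mu, lam

    class_names = np.array([f"Class{j + 1}" for j in range(k)])
    return SimulatedDataset(
        counts=counts.astype(np.int32),
        gene_ids=[f"Gene{i + 1}" for i in range(n_genes)],
        cell_ids=[f"Cell{i + 1}" for i in range(n_cells)],
        true_group=class_names[groups],
        params={
            "seed": config.seed,
            "k": k,
            "group_probs": list(config.group_probs),
            "dropout_mid": None if dropout_mid is None else float(dropout_mid),
            "dropout_shape": config.dropout_shape,
            "dropout_target": config.dropout_target,
            "realized_dropout": realized_dropout,
            "zero_fraction": float((counts == 0).mean()),
        },
    )


def stratified_split(
    data: SimulatedDataset, test_fraction: float = 0.3, seed: int = 0
) -> SimulatedDataset:
    """Annotate each cell as bulk_pool or test, stratified by true group."""
    if not 0 < test_fraction < 1:
        raise PipetError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    truth = np.asarray(data.true_group)
    assignment = np.full(data.n_cells, "bulk_pool", dtype=object)
    for cls in data.class_names:
        idx = np.flatnonzero(truth == cls)
        n_test = int(round(test_fraction * len(idx)))
        test_idx = rng.permutation(idx)[:n_test]
        assignment[test_idx] = "test"
    return replace(data, split_assignment=np.asarray(assignment, dtype=object))


def make_pseudobulk(
    data: SimulatedDataset,
    samples_per_class: int = 50,
    cells_per_sample: int = 500,
    seed: int = 0,
) -> BulkDataset:
    """Aggregate random cells (with replacement) into pseudobulk samples.

    Each sample is the genewise sum of ``cells_per_sample`` cells drawn
    uniformly from the class's bulk pool.
    """
    if samples_per_class < 1 or cells_per_sample < 1:
        raise PipetError("samples_per_class and cells_per_sample must be >= 1")
    rng = np.random.default_rng(seed)
    truth = np.asarray(data.true_group)
    pool_mask = (
        np.ones(data.n_cells, dtype=bool)
        if data.split_assignment is None
        else np.asarray(data.split_assignment) == "bulk_pool"
    )
    cols, sample_ids, phenotype = [], [], []
    for cls in data.class_names:
        pool = np.flatnonzero(pool_mask & (truth == cls))
        if len(pool) == 0:
            raise PipetError(f"class {cls!r} has no cells in the bulk pool")
        for s in range(samples_per_class):
            idx = rng.choice(pool, size=cells_per_sample, replace=True)
            cols.append(data.counts[:, idx].sum(axis=1))
            sample_ids.append(f"{cls}_bulk{s + 1:02d}")
            phenotype.append(cls)
    return BulkDataset(
        counts=np.column_stack(cols).astype(np.int64),
        gene_ids=list(data.gene_ids),
        sample_ids=sample_ids,
        phenotype=phenotype,
    )


def cohens_kappa(
    truth, predicted, unassigned: str = "exclude", unassigned_label: str = "Unassigned"
) -> KappaResult:
    """Chance-corrected agreement between two label vectors.

    kappa = (P0 - Pe) / (1 - Pe) where P0 is the observed agreement and
    Pe the agreement expected from the marginals.  Cells labelled
    ``unassigned_label`` are excluded by default (``unassigned="include"``
    keeps them as their own category).
    """
    truth = np.asarray(list(map(str, truth)))
    predicted = np.asarray(list(map(str, predicted)))
    if truth.shape != predicted.shape:
        raise PipetError("truth and prediction must have equal length")
    if truth.size == 0:
        raise PipetError("empty label vectors")
    n_excluded = 0
    if unassigned == "exclude":
        keep = predicted != unassigned_label
        n_excluded = int((~keep).sum())
        truth, predicted = truth[keep], predicted[keep]
        if truth.size == 0:
            raise PipetError("all cells are unassigned; kappa undefined")
    elif unassigned != "include":
        raise PipetError(f"unknown unassigned policy {unassigned!r}")
    labels = sorted(set(truth) | set(predicted))
    table = pd.crosstab(
        pd.Categorical(truth, categories=labels),
        pd.Categorical(predicted, categories=labels),
        dropna=False,
    )
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    m = table.to_numpy(dtype=float)
    n = m.sum()
    p0 = np.trace(m) / n
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / n**2
    kappa = 1.0 if pe == 1.0 else (p0 - pe) / (1.0 - pe)
    return KappaResult(
        kappa=float(kappa), p0=float(p0), pe=float(pe),
        table=table, n=int(n), n_excluded=n_excluded,
    )


def run_consistency_experiment(
    k: int,
    dropout_target: float | None = None,
    seed: int = 0,
    config: SimConfig | None = None,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    metric: str = "cosine",
    n_perm: int = 1000,
    alpha: float = 0.05,
    gate: str = "p",
    min_cell_fraction: float = 0.0,
    samples_per_class: int = 50,
    cells_per_sample: int = 500,
) -> tuple[KappaResult, dict]:
    """Full simulation-study loop for one configuration.

    simulate -> stratified 70/30 split -> pseudobulk -> marker selection ->
    templates -> nearest-template prediction on the held-out cells ->
    Cohen's kappa against the true groups.
    """
    from .inference import predict
    from .similarity import CellMatrix, filter_genes, lognormalize

    if config is None:
        if k not in GROUP_PROBS:
            raise PipetError(f"no default group probabilities for k={k}")
        config = SimConfig(
            group_probs=GROUP_PROBS[k], dropout_target=dropout_target, seed=seed
        )
    else:
        config = replace(
            config, group_probs=GROUP_PROBS.get(k, config.group_probs),
            dropout_target=dropout_target, seed=seed,
        )

    data = simulate_sc(config)
    data = stratified_split(data, test_fraction=0.3, seed=seed + 1)
    bulk = make_pseudobulk(
        data, samples_per_class=samples_per_class,
        cells_per_sample=cells_per_sample, seed=seed + 2,
    )
    markers = select_markers(bulk, fdr_threshold, lfc_threshold)
    templates = build_templates(markers)

    test_mask = np.asarray(data.split_assignment) == "test"
    test = data.subset_cells(test_mask)
    cells = CellMatrix(
        values=test.counts, gene_ids=test.gene_ids,
        cell_ids=test.cell_ids, layer_tag="raw_counts",
    )
    cells = filter_genes(cells, min_cell_fraction)
    cells = lognormalize(cells)
    records, manifest = predict(
        cells, templates, metric=metric, n_perm=n_perm,
        seed=seed + 3, alpha=alpha, gate=gate,
    )
    pred = {r.cell_id: r.label for r in records}
    predicted = [pred[c] for c in test.cell_ids]
    result = cohens_kappa(test.true_group, predicted)
    manifest.update(
        {
            "k": k,
            "dropout_target": dropout_target,
            "realized_dropout": data.params["realized_dropout"],
            "zero_fraction": data.params["zero_fraction"],
            "marker_counts": markers.sizes,
            "n_test_cells": int(test_mask.sum()),
            "kappa": result.kappa,
            "p0": result.p0,
            "n_excluded_unassigned": result.n_excluded,
        }
    )
    return result, manifest
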