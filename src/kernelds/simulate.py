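"""Seeded multi-subject single-cell simulator for the five differential
distribution patterns.

Each (gene, cluster) unit draws per-cell expression from a one- or
two-component mixture.  Components are parametrized by their mean and
standard deviation on the observed expression scale and realized as
log-normal draws by moment matching (negative binomial optionally, for
count realism), so the defining constraints of the patterns hold exactly
at the population level:

- DE  shift of the entire distribution (component means moved by ``de_shift``);
- DP  the same two components with the mixture weight moved by ``dp_shift``;
- DM  unimodal against an equal-weight bimodal mixture;
- DB  unimodal against bimodal with *equal* group means — invisible to a
  pseudobulk mean but a clear distributional difference;
- DV  equal means with the variance scaled by ``dv_ratio``.

Each subject additionally draws a small random location offset applied to
all of its component means, mimicking biological replicate variability —
without it the multi-subject design would be exchangeable with cells.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import TestUnit

__all__ = [
    "SimulationConfig",
    "DIFFERENTIAL_TYPES",
    "simulate_unit",
    "simulate_dataset",
    "population_moments",
    "unit_seed_for",
]

DIFFERENTIAL_TYPES = ("DE", "DP", "DM", "DB", "DV")


@dataclass
class SimulationConfig:
    """Generator parameters; defaults mirror the reference study design.

    ``n_genes=4000``, three clusters, two groups of three subjects and an
    average of 200 cells per subject per cluster with 10% of genes per
    cluster differential, split equally over the five patterns.  The
    default effect sizes were calibrated once (see
    ``scripts/calibrate_effects.py``) so that the square-root pseudo-F
    test has per-pattern power between 0.3 and 0.9 at this design.  Effect
    sizes are expressed on the observed expression scale: ``de_shift``
    moves component means, ``dp_shift`` moves the mixture weight,
    ``mode_separation`` is the distance between the two modes and
    ``dv_ratio`` multiplies the variance.
    """

    n_genes: int = 4000
    n_clusters: int = 3
    subjects_per_group: int = 3
    cells_per_subject_per_cluster: int = 200
    pct_differential: float = 0.10
    type_mix: dict[str, float] = field(
        default_factory=lambda: {t: 0.2 for t in DIFFERENTIAL_TYPES}
    )
    base_mean: float = 3.0
    base_sd: float = 1.2
    de_shift: float = 0.5
    dp_shift: float = 0.2
    dp_base_weight: float = 0.3
    mode_separation: float = 1.5
    dv_ratio: float = 1.6
    subject_sd_factor: float = 0.1
    family: str = "lognormal"  # or "negative-binomial"
    effect_dilution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_differential <= 1.0:
            raise ValueError("pct_differential must be in [0, 1]")
        for name in ("n_genes", "n_clusters", "subjects_per_group",
                     "cells_per_subject_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        total = sum(self.type_mix.values())
        if total <= 0 or any(v < 0 for v in self.type_mix.values()):
            raise ValueError("type_mix weights must be non-negative, sum > 0")
        self.type_mix = {k: v / total for k, v in self.type_mix.items()}
        if any(k not in DIFFERENTIAL_TYPES for k in self.type_mix):
            raise ValueError("unknown differential type in type_mix")
        if self.family not in ("lognormal", "negative-binomial"):
            raise ValueError("family must be 'lognormal' or 'negative-binomial'")


def _mixture_for(kind: str, cfg: SimulationConfig) -> tuple[list[tuple[float, float]], list[float]]:
    """(components, weights) per group as value-scale (mean, sd) pairs.

    Returns ``(components_g0, weights_g0), (components_g1, weights_g1)``
    flattened into a dict for clarity.
    """
    m, s = cfg.base_mean, cfg.base_sd
    dil = cfg.effect_dilution
    sep = cfg.mode_separation * dil
    if kind == "null":
        g0 = ([(m, s)], [1.0])
        g1 = ([(m, s)], [1.0])
    elif kind == "DE":
        g0 = ([(m, s)], [1.0])
        g1 = ([(m + cfg.de_shift * dil, s)], [1.0])
    elif kind == "DP":
        w0 = cfg.dp_base_weight
        w1 = min(w0 + cfg.dp_shift * dil, 1.0)
        comps = [(m, s), (m + sep, s)]
        g0 = (comps, [1 - w0, w0])
        g1 = (comps, [1 - w1, w1])
    elif kind == "DM":
        g0 = ([(m, s)], [1.0])
        g1 = ([(m, s), (m + sep, s)], [0.5, 0.5])
    elif kind == "DB":
        # unimodal at the bimodal mixture's mean: group means match exactly
        g0 = ([(m + sep / 2, s)], [1.0])
        g1 = ([(m, s), (m + sep, s)], [0.5, 0.5])
    elif kind == "DV":
        ratio = 1.0 + (cfg.dv_ratio - 1.0) * dil
        g0 = ([(m, s)], [1.0])
        g1 = ([(m, s * np.sqrt(ratio))], [1.0])
    else:
        raise ValueError(f"unknown unit type {kind!r}")
    return {0: g0, 1: g1}


def population_moments(kind: str, cfg: SimulationConfig, group: int) -> tuple[float, float]:
    """Population mean and variance of a group's mixture, from its parameters."""
    comps, weights = _mixture_for(kind, cfg)[group]
    means = np.array([c[0] for c in comps])
    sds = np.array([c[1] for c in comps])
    w = np.array(weights)
    mean = float(w @ means)
    var = float(w @ (sds**2 + means**2) - mean**2)
    return mean, var


def _draw_component(rng: np.random.Generator, mean: float, sd: float,
                    size: int, family: str) -> np.ndarray:
    mean = max(mean, 1e-6)
    if family == "lognormal":
        # moment-matched log-normal: preserves the requested mean and sd
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        return rng.lognormal(mu, np.sqrt(sigma2), size)
    # negative binomial; variance floored just above Poisson when sd^2 <= mean
    var = max(sd**2, mean * 1.05)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size).astype(float)


def unit_seed_for(root_seed: int, feature_id: str, cluster_id: str) -> np.random.SeedSequence:
    """Independent, order-invariant RNG stream keyed by (feature, cluster)."""
    key = zlib.crc32(f"{feature_id}|{cluster_id}".encode())
    return np.random.SeedSequence(entropy=[int(root_seed) % (2**31), key])


def simulate_unit(
    kind: str,
    cfg: SimulationConfig,
    unit_seed: int | np.random.SeedSequence | None = None,
    feature_id: str = "gene",
    cluster_id: str = "cluster",
) -> tuple[TestUnit, str]:
    """Draw one (feature, cluster) unit under the given pattern.

    Returns the unit together with its truth label.  Group 0 subjects are
    listed first; each subject receives its own location offset drawn
    with standard deviation ``subject_sd_factor * base_sd``.
    """
    mixtures = _mixture_for(kind, cfg)
    rng = np.random.default_rng(unit_seed)
    g = cfg.subjects_per_group
    n_cells = cfg.cells_per_subject_per_cluster
    subject_ids, values, outcome = [], [], []
    for group in (0, 1):
        comps, weights = mixtures[group]
        for s in range(g):
            sid = f"s{group * g + s:02d}"
            offset = rng.normal(0.0, cfg.subject_sd_factor * cfg.base_sd)
            counts = rng.multinomial(n_cells, weights)
            draws = [
                _draw_component(rng, mean + offset, sd, k, cfg.family)
                for (mean, sd), k in zip(comps, counts)
                if k > 0
            ]
            cells = np.concatenate(draws) if draws else np.empty(0)
            values.append(rng.permutation(cells))
            subject_ids.append(sid)
            outcome.append(group)
    unit = TestUnit(
        feature_id=feature_id,
        cluster_id=cluster_id,
        subject_ids=subject_ids,
        values=values,
        outcome=np.array(outcome, dtype=float),
    )
    return unit, kind


def _assign_types(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Per-cluster gene labels: exactly round(pct * n_genes) differential."""
    n_diff = int(round(cfg.pct_differential * cfg.n_genes))
    active = [t for t in DIFFERENTIAL_TYPES if cfg.type_mix.get(t, 0.0) > 0]
    weights = np.array([cfg.type_mix[t] for t in active])
    # largest-remainder apportionment of n_diff over the active types
    raw = weights / weights.sum() * n_diff
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n_diff - counts.sum()]:
        counts[i] += 1
    labels = ["null"] * cfg.n_genes
    diff_idx = rng.choice(cfg.n_genes, size=n_diff, replace=False)
    pos = 0
    for t, c in zip(active, counts):
        for idx in diff_idx[pos: pos + c]:
            labels[idx] = t
        pos += c
    return labels


def simulate_dataset(cfg: SimulationConfig):
    """Full cells x genes dataset across clusters, plus a truth table.

    Every (gene, cluster) block is drawn from its own seeded stream, so
    the dataset is reproducible and invariant to generation order.  The
    truth table has one row per (feature, cluster) with the pattern label
    (``null`` for non-differential pairs).
    """
    from .pipeline import SingleCellDataset  # deferred: pipeline imports none of this

    rng = np.random.default_rng(cfg.seed)
    g = cfg.subjects_per_group
    subject_ids = [f"s{i:02d}" for i in range(2 * g)]
    outcome = np.array([0] * g + [1] * g, dtype=float)
    n_cells_per_subject = cfg.cells_per_subject_per_cluster
    feature_ids = [f"gene{j:04d}" for j in range(cfg.n_genes)]
    cluster_ids = [f"cluster{c}" for c in range(cfg.n_clusters)]

    cell_rows = []
    blocks = []
    truth_rows = []
    for cluster in cluster_ids:
        labels = _assign_types(cfg, rng)
        n_cluster_cells = 2 * g * n_cells_per_subject
        block = np.empty((n_cluster_cells, cfg.n_genes))
        for j, (feature, kind) in enumerate(zip(feature_ids, labels)):
            unit, _ = simulate_unit(
                kind, cfg, unit_seed_for(cfg.seed, feature, cluster),
                feature_id=feature, cluster_id=cluster,
            )
            block[:, j] = np.concatenate(unit.values)
            truth_rows.append(
                {"feature": feature, "cluster": cluster, "type": kind,
                 "is_differential": kind != "null"}
            )
        blocks.append(block)
        for sid in subject_ids:
            for k in range(n_cells_per_subject):
                cell_rows.append(
                    {"barcode": f"{cluster}_{sid}_c{k:04d}",
                     "subject": sid, "cluster": cluster}
                )

    matrix = np.vstack(blocks)
    cell_meta = pd.DataFrame(cell_rows)
    subject_meta = pd.DataFrame({"subject": subject_ids, "group": outcome.astype(int)})
    truth = pd.DataFrame(truth_rows)
    dataset = SingleCellDataset(
        matrix=matrix,
        cell_meta=cell_meta,
        subject_meta=subject_meta,
        feature_ids=feature_ids,
    )
    return dataset, truth
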