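"""Compositional preprocessing of ASV count tables.

Order of operations as used by the pipeline: taxonomy filter (fungi only)
-> rarefaction to a fixed per-kingdom depth -> prevalence filter ->
Bayesian-multiplicative zero replacement -> centred log-ratio (CLR)
transform.  Fungal and bacterial tables are processed independently
(separate sequencing depths) and only combined inside the network stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tables_io import CountTable

__all__ = [
    "Composition",
    "ClrMatrix",
    "filter_taxonomy",
    "filter_prevalence",
    "rarefy",
    "replace_zeros_bayesian",
    "clr_transform",
    "closure",
]

logger = logging.getLogger(__name__)


@dataclass
class Composition:
    """Strictly positive proportions; each row (sample) sums to one."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("Composition values must be strictly positive")
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("Composition rows must sum to 1 (within 1e-12)")


@dataclass
class ClrMatrix:
    """Centred log-ratio coordinates; each row sums to zero."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.abs(self.values.sum(axis=1)) > 1e-9):
            raise ValueError("ClrMatrix rows must sum to 0 (within 1e-9)")


def filter_taxonomy(table: CountTable, lineage_prefix: str) -> CountTable:
    """Retain taxa whose lineage contains ``lineage_prefix`` at any rank.

    Matching is case-sensitive on the semicolon-delimited rank tokens
    (e.g. ``'Neocallimastigomycota'`` matches ``'p__Neocallimastigomycota'``).
    """
    keep = []
    for i, lineage in enumerate(table.taxonomy):
        ranks = [r.strip() for r in lineage.split(";")]
        if any(lineage_prefix in r for r in ranks):
            keep.append(i)
    if not keep:
        warnings.warn(
            f"taxonomy filter {lineage_prefix!r} retained no taxa", stacklevel=2
        )
    return table.select_taxa(keep)


def filter_prevalence(table: CountTable, min_fraction: float) -> CountTable:
    """Keep taxa present (count > 0) in at least ``ceil(min_fraction * n)`` samples."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    n = table.n_samples
    threshold = int(np.ceil(min_fraction * n))
    prevalence = (table.counts > 0).sum(axis=0)
    keep = np.flatnonzero(prevalence >= threshold)
    return table.select_taxa(keep)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a logged
    warning (standard practice for equal-depth comparisons).  Subsampling
    is a multivariate-hypergeometric draw, deterministic under ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep_samples = []
    new_counts = []
    for s in range(table.n_samples):
        if totals[s] < depth:
            logger.warning(
                "dropping sample %s: total %d below rarefaction depth %d",
                table.sample_ids[s], totals[s], depth,
            )
            continue
        keep_samples.append(s)
        if totals[s] == depth:
            new_counts.append(table.counts[s].copy())
        else:
            new_counts.append(
                rng.multivariate_hypergeometric(table.counts[s], depth)
            )
    if not keep_samples:
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    return CountTable(
        sample_ids=[table.sample_ids[i] for i in keep_samples],
        taxon_ids=list(table.taxon_ids),
        counts=np.asarray(new_counts, dtype=np.int64),
        taxonomy=list(table.taxonomy),
    )


def closure(counts: np.ndarray) -> np.ndarray:
    """Row-wise total-sum scaling to proportions."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("cannot close a sample with zero total")
    return counts / totals


def replace_zeros_bayesian(
    table: CountTable, prior_strength: float = 1.0
) -> Composition:
    """Bayesian-multiplicative replacement of count zeros.

    Zeros in sample ``j`` (total ``n_j``) are imputed as the posterior
    proportion ``t_i * s / (n_j + s)`` with prior strength ``s``
    (default 1) and prior ``t_i`` equal to taxon ``i``'s mean relative
    abundance over the samples where it is present.  Observed proportions
    are then multiplicatively rescaled by ``1 - sum(imputed)`` so ratios
    among observed taxa are preserved.  Any imputed value that would reach
    the smallest observed proportion of its sample is shrunk by 0.65
    (repeatedly if needed) with a warning.
    """
    counts = np.asarray(table.counts, dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every sample must have at least one positive count")
    if np.any((counts > 0).sum(axis=0) == 0):
        raise ValueError("every taxon must be positive in at least one sample")

    props = counts / totals[:, None]
    present = counts > 0
    # prior: mean relative abundance where present
    with np.errstate(invalid="ignore"):
        t = np.where(present, props, np.nan)
        prior = np.nanmean(t, axis=0)

    out = props.copy()
    shrunk = False
    for j in range(counts.shape[0]):
        zeros = ~present[j]
        if not zeros.any():
            continue
        imputed = prior[zeros] * prior_strength / (totals[j] + prior_strength)
        min_obs = props[j, present[j]].min()
        while np.any(imputed >= min_obs):
            imputed = np.where(imputed >= min_obs, imputed * 0.65, imputed)
            shrunk = True
        scale = (1.0 - imputed.sum())
        out[j, present[j]] = props[j, present[j]] * scale
        out[j, zeros] = imputed
    if shrunk:
        warnings.warn(
            "some imputed zeros reached the smallest observed proportion and "
            "were shrunk by 0.65",
            stacklevel=2,
        )
    # guard against floating drift
    out = out / out.sum(axis=1, keepdims=True)
    return Composition(list(table.sample_ids), list(table.taxon_ids), out)


def clr_transform(comp: Composition) -> ClrMatrix:
    """Centred log-ratio transform: ``ln(x_i) - mean_i ln(x_i)`` per sample."""
    vals = np.asarray(comp.values, dtype=float)
    if np.any(vals <= 0):
        raise ValueError("CLR requires strictly positive input")
    logs = np.log(vals)
    clr = logs - logs.mean(axis=1, keepdims=True)
    # exact zero-sum within floating tolerance
    clr -= clr.sum(axis=1, keepdims=True) / clr.shape[1]
    return ClrMatrix(
        list(comp.sample_ids), list(comp.taxon_ids), clr, provenance="clr(composition)"
    )
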