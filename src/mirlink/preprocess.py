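"""Detection filtering, quantile normalization and probe->gene collapsing.

The preprocessing contract for one-color array data: probes undetected in
too many arrays are excluded, intensities are quantile-normalized jointly
across all arrays of both groups, and mRNA probes are collapsed to unique
genes before enrichment analysis.
"""

from __future__ import annotations

from typing import Dict, List, Literal

import numpy as np
import pandas as pd

from .containers import CollapseMap, ExpressionMatrix, FeatureKind

__all__ = ["filter_detected", "quantile_normalize", "collapse_probes"]


def filter_detected(m: ExpressionMatrix, min_fraction: float = 1.0) -> ExpressionMatrix:
    """Keep features detected in at least ``min_fraction`` of samples.

    Feature order is preserved.  The default requires detection on every
    array, matching the convention of excluding undetected probes outright.
    """
    if m.detected is None:
        raise ValueError(
            "matrix has no detection flags; supply them or skip detection filtering"
        )
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError(f"min_fraction must be in [0,1], got {min_fraction}")
    frac = m.detected.to_numpy().mean(axis=1)
    keep = [fid for fid, f in zip(m.feature_ids, frac) if f >= min_fraction]
    return m.subset_features(keep)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the across-sample mean order statistics.

    After normalization all columns share one multiset of values and each
    column's rank order is unchanged.  Tied values within a column receive
    the mean of the quantile means their rank slots span, so ties stay tied.
    NA cells must be removed (detection-filter) first.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    X = m.values.to_numpy()
    if not np.isfinite(X).all():
        raise ValueError("matrix contains NA cells; filter undetected features first")
    n, k = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)  # mean of order statistics per rank slot
    out = np.empty_like(X)
    for j in range(k):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        # average the reference values over each block of tied input values
        sorted_vals = col[order]
        block_start = 0
        for i in range(1, n + 1):
            if i == n or sorted_vals[i] != sorted_vals[block_start]:
                block_mean = ref[block_start:i].mean()
                assigned[order[block_start:i]] = block_mean
                block_start = i
        out[:, j] = assigned
    values = pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids)
    return ExpressionMatrix(values, m.feature_kind, m.detected)


def collapse_probes(
    m: ExpressionMatrix,
    cmap: CollapseMap,
    method: Literal["max_mean", "mean"] = "max_mean",
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    ``max_mean`` (default) keeps, for each gene, the probe with the highest
    mean intensity; ``mean`` averages all probes of the gene per sample.
    Gene rows appear in order of each gene's first probe occurrence.
    """
    if method not in ("max_mean", "mean"):
        raise ValueError(f"unknown collapse method {method!r}")
    missing = [p for p in m.feature_ids if p not in cmap]
    if missing:
        raise KeyError(
            f"{len(missing)} probe(s) absent from collapse map: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    probe_means = m.values.to_numpy().mean(axis=1)
    gene_probes: Dict[str, List[int]] = {}
    gene_order: List[str] = []
    for i, probe in enumerate(m.feature_ids):
        g = cmap[probe]
        if g not in gene_probes:
            gene_probes[g] = []
            gene_order.append(g)
        gene_probes[g].append(i)
    rows = []
    X = m.values.to_numpy()
    for g in gene_order:
        idx = gene_probes[g]
        if method == "max_mean":
            best = max(idx, key=lambda i: (probe_means[i], -i))
            rows.append(X[best])
        else:
            rows.append(X[idx].mean(axis=0))
    values = pd.DataFrame(np.asarray(rows), index=gene_order, columns=m.sample_ids)
    return ExpressionMatrix(values, FeatureKind.GENE)
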