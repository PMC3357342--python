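"""Moderated two-group differential expression and qPCR fold computation.

The test statistic is a Bayesian-regularized (Cyber-T-style) pooled t: each
feature's pooled variance is shrunk toward a local background variance
estimated from the features closest in mean intensity.  On low-replicate
arrays this stabilizes the denominator of the t statistic for features whose
sample variance is accidentally tiny, at the cost of ``prior_df`` pseudo-
observations of the background variance.

Posterior variance:  s~^2 = (nu0 * s0^2 + (n-2) * s_pooled^2) / (nu0 + n - 2)
where s0^2 is the mean pooled variance over the ``window_size`` features
nearest in mean intensity, and the t statistic carries nu0 + n - 2 degrees
of freedom.  With nu0 = 0 this is exactly the ordinary pooled-variance
two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DERecord, ExpressionMatrix, GroupDesign

__all__ = [
    "ModeratedTestConfig",
    "moderated_t",
    "bh_qvalues",
    "signed_fold",
    "QPCRRecord",
    "ddct_fold",
    "ModeratedTTest",
    "DifferentialExpressionResults",
]


@dataclass(frozen=True)
class ModeratedTestConfig:
    """Hyperparameters of the moderated t-test.

    prior_df : weight (pseudo-degrees-of-freedom) of the background variance;
        0 recovers the ordinary pooled t-test.
    window_size : odd number of intensity-ranked neighbours averaged into the
        background variance estimate; clipped to the feature count.
    """

    prior_df: float = 10.0
    window_size: int = 101

    def __post_init__(self):
        if self.prior_df < 0:
            raise ValueError(f"prior_df must be >= 0, got {self.prior_df}")
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError(
                f"window_size must be an odd positive integer, got {self.window_size}"
            )


def _group_arrays(m: ExpressionMatrix, d: GroupDesign):
    exp = [s for s in m.sample_ids if d.assignment.get(s) == "exposure"]
    ctl = [s for s in m.sample_ids if d.assignment.get(s) == "control"]
    if len(exp) < 2 or len(ctl) < 2:
        raise ValueError(
            f"need >=2 samples per group, got exposure={len(exp)}, control={len(ctl)}"
        )
    X = m.values[exp].to_numpy()
    Y = m.values[ctl].to_numpy()
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("matrix contains non-finite values; filter/normalize first")
    return X, Y


def _background_variance(mean_intensity: np.ndarray, s2_pooled: np.ndarray, w: int):
    """Mean pooled variance of the w features nearest in mean intensity.

    Features are ranked by mean intensity; each feature's window is the w
    contiguous ranked neighbours centred on it, shifted inward at the edges
    so it always holds exactly w features.
    """
    m = len(mean_intensity)
    w = min(w, m)
    order = np.argsort(mean_intensity, kind="stable")
    s2_sorted = s2_pooled[order]
    csum = np.concatenate([[0.0], np.cumsum(s2_sorted)])
    half = w // 2
    idx = np.arange(m)
    start = np.clip(idx - half, 0, m - w)
    window_mean = (csum[start + w] - csum[start]) / w
    out = np.empty(m)
    out[order] = window_mean
    return out


def moderated_t(
    m: ExpressionMatrix,
    d: GroupDesign,
    cfg: ModeratedTestConfig = ModeratedTestConfig(),
) -> List[DERecord]:
    """Run the moderated t-test on every feature; records sorted by p-value.

    Returns one :class:`DERecord` per feature with signed fold, moderated t,
    two-sided p and Benjamini-Hochberg q.
    """
    X, Y = _group_arrays(m, d)
    n1, n2 = X.shape[1], Y.shape[1]
    df_resid = n1 + n2 - 2
    mean1 = X.mean(axis=1)
    mean2 = Y.mean(axis=1)
    v1 = X.var(axis=1, ddof=1)
    v2 = Y.var(axis=1, ddof=1)
    s2_pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
    nu0 = cfg.prior_df
    if nu0 > 0:
        intensity = np.concatenate([X, Y], axis=1).mean(axis=1)
        s0sq = _background_variance(intensity, s2_pooled, cfg.window_size)
        s2_post = (nu0 * s0sq + df_resid * s2_pooled) / (nu0 + df_resid)
    else:
        s2_post = s2_pooled
    if np.all(s2_post == 0):
        raise ValueError(
            "all features have zero variance and prior_df=0; the t statistic "
            "is undefined — use a positive prior_df"
        )
    delta = mean1 - mean2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
    df_total = nu0 + df_resid
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)  # p in (0,1] for downstream BH
    q = bh_qvalues(list(p))
    folds = signed_fold(m, d)
    records = [
        DERecord(
            feature_id=fid,
            fold=folds[fid],
            t_stat=float(t[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
        )
        for i, fid in enumerate(m.feature_ids)
    ]
    records.sort(key=lambda r: (r.p_value, r.feature_id))
    return records


def bh_qvalues(p: Sequence[float], pi0: Optional[float] = None) -> List[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_i = min over {j : p_j >= p_i} of p_j * m / rank_j, clipped to 1.
    An optional Storey-style pi0 (estimated null fraction) rescales every
    q-value; pass ``pi0="storey"`` upstream via :func:`storey_pi0`.
    """
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return []
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(arr, method="fdr_bh")[1]
    if pi0 is not None:
        if not (0 < pi0 <= 1):
            raise ValueError(f"pi0 must be in (0,1], got {pi0}")
        q = np.minimum(q * pi0, 1.0)
    return [float(x) for x in q]


def storey_pi0(p: Sequence[float], lam: float = 0.5) -> float:
    """Storey's estimate of the null fraction: #{p > lam} / ((1-lam) m)."""
    arr = np.asarray(list(p), dtype=float)
    if not (0 < lam < 1):
        raise ValueError("lambda must be in (0,1)")
    pi0 = float((arr > lam).mean() / (1.0 - lam))
    return min(max(pi0, 1.0 / len(arr)), 1.0)


def signed_fold(m: ExpressionMatrix, d: GroupDesign) -> Dict[str, float]:
    """Signed fold change per feature from log2 group means.

    With ratio r = 2^(mean_exposure - mean_control): fold = r when r >= 1,
    otherwise -1/r; a ratio of exactly 1 reports +1.0.  So -1.68 denotes a
    1.68-fold decrease under exposure.
    """
    exp = [s for s in m.sample_ids if d.assignment.get(s) == "exposure"]
    ctl = [s for s in m.sample_ids if d.assignment.get(s) == "control"]
    if not exp or not ctl:
        raise ValueError("design covers no samples of the matrix for one group")
    diff = m.values[exp].mean(axis=1) - m.values[ctl].mean(axis=1)
    ratio = np.power(2.0, diff.to_numpy())
    fold = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    return {fid: float(f) for fid, f in zip(m.feature_ids, fold)}


@dataclass(frozen=True)
class QPCRRecord:
    """Raw qPCR cycle numbers for one target gene and its reference gene.

    ``ct_target`` / ``ct_reference`` map sample -> replicate Ct values
    (typically triplicates); replicates are averaged before delta-Ct.
    """

    ct_target: Mapping[str, Sequence[float]]
    ct_reference: Mapping[str, Sequence[float]]
    design: GroupDesign

    def __post_init__(self):
        for name, table in (("target", self.ct_target), ("reference", self.ct_reference)):
            for s, cts in table.items():
                if len(cts) == 0 or any(c <= 0 for c in cts):
                    raise ValueError(f"{name} Ct values for {s!r} must be positive")


def ddct_fold(rec: QPCRRecord) -> float:
    """Relative expression by the 2^-ddCt method, exposure relative to control.

    Per sample: dCt = mean(Ct_target) - mean(Ct_reference); ddCt is the
    difference of the exposure and control group-mean dCt.
    """
    dct: Dict[str, float] = {}
    for s, cts in rec.ct_target.items():
        if s not in rec.ct_reference:
            raise ValueError(f"missing reference-gene Ct for sample {s!r}")
        dct[s] = float(np.mean(cts)) - float(np.mean(rec.ct_reference[s]))
    exp = [dct[s] for s in rec.design.exposure_samples if s in dct]
    ctl = [dct[s] for s in rec.design.control_samples if s in dct]
    if not exp or not ctl:
        raise ValueError("need dCt values in both groups")
    ddct = float(np.mean(exp)) - float(np.mean(ctl))
    return float(2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class ModeratedTTest:
    """Moderated two-group differential expression model.

    Examples
    --------
    >>> model = ModeratedTTest(matrix, design, prior_df=10, window_size=101)
    >>> res = model.fit()
    >>> res.significant(q=0.05)   # doctest: +SKIP
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        design: GroupDesign,
        prior_df: float = 10.0,
        window_size: int = 101,
    ):
        self.matrix = matrix
        self.design = design
        # window clipped to an odd size <= feature count
        w = min(window_size, matrix.n_features)
        if w % 2 == 0:
            w -= 1
        self.config = ModeratedTestConfig(prior_df=prior_df, window_size=max(w, 1))

    def fit(self) -> "DifferentialExpressionResults":
        records = moderated_t(self.matrix, self.design, self.config)
        return DifferentialExpressionResults(self, records)


class DifferentialExpressionResults:
    """Fitted DE results: records sorted by p, frame/summary/selection views."""

    def __init__(self, model: ModeratedTTest, records: List[DERecord]):
        self.model = model
        self.records = records

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [r.feature_id for r in self.records],
                "fold": [r.fold for r in self.records],
                "t": [r.t_stat for r in self.records],
                "p": [r.p_value for r in self.records],
                "q": [r.q_value for r in self.records],
                "direction": [r.direction for r in self.records],
            }
        ).set_index("feature")

    def significant(self, q: float = 0.05) -> List[DERecord]:
        return [r for r in self.records if r.q_value <= q]

    def summary(self, q: float = 0.05) -> str:
        sig = self.significant(q)
        n_up = sum(1 for r in sig if r.direction == "up")
        n_down = len(sig) - n_up
        cfg = self.model.config
        lines = [
            "Moderated two-group t-test",
            "==========================",
            f"features tested:      {len(self.records)}",
            f"exposure / control n: {len(self.model.design.exposure_samples)}"
            f" / {len(self.model.design.control_samples)}",
            f"prior_df (nu0):       {cfg.prior_df}",
            f"variance window (w):  {cfg.window_size}",
            f"significant at Q<={q}: {len(sig)} ({n_up} up, {n_down} down)",
        ]
        head = self.frame().head(10)
        lines.append("")
        lines.append(head.to_string(float_format=lambda x: f"{x:.4g}"))
        return "\n".join(lines)
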