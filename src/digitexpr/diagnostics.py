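"""Data-quality diagnostics: p-value uniformity, replicate concordance,
and dispersion comparisons between datasets.

Under a correct null most genes are not differentially expressed, so the
adjacent-digit p-value histogram should be flat; real digit-identity signal
inflates the first bin. The KS distance from Uniform(0, 1) plus the
first-bin excess operationalize the visual inspection of such histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, ValidationError
from .diffexp import DispersionEstimates

logger = logging.getLogger(__name__)


@dataclass
class UniformityReport:
    ks_distance: float
    first_bin_excess: float
    histogram: np.ndarray
    n: int
    uniform_like: bool


def pvalue_uniformity(p, n_bins: int = 20, ks_threshold: float = 0.05) -> UniformityReport:
    """KS distance of a p-value sample from Uniform(0,1), the excess mass in
    the first histogram bin, and the histogram itself.

    NaNs are dropped. ``uniform_like`` is True iff KS < ``ks_threshold``.
    """
    p = np.asarray(p, float)
    p = p[~np.isnan(p)]
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    if p.size < 100:
        logger.warning("only %d p-values; uniformity statistics are noisy", p.size)
    if p.size == 0:
        raise ValidationError("no p-values")
    x = np.sort(p)
    n = x.size
    cdf_hi = np.arange(1, n + 1) / n
    cdf_lo = np.arange(0, n) / n
    ks = float(np.max(np.maximum(np.abs(cdf_hi - x), np.abs(x - cdf_lo))))
    hist, _ = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    first_excess = float(hist[0] / n - 1.0 / n_bins)
    return UniformityReport(
        ks_distance=ks,
        first_bin_excess=first_excess,
        histogram=hist,
        n=n,
        uniform_like=ks < ks_threshold,
    )


@dataclass
class ConcordanceReport:
    pairwise: pd.DataFrame  # group, sample_a, sample_b, r
    best_pairs: pd.DataFrame  # group, sample_a, sample_b, r, below_0_99
    singletons: list


def replicate_concordance(em: ExpressionMatrix, groups: dict) -> ConcordanceReport:
    """Within-group pairwise Pearson correlations and the best pair per group.

    ``groups`` maps sample -> group label. The best pair is the argmax-r
    pair (ties break lexicographically on the sorted sample-ID pair); groups
    whose best pair has r < 0.99 are flagged. Singleton groups are reported
    without a pair.
    """
    values = em.values
    pair_rows, best_rows, singles = [], [], []
    labels = pd.Series({s: groups[s] for s in values.columns})
    for group, idx in labels.groupby(labels).groups.items():
        members = sorted(idx)
        if len(members) < 2:
            singles.append(group)
            continue
        best = None
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                r = float(np.corrcoef(values[a], values[b])[0, 1])
                pair_rows.append(dict(group=group, sample_a=a, sample_b=b, r=r))
                key = (-r, a, b)
                if best is None or key < best[0]:
                    best = (key, a, b, r)
        _, a, b, r = best
        best_rows.append(
            dict(group=group, sample_a=a, sample_b=b, r=r, below_0_99=r < 0.99)
        )
    return ConcordanceReport(
        pairwise=pd.DataFrame(pair_rows),
        best_pairs=pd.DataFrame(best_rows),
        singletons=singles,
    )


def best_pair_samples(em: ExpressionMatrix, groups: dict) -> list:
    """Sample IDs of the two most-correlated replicates of every group —
    the robustness subset for re-running differential expression."""
    rep = replicate_concordance(em, groups)
    out = []
    for _, row in rep.best_pairs.iterrows():
        out.extend([row["sample_a"], row["sample_b"]])
    return out


def dispersion_summary(estimates: dict) -> pd.DataFrame:
    """Per-dataset mean and quartiles of tagwise dispersion, ordered by mean.

    ``estimates`` maps a dataset label to DispersionEstimates (or a Series
    of tagwise values).
    """
    rows = []
    for name, est in estimates.items():
        tag = est.tagwise if isinstance(est, DispersionEstimates) else pd.Series(est)
        rows.append(
            dict(
                dataset=name,
                mean=float(tag.mean()),
                q25=float(tag.quantile(0.25)),
                median=float(tag.quantile(0.5)),
                q75=float(tag.quantile(0.75)),
                common=float(est.common) if isinstance(est, DispersionEstimates) else np.nan,
            )
        )
    return pd.DataFrame(rows).sort_values("mean").reset_index(drop=True)
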