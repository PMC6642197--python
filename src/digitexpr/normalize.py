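"""Count normalization for the multivariate analyses.

Counts are converted to transcripts-per-million (TPM) using per-gene median
transcript lengths, variance-stabilized with a square-root transform, and —
when samples from several stages or limbs are analysed together — mean-
centered per gene within declared "bulks" (all samples of one stage, or all
samples of one limb). After bulk centering a gene's values within each bulk
average to zero, so sample-sample Pearson correlations range over [-1, 1].
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import (
    CountMatrix,
    ExpressionMatrix,
    TranscriptLengthTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


def compute_tpm(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """TPM for one sample over a gene universe.

    TPM_g = 1e6 * (c_g / L_g) / sum_j (c_j / L_j). An all-zero sample yields
    all-zero TPM with a warning (degenerate but representable).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.size == 0:
        raise ValidationError("empty gene universe")
    if (lengths <= 0).any():
        raise ValidationError("non-positive transcript length in universe")
    rate = counts / lengths
    denom = rate.sum()
    if denom == 0:
        logger.warning("sample has zero total counts; TPM set to all zeros")
        return np.zeros_like(rate)
    return 1e6 * rate / denom


def tpm_matrix(
    cm: CountMatrix,
    lengths: TranscriptLengthTable,
    gene_universe=None,
) -> ExpressionMatrix:
    """TPM for every sample; the denominator runs over ``gene_universe``
    (default: all genes of the matrix)."""
    if gene_universe is None:
        genes = list(cm.gene_ids)
        universe = "full"
    else:
        genes = [g for g in cm.gene_ids if g in set(gene_universe)]
        if not genes:
            raise ValidationError("gene universe shares no genes with count matrix")
        universe = "subset"
    L = lengths.for_genes(genes)
    sub = cm.counts.loc[genes].to_numpy(dtype=float)
    rate = sub / L[:, None]
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        logger.warning(
            "samples with zero total counts: %s", list(cm.sample_ids[zero])
        )
    denom = np.where(zero, 1.0, denom)
    vals = 1e6 * rate / denom
    vals[:, zero] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=cm.sample_ids),
        transform_state="tpm",
        universe=universe,
    )


def sqrt_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise square root of a TPM matrix (variance stabilization)."""
    em.require_state("tpm")
    return ExpressionMatrix(
        np.sqrt(em.values), transform_state="sqrt_tpm", universe=em.universe
    )


def bulk_center(em: ExpressionMatrix, bulk_assignment: dict) -> ExpressionMatrix:
    """Per-gene mean-centering within each declared bulk of samples.

    ``bulk_assignment`` maps every sample ID to a bulk label (typically the
    stage or the limb). Singleton bulks are permitted — they center to all
    zeros — but logged. Idempotent.
    """
    if em.transform_state != "centered_sqrt_tpm":  # idempotent on centered input
        em.require_state("sqrt_tpm")
    missing = [s for s in em.sample_ids if s not in bulk_assignment]
    if missing:
        raise ValidationError(f"samples without bulk assignment: {missing[:5]}")
    out = em.values.copy().astype(float)
    labels = pd.Series({s: bulk_assignment[s] for s in em.sample_ids})
    for bulk, idx in labels.groupby(labels).groups.items():
        cols = list(idx)
        if len(cols) == 1:
            logger.warning("bulk %r has a single sample; centering yields zeros", bulk)
        sub = out[cols]
        out[cols] = sub.sub(sub.mean(axis=1), axis=0)
    return ExpressionMatrix(
        out,
        transform_state="centered_sqrt_tpm",
        bulk_assignment={s: bulk_assignment[s] for s in em.sample_ids},
        universe=em.universe,
    )


def normalize_for_multivariate(
    cm: CountMatrix,
    lengths: TranscriptLengthTable,
    gene_universe=None,
    bulk_by: str | None = None,
) -> ExpressionMatrix:
    """Convenience chain: TPM -> sqrt -> (optional) bulk centering.

    ``bulk_by`` names a metadata column ('stage' or 'limb'); when given, each
    distinct value forms one bulk.
    """
    em = sqrt_transform(tpm_matrix(cm, lengths, gene_universe))
    if bulk_by is not None:
        bulks = cm.metadata[bulk_by].to_dict()
        em = bulk_center(em, bulks)
    return em
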