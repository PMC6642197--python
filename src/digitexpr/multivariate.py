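"""Sample-level multivariate structure: hierarchical clustering with
bootstrap support, centered PCA, supplementary projection, and digit
correspondence calls.

Clustering follows the classic expression-profile recipe: 1 - Pearson r
between sample profiles as the dissimilarity, average-linkage (UPGMA-style)
agglomeration, and node support from resampling genes with replacement
(bootstrap proportion BP, optionally a multiscale approximately-unbiased AU
value). PCA is gene-centered and unscaled; held-out samples (e.g. another
species' digits mapped through one-to-one orthologs) are projected into the
fitted plane as supplementary observations and assigned to the nearest
reference-digit centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import ClusterTree, ExpressionMatrix, TreeNode, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Correlation dissimilarity + average linkage
# ---------------------------------------------------------------------------


def correlation_dissimilarity(em_or_values) -> pd.DataFrame:
    """d(i, j) = 1 - Pearson r between sample expression profiles.

    Symmetric with zero diagonal; range [0, 2]. A zero-variance sample
    profile is rejected by name (its correlation is undefined).
    """
    values = em_or_values.values if isinstance(em_or_values, ExpressionMatrix) else em_or_values
    if values.shape[1] < 2:
        raise ValidationError("need >=2 samples for a dissimilarity matrix")
    arr = values.to_numpy(float)
    sd = arr.std(axis=0)
    if (sd == 0).any():
        bad = list(values.columns[sd == 0])
        raise ValidationError(f"zero-variance sample profile(s): {bad}")
    r = np.corrcoef(arr.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


def average_linkage(dissim: pd.DataFrame) -> ClusterTree:
    """UPGMA-style agglomeration with a deterministic tie rule.

    At each step the pair with the smallest average dissimilarity merges;
    exact ties break on the lexicographically smallest (sorted) member sets.
    Merged-cluster distances are member-count-weighted averages, so heights
    are non-decreasing toward the root.
    """
    labels = list(dissim.index)
    n = len(labels)
    D = dissim.to_numpy(float).copy()
    clusters = {i: TreeNode(label=labels[i]) for i in range(n)}
    members = {i: (labels[i],) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1:]:
                key = (D[a, b], min(sorted(members[a]), sorted(members[b])),
                       max(sorted(members[a]), sorted(members[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (h, _, _), a, b = best
        node = TreeNode(height=float(h), children=(clusters[a], clusters[b]))
        # Lance-Williams update for average linkage
        D = np.pad(D, ((0, 1), (0, 1)))
        for c in active:
            if c in (a, b):
                continue
            D[next_id, c] = D[c, next_id] = (
                sizes[a] * D[a, c] + sizes[b] * D[b, c]
            ) / (sizes[a] + sizes[b])
        clusters[next_id] = node
        members[next_id] = tuple(sorted(members[a] + members[b]))
        sizes[next_id] = sizes[a] + sizes[b]
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return ClusterTree(root=clusters[active[0]])


def bootstrap_support(
    em: ExpressionMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    compute_au: bool = False,
    au_scales=None,
) -> ClusterTree:
    """Cluster samples and attach gene-resampling bootstrap support.

    BP(node) = percentage of ``n_boot`` replicate trees (genes resampled with
    replacement) that contain the node's exact leaf set. With
    ``compute_au=True`` a multiscale bootstrap (resample sizes r*n_genes over
    ``au_scales``, default ten scales in [0.5, 1.4]) yields approximately-
    unbiased AU values via the signed-distance fit z(r) = v*sqrt(r) + c/sqrt(r).
    """
    if em.values.shape[1] < 3:
        raise ValidationError("bootstrap support needs >=3 samples")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; support values will be noisy", n_boot)
    rng = np.random.default_rng(seed)
    base_d = correlation_dissimilarity(em)
    tree = average_linkage(base_d)
    target = {frozenset(fs) for fs in tree.clusters()}
    values = em.values
    n_genes = values.shape[0]
    scales = list(au_scales) if au_scales is not None else list(np.linspace(0.5, 1.4, 10))
    if not compute_au:
        scales = [1.0]
    counts = {s: {fs: 0 for fs in target} for s in scales}
    arr = values.to_numpy(float)
    cols = list(values.columns)
    for scale in scales:
        m = max(2, int(round(scale * n_genes)))
        for _ in range(n_boot):
            idx = rng.integers(0, n_genes, size=m)
            sub = arr[idx]
            sd = sub.std(axis=0)
            if (sd == 0).any():
                continue
            r = np.corrcoef(sub.T)
            d = pd.DataFrame(np.clip(1.0 - r, 0, 2), index=cols, columns=cols)
            np.fill_diagonal(d.values, 0.0)
            boot_clusters = average_linkage(d).clusters()
            for fs in target:
                if fs in boot_clusters:
                    counts[scale][fs] += 1
    for node in tree.internal_nodes():
        fs = frozenset(node.leaves())
        bp1 = counts[1.0][fs] / n_boot if 1.0 in counts else None
        if bp1 is None:  # nearest scale to 1 when AU grid lacks exactly 1.0
            nearest = min(scales, key=lambda s: abs(s - 1.0))
            bp1 = counts[nearest][fs] / n_boot
        node.bp = 100.0 * bp1
        if compute_au:
            node.au = 100.0 * _au_from_multiscale(
                [counts[s][fs] / n_boot for s in scales], scales
            )
    tree.n_boot = n_boot
    return tree


def _au_from_multiscale(bps, scales) -> float:
    """AU p-value from bootstrap proportions across resample scales.

    Fit z(r) = Phi^{-1}(1 - BP_r) = v*sqrt(r) + c/sqrt(r) by least squares;
    AU = 1 - Phi(v - c). Degenerate (all 0 or all 1) proportions short-circuit.
    """
    bps = np.clip(np.asarray(bps, float), 1e-6, 1 - 1e-6)
    if np.all(bps > 1 - 2e-6):
        return 1.0
    if np.all(bps < 2e-6):
        return 0.0
    r = np.sqrt(np.asarray(scales, float))
    z = norm.ppf(1.0 - bps)
    A = np.column_stack([r, 1.0 / r])
    (v, c), *_ = np.linalg.lstsq(A, z, rcond=None)
    return float(np.clip(1.0 - norm.cdf(v - c), 0.0, 1.0))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Gene-centered, unscaled PCA of a samples x genes view of expression.

    ``loadings`` are orthonormal gene-space axes (genes x components) with a
    deterministic sign convention (largest-|entry| positive); ``scores`` are
    samples x components; ``explained`` the per-component variance fractions.
    """

    gene_means: pd.Series
    loadings: pd.DataFrame  # genes x components
    scores: pd.DataFrame  # samples x components
    explained: np.ndarray
    state: str
    digit_labels: pd.Series | None = None  # per training sample, for centroids

    def project(self, em: ExpressionMatrix) -> pd.DataFrame:
        """Project held-out samples as supplementary observations.

        The samples must share the model's gene universe and expression
        state; they are centered with the *model's* gene means.
        """
        if em.transform_state != self.state:
            raise ValidationError(
                f"projection needs expression state {self.state!r}, got "
                f"{em.transform_state!r}"
            )
        missing = [g for g in self.loadings.index if g not in em.values.index]
        if missing:
            raise ValidationError(f"projection input lacks genes {missing[:5]}")
        M = em.values.loc[self.loadings.index].to_numpy(float).T
        centered = M - self.gene_means.to_numpy(float)
        S = centered @ self.loadings.to_numpy(float)
        return pd.DataFrame(S, index=em.values.columns, columns=self.loadings.columns)


def fit_pca(em: ExpressionMatrix, n_components: int | None = None,
            digit_labels: pd.Series | None = None, scale: bool = False) -> PCAModel:
    """Centered (optionally scaled) PCA of samples over genes via SVD.

    Component signs are fixed by making each loading vector's largest-
    magnitude entry positive, so fixtures and bootstrap alignment are stable.
    """
    values = em.values
    if values.shape[0] < 1:
        raise ValidationError("PCA needs at least one gene")
    if values.shape[1] < 2:
        raise ValidationError("PCA needs at least two samples")
    M = values.to_numpy(float).T  # samples x genes
    means = M.mean(axis=0)
    Mc = M - means
    if scale:
        sd = Mc.std(axis=0, ddof=1)
        Mc = Mc / np.where(sd > 0, sd, 1.0)
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    k = min(len(s), n_components or len(s))
    # deterministic signs
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(Vt[:k].T, index=values.index, columns=comps)
    scores = pd.DataFrame((U[:, :k] * s[:k]), index=values.columns, columns=comps)
    total_var = (s ** 2).sum()
    explained = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCAModel(
        gene_means=pd.Series(means, index=values.index),
        loadings=loadings,
        scores=scores,
        explained=explained,
        state=em.transform_state,
        digit_labels=digit_labels,
    )


def project_supplementary(model: PCAModel, em: ExpressionMatrix) -> pd.DataFrame:
    """Scores of held-out samples in the reference PCA (see PCAModel.project)."""
    return model.project(em)


def bootstrap_pca(
    em: ExpressionMatrix, n_boot: int = 1000, seed: int = 0, n_components: int = 2
):
    """Resample samples with replacement, refit the PCA, align signs to the
    reference fit, and summarize per-sample score dispersion.

    Returns (summary DataFrame with per-sample mean and sd of bootstrap
    scores per component, reference PCAModel).
    """
    if em.values.shape[1] < 3:
        raise ValidationError("bootstrap PCA needs >=3 samples")
    rng = np.random.default_rng(seed)
    ref = fit_pca(em, n_components=n_components)
    comps = list(ref.loadings.columns)
    samples = list(em.values.columns)
    sums = {s: np.zeros(len(comps)) for s in samples}
    sq = {s: np.zeros(len(comps)) for s in samples}
    nobs = {s: 0 for s in samples}
    n = len(samples)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        chosen = [samples[i] for i in idx]
        if len(set(chosen)) < 2:
            continue
        sub = ExpressionMatrix(
            em.values.iloc[:, idx].set_axis(range(n), axis=1),
            em.transform_state, em.bulk_assignment, em.universe,
        )
        boot = fit_pca(sub, n_components=len(comps))
        # align each bootstrap component's sign to the reference loadings
        L = boot.loadings.to_numpy(float)
        flip = np.sign(
            np.einsum("gk,gk->k", L[:, : len(comps)], ref.loadings.to_numpy(float))
        )
        flip[flip == 0] = 1.0
        S = boot.scores.to_numpy(float)[:, : len(comps)] * flip
        for pos, s_name in enumerate(chosen):
            sums[s_name] += S[pos]
            sq[s_name] += S[pos] ** 2
            nobs[s_name] += 1
    rows = []
    for s_name in samples:
        k = max(nobs[s_name], 1)
        mean = sums[s_name] / k
        var = np.maximum(sq[s_name] / k - mean ** 2, 0.0)
        rows.append(
            dict(
                sample=s_name,
                n_boot_appearances=nobs[s_name],
                **{f"mean_{c}": mean[j] for j, c in enumerate(comps)},
                **{f"sd_{c}": np.sqrt(var[j]) for j, c in enumerate(comps)},
            )
        )
    return pd.DataFrame(rows).set_index("sample"), ref


# ---------------------------------------------------------------------------
# Correspondence calls
# ---------------------------------------------------------------------------


@dataclass
class CorrespondenceCall:
    """Nearest reference-digit assignment of projected samples in the PCA plane."""

    table: pd.DataFrame  # per projected sample: digit, distance, margin, runner_up
    plane: tuple = ("PC1", "PC2")
    centroids: pd.DataFrame = field(default=None, repr=False)


def call_correspondence(
    model: PCAModel,
    projected_scores: pd.DataFrame,
    plane: tuple = ("PC1", "PC2"),
) -> CorrespondenceCall:
    """Assign each projected sample to the nearest reference digit centroid.

    Centroids are per-digit means of the training scores in the leading
    plane; assignment is Euclidean nearest-centroid, exact ties go to the
    lower digit number with margin 0 flagged.
    """
    if model.digit_labels is None:
        raise ValidationError("reference PCA has no digit labels")
    labels = model.digit_labels
    if labels.nunique() < 2:
        raise ValidationError("need >=2 reference digit groups")
    counts = labels.value_counts()
    if (counts < 1).any():
        raise ValidationError("reference digit group with no replicates")
    plane = tuple(plane)
    ref = model.scores.loc[labels.index, list(plane)]
    centroids = ref.groupby(labels).mean().sort_index()
    P = projected_scores[list(plane)].to_numpy(float)
    C = centroids.to_numpy(float)
    dist = np.sqrt(((P[:, None, :] - C[None, :, :]) ** 2).sum(axis=2))
    rows = []
    digits = list(centroids.index)
    for i, s in enumerate(projected_scores.index):
        order = np.lexsort((digits, dist[i]))  # distance, then lower digit
        best, second = order[0], order[1]
        rows.append(
            dict(
                sample=s,
                digit=digits[best],
                distance=dist[i, best],
                runner_up=digits[second],
                margin=dist[i, second] - dist[i, best],
                tie=bool(np.isclose(dist[i, best], dist[i, second])),
            )
        )
    return CorrespondenceCall(
        table=pd.DataFrame(rows).set_index("sample"), plane=plane, centroids=centroids
    )


# ---------------------------------------------------------------------------
# Cross-species projection workflow
# ---------------------------------------------------------------------------


def cross_species_projection(
    reference_em: ExpressionMatrix,
    reference_digits: pd.Series,
    heldout_em: ExpressionMatrix,
    gene_map: dict,
    plane: tuple = ("PC1", "PC2"),
):
    """Fit a reference-species PCA and project another species' digits.

    ``reference_em`` and ``heldout_em`` are centered-sqrt-TPM matrices over
    matching gene universes (each species bulk-centered with its own means);
    ``gene_map`` maps held-out gene IDs to their reference orthologs. Returns
    (PCAModel, projected scores, CorrespondenceCall).
    """
    missing = [g for g in heldout_em.values.index if g not in gene_map]
    if missing:
        raise ValidationError(f"held-out genes without ortholog mapping: {missing[:5]}")
    renamed = ExpressionMatrix(
        heldout_em.values.rename(index=gene_map),
        heldout_em.transform_state,
        heldout_em.bulk_assignment,
        heldout_em.universe,
    )
    model = fit_pca(reference_em, digit_labels=reference_digits)
    scores = project_supplementary(model, renamed)
    call = call_correspondence(model, scores, plane=plane)
    return model, scores, call
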