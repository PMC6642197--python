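"""Cross-species conservation statistics over one-to-one orthologs.

Given per-species differential-expression results at a digit boundary, the
questions are: which ortholog groups are called DE in *every* species
(conserved differentially expressed genes, CDEGs); is the size of that
intersection larger than chance; and do DE genes of one species show
correlated fold changes in the orthologs of other species beyond what
expression-matched random genes show?

The chance model for set overlap is independent uniform draws of the
per-species set sizes k_i from a shared universe of N ortholog groups: a
fixed gene lies in all sets with probability p = prod_i k_i / N, the
expected overlap is N*p, and the overlap tail is an exact Binomial(N, p)
sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, mannwhitneyu, pearsonr, ttest_ind

from .datamodel import OrthologMap, ValidationError
from .diffexp import DEResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# DE sets over the ortholog universe
# ---------------------------------------------------------------------------


def de_sets_by_boundary(
    results: dict,
    orthologs: OrthologMap,
    fdr_threshold: float = 0.05,
    method: str = "bh",
) -> tuple[dict, int]:
    """Per-species DE ortholog-group sets at one boundary.

    ``results`` maps species -> DEResult (all for the same digit boundary).
    Gene IDs are translated to ortholog group IDs through the one-to-one
    rows; genes outside the one-to-one universe never appear. Returns
    ({species: set of group_ids}, N = size of the one-to-one universe).
    """
    missing = [sp for sp in results if sp not in orthologs.species_set]
    if missing:
        raise ValidationError(f"species missing from ortholog map: {missing}")
    o2o = orthologs.one_to_one_table()
    if o2o.empty:
        raise ValidationError("empty one-to-one ortholog universe")
    sets = {}
    for sp, res in results.items():
        sig = set(res.significant(fdr_threshold, method=method))
        gene_to_group = pd.Series(o2o.index, index=o2o[sp])
        sets[sp] = set(gene_to_group.loc[gene_to_group.index.intersection(sig)])
    return sets, len(o2o)


@dataclass
class ConservationResult:
    boundary: object
    species: tuple
    n_universe: int
    set_sizes: dict
    intersection: frozenset
    direction_consistent: frozenset

    @property
    def n_conserved(self) -> int:
        return len(self.intersection)


def intersect_conserved(
    sets: dict,
    n_universe: int,
    boundary=None,
    directions: dict | None = None,
) -> ConservationResult:
    """Membership intersection across species, with a direction-consistent
    subset when per-species fold-change signs are supplied.

    ``directions`` maps species -> {group_id: sign of fold change}; a member
    is direction-consistent iff its sign agrees across all species.
    """
    if len(sets) < 2:
        raise ValidationError("need >=2 species for a conservation intersection")
    species = tuple(sets)
    inter = frozenset(set.intersection(*[set(s) for s in sets.values()]))
    consistent = inter
    if directions is not None:
        keep = set()
        for g in inter:
            signs = {np.sign(directions[sp].get(g, 0.0)) for sp in species}
            if len(signs) == 1 and 0 not in signs:
                keep.add(g)
        consistent = frozenset(keep)
    return ConservationResult(
        boundary=boundary,
        species=species,
        n_universe=n_universe,
        set_sizes={sp: len(s) for sp, s in sets.items()},
        intersection=inter,
        direction_consistent=consistent,
    )


# ---------------------------------------------------------------------------
# Binomial overlap statistics
# ---------------------------------------------------------------------------


@dataclass
class BinomialOverlapResult:
    n_universe: int
    set_sizes: tuple
    p_per_gene: float
    expected_overlap: float
    observed_overlap: int
    tail_probability: float


def gene_recovery_probability(n_universe: int, set_sizes) -> float:
    """Chance that one fixed gene lies in every independently drawn set:
    p = prod_i k_i / N."""
    k = np.asarray(list(set_sizes), float)
    if (k < 0).any() or (k > n_universe).any():
        raise ValidationError("set sizes must lie in [0, N]")
    return float(np.prod(k / n_universe))


def binomial_overlap_test(
    n_universe: int, set_sizes, observed_overlap: int
) -> BinomialOverlapResult:
    """Exact binomial test of a multi-set overlap against the chance model.

    p = prod k_i/N per gene, expected overlap N*p, and the upper tail
    P(Binomial(N, p) >= X) by exact summation.
    """
    sizes = tuple(int(k) for k in set_sizes)
    if observed_overlap > min(sizes):
        raise ValidationError(
            f"observed overlap {observed_overlap} exceeds smallest set {min(sizes)}"
        )
    if observed_overlap < 0:
        raise ValidationError("observed overlap must be >= 0")
    p = gene_recovery_probability(n_universe, sizes)
    tail = float(binom.sf(observed_overlap - 1, n_universe, p))
    return BinomialOverlapResult(
        n_universe=n_universe,
        set_sizes=sizes,
        p_per_gene=p,
        expected_overlap=n_universe * p,
        observed_overlap=int(observed_overlap),
        tail_probability=tail,
    )


def overlap_null_montecarlo(
    n_universe: int, set_sizes, observed_overlap: int, n_draws: int = 10 ** 5,
    seed: int = 0, mode: str = "bernoulli",
) -> tuple[float, float]:
    """Monte-Carlo overlap null; the independent cross-check of
    :func:`binomial_overlap_test`.

    ``mode="bernoulli"`` (default) draws each gene into set i independently
    with probability k_i/N — the membership model the binomial test assumes,
    under which the overlap is exactly Binomial(N, prod k_i/N).
    ``mode="fixed_size"`` draws uniform k_i-subsets instead; memberships are
    then negatively correlated and the binomial tail overstates the true
    tail (it is conservative), noticeably so at small N.

    Returns (tail estimate, its binomial standard error).
    """
    rng = np.random.default_rng(seed)
    sizes = list(set_sizes)
    inter = np.ones((n_draws, n_universe), dtype=bool)
    for k in sizes:
        u = rng.random((n_draws, n_universe))
        if mode == "bernoulli":
            member = u < (k / n_universe)
        elif mode == "fixed_size":
            # uniform k-subsets per draw: the k smallest of N iid uniforms
            if k == 0:
                member = np.zeros_like(inter)
            else:
                kth = np.partition(u, k - 1, axis=1)[:, k - 1]
                member = u <= kth[:, None]
        else:
            raise ValidationError(f"unknown Monte-Carlo mode {mode!r}")
        inter &= member
    overlap = inter.sum(axis=1)
    est = float((overlap >= observed_overlap).mean())
    se = float(np.sqrt(max(est * (1 - est), 1.0 / n_draws) / n_draws))
    return est, se


# ---------------------------------------------------------------------------
# Fold changes and the matched-random-gene procedure
# ---------------------------------------------------------------------------


def fold_change(tpm_anterior, tpm_posterior, pseudocount: float = 1.0) -> np.ndarray:
    """log2((TPM_posterior + eps) / (TPM_anterior + eps)); antisymmetric
    under swapping the digits."""
    a = np.asarray(tpm_anterior, float)
    b = np.asarray(tpm_posterior, float)
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("TPM values must be >= 0")
    return np.log2((b + pseudocount) / (a + pseudocount))


def match_by_expression(
    origin_anchor: pd.Series, pool_anchor: pd.Series, exclude: dict | None = None
) -> pd.Series:
    """For each origin gene, the pool gene most similar in anchor TPM.

    ``origin_anchor``: origin gene -> TPM at the anterior digit;
    ``pool_anchor``: candidate gene -> anchor TPM in the target species;
    ``exclude`` maps each origin gene to the pool gene(s) it may not match
    (its own ortholog). Matching is independent per gene (repeats allowed);
    ties break to the lexicographically smallest gene ID.
    """
    if pool_anchor.empty:
        raise ValidationError("empty candidate pool")
    pool = pool_anchor.sort_index()
    pool_ids = np.array(pool.index)
    pool_vals = pool.to_numpy(float)
    out = {}
    for g, anchor in origin_anchor.items():
        banned = set()
        if exclude and g in exclude:
            ex = exclude[g]
            banned = {ex} if isinstance(ex, str) else set(ex)
        mask = ~np.isin(pool_ids, list(banned)) if banned else np.ones(len(pool_ids), bool)
        if not mask.any():
            raise ValidationError(f"candidate pool exhausted for origin gene {g!r}")
        diffs = np.abs(pool_vals[mask] - float(anchor))
        cand_ids = pool_ids[mask]
        best = np.flatnonzero(diffs == diffs.min())
        # pool is sorted by gene ID, so the first minimal entry is the
        # lexicographically smallest
        out[g] = cand_ids[best[0]]
    return pd.Series(out, name="matched_gene")


@dataclass
class FoldChangeCorrelationResult:
    """Ortholog vs matched-random fold-change correlations for one origin set."""

    origin_species: str
    boundary: tuple
    ortholog_r: pd.Series  # per (comparison species, stage) label
    random_r: pd.Series
    t_pvalue: float = np.nan
    mw_pvalue: float = np.nan
    mean_difference: float = np.nan

    def __post_init__(self):
        ok_o = self.ortholog_r.dropna()
        ok_r = self.random_r.dropna()
        if len(ok_o) >= 2 and len(ok_r) >= 2:
            self.t_pvalue = float(ttest_ind(ok_o, ok_r, equal_var=False).pvalue)
            self.mw_pvalue = float(
                mannwhitneyu(ok_o, ok_r, alternative="two-sided").pvalue
            )
        if len(ok_o) and len(ok_r):
            self.mean_difference = float(ok_o.mean() - ok_r.mean())


def _safe_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(pearsonr(x, y).statistic)


def foldchange_correlation_analysis(
    origin_species: str,
    boundary: tuple,
    origin_genes,
    tpm_by_species: dict,
    digit_of_sample: dict,
    orthologs: OrthologMap,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> FoldChangeCorrelationResult:
    """The matched-random-gene fold-change correlation procedure.

    For an origin species' DE gene set at one boundary: compute per-gene
    log2 TPM fold changes (posterior vs anterior digit means) in the origin
    species; in every other species compute (a) the fold changes of the
    orthologs and (b) the fold changes of random genes matched on anterior-
    digit TPM (own ortholog excluded); report the Pearson correlations of the
    origin vector against each, and compare the two collections with a
    Welch t-test and a Mann-Whitney U test.

    ``tpm_by_species``: species -> TPM ExpressionMatrix (or DataFrame);
    ``digit_of_sample``: species -> {sample: digit} for the two boundary
    digits. Stages are treated as separate comparisons when the sample
    index encodes them via ``digit_of_sample`` keys of the form
    (stage, {sample: digit}).
    """
    origin_genes = list(origin_genes)
    if len(origin_genes) < 3:
        raise ValidationError("origin DE set must have >=3 genes")
    d_ant, d_post = boundary
    o2o = orthologs.one_to_one_table()

    def digit_means(species):
        vals = tpm_by_species[species]
        vals = vals.values if hasattr(vals, "transform_state") else vals
        assign = digit_of_sample[species]
        ant = [s for s, d in assign.items() if d == d_ant]
        post = [s for s, d in assign.items() if d == d_post]
        if not ant or not post:
            raise ValidationError(f"species {species!r} lacks boundary digits")
        return vals[ant].mean(axis=1), vals[post].mean(axis=1)

    ant_o, post_o = digit_means(origin_species)
    # origin genes must be one-to-one ortholog members of the origin species
    groups = pd.Series(o2o.index, index=o2o[origin_species])
    origin_in_univ = [g for g in origin_genes if g in groups.index]
    if len(origin_in_univ) < 3:
        raise ValidationError("fewer than 3 origin genes in the one-to-one universe")
    fc_origin = pd.Series(
        fold_change(ant_o.loc[origin_in_univ], post_o.loc[origin_in_univ], pseudocount),
        index=origin_in_univ,
    )
    orth_r, rand_r = {}, {}
    for sp in tpm_by_species:
        if sp == origin_species:
            continue
        ant_t, post_t = digit_means(sp)
        target_genes = o2o.loc[groups.loc[origin_in_univ], sp]
        target_genes.index = origin_in_univ
        present = [g for g in origin_in_univ if target_genes[g] in ant_t.index]
        if len(present) < 3:
            orth_r[sp] = np.nan
            rand_r[sp] = np.nan
            continue
        tg = target_genes.loc[present]
        fc_orth = fold_change(ant_t.loc[tg], post_t.loc[tg], pseudocount)
        orth_r[sp] = _safe_pearson(fc_origin.loc[present], fc_orth)
        # matched random genes: pool = one-to-one orthologs of sp, excluding
        # each origin gene's own ortholog, matched on anterior TPM
        pool_genes = [g for g in o2o[sp] if g in ant_t.index]
        pool_anchor = ant_t.loc[pool_genes]
        matched = match_by_expression(
            ant_t.loc[tg].set_axis(present),
            pool_anchor,
            exclude={g: tg[g] for g in present},
        )
        fc_rand = fold_change(
            ant_t.loc[matched.values], post_t.loc[matched.values], pseudocount
        )
        rand_r[sp] = _safe_pearson(fc_origin.loc[present], fc_rand)
    return FoldChangeCorrelationResult(
        origin_species=origin_species,
        boundary=boundary,
        ortholog_r=pd.Series(orth_r, dtype=float),
        random_r=pd.Series(rand_r, dtype=float),
    )


def compare_correlation_sets(ortholog_r, random_r) -> dict:
    """Welch t-test and Mann-Whitney U comparison of pooled correlation
    collections (e.g. pooled across seeds or boundaries)."""
    o = pd.Series(ortholog_r, dtype=float).dropna()
    r = pd.Series(random_r, dtype=float).dropna()
    if len(o) < 2 or len(r) < 2:
        raise ValidationError("need >=2 correlations per group")
    return {
        "mean_ortholog_r": float(o.mean()),
        "mean_random_r": float(r.mean()),
        "mean_difference": float(o.mean() - r.mean()),
        "t_pvalue": float(ttest_ind(o, r, equal_var=False).pvalue),
        "mw_pvalue": float(mannwhitneyu(o, r, alternative="two-sided").pvalue),
    }
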