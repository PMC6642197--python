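"""Canned end-to-end study recipes on synthetic data.

Each function runs one complete analysis scenario — simulate, normalize,
test, summarize — under the package's default study conditions and returns
the headline quantities. They are the reproducible backbone for the
calibration checks, the examples, and the acceptance summary:

* adjacent-digit null calibration (p-value uniformity and type-I rate);
* conserved-module (CDEG) recovery across three species;
* bootstrap clustering support for a differentiated digit vs a homogeneous
  limb;
* frame-shift recovery by PCA projection of a 4-digit species into a
  5-digit reference plane;
* the matched-random-gene fold-change correlation comparison, planted and
  null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import conservation as cons
from . import diagnostics as dg
from . import multivariate as mv
from . import normalize as nm
from .diffexp import design_from_metadata, estimate_dispersions, lrt_pairwise
from .simulate import (
    SimulationConfig,
    SpeciesSpec,
    conserved_module_config,
    frameshift_scenario_config,
    null_config,
    score_recovery,
    simulate_counts,
)


def run_null_calibration(seed: int, n_genes: int = 2000) -> dict:
    """No planted effects, 2 digits x 3 replicates, sibling dispersions:
    adjacent-digit LRT p-values should be uniform with a ~5% type-I rate."""
    res = simulate_counts(null_config(seed=seed, n_genes=n_genes))
    cm = res.counts["mouse"]
    design = design_from_metadata(cm.metadata, (1, 2))
    disp = estimate_dispersions(cm, design)
    de = lrt_pairwise(cm, design, disp)
    p = de.table["pvalue"].dropna()
    rep = dg.pvalue_uniformity(p)
    return {
        "ks": rep.ks_distance,
        "frac_sig": float((p < 0.05).mean()),
        "n": int(p.size),
    }


def run_cdeg_recovery(seed: int, fdr: float = 0.05) -> dict:
    """Three species with a planted 30-gene conserved D1 module: run the
    D1-vs-D2 test per species, intersect DE sets over one-to-one orthologs,
    and score recovery against the planted truth."""
    res = simulate_counts(conserved_module_config(seed=seed))
    de_results = {}
    for sp, cm in res.counts.items():
        design = design_from_metadata(cm.metadata, (1, 2))
        disp = estimate_dispersions(cm, design)
        de_results[sp] = lrt_pairwise(cm, design, disp)
    sets, n_univ = cons.de_sets_by_boundary(de_results, res.orthologs, fdr)
    c = cons.intersect_conserved(sets, n_univ)
    sens, fdp = score_recovery(res.truth, c.intersection, "D1_module")
    overlap = cons.binomial_overlap_test(
        n_univ, [len(s) for s in sets.values()], len(c.intersection)
    )
    return {
        "sensitivity": sens,
        "fdp": fdp,
        "n_conserved": len(c.intersection),
        "set_sizes": c.set_sizes,
        "n_universe": n_univ,
        "expected_overlap": overlap.expected_overlap,
        "tail_probability": overlap.tail_probability,
    }


def run_planted_cluster_support(seed: int, n_boot: int = 1000) -> float:
    """Bootstrap support (BP, %) of the D1-replicate clade when the limb
    carries a strongly differentiated D1, clustering the TF gene list."""
    res = simulate_counts(conserved_module_config(seed=seed))
    cm = res.counts["mouse"]
    genes = sorted(res.gene_lists["tf_mouse"].members)
    em = nm.sqrt_transform(nm.tpm_matrix(cm, res.lengths)).subset_genes(genes)
    tree = mv.bootstrap_support(em, n_boot=n_boot, seed=seed)
    d1 = [s for s in cm.sample_ids if cm.metadata.loc[s, "digit"] == 1]
    bp = tree.support_of(d1)
    return -1.0 if bp is None else float(bp)  # -1: D1 not even monophyletic


def run_homogeneous_cluster_support(seed: int, n_boot: int = 1000) -> float:
    """Maximum non-root BP in a homogeneous (no planted structure) limb,
    clustering a random gene list of module size."""
    res = simulate_counts(null_config(seed=seed, n_genes=1000, n_digits=5))
    cm = res.counts["mouse"]
    rng = np.random.default_rng(seed)
    genes = list(rng.choice(cm.gene_ids, 30, replace=False))
    em = nm.sqrt_transform(nm.tpm_matrix(cm, res.lengths)).subset_genes(genes)
    tree = mv.bootstrap_support(em, n_boot=n_boot, seed=seed)
    return float(
        max(
            n.bp for n in tree.internal_nodes()
            if len(n.leaves()) < cm.n_samples
        )
    )


def run_frameshift_recovery(seed: int) -> dict:
    """Project the 4-digit frame-shift species into the 5-digit reference
    PCA plane (module gene set, per-species bulk centering) and check that
    position 2 reads as D1 and positions 3, 4 as D3, D4."""
    res = simulate_counts(frameshift_scenario_config(seed=seed))
    groups = sorted(set().union(*res.truth.modules_by_group.values()))
    o2o = res.orthologs.one_to_one_table()
    cm_ref = res.counts["pentadactyl"]
    cm_bird = res.counts["bird"]
    em_ref = nm.sqrt_transform(nm.tpm_matrix(cm_ref, res.lengths)).subset_genes(
        list(o2o.loc[groups, "pentadactyl"])
    )
    em_ref = nm.bulk_center(em_ref, {s: "ref" for s in em_ref.sample_ids})
    em_bird = nm.sqrt_transform(nm.tpm_matrix(cm_bird, res.lengths)).subset_genes(
        list(o2o.loc[groups, "bird"])
    )
    em_bird = nm.bulk_center(em_bird, {s: "bird" for s in em_bird.sample_ids})
    gene_map = dict(zip(o2o["bird"], o2o["pentadactyl"]))
    _, scores, call = mv.cross_species_projection(
        em_ref, cm_ref.metadata["digit"], em_bird, gene_map
    )
    tab = call.table.join(cm_bird.metadata["digit"].rename("position"))
    expected = {2: 1, 3: 3, 4: 4}
    correct = all(
        tab.loc[tab["position"] == pos, "digit"].eq(want).all()
        for pos, want in expected.items()
    )
    return {"correct": bool(correct), "calls": tab[["position", "digit", "margin"]]}


def run_foldchange_comparison(seed: int, fdr: float = 0.05) -> dict:
    """Planted conservation: mouse D1-vs-D2 DE genes, ortholog vs matched-
    random fold-change correlations in the other two species."""
    res = simulate_counts(conserved_module_config(seed=seed))
    cm = res.counts["mouse"]
    design = design_from_metadata(cm.metadata, (1, 2))
    disp = estimate_dispersions(cm, design)
    de = lrt_pairwise(cm, design, disp)
    sig = list(de.significant(fdr))
    tpms = {sp: nm.tpm_matrix(c, res.lengths) for sp, c in res.counts.items()}
    digit_of = {
        sp: {
            s: res.counts[sp].metadata.loc[s, "digit"]
            for s in res.counts[sp].sample_ids
            if res.counts[sp].metadata.loc[s, "digit"] in (1, 2)
        }
        for sp in res.counts
    }
    r = cons.foldchange_correlation_analysis(
        "mouse", (1, 2), sig, tpms, digit_of, res.orthologs, seed=seed
    )
    return {
        "ortholog_r": list(r.ortholog_r.dropna()),
        "random_r": list(r.random_r.dropna()),
    }


def _null_three_species(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_genes=625,
        ortholog_fraction=0.8,
        species=tuple(
            SpeciesSpec(n, homogeneous=True) for n in ("mouse", "alligator", "anolis")
        ),
        seed=seed,
    )


def run_foldchange_null(seed: int, origin_size: int = 46) -> dict:
    """No conservation: a random origin gene set, all adjacent boundaries x
    both comparison species; one Mann-Whitney comparison per seed."""
    res = simulate_counts(_null_three_species(seed))
    rng = np.random.default_rng(seed)
    o2o = res.orthologs.one_to_one_table()
    origin = list(rng.choice(o2o["mouse"], origin_size, replace=False))
    tpms = {sp: nm.tpm_matrix(c, res.lengths) for sp, c in res.counts.items()}
    o_all, r_all = [], []
    for b in [(1, 2), (2, 3), (3, 4), (4, 5)]:
        digit_of = {
            sp: {
                s: res.counts[sp].metadata.loc[s, "digit"]
                for s in res.counts[sp].sample_ids
                if res.counts[sp].metadata.loc[s, "digit"] in b
            }
            for sp in res.counts
        }
        r = cons.foldchange_correlation_analysis(
            "mouse", b, origin, tpms, digit_of, res.orthologs, seed=seed
        )
        o_all += list(r.ortholog_r.dropna())
        r_all += list(r.random_r.dropna())
    comp = cons.compare_correlation_sets(o_all, r_all)
    return {"mw_pvalue": comp["mw_pvalue"], "mean_difference": comp["mean_difference"]}
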