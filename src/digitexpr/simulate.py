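"""Synthetic multi-species digit count data with known ground truth.

The generator emulates the design of a comparative digit-transcriptomics
study: for each species, negative-binomial read counts over 4-5 digits x
2-4 replicates (optionally several stages), with

* gene-wise overdispersion phi drawn log-normally around a regime mean —
  a low "sibling" regime (inbred/sibling animals) and a high "population"
  regime (wild-caught animals);
* a shared one-to-one ortholog backbone: a configurable fraction of genes
  have exactly one counterpart in every species, with log-normal
  cross-species noise on the shared baseline so ortholog matching is
  informative but imperfect;
* planted digit-identity structure: digit-specific modules (e.g. a
  conserved D1 module of "transcription factor" genes up-regulated
  2^effect-fold in D1 of every species), an anterior-posterior gradient
  module, and species-specific modules;
* a frame-shift species whose digit at *position* 2 executes the D1
  identity program while positions 3 and 4 run their own posterior
  programs — the recoverable analogue of the bird-wing scenario;
* a homogeneous-species flag that silences all planted effects (the
  negative control for clustering and DE calibration).

Counts are NB with mean mu_gs = library_size_s x relative_expression and
variance mu + phi mu^2 (gamma-Poisson mixture; the phi -> 0 limit is
Poisson). Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    CountMatrix,
    GeneList,
    OrthologMap,
    TranscriptLengthTable,
    ValidationError,
)

#: log-normal dispersion regime means: sibling-derived vs population-derived
DISPERSION_REGIMES = {"sibling": 0.02, "population": 0.15}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModuleSpec:
    """A planted digit-identity module.

    ``digit`` is the *identity* (developmental program) whose samples carry
    the multiplicative 2**log2_effect; ``species`` restricts the module to
    one species (None = conserved, drawn from the ortholog backbone);
    ``is_tf`` flags members as transcription factors.
    """

    name: str
    n_genes: int
    log2_effect: float
    digit: int
    species: str | None = None
    is_tf: bool = True


@dataclass(frozen=True)
class GradientSpec:
    """An anterior-posterior gradient module.

    Member genes carry a log2 effect of
    ``direction * max_log2_effect * (identity - 3) / 4`` — graded
    monotonically along the digit series, centered on the middle digit, with
    half the genes increasing posteriorly (Hox-like) and half anteriorly, so
    the gradient axis is not confounded with a species' digit composition.
    """

    n_genes: int = 40
    max_log2_effect: float = 2.0
    name: str = "ap_gradient"


@dataclass(frozen=True)
class SpeciesSpec:
    """One species' sampling design and planted-structure switches.

    ``digit_identity`` maps digit *position* -> identity program (default:
    identity = position). A frame-shift species maps position 2 to identity
    1. ``homogeneous=True`` silences every planted effect (all digits share
    one expression profile up to noise).
    """

    name: str
    n_digits: int = 5
    replicates: int = 3
    dispersion_regime: str = "sibling"
    stages: tuple = ("s1",)
    limb: str = "fore"
    homogeneous: bool = False
    digit_identity: tuple | None = None  # ((position, identity-or-None), ...)

    def identity_of(self, position: int):
        if self.digit_identity is None:
            return position
        return dict(self.digit_identity).get(position, position)


def frameshift_species(
    name: str = "bird",
    replicates: int = 3,
    dispersion_regime: str = "population",
) -> SpeciesSpec:
    """A 4-digit species whose position-2 digit runs the D1 program and
    whose positions 3, 4 run their own posterior programs (position 1 runs
    no identity module)."""
    return SpeciesSpec(
        name=name,
        n_digits=4,
        replicates=replicates,
        dispersion_regime=dispersion_regime,
        digit_identity=((1, None), (2, 1), (3, 3), (4, 4)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    species: tuple = (SpeciesSpec("mouse"),)
    ortholog_fraction: float = 0.5
    modules: tuple = ()
    gradient: GradientSpec | None = None
    tf_fraction: float = 0.3  # non-module genes also flagged TF at this rate
    baseline_sdlog: float = 1.2  # spread of relative expression (natural log)
    library_size_mean: float = 1e6
    library_size_cv: float = 0.2
    cross_species_sd: float = 0.25  # log-normal ortholog baseline noise
    dispersion_sdlog: float = 0.5  # gene-wise spread around the regime mean
    stage_effect_sd: float = 0.15  # per-gene per-stage log-normal wobble
    length_range_bp: tuple = (500, 5000)  # log-uniform transcript lengths
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if not self.species:
            raise ValidationError("at least one species required")
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate species names")
        for sp in self.species:
            if sp.replicates <= 0 or sp.n_digits <= 0:
                raise ValidationError(f"degenerate design for species {sp.name!r}")
            if sp.dispersion_regime not in DISPERSION_REGIMES:
                raise ValidationError(
                    f"unknown dispersion regime {sp.dispersion_regime!r}"
                )
        if not 0.0 <= self.ortholog_fraction <= 1.0:
            raise ValidationError("ortholog_fraction must lie in [0, 1]")
        n_module = sum(m.n_genes for m in self.modules if m.species is None)
        n_module += self.gradient.n_genes if self.gradient else 0
        if n_module > int(self.ortholog_fraction * self.n_genes):
            raise ValidationError("conserved modules exceed the ortholog backbone")


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: per-gene module membership, true
    per-digit relative means and dispersions, per-sample library sizes."""

    config: SimulationConfig
    gene_truth: dict  # species -> DataFrame (index gene_id)
    sample_truth: pd.DataFrame  # index sample_id: species, library_size
    modules_by_group: dict  # module name -> frozenset of ortholog group IDs
    modules_by_species_gene: dict  # (species, module) -> frozenset of gene IDs

    def true_log2_effect(self, species: str, gene_id: str, digit_a: int, digit_b: int) -> float:
        row = self.gene_truth[species].loc[gene_id]
        return float(np.log2(row[f"rel_d{digit_b}"] / row[f"rel_d{digit_a}"]))


def score_recovery(
    truth: SyntheticTruth, called, target_module: str, species: str | None = None
) -> tuple[float, float]:
    """Sensitivity and false-discovery proportion of a called gene set
    against a planted module.

    With ``species=None`` the module and ``called`` are ortholog *group*
    IDs (the CDEG setting); otherwise species gene IDs.
    """
    if species is None:
        if target_module not in truth.modules_by_group:
            raise ValidationError(f"unknown module {target_module!r}")
        module = truth.modules_by_group[target_module]
    else:
        key = (species, target_module)
        if key not in truth.modules_by_species_gene:
            raise ValidationError(f"unknown module {key!r}")
        module = truth.modules_by_species_gene[key]
    called = set(called)
    sensitivity = len(called & module) / len(module)
    fdp = len(called - module) / max(1, len(called))
    return sensitivity, fdp


@dataclass
class SimulationResult:
    """Everything one simulation produces, keyed per species where the
    species' gene universes differ."""

    counts: dict  # species -> CountMatrix
    lengths: TranscriptLengthTable  # covers all species' genes
    orthologs: OrthologMap
    gene_lists: dict  # name -> GeneList
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def nb_draws(rng: np.random.Generator, mu, phi) -> np.ndarray:
    """NB(mu, phi) draws with var = mu + phi mu^2 via the gamma-Poisson
    mixture; phi <= 1e-12 falls back to Poisson."""
    mu = np.asarray(mu, float)
    phi = np.broadcast_to(np.asarray(phi, float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 1e-12
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        shape = 1.0 / phi[~pois]
        lam = rng.gamma(shape, phi[~pois] * mu[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def simulate_counts(config: SimulationConfig) -> SimulationResult:
    """Draw one synthetic dataset. Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_orth = int(round(config.ortholog_fraction * n))
    group_ids = [f"og{i:05d}" for i in range(n_orth)]
    species_names = [sp.name for sp in config.species]

    # shared ortholog baseline (relative expression, arbitrary scale)
    base_orth = rng.lognormal(0.0, config.baseline_sdlog, size=n_orth)

    # assign conserved modules (incl. gradient) to disjoint ortholog groups
    conserved = [m for m in config.modules if m.species is None]
    pool = rng.permutation(n_orth)
    cursor = 0
    modules_by_group: dict = {}
    module_of_group = np.full(n_orth, "", dtype=object)
    grad_level = np.zeros(n_orth)  # per-group gradient membership flag
    for m in conserved:
        idx = pool[cursor: cursor + m.n_genes]
        cursor += m.n_genes
        modules_by_group[m.name] = frozenset(group_ids[i] for i in idx)
        module_of_group[idx] = m.name
    if config.gradient is not None:
        g = config.gradient
        idx = pool[cursor: cursor + g.n_genes]
        cursor += g.n_genes
        modules_by_group[g.name] = frozenset(group_ids[i] for i in idx)
        module_of_group[idx] = g.name
        # alternate directions: half increase posteriorly, half anteriorly
        grad_level[idx] = np.where(np.arange(len(idx)) % 2 == 0, 1.0, -1.0)

    # TF flags: all conserved-module genes plus a random fraction elsewhere
    tf_group = np.array([bool(module_of_group[i]) for i in range(n_orth)], dtype=bool)
    extra = rng.random(n_orth) < config.tf_fraction
    tf_group |= extra

    ortho_rows = {sp: [f"{sp}_g{i:05d}" for i in range(n_orth)] for sp in species_names}
    counts_by_species: dict = {}
    gene_truth: dict = {}
    sample_rows = []
    modules_by_species_gene: dict = {}
    gene_lists: dict = {}
    lengths_all = {}

    sdlib = np.sqrt(np.log1p(config.library_size_cv ** 2))

    for sp in config.species:
        spn = sp.name
        n_priv = n - n_orth
        priv_ids = [f"{spn}_p{i:05d}" for i in range(n_priv)]
        gene_ids = ortho_rows[spn] + priv_ids

        base = np.empty(n)
        base[:n_orth] = base_orth * rng.lognormal(0.0, config.cross_species_sd, n_orth)
        base[n_orth:] = rng.lognormal(0.0, config.baseline_sdlog, n_priv)

        phi_mean = DISPERSION_REGIMES[sp.dispersion_regime]
        phi = rng.lognormal(
            np.log(phi_mean) - 0.5 * config.dispersion_sdlog ** 2,
            config.dispersion_sdlog,
            n,
        )

        module_label = np.full(n, "", dtype=object)
        module_label[:n_orth] = module_of_group
        is_tf = np.zeros(n, bool)
        is_tf[:n_orth] = tf_group
        is_tf[n_orth:] = rng.random(n_priv) < config.tf_fraction

        # species-specific modules drawn from private genes
        priv_pool = n_orth + rng.permutation(n_priv)
        pcur = 0
        for m in config.modules:
            if m.species != spn:
                continue
            idx = priv_pool[pcur: pcur + m.n_genes]
            if len(idx) < m.n_genes:
                raise ValidationError(
                    f"not enough private genes for module {m.name!r} in {spn!r}"
                )
            pcur += m.n_genes
            module_label[idx] = m.name
            is_tf[idx] |= m.is_tf
            modules_by_species_gene[(spn, m.name)] = frozenset(
                gene_ids[i] for i in idx
            )

        # per-identity log2 effects
        grad_gene = np.zeros(n)
        grad_gene[:n_orth] = grad_level
        identities = sorted(
            {sp.identity_of(p) for p in range(1, sp.n_digits + 1) if sp.identity_of(p) is not None}
        )
        effect_by_identity = {}
        for ident in set(identities) | set(range(1, 6)):
            eff = np.zeros(n)
            for m in config.modules:
                if m.digit != ident:
                    continue
                if m.species not in (None, spn):
                    continue
                eff += np.where(module_label == m.name, m.log2_effect, 0.0)
            if config.gradient is not None:
                eff += grad_gene * config.gradient.max_log2_effect * (ident - 3) / 4.0
            effect_by_identity[ident] = eff

        # relative expression per digit position
        rel = {}
        for pos in range(1, sp.n_digits + 1):
            ident = sp.identity_of(pos)
            if sp.homogeneous or ident is None:
                rel[pos] = base.copy()
            else:
                rel[pos] = base * 2.0 ** effect_by_identity[ident]
        scale = sum(b.sum() for b in rel.values()) / len(rel)
        for pos in rel:
            rel[pos] = rel[pos] / scale  # library size keeps its meaning

        stage_mult = {
            st: rng.lognormal(0.0, config.stage_effect_sd, n) for st in sp.stages
        }

        cols, col_names, meta_rows = [], [], []
        for st in sp.stages:
            for pos in range(1, sp.n_digits + 1):
                for rep in range(1, sp.replicates + 1):
                    sid = f"{spn}_{sp.limb}_{st}_d{pos}_r{rep}"
                    lib = rng.lognormal(
                        np.log(config.library_size_mean) - 0.5 * sdlib ** 2, sdlib
                    )
                    mu = lib * rel[pos] * stage_mult[st]
                    cols.append(nb_draws(rng, mu, phi))
                    col_names.append(sid)
                    meta_rows.append(
                        dict(
                            sample_id=sid,
                            species=spn,
                            limb=sp.limb,
                            digit=pos,
                            stage=st,
                            replicate=rep,
                        )
                    )
                    sample_rows.append(
                        dict(sample_id=sid, species=spn, library_size=lib)
                    )
        counts = pd.DataFrame(
            np.column_stack(cols), index=gene_ids, columns=col_names
        )
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        counts_by_species[spn] = CountMatrix(counts, meta)

        truth = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
        truth["group_id"] = group_ids + [""] * n_priv
        truth["module"] = module_label
        truth["is_tf"] = is_tf
        truth["phi"] = phi
        for pos in range(1, sp.n_digits + 1):
            truth[f"rel_d{pos}"] = rel[pos]
        gene_truth[spn] = truth

        lengths_all.update(
            dict(
                zip(
                    gene_ids,
                    np.exp(
                        rng.uniform(
                            np.log(config.length_range_bp[0]),
                            np.log(config.length_range_bp[1]),
                            n,
                        )
                    ),
                )
            )
        )

        gene_lists[f"tf_{spn}"] = GeneList(
            f"tf_{spn}", frozenset(np.array(gene_ids)[is_tf])
        )
        for m_name in modules_by_group:
            members = frozenset(
                ortho_rows[spn][i] for i in range(n_orth) if module_of_group[i] == m_name
            )
            modules_by_species_gene[(spn, m_name)] = members
            gene_lists[f"{m_name}_{spn}"] = GeneList(f"{m_name}_{spn}", members)

    ortho_table = pd.DataFrame(
        {sp: ortho_rows[sp] for sp in species_names},
        index=pd.Index(group_ids, name="group_id"),
    )
    orthologs = OrthologMap(ortho_table, tuple(species_names))
    truth = SyntheticTruth(
        config=config,
        gene_truth=gene_truth,
        sample_truth=pd.DataFrame(sample_rows).set_index("sample_id"),
        modules_by_group=modules_by_group,
        modules_by_species_gene=modules_by_species_gene,
    )
    return SimulationResult(
        counts=counts_by_species,
        lengths=TranscriptLengthTable(pd.Series(lengths_all, name="length")),
        orthologs=orthologs,
        gene_lists=gene_lists,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Canned study designs
# ---------------------------------------------------------------------------


def conserved_module_config(
    seed: int = 0,
    n_species: int = 3,
    n_orthologs: int = 1000,
    module_size: int = 30,
    log2_effect: float = 2.0,
    replicates: int = 3,
    regime: str = "sibling",
) -> SimulationConfig:
    """Three pentadactyl species sharing a conserved D1 identity module —
    the CDEG-recovery study design."""
    names = ["mouse", "alligator", "anolis", "human"][:n_species]
    n_genes = int(round(n_orthologs / 0.8))
    return SimulationConfig(
        n_genes=n_genes,
        ortholog_fraction=n_orthologs / n_genes,
        species=tuple(
            SpeciesSpec(nm, replicates=replicates, dispersion_regime=regime)
            for nm in names
        ),
        modules=(ModuleSpec("D1_module", module_size, log2_effect, digit=1),),
        seed=seed,
    )


def frameshift_scenario_config(seed: int = 0, replicates: int = 3) -> SimulationConfig:
    """A 5-digit reference species plus a 4-digit frame-shift species whose
    position-2 digit runs the D1 program; D1/D3/D4 identity modules plus an
    anterior-posterior gradient give every reference digit a distinct
    expression signature."""
    return SimulationConfig(
        n_genes=1250,
        ortholog_fraction=0.8,
        species=(
            SpeciesSpec("pentadactyl", replicates=replicates),
            frameshift_species("bird", replicates=replicates, dispersion_regime="sibling"),
        ),
        modules=(
            ModuleSpec("D1_module", 30, 2.0, digit=1),
            ModuleSpec("D3_module", 12, 1.0, digit=3),
            ModuleSpec("D4_module", 12, 1.0, digit=4),
        ),
        gradient=GradientSpec(n_genes=60, max_log2_effect=2.5),
        seed=seed,
    )


def null_config(
    seed: int = 0,
    n_genes: int = 2000,
    n_digits: int = 2,
    replicates: int = 3,
    regime: str = "sibling",
) -> SimulationConfig:
    """One species, no planted effects — the DE calibration null."""
    return SimulationConfig(
        n_genes=n_genes,
        ortholog_fraction=0.0,
        species=(
            SpeciesSpec(
                "mouse",
                n_digits=n_digits,
                replicates=replicates,
                dispersion_regime=regime,
                homogeneous=True,
            ),
        ),
        seed=seed,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["species"] = tuple(
        SpeciesSpec(**{**s, "stages": tuple(s.get("stages", ("s1",))),
                       "digit_identity": (tuple(map(tuple, s["digit_identity"]))
                                          if s.get("digit_identity") else None)})
        for s in d.get("species", [])
    )
    d["modules"] = tuple(ModuleSpec(**m) for m in d.get("modules", []))
    if d.get("gradient"):
        d["gradient"] = GradientSpec(**d["gradient"])
    if d.get("length_range_bp"):
        d["length_range_bp"] = tuple(d["length_range_bp"])
    return SimulationConfig(**d)
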