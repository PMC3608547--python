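"""High-level comparative meta-analyses.

Drives the full analysis programme over a comparative effect-size
dataset: overall mean effects, per-moderator level means, full
moderator models, interaction model building with DIC selection, the
within- versus across-male comparison, a median-split reporting view
of the cost-by-promiscuity interaction, and the phylogenetic variant
in which the nested taxonomy is replaced by a tree-derived species
relatedness matrix.

All effects are modelled on the Fisher-Z scale; reported summaries are
back-transformed to r per posterior draw (``tanh`` applied to each
draw, then summarised) unless ``r_scale="mean_z"`` is requested, which
back-transforms the Z-scale summaries instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy import stats as _stats

from .dataset import (
    DesignMatrixBundle,
    EffectRecord,
    MODERATORS,
    build_design,
    species_summary,
)
from .mixed import (
    FitSummary,
    MCMCSettings,
    ParamSummary,
    PosteriorSamples,
    Prior,
    fit,
    summarize,
    summarize_draws,
)

__all__ = [
    "AnalysisConfig",
    "PhyloStructure",
    "run_table1_analysis",
    "select_by_dic",
    "within_vs_across",
    "build_relatedness",
    "fit_phylogenetic",
    "cost_by_paternity_view",
]

#: the biologically motivated candidate interactions
CANDIDATE_INTERACTIONS = (
    ("zr_cost", "zr_benefit"),
    ("zr_cost", "multiple_paternity"),
    ("zr_benefit", "multiple_paternity"),
)


@dataclass
class AnalysisConfig:
    """What to run: dataset flavour, stage, terms and chain settings."""

    dataset: str = "adjust"
    stage: str = "single_term"  # single_term | full_model | interactions
    terms: List[str] = field(default_factory=list)
    interactions: List[Tuple[str, str]] = field(default_factory=list)
    prior: Prior = field(default_factory=Prior)
    settings: MCMCSettings = field(default_factory=MCMCSettings)
    r_scale: str = "tanh_mean"  # tanh per draw then summarise | "mean_z"

    def __post_init__(self) -> None:
        if self.stage not in ("single_term", "full_model", "interactions"):
            raise ValueError("unknown stage")
        mains = set(self.terms)
        for a, b in self.interactions:
            if a not in mains or b not in mains:
                raise ValueError(
                    f"interaction ({a}, {b}) references terms outside the main effects"
                )


def _r_summary(samples: PosteriorSamples, combo: np.ndarray, r_scale: str) -> ParamSummary:
    """Posterior summary of a linear combination of fixed effects on the r scale."""
    draws_z = samples.beta @ combo
    if r_scale == "tanh_mean":
        return summarize_draws(np.tanh(draws_z))
    z = summarize_draws(draws_z)
    return ParamSummary(
        mean=math.tanh(z.mean), sd=z.sd, mode=math.tanh(z.mode),
        ci_low=math.tanh(z.ci_low), ci_high=math.tanh(z.ci_high), pmcmc=z.pmcmc,
    )


def _term_rows(
    samples: PosteriorSamples,
    bundle: DesignMatrixBundle,
    term: str,
    r_scale: str,
) -> Dict[str, ParamSummary]:
    """Reporting rows for one model term.

    Two-level (-1/+1 coded) moderators are reported as level-specific
    mean effects, intercept -/+ coefficient; covariates and interaction
    columns are reported as their (Z-scale) slope.
    """
    p = len(samples.beta_names)
    rows: Dict[str, ParamSummary] = {}
    meta = bundle.coding.get(term)
    if meta is not None and meta["type"] == "factor2":
        j0 = samples.beta_names.index("intercept")
        j1 = samples.beta_names.index(term)
        for level, code in meta["levels"].items():
            combo = np.zeros(p)
            combo[j0] = 1.0
            combo[j1] = code
            rows[f"{term}={level}"] = _r_summary(samples, combo, r_scale)
        return rows
    for j, name in enumerate(samples.beta_names):
        if name == term or name.startswith(f"{term}["):
            rows[name] = summarize_draws(samples.beta[:, j])
    if not rows:
        raise ValueError(f"term {term!r} not present in the fitted model")
    return rows


def run_table1_analysis(
    records: Sequence[EffectRecord], config: AnalysisConfig
) -> dict:
    """Run one block of the analysis programme.

    ``single_term`` fits the intercept-only model (overall mean effect)
    plus one model per term; ``full_model`` fits everything jointly;
    ``interactions`` additionally builds candidate interaction models
    and selects the best by DIC.  Results carry r-scale summaries,
    pMCMC, DIC and variance-percent tables.
    """
    out: dict = {"dataset": config.dataset, "stage": config.stage, "blocks": {}}

    def one_fit(terms: Iterable[str], label: str, report_terms: Sequence[str]) -> dict:
        bundle = build_design(records, terms=terms)
        samples = fit(bundle, config.prior, config.settings)
        summary = summarize(samples, bundle)
        p = len(samples.beta_names)
        combo = np.zeros(p)
        combo[samples.beta_names.index("intercept")] = 1.0
        block = {
            "mean_effect_r": _r_summary(samples, combo, config.r_scale),
            "terms": {},
            "variance_percent": summary.variance_percent,
            "dic": summary.dic,
        }
        for term in report_terms:
            block["terms"][term] = _term_rows(samples, bundle, term, config.r_scale)
        out["blocks"][label] = block
        return {"bundle": bundle, "samples": samples, "summary": summary}

    if config.stage == "single_term":
        one_fit((), "overall", ())
        for term in config.terms:
            one_fit([term], term, [term])
    elif config.stage == "full_model":
        one_fit(config.terms, "full", config.terms)
    else:
        interactions = list(config.interactions) or [
            (a, b) for a, b in CANDIDATE_INTERACTIONS
            if a in config.terms and b in config.terms
        ]
        selection = select_by_dic(
            records, config.terms, interactions, config.prior, config.settings
        )
        out["dic_by_model"] = selection["dic_by_model"]
        out["best_model"] = selection["best_model"]
        label = "best"
        best_terms = selection["best_terms"]
        one_fit(best_terms, label, best_terms)
    return out


def select_by_dic(
    records: Sequence[EffectRecord],
    main_terms: Sequence[str],
    interactions: Sequence[Tuple[str, str]],
    prior: Prior = Prior(),
    settings: MCMCSettings = MCMCSettings(),
) -> dict:
    """Fit the main-effects model and each main+interaction model and
    rank them by DIC (lower is better)."""
    models: Dict[str, List] = {"main": list(main_terms)}
    for a, b in interactions:
        models[f"main+{a}:{b}"] = list(main_terms) + [f"{a}:{b}"]
    dic_by_model: Dict[str, float] = {}
    for label, terms in models.items():
        bundle = build_design(records, terms=terms)
        samples = fit(bundle, prior, settings)
        dic_by_model[label] = summarize(samples, bundle).dic
    best_model = min(dic_by_model, key=dic_by_model.get)
    return {
        "dic_by_model": dic_by_model,
        "best_model": best_model,
        "best_terms": models[best_model],
    }


def within_vs_across(
    records: Sequence[EffectRecord],
    prior: Optional[Prior] = None,
    settings: Optional[MCMCSettings] = None,
) -> dict:
    """Compare effects measured within males across breeding attempts with
    effects measured across males.

    Always reports, for species measured under both designs, the
    Spearman and Pearson correlations of their weighted mean Fisher-Z
    values.  When prior/settings are supplied, model-based per-scope
    mean effects (test_scope as a -1/+1 moderator) are included.
    """
    by_scope = {"within": [], "across": []}
    for rec in records:
        scope = rec.moderators.get("test_scope")
        if scope not in by_scope:
            raise ValueError(f"record {rec.effect_id} lacks a valid test_scope moderator")
        by_scope[scope].append(rec)

    means: Dict[str, Dict[str, float]] = {}
    for scope, recs in by_scope.items():
        if recs:
            tab = species_summary(recs)
            means[scope] = dict(zip(tab["species"], tab["mean_zr"]))
        else:
            means[scope] = {}
    both = sorted(set(means["within"]) & set(means["across"]))
    out: dict = {"n_species_both": len(both), "species_both": both}
    if len(both) >= 2:
        w = [means["within"][s] for s in both]
        a = [means["across"][s] for s in both]
        out["spearman"] = float(_stats.spearmanr(w, a).statistic)
        out["pearson"] = float(_stats.pearsonr(w, a).statistic)
        if len(both) < 3:
            out["warning"] = "fewer than 3 dual-scope species; correlations unstable"
    else:
        out["spearman"] = out["pearson"] = float("nan")
        out["warning"] = "fewer than 2 dual-scope species"

    if prior is not None and settings is not None:
        bundle = build_design(records, terms=["test_scope"])
        samples = fit(bundle, prior, settings)
        out["scope_means_r"] = {
            k: v.as_dict()
            for k, v in _term_rows(samples, bundle, "test_scope", "tanh_mean").items()
        }
    return out


@dataclass
class PhyloStructure:
    """A pruned tree plus the species relatedness matrix it implies."""

    tree: dendropy.Tree
    relatedness: np.ndarray
    species: List[str]

    def aligned(self, species: Sequence[str]) -> np.ndarray:
        """Relatedness matrix re-ordered to a given species list."""
        lut = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in species if s not in lut]
        if missing:
            raise ValueError(f"species not in the tree: {missing}")
        idx = np.array([lut[s] for s in species])
        return self.relatedness[np.ix_(idx, idx)]


def build_relatedness(
    newick_text: str, species_subset: Optional[Sequence[str]] = None
) -> PhyloStructure:
    """Parse a Newick tree, prune to the focal species, and build the
    relatedness matrix.

    ``A[i, j]`` is the root-to-MRCA path length shared by tips i and j,
    scaled per tip pair by the geometric mean of the two root-to-tip
    depths (for an ultrametric tree this is simply shared depth / total
    depth); the diagonal is 1.
    """
    tree = dendropy.Tree.get(data=newick_text, schema="newick")
    tree.is_rooted = True
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if species_subset is not None:
        missing = sorted(set(species_subset) - tip_labels)
        if missing:
            raise ValueError(f"tips absent from the tree: {missing}")
        tree.retain_taxa_with_labels(list(species_subset))
    tree.encode_bipartitions()
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    species = [lf.taxon.label for lf in leaves]
    depths = np.array([lf.distance_from_root() for lf in leaves])
    if np.any(depths <= 0):
        raise ValueError("zero-length root-to-tip path; tree has no usable branch lengths")
    n = len(leaves)
    A = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mrca = tree.mrca(taxa=[leaves[i].taxon, leaves[j].taxon])
            shared = mrca.distance_from_root()
            A[i, j] = A[j, i] = shared / math.sqrt(depths[i] * depths[j])
    return PhyloStructure(tree=tree, relatedness=A, species=species)


def fit_phylogenetic(
    bundle: DesignMatrixBundle,
    phylo: PhyloStructure,
    prior: Prior = Prior(),
    settings: MCMCSettings = MCMCSettings(),
) -> Tuple[FitSummary, PosteriorSamples]:
    """Phylogenetic mixed-model meta-analysis.

    The nested class/family/species structure is replaced by a single
    species effect ``u ~ N(0, sigma2 * A)`` with A from the tree; the
    study effect is retained.
    """
    A = phylo.aligned(bundle.group_labels["species"])
    samples = fit(
        bundle, prior, settings,
        random_effects=("species", "study"),
        block_cov={"species": A},
    )
    return summarize(samples, bundle), samples


def cost_by_paternity_view(records: Sequence[EffectRecord]) -> dict:
    """Median-split reporting view of the cost-by-promiscuity interaction.

    Species are split at the median multiple paternity; within each
    half, the adjustment effect (Fisher-Z) is regressed on the cost
    effect size by inverse-variance weighted least squares.  Purely a
    graphical/reporting device — the model itself keeps both variables
    continuous.
    """
    rows = [
        rec for rec in records
        if rec.covariates.get("multiple_paternity") is not None
        and rec.covariates.get("zr_cost") is not None
    ]
    if len(rows) < 4:
        raise ValueError("need at least 4 records with both covariates observed")
    mp = np.array([rec.covariates["multiple_paternity"] for rec in rows])
    median = float(np.median(mp))
    out = {"median_multiple_paternity": median, "halves": {}}
    for label, mask in (("low", mp <= median), ("high", mp > median)):
        recs = [r for r, m in zip(rows, mask) if m]
        if len(recs) < 2:
            out["halves"][label] = {"n": len(recs), "slope": float("nan")}
            continue
        x = np.array([r.covariates["zr_cost"] for r in recs])
        y = np.array([r.effect.zr for r in recs])
        w = np.array([r.effect.weight for r in recs])
        X = np.column_stack([np.ones(len(recs)), x])
        beta, *_ = np.linalg.lstsq(X * np.sqrt(w)[:, None], y * np.sqrt(w), rcond=None)
        out["halves"][label] = {
            "n": len(recs), "intercept": float(beta[0]), "slope": float(beta[1]),
        }
    return out
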