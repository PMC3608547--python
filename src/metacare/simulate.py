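"""Synthetic comparative effect-size datasets with known ground truth.

The generator emulates the statistical structure of a comparative
paternal-care meta-dataset: a nested taxonomy (class / family /
species / study), per-level Gaussian random effects, fixed effects on
coded moderators and standardised species-level covariates, and
observed Fisher-Z effect sizes equal to the latent value plus sampling
noise with variance exactly ``1/(n - 3)``.

The default ``paper_like`` preset reproduces the canonical dataset
shape used throughout the tests — 192 effect sizes from 62 studies on
48 species in 29 families and 5 classes — with an overall mean effect
of r = 0.35 (Fisher-Z 0.365) and random-effect variance split across
class / family / species / study / units as 34.78 / 17.99 / 9.17 /
36.15 / 1.91 percent of a total of 0.2.  Species-level covariates are
multiple paternity (uniform on 6.1-97.5%), cost and benefit effect
sizes, and proportion of male care, each with realistic missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dataset import EffectRecord, build_design
from .effects import EffectSize, TestStatistic, fisher_z

__all__ = ["SyntheticConfig", "generate_dataset", "generate_statistics", "generate_tree"]

#: variance fractions (percent) used by the paper_like preset, in the
#: order class, family, species, study, units
PAPER_LIKE_FRACTIONS = (34.78, 17.99, 9.17, 36.15, 1.91)


@dataclass
class SyntheticConfig:
    """Ground-truth configuration for one synthetic dataset."""

    n_classes: int = 5
    n_families: int = 29
    n_species: int = 48
    n_studies: int = 62
    n_effects: int = 192
    beta_true: Dict[str, float] = field(default_factory=lambda: {"intercept": 0.365})
    variance_true: Dict[str, float] = field(
        default_factory=lambda: dict(
            zip(("class", "family", "species", "study", "units"),
                (0.2 * f / 100.0 for f in PAPER_LIKE_FRACTIONS))
        )
    )
    n_median: float = 30.0       # per-effect sample sizes ~ lognormal
    n_sigma: float = 0.6
    n_min: int = 10
    mp_range: Tuple[float, float] = (6.1, 97.5)   # multiple paternity, percent
    zr_cost_mean: float = 0.27
    zr_cost_sd: float = 0.25
    zr_benefit_mean: float = 0.51
    zr_benefit_sd: float = 0.35
    missingness: Dict[str, float] = field(
        default_factory=lambda: {
            "multiple_paternity": 0.25,
            "zr_cost": 0.50,
            "zr_benefit": 0.29,
            "prop_male_care": 0.30,
        }
    )
    within_scope_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_classes, self.n_families, self.n_species,
                  self.n_studies, self.n_effects)
        if any(c <= 0 for c in counts):
            raise ValueError("all taxonomy counts must be positive")
        if not (self.n_classes <= self.n_families <= self.n_species
                <= self.n_studies <= self.n_effects):
            raise ValueError("counts must nest: classes <= families <= species <= studies <= effects")
        if any(v < 0 for v in self.variance_true.values()):
            raise ValueError("variances must be non-negative")
        if any(not (0 <= m < 1) for m in self.missingness.values()):
            raise ValueError("missingness fractions must lie in [0, 1)")

    @classmethod
    def paper_like(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """The canonical preset (see module docstring)."""
        return cls(seed=seed, **overrides)


def _partition(n_children: int, n_parents: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each of n_children a parent, every parent non-empty,
    extras spread at random — exact totals guaranteed."""
    base = np.arange(n_parents)
    extra = rng.choice(n_parents, size=n_children - n_parents, replace=True)
    return np.sort(np.concatenate([base, extra]))


def generate_dataset(config: SyntheticConfig) -> Tuple[List[EffectRecord], dict]:
    """Draw one synthetic dataset and its ground-truth record.

    Covariates are standardised (and missing cells imputed to zero)
    with exactly the same coding as the analysis pipeline before the
    true fixed effects are applied, so recovery tests compare like with
    like.
    """
    rng = np.random.default_rng(config.seed)

    fam_class = _partition(config.n_families, config.n_classes, rng)
    sp_family = _partition(config.n_species, config.n_families, rng)
    study_species = _partition(config.n_studies, config.n_species, rng)
    effect_study = _partition(config.n_effects, config.n_studies, rng)

    # species-level covariates, with missingness at the species level
    mp = rng.uniform(*config.mp_range, size=config.n_species)
    zr_cost = rng.normal(config.zr_cost_mean, config.zr_cost_sd, size=config.n_species)
    zr_benefit = rng.normal(config.zr_benefit_mean, config.zr_benefit_sd, size=config.n_species)
    pmc = rng.beta(2.0, 2.0, size=config.n_species)
    cov_values = {
        "multiple_paternity": mp, "zr_cost": zr_cost,
        "zr_benefit": zr_benefit, "prop_male_care": pmc,
    }
    cov_missing = {
        name: rng.random(config.n_species) < config.missingness.get(name, 0.0)
        for name in cov_values
    }

    n_sizes = np.maximum(
        np.round(np.exp(rng.normal(math.log(config.n_median), config.n_sigma,
                                   size=config.n_effects))).astype(int),
        config.n_min,
    )

    moderator_levels = {
        "care_measure": ("amount", "probability"),
        "design": ("experimental", "observational"),
        "genetic": ("no", "yes"),
        "female_access": ("no", "yes"),
        "competitor": ("no", "yes"),
    }
    moderators = {
        name: rng.choice(levels, size=config.n_effects)
        for name, levels in moderator_levels.items()
    }
    moderators["test_scope"] = np.where(
        rng.random(config.n_effects) < config.within_scope_frac, "within", "across"
    )
    moderators["outcome_measure"] = rng.choice(
        ("condition", "recruitment", "survival"), size=config.n_effects
    )

    def make_record(i: int, eff: EffectSize) -> EffectRecord:
        st = effect_study[i]
        sp = study_species[st]
        fam = sp_family[sp]
        cls_ = fam_class[fam]
        covs: Dict[str, Optional[float]] = {}
        for name, vals in cov_values.items():
            covs[name] = None if cov_missing[name][sp] else float(vals[sp])
        return EffectRecord(
            effect=eff,
            effect_id=f"e{i:04d}",
            study_id=f"st{st:03d}",
            species=f"sp{sp:03d}",
            family=f"f{fam:02d}",
            tax_class=f"c{cls_}",
            moderators={k: str(v[i]) for k, v in moderators.items()},
            covariates=covs,
        )

    # placeholder records to obtain the pipeline's own design coding
    placeholder = [make_record(i, EffectSize.from_r(0.0, int(n_sizes[i])))
                   for i in range(config.n_effects)]
    terms = [t for t in config.beta_true if t != "intercept"]
    bundle = build_design(placeholder, terms=terms)
    beta_vec = np.array([config.beta_true.get(c, 0.0) for c in bundle.columns])

    u: Dict[str, np.ndarray] = {}
    level_sizes = {
        "class": config.n_classes, "family": config.n_families,
        "species": config.n_species, "study": config.n_studies,
    }
    latent = bundle.X @ beta_vec
    for level, size in level_sizes.items():
        sd = math.sqrt(config.variance_true.get(level, 0.0))
        u[level] = rng.normal(0.0, sd, size=size) if sd > 0 else np.zeros(size)
        # bundle groups are sorted-label indices; synthetic labels sort numerically
        latent = latent + u[level][bundle.groups[level]]
    sd_units = math.sqrt(config.variance_true.get("units", 0.0))
    latent = latent + rng.normal(0.0, sd_units, size=config.n_effects)
    observed = latent + rng.normal(0.0, np.sqrt(1.0 / (n_sizes - 3)))

    records = [
        make_record(i, EffectSize.from_r(math.tanh(observed[i]), int(n_sizes[i])))
        for i in range(config.n_effects)
    ]
    truth = {
        "beta": dict(config.beta_true),
        "beta_columns": list(bundle.columns),
        "variance": dict(config.variance_true),
        "u": {k: v.tolist() for k, v in u.items()},
        "latent_zr": latent.tolist(),
        "config": asdict(config),
    }
    return records, truth


def generate_statistics(
    records: Sequence[EffectRecord],
    design: str = "two_group_t",
    seed: int = 0,
    noise: bool = True,
) -> List[EffectRecord]:
    """Replace each record's effect with one derived from a simulated raw
    study, populating the TestStatistic fields.

    ``two_group_t`` simulates a two-group comparison of total size n
    whose point-biserial correlation has the record's r as truth and
    reports the t statistic (df = n - 2); ``correlation`` simulates a
    bivariate normal sample and reports the observed r.  With
    ``noise=False`` the statistic is computed from the exact closed
    form, so conversion recovers the input r.
    """
    rng = np.random.default_rng(seed)
    out: List[EffectRecord] = []
    for rec in records:
        r_true = rec.effect.r
        n = rec.effect.n
        if n < 4:
            raise ValueError("simulating a study requires n >= 4")
        if design == "two_group_t":
            df = n - 2
            if noise:
                x = np.zeros(n)
                x[: n // 2] = 1.0
                xc = (x - x.mean()) / x.std(ddof=0)
                yvals = r_true * xc + math.sqrt(max(1.0 - r_true**2, 1e-12)) * rng.standard_normal(n)
                r_obs = float(np.corrcoef(x, yvals)[0, 1])
                r_obs = max(min(r_obs, 0.999999), -0.999999)
            else:
                r_obs = r_true
            t = r_obs * math.sqrt(df / max(1.0 - r_obs**2, 1e-12))
            stat = TestStatistic(kind="t", value=abs(t), df1=df, n=n,
                                 sign=1 if t >= 0 else -1)
        elif design == "correlation":
            if noise:
                cov = [[1.0, r_true], [r_true, 1.0]]
                sample = rng.multivariate_normal([0.0, 0.0], cov, size=n)
                r_obs = float(np.corrcoef(sample[:, 0], sample[:, 1])[0, 1])
                r_obs = max(min(r_obs, 0.999999), -0.999999)
            else:
                r_obs = r_true
            stat = TestStatistic(kind="r", value=r_obs, n=n)
        else:
            raise ValueError("design must be 'two_group_t' or 'correlation'")
        out.append(
            EffectRecord(
                effect=EffectSize.from_statistic(stat),
                effect_id=rec.effect_id,
                study_id=rec.study_id,
                species=rec.species,
                family=rec.family,
                tax_class=rec.tax_class,
                dataset=rec.dataset,
                moderators=dict(rec.moderators),
                covariates=dict(rec.covariates),
                statistic=stat,
            )
        )
    return out


class _Node:
    __slots__ = ("birth", "children", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.children: List["_Node"] = []
        self.label: Optional[str] = None


def generate_tree(n_tips: int, seed: int = 0, labels: Optional[Sequence[str]] = None) -> str:
    """Ultrametric pure-birth (Yule) tree as a Newick string.

    Tip labels default to ``sp000 .. sp{n-1}`` to match the synthetic
    species naming.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    if labels is not None and len(labels) != n_tips:
        raise ValueError("labels must match n_tips")
    rng = np.random.default_rng(seed)
    # the root splits at time 0 into two lineages; a lineage spans from its
    # birth to the moment it splits (or to the present, t_end, for tips)
    root = _Node(0.0)
    first, second = _Node(0.0), _Node(0.0)
    root.children = [first, second]
    active = [first, second]
    t = 0.0
    while len(active) < n_tips:
        t += float(rng.exponential(1.0 / len(active)))
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        kids = [_Node(t), _Node(t)]
        parent.children = kids
        active.extend(kids)
    t_end = t + float(rng.exponential(1.0 / n_tips))
    if labels is None:
        labels = [f"sp{i:03d}" for i in range(n_tips)]
    for node, label in zip(active, labels):
        node.label = label

    def newick(node: _Node) -> str:
        end = node.children[0].birth if node.children else t_end
        length = end - node.birth
        if not node.children:
            return f"{node.label}:{length:.10f}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{length:.10f}"

    inner = ",".join(newick(c) for c in root.children)
    return f"({inner});"
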