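"""Synthetic clonal-strain observation tables with known ground truth.

The generator emulates a panel of clonal (parthenogenetic) strains scored
for discrete morphological characters: every individual of a strain
shares the strain's latent genetic value, so between-strain variance is
genetic.  Per character, strain effects are drawn on the link scale
(Normal with variance σ²G, plus an optional clade shift), individuals are
Bernoulli or Poisson draws through the canonical link, bilateral
characters get an independent draw per body side, rare outliers push
near-two-valued counts beyond their common range, and observations go
missing sporadically ("not always visible" on a slide mount).

The truth record keeps every latent value and the implied latent-scale
H² per character, so parameter-recovery tests never re-simulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .data_io import (
    BinaryTaxonMatrix,
    CharacterSpec,
    ObservationTable,
    ThresholdRule,
    Tree,
    TreeNode,
    ValidationError,
)
from .heritability import LOGIT_RESIDUAL_VARIANCE, poisson_residual_variance

__all__ = [
    "CharacterConfig",
    "GeneratorConfig",
    "TruthRecord",
    "SyntheticDataset",
    "generate_observations",
    "generate_matrix_on_tree",
    "study_default_config",
    "two_clade_config",
]


@dataclass(frozen=True)
class CharacterConfig:
    """Generative settings for one character.

    ``baseline`` is on the link scale (logit of the state-1 probability,
    or log of the expected count).  ``sigma2_G`` is the strain-effect
    variance on that scale.  ``clade_coef`` scales the global clade
    effect for this character (clade B shifted by +coef·effect/2, clade A
    by −coef·effect/2).  For binomial characters with ``threshold_cut``,
    raw values are emitted as counts: cut + state, with outliers pushed
    outward past the common pair at ``outlier_rate``.  ``strain_offsets``
    adds fixed link-scale shifts for named strains.
    """

    character_id: str
    family: str
    baseline: float = 0.0
    sigma2_G: float = 0.0
    bilateral: bool = False
    outlier_rate: float = 0.0
    threshold_cut: Optional[int] = None
    clade_coef: float = 1.0
    body_part: str = "head"
    strain_offsets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma2_G < 0:
            raise ValidationError("sigma2_G must be ≥ 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValidationError("outlier_rate must be in [0, 1]")

    def to_spec(self) -> CharacterSpec:
        rule = None
        if self.threshold_cut is not None:
            rule = ThresholdRule(self.character_id, self.threshold_cut, True)
        return CharacterSpec(
            character_id=self.character_id, body_part=self.body_part,
            family=self.family, bilateral=self.bilateral, binarize_rule=rule,
            description="synthetic",
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design for a synthetic strain panel.

    ``n_individuals`` is an int or an inclusive (low, high) range drawn
    per strain.  ``clades`` maps strains to "A"/"B"; unmapped strains get
    no clade shift.  ``seed`` is mandatory: all randomness flows from it.
    """

    strains: tuple[str, ...]
    characters: tuple[CharacterConfig, ...]
    seed: int
    n_individuals: int | tuple[int, int] = (8, 12)
    clades: dict = field(default_factory=dict)
    clade_effect: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError("missing_rate must be in [0, 1]")
        if len(set(self.strains)) != len(self.strains):
            raise ValidationError("strain labels must be unique")


@dataclass
class TruthRecord:
    """Generative ground truth: latent values and implied heritabilities.

    ``true_H2`` uses the generative parameters (σ²G plus the population
    variance of the clade offsets, over the latent-scale residual
    convention); ``realized_H2`` uses the realized strain effects.
    """

    strain_effects: dict  # character_id -> {strain: latent effect incl. clade shift}
    clade_offsets: dict   # character_id -> {strain: clade component only}
    true_H2: dict
    realized_H2: dict
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


@dataclass
class SyntheticDataset:
    table: ObservationTable
    specs: dict
    truth: TruthRecord


def _clade_offset(cfg: GeneratorConfig, char: CharacterConfig, strain: str) -> float:
    clade = cfg.clades.get(strain)
    if clade == "A":
        return -char.clade_coef * cfg.clade_effect / 2.0
    if clade == "B":
        return +char.clade_coef * cfg.clade_effect / 2.0
    return 0.0


def _true_h2(char: CharacterConfig, offsets: Sequence[float]) -> float:
    off = np.asarray(offsets, dtype=float)
    var_between = char.sigma2_G + float(off.var())  # population variance of clade shifts
    if char.family == "binomial":
        resid = LOGIT_RESIDUAL_VARIANCE
    else:
        # marginal mean of a lognormal-latent Poisson
        lam = float(np.mean(np.exp(char.baseline + off + char.sigma2_G / 2.0)))
        resid = poisson_residual_variance(lam)
    if var_between == 0.0:
        return 0.0
    return var_between / (var_between + resid)


def generate_observations(config: GeneratorConfig) -> SyntheticDataset:
    """Draw an observation table plus its ground-truth record."""
    rng = np.random.default_rng(config.seed)
    strains = list(config.strains)
    if isinstance(config.n_individuals, int):
        n_ind = {s: config.n_individuals for s in strains}
    else:
        lo, hi = config.n_individuals
        n_ind = {s: int(rng.integers(lo, hi + 1)) for s in strains}

    rows = []
    strain_effects: dict = {}
    clade_offsets: dict = {}
    true_h2: dict = {}
    realized_h2: dict = {}
    for char in config.characters:
        cid = char.character_id
        offsets = {s: _clade_offset(config, char, s) + char.strain_offsets.get(s, 0.0)
                   for s in strains}
        iid = rng.normal(0.0, np.sqrt(char.sigma2_G), size=len(strains))
        eff = {s: offsets[s] + iid[i] for i, s in enumerate(strains)}
        strain_effects[cid] = eff
        clade_offsets[cid] = offsets
        true_h2[cid] = _true_h2(char, list(offsets.values()))
        eff_arr = np.array(list(eff.values()))
        var_real = float(eff_arr.var())
        if char.family == "binomial":
            resid = LOGIT_RESIDUAL_VARIANCE
        else:
            lam = float(np.mean(np.exp(char.baseline + eff_arr)))
            resid = poisson_residual_variance(lam)
        realized_h2[cid] = var_real / (var_real + resid) if var_real > 0 else 0.0

        for s in strains:
            eta = char.baseline + eff[s]
            sides = ("left", "right") if char.bilateral else ("none",)
            for j in range(n_ind[s]):
                ind = f"{s}-{j + 1:02d}"
                for side in sides:
                    if char.family == "binomial":
                        p = 1.0 / (1.0 + np.exp(-eta))
                        state = int(rng.random() < p)
                        if char.threshold_cut is None:
                            value = state
                        else:
                            value = char.threshold_cut + state
                            if char.outlier_rate > 0 and rng.random() < char.outlier_rate:
                                jump = int(rng.integers(2, 4))  # 2 or 3
                                value = value - jump if state == 0 else value + jump
                                value = max(value, 0)
                    else:
                        value = int(rng.poisson(np.exp(eta)))
                    missing = rng.random() < config.missing_rate
                    rows.append((s, ind, cid, side,
                                 np.nan if missing else float(value)))

    import pandas as pd

    df = pd.DataFrame(rows, columns=ObservationTable.COLUMNS)
    specs = {c.character_id: c.to_spec() for c in config.characters}
    table = ObservationTable(df, specs)
    truth = TruthRecord(strain_effects=strain_effects, clade_offsets=clade_offsets,
                        true_H2=true_h2, realized_H2=realized_h2, seed=config.seed)
    return SyntheticDataset(table=table, specs=specs, truth=truth)


def generate_matrix_on_tree(tree: Tree, n_characters: int, flip_prob: float,
                            seed: int) -> tuple[BinaryTaxonMatrix, Tree]:
    """Evolve binary characters root→leaves; each edge flips the state w.p. flip_prob.

    Returns the matrix and the generating tree (the recovery truth).
    """
    if not 0.0 <= flip_prob < 0.5:
        raise ValidationError("flip_prob must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    taxa = tree.leaf_labels()
    states = {t: np.zeros(n_characters, dtype=int) for t in taxa}

    def walk(node: TreeNode, state: np.ndarray) -> None:
        for child in node.children:
            flips = rng.random(n_characters) < flip_prob
            child_state = np.where(flips, 1 - state, state)
            if child.is_leaf:
                states[child.label] = child_state
            else:
                walk(child, child_state)

    root_state = rng.integers(0, 2, size=n_characters)
    walk(tree.root, root_state)
    matrix = BinaryTaxonMatrix(
        taxa=taxa, characters=[f"c{j + 1:02d}" for j in range(n_characters)],
        states=np.array([states[t] for t in taxa]),
    )
    return matrix, tree


def two_clade_config(seed: int, *, n_characters: int = 8,
                     clade_effect: float = 2.0, sigma2_G: float = 0.25,
                     n_individuals: int = 10) -> GeneratorConfig:
    """Two-clade recovery benchmark: 12 strains in clades of 5 and 7.

    Binary characters with a link-scale clade separation of
    ``clade_effect`` over iid strain noise of variance ``sigma2_G``
    (default separation / within-clade sd = 4, the strong-separation
    regime in which both tree methods are expected to recover the clades).
    """
    A = tuple(f"A{i}" for i in range(1, 6))
    B = tuple(f"B{i}" for i in range(1, 8))
    chars = tuple(
        CharacterConfig(character_id=f"{j:02d}", family="binomial",
                        sigma2_G=sigma2_G, clade_coef=1.0)
        for j in range(1, n_characters + 1)
    )
    return GeneratorConfig(
        strains=A + B, characters=chars, seed=seed,
        n_individuals=n_individuals,
        clades={**{s: "A" for s in A}, **{s: "B" for s in B}},
        clade_effect=clade_effect,
    )


# ---------------------------------------------------------------------------
# the default study-like panel


def study_default_config(seed: int) -> GeneratorConfig:
    """A 12-strain panel shaped like the real study design.

    Eleven clonal strains in two clades (five in A, six in B) plus one
    sexual lineage of unresolved affinity; 18 characters spanning the
    three kinds such a chaetotaxic survey produces: nine strongly
    heritable two-state characters, a borderline and three non-divergent
    subcoxal counts, and wide-range setal counts with weak strain
    structure.  Between-strain variances are back-computed from the
    target heritabilities via the latent-scale residual convention; for
    the clade-patterned characters half of that variance is carried by
    the clade split.
    """
    A = ("AP", "GB", "HA", "BR", "BV")
    B = ("DK", "GM", "PB", "TO", "US", "WI")
    clades = {**{s: "A" for s in A}, **{s: "B" for s in B}}
    strains = ("SH",) + A + B

    pi2_3 = LOGIT_RESIDUAL_VARIANCE

    def bino(cid, part, h2, *, cut=None, bilateral=False, clade_frac=0.0,
             outlier_rate=0.0):
        total = h2 / (1.0 - h2) * pi2_3
        delta = np.sqrt(2.0 * clade_frac * total)  # offsets ±delta/2 carry ~clade_frac of total
        return CharacterConfig(
            character_id=cid, family="binomial", baseline=0.0,
            sigma2_G=total * (1.0 - clade_frac), bilateral=bilateral,
            outlier_rate=outlier_rate, threshold_cut=cut,
            clade_coef=delta, body_part=part,
        )

    def pois(cid, part, lam, h2, *, bilateral=False, clade_frac=0.0, offsets=None):
        resid = poisson_residual_variance(lam)
        total = h2 / (1.0 - h2) * resid if h2 > 0 else 0.0
        delta = np.sqrt(2.0 * clade_frac * total) if total > 0 else 0.0
        return CharacterConfig(
            character_id=cid, family="poisson", baseline=float(np.log(lam)),
            sigma2_G=total * (1.0 - clade_frac), bilateral=bilateral,
            clade_coef=delta, body_part=part,
            strain_offsets=offsets or {},
        )

    characters = (
        bino("01", "head", 0.94),
        bino("02", "head", 0.78, cut=4, outlier_rate=0.01, clade_frac=0.5),
        pois("03", "head", 24.0, 0.044, clade_frac=0.5),
        bino("04", "head", 0.86, cut=4, outlier_rate=0.01),
        bino("05", "head", 0.94, bilateral=True, clade_frac=0.5),
        bino("06", "thorax", 0.20, cut=3, outlier_rate=0.01),
        pois("07", "thorax", 8.0, 0.0),
        pois("08", "thorax", 6.0, 0.0),
        pois("09", "thorax", 10.0, 0.0),
        bino("10", "thorax", 0.88),
        bino("11", "thorax", 0.78, cut=1, clade_frac=0.5),
        pois("12", "abdomen", 30.0, 0.03, bilateral=True,
             offsets={"SH": -0.15}),
        pois("13", "abdomen", 6.0, 0.12),
        bino("14", "abdomen", 0.80, cut=3, outlier_rate=0.01),
        bino("15", "abdomen", 0.15, cut=3, outlier_rate=0.01),
        bino("16", "abdomen", 0.94, cut=2, outlier_rate=0.01, clade_frac=0.5),
        bino("17", "abdomen", 0.85, cut=1, bilateral=True, outlier_rate=0.01),
        pois("18", "abdomen", 18.0, 0.12, bilateral=True, clade_frac=0.5),
    )
    return GeneratorConfig(
        strains=strains, characters=characters, seed=seed,
        n_individuals=(8, 12), clades=clades, clade_effect=1.0,
        missing_rate=0.05,
    )
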