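"""Exact segregation model for a haploid two-parent cross with epistasis.

A cross between two haploid lines produces haploid progeny whose genotype at
each functional locus is simply the parent of origin of that chromosomal
segment.  With ``k`` functional loci on distinct chromosomes, the progeny
fall into ``2**k`` equiprobable genotype classes.  A phenotype rule maps
each class to a phenotype (here: ``suppressed`` = capable of 3D gametophore
growth, ``non_suppressed`` = the original 2D-restricted mutant phenotype),
and an optional per-class relative viability distorts the Mendelian ratios.

The canonical design modelled here is a suppressor screen: parent 1 is the
mutagenized line carrying both the selection-locus disruption (*NOG1*) and
the unknown suppressor lesion (*SNOG1A*); parent 2 is the wild-type donor
(Reute).  Progeny are non-suppressed only when they inherit the selection
mutation *without* the suppressor lesion — exactly one of the four classes —
so a quarter of viable progeny show the original mutant phenotype.

Conditioning the classes on phenotype gives the allele frequencies expected
in phenotype-sorted sequencing pools: the wild-type-donor allele at the
suppressor locus has frequency 1 in the non-suppressed (control) pool and
1/3 in the suppressed (mutant) pool; any unlinked marker sits at 1/2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUPPRESSED",
    "NON_SUPPRESSED",
    "POOL_PHENOTYPE",
    "FunctionalLocus",
    "PhenotypeModel",
    "ExpectedPoolFrequency",
    "GoodnessOfFit",
    "suppressor_screen_model",
    "enumerate_progeny_classes",
    "expected_phenotype_fraction",
    "expected_pool_allele_frequency",
    "infer_viability",
    "segregation_goodness_of_fit",
]

SUPPRESSED = "suppressed"
NON_SUPPRESSED = "non_suppressed"

#: phenotype that defines membership of each sequencing pool
POOL_PHENOTYPE = {"control": NON_SUPPRESSED, "mutant": SUPPRESSED}

_ROLES = ("selection", "suppressor")


@dataclass(frozen=True)
class FunctionalLocus:
    """A phenotype-determining locus segregating in the cross.

    Parameters
    ----------
    name
        Locus identifier, e.g. ``"NOG1"``.
    chromosome
        Chromosome carrying the locus.
    position_bp
        0-based physical position.
    position_cm
        Genetic map position in centimorgans.
    mutant_parent
        Which parent (1 or 2) carries the non-functional allele.
    role
        ``"selection"`` for the locus the screen selects on (the *NOG1*
        disruption) or ``"suppressor"`` for the lesion being mapped.
    """

    name: str
    chromosome: str
    position_bp: int
    position_cm: float
    mutant_parent: int
    role: str

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"locus {self.name}: position_bp must be >= 0")
        if self.position_cm < 0:
            raise ValueError(f"locus {self.name}: position_cm must be >= 0")
        if self.mutant_parent not in (1, 2):
            raise ValueError(f"locus {self.name}: mutant_parent must be 1 or 2")
        if self.role not in _ROLES:
            raise ValueError(f"locus {self.name}: role must be one of {_ROLES}")


@dataclass(frozen=True)
class PhenotypeModel:
    """Epistasis rule plus per-class viability for a haploid cross.

    ``rule`` maps each allele combination — a tuple giving the parent of
    origin (1 or 2) at every locus, in ``loci`` order — to a phenotype
    label.  ``viability`` gives the relative survival of each class;
    classes omitted from the mapping default to 1.
    """

    loci: tuple[FunctionalLocus, ...]
    rule: Mapping[tuple[int, ...], str]
    viability: Mapping[tuple[int, ...], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("PhenotypeModel needs at least one locus")
        for combo in self.all_combinations():
            if combo not in self.rule:
                raise ValueError(
                    f"phenotype rule is incomplete: missing allele combination {combo}"
                )
        for combo, v in self.viability.items():
            if combo not in self.rule:
                raise ValueError(f"viability given for unknown combination {combo}")
            if not v > 0:
                raise ValueError(f"viability for {combo} must be > 0, got {v}")

    def all_combinations(self) -> list[tuple[int, ...]]:
        return list(itertools.product((1, 2), repeat=len(self.loci)))

    def class_viability(self, combo: tuple[int, ...]) -> float:
        return float(self.viability.get(combo, 1.0))

    def phenotypes(self) -> set[str]:
        return set(self.rule.values())

    def locus(self, role_or_name: str) -> FunctionalLocus:
        """Look a locus up by role (``selection``/``suppressor``) or name."""
        for loc in self.loci:
            if loc.role == role_or_name or loc.name == role_or_name:
                return loc
        raise KeyError(f"no locus with role or name {role_or_name!r}")

    def class_label(self, combo: tuple[int, ...]) -> str:
        parts = []
        for locus, origin in zip(self.loci, combo):
            mutant = origin == locus.mutant_parent
            parts.append(locus.name.lower() if mutant else locus.name.upper())
        return "/".join(parts)


@dataclass(frozen=True)
class ExpectedPoolFrequency:
    """Expected parent-2 allele frequency at a marker linked to a locus."""

    pool: str
    recombination_fraction: float
    frequency: float


@dataclass(frozen=True)
class GoodnessOfFit:
    statistic: float
    df: int
    pvalue: float


def _default_selection_locus() -> FunctionalLocus:
    return FunctionalLocus("NOG1", "Chr01", 2_000_000, 40.0, 1, "selection")


def _default_suppressor_locus() -> FunctionalLocus:
    return FunctionalLocus("SNOG1A", "Chr08", 2_500_000, 50.0, 1, "suppressor")


def suppressor_screen_model(
    selection: FunctionalLocus | None = None,
    suppressor: FunctionalLocus | None = None,
    selection_class_viability: float = 1.0,
) -> PhenotypeModel:
    """Build the canonical two-locus suppressor-screen model.

    Parent 1 (the mutagenized line) carries the non-functional allele at
    both loci.  A progeny individual is non-suppressed only when it carries
    the selection-locus mutation together with the wild-type suppressor
    allele; every other combination can grow 3D shoots.
    ``selection_class_viability`` reduces the survival of every class that
    carries the selection-locus mutant allele (modelling, e.g., impaired
    spore germination of the disruptant), leaving the rule itself intact.
    """
    selection = selection or _default_selection_locus()
    suppressor = suppressor or _default_suppressor_locus()
    if selection.role != "selection" or suppressor.role != "suppressor":
        raise ValueError("loci must be passed with matching roles")
    loci = (selection, suppressor)
    rule: dict[tuple[int, ...], str] = {}
    viability: dict[tuple[int, ...], float] = {}
    for combo in itertools.product((1, 2), repeat=2):
        sel_mutant = combo[0] == selection.mutant_parent
        sup_mutant = combo[1] == suppressor.mutant_parent
        rule[combo] = NON_SUPPRESSED if (sel_mutant and not sup_mutant) else SUPPRESSED
        if sel_mutant and selection_class_viability != 1.0:
            viability[combo] = selection_class_viability
    return PhenotypeModel(loci=loci, rule=rule, viability=viability)


def enumerate_progeny_classes(model: PhenotypeModel) -> pd.DataFrame:
    """Enumerate all ``2**k`` progeny genotype classes.

    Returns a table with one row per allele combination: the raw Mendelian
    probability (``2**-k`` each), the viability-adjusted probability
    (renormalized to sum to 1), and the phenotype assigned by the rule.
    """
    combos = model.all_combinations()
    k = len(model.loci)
    raw = np.full(len(combos), 2.0**-k)
    viab = np.array([model.class_viability(c) for c in combos])
    adj = raw * viab
    adj = adj / adj.sum()
    return pd.DataFrame(
        {
            "origins": combos,
            "label": [model.class_label(c) for c in combos],
            "raw_prob": raw,
            "viability": viab,
            "adj_prob": adj,
            "phenotype": [model.rule[c] for c in combos],
        }
    )


def expected_phenotype_fraction(model: PhenotypeModel, phenotype: str) -> float:
    """Viability-adjusted probability that a surviving progeny shows ``phenotype``.

    For the canonical screen rule with a shared viability ``v`` on the two
    selection-mutant classes this equals ``v / (2 + 2 v)`` for the
    non-suppressed phenotype — 1/4 at full viability.
    """
    if phenotype not in model.phenotypes():
        raise ValueError(
            f"unknown phenotype {phenotype!r}; rule defines {sorted(model.phenotypes())}"
        )
    table = enumerate_progeny_classes(model)
    return float(table.loc[table["phenotype"] == phenotype, "adj_prob"].sum())


def expected_pool_allele_frequency(
    model: PhenotypeModel,
    pool: str,
    anchor_locus: FunctionalLocus,
    r: float,
) -> ExpectedPoolFrequency:
    """Expected parent-2 allele frequency in a phenotype-sorted pool.

    The marker of interest sits at recombination fraction ``r`` from
    ``anchor_locus``.  Class probabilities are conditioned on membership of
    the pool (control = non-suppressed, mutant = suppressed progeny); within
    each class the marker shares the anchor's parental origin with
    probability ``1 - r``.  At ``r = 0.5`` the marker is unlinked and the
    frequency is 1/2 in any pool.
    """
    if pool not in POOL_PHENOTYPE:
        raise ValueError(f"pool must be one of {sorted(POOL_PHENOTYPE)}, got {pool!r}")
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    try:
        locus_index = model.loci.index(anchor_locus)
    except ValueError:
        raise ValueError(f"anchor locus {anchor_locus.name} is not in the model") from None

    table = enumerate_progeny_classes(model)
    in_pool = table["phenotype"] == POOL_PHENOTYPE[pool]
    total = table.loc[in_pool, "adj_prob"].sum()
    if total == 0:
        raise ValueError(f"no progeny class has the {pool} pool's phenotype")
    weights = table.loc[in_pool, "adj_prob"] / total
    anchor_is_p2 = np.array(
        [c[locus_index] == 2 for c in table.loc[in_pool, "origins"]], dtype=float
    )
    # marker is parent-2 either by sharing a parent-2 anchor (prob 1-r) or
    # by recombining away from a parent-1 anchor (prob r)
    f = float(np.sum(weights.to_numpy() * (anchor_is_p2 * (1 - r) + (1 - anchor_is_p2) * r)))
    return ExpectedPoolFrequency(pool=pool, recombination_fraction=r, frequency=f)


def infer_viability(observed_nonsuppressed_fraction: float) -> float:
    """Invert the non-suppressed fraction to a selection-class viability.

    Under the canonical rule with shared viability ``v`` on the
    selection-mutant classes, the surviving non-suppressed fraction is
    ``f = v / (2 + 2 v)``; this returns ``v = 2 f / (1 - 2 f)``.
    """
    f = observed_nonsuppressed_fraction
    if not 0.0 <= f < 0.5:
        raise ValueError(
            f"non-suppressed fraction must be in [0, 0.5); got {f} "
            "(f >= 0.5 is unreachable for any positive viability)"
        )
    return 2.0 * f / (1.0 - 2.0 * f)


def segregation_goodness_of_fit(
    observed_counts: Sequence[float],
    expected_fractions: Sequence[float],
) -> GoodnessOfFit:
    """Pearson chi-square test of observed phenotype counts against a ratio."""
    obs = np.asarray(observed_counts, dtype=float)
    exp_frac = np.asarray(expected_fractions, dtype=float)
    if obs.ndim != 1 or obs.shape != exp_frac.shape:
        raise ValueError("observed counts and expected fractions must align")
    if np.any(obs < 0):
        raise ValueError("observed counts must be >= 0")
    n = obs.sum()
    if n <= 0:
        raise ValueError("total observed count must be > 0")
    if not np.isclose(exp_frac.sum(), 1.0):
        raise ValueError("expected fractions must sum to 1")
    if np.any((exp_frac == 0) & (obs > 0)):
        raise ValueError("nonzero count observed in a class with expected fraction 0")
    keep = exp_frac > 0
    stat, p = stats.chisquare(obs[keep], f_exp=n * exp_frac[keep])
    return GoodnessOfFit(statistic=float(stat), df=int(keep.sum() - 1), pvalue=float(p))
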