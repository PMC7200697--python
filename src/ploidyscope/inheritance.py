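"""Mode-of-inheritance inference and marker-selected backcross simulation.

Two parental lines (``strainA`` = BALB/cJ-like, ``strainB`` = BALB/cByJ-like)
differ in a quantitative trait that is scored categorically (low / high /
intermediate) in parents and reciprocal F1s.  A hypothesis space of
single-locus :class:`TraitModel`\\ s — linkage (X vs autosome), which strain
carries the high allele, dominance, cell autonomy, maternal effect,
imprinting — is enumerated exhaustively (96 models) and filtered against the
observed pattern with :func:`infer_consistent_models`.

Cell autonomy matters only for X-linked heterozygous females: a
cell-autonomous X-linked trait is mosaic under X-inactivation and predicts
an intermediate phenotype, whereas a nonautonomous trait shows the dominant
allele's phenotype.

:func:`simulate_backcross` quantifies the genome composition produced by the
study's breeding design: F1 females backcrossed to the recurrent parent for
three generations selecting daughters that remain heterozygous at one
X-linked marker, then a final cross whose male offspring are scored for the
length-weighted fraction of the genome homozygous for the recurrent parent.
Crossovers follow a Haldane (no-interference) model: Poisson-many per
meiosis at the map length / 100 Morgans, uniform positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CrossObservation",
    "DEFAULT_MOUSE_MAP",
    "GenomeModel",
    "BreedingScheme",
    "SelectionError",
    "TraitModel",
    "infer_consistent_models",
    "model_space",
    "mononuclear_cm_observation",
    "nuclear_ploidy_observation",
    "predict_phenotype",
    "simulate_backcross",
    "simulate_unselected_backcross",
    "summarize_backcross",
]

STRAINS = ("strainA", "strainB")
SEXES = ("male", "female")
PHENOTYPES = ("low", "high", "intermediate")


class SelectionError(RuntimeError):
    """A generation's selection predicate could not be satisfied."""


# ---------------------------------------------------------------------------
# Trait models and phenotype prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitModel:
    """One single-locus inheritance hypothesis."""

    linkage: str  # "X-linked" | "autosomal"
    high_allele_origin: str  # "strainA" | "strainB"
    high_allele_dominant: bool
    autonomy: str  # "cell-autonomous" | "nonautonomous"
    maternal_effect: bool
    imprinted_parent: str  # "none" | "maternal" | "paternal"


def model_space() -> list[TraitModel]:
    """The full 2 x 2 x 2 x 2 x 2 x 3 = 96-model hypothesis space."""
    return [
        TraitModel(*combo)
        for combo in itertools.product(
            ("X-linked", "autosomal"),
            STRAINS,
            (True, False),
            ("cell-autonomous", "nonautonomous"),
            (False, True),
            ("none", "maternal", "paternal"),
        )
    ]


def _level(allele_origin: str, model: TraitModel) -> str:
    return "high" if allele_origin == model.high_allele_origin else "low"


def predict_phenotype(model: TraitModel, mother: str, father: str, sex: str) -> str:
    """Deterministic phenotype of an offspring of purebred parents.

    ``mother`` / ``father`` are the parental strains (equal for parental
    animals, different for F1s).  Total over valid inputs.

    Conventions where the genetics is degenerate:

    * A maternal-effect trait is set by the mother's own (homozygous)
      genotype, overriding the offspring's.
    * Imprinting silences the allele inherited from the imprinted parent
      when the offspring carries two alleles of the locus; hemizygous and
      homozygous genotypes are unaffected.
    * X-linked males are hemizygous for their mother's allele.
    """
    if mother not in STRAINS or father not in STRAINS or sex not in SEXES:
        raise ValueError("invalid cross context")
    if model.maternal_effect:
        return _level(mother, model)
    if model.linkage == "X-linked" and sex == "male":
        return _level(mother, model)
    # Two copies of the locus (autosomal, or X-linked female).
    if mother == father:
        return _level(mother, model)
    if model.imprinted_parent == "maternal":
        return _level(father, model)  # maternal copy silenced
    if model.imprinted_parent == "paternal":
        return _level(mother, model)
    if model.linkage == "X-linked" and model.autonomy == "cell-autonomous":
        return "intermediate"  # X-inactivation mosaic
    return "high" if model.high_allele_dominant else "low"


@dataclass(frozen=True)
class CrossObservation:
    """Categorical phenotypes of parents and reciprocal F1s.

    ``parental`` maps ``(strain, sex)`` and ``f1`` maps ``(mother_strain,
    sex)`` to a phenotype level, or ``None`` for an explicitly missing cell.
    All eight cells must be present as keys.
    """

    parental: Mapping[tuple[str, str], str | None]
    f1: Mapping[tuple[str, str], str | None]

    def __post_init__(self):
        for strain in STRAINS:
            for sex in SEXES:
                if (strain, sex) not in self.parental:
                    raise ValueError(f"parental cell {(strain, sex)} missing")
                if (strain, sex) not in self.f1:
                    raise ValueError(f"f1 cell (mother={strain}, {sex}) missing")
        for value in (*self.parental.values(), *self.f1.values()):
            if value is not None and value not in PHENOTYPES:
                raise ValueError(f"invalid phenotype {value!r}")

    def cells(self):
        """Yield ((mother, father, sex), observed) for every non-missing cell."""
        other = {"strainA": "strainB", "strainB": "strainA"}
        for (strain, sex), obs in self.parental.items():
            if obs is not None:
                yield (strain, strain, sex), obs
        for (mother, sex), obs in self.f1.items():
            if obs is not None:
                yield (mother, other[mother], sex), obs


def infer_consistent_models(
    obs: CrossObservation, models: Iterable[TraitModel] | None = None
) -> list[TraitModel]:
    """Models whose predictions match every observed cell.

    An empty result is a valid outcome, not an error.  Missing cells
    constrain nothing.
    """
    if models is None:
        models = model_space()
    cells = list(obs.cells())
    return [
        m
        for m in models
        if all(predict_phenotype(m, *ctx) == observed for ctx, observed in cells)
    ]


def mononuclear_cm_observation() -> CrossObservation:
    """The observed mononuclear-cardiomyocyte pattern.

    strainB (cByJ-like) parents are high in both sexes; among F1s only
    males from strainB mothers are high — females are low in both cross
    directions.
    """
    return CrossObservation(
        parental={
            ("strainA", "male"): "low",
            ("strainA", "female"): "low",
            ("strainB", "male"): "high",
            ("strainB", "female"): "high",
        },
        f1={
            ("strainA", "male"): "low",
            ("strainA", "female"): "low",
            ("strainB", "male"): "high",
            ("strainB", "female"): "low",
        },
    )


def nuclear_ploidy_observation() -> CrossObservation:
    """The observed mononuclear-nuclear-diploidy pattern.

    Scoring the diploid share of mononuclear nuclei: strainA (cJ-like) is
    high, strainB low, and every F1 sits at the strainA level regardless of
    cross direction or sex.
    """
    return CrossObservation(
        parental={
            ("strainA", "male"): "high",
            ("strainA", "female"): "high",
            ("strainB", "male"): "low",
            ("strainB", "female"): "low",
        },
        f1={
            ("strainA", "male"): "high",
            ("strainA", "female"): "high",
            ("strainB", "male"): "high",
            ("strainB", "female"): "high",
        },
    )


# ---------------------------------------------------------------------------
# Genome model and backcross simulation
# ---------------------------------------------------------------------------

#: Genetic lengths in centimorgans: 19 autosomes spanning ~39-98 cM plus an
#: 80 cM X, loosely following the mouse linkage map.
DEFAULT_MOUSE_MAP: dict[str, float] = {
    "1": 98.0, "2": 96.0, "3": 82.0, "4": 88.0, "5": 90.0,
    "6": 79.0, "7": 89.0, "8": 76.0, "9": 75.0, "10": 77.0,
    "11": 88.0, "12": 64.0, "13": 67.0, "14": 66.0, "15": 59.0,
    "16": 57.0, "17": 61.0, "18": 59.0, "19": 39.0, "X": 80.0,
}

DONOR, RECURRENT = 1, 0


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome map lengths (cM) with Haldane crossovers."""

    chromosome_cM: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOUSE_MAP)
    )

    def __post_init__(self):
        if "X" not in self.chromosome_cM:
            raise ValueError("genome must include an X chromosome")
        for chrom, length in self.chromosome_cM.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosome_cM if c != "X"]


@dataclass(frozen=True)
class BreedingScheme:
    """The marker-selected recurrent backcross design.

    F1 females (donor x recurrent) are crossed to recurrent males for
    ``n_marker_backcrosses`` generations, keeping only daughters still
    heterozygous (donor allele present) at ``marker_chrom:marker_pos_cM``;
    a final cross to recurrent males produces the terminal male cohort.
    """

    n_marker_backcrosses: int = 3
    marker_chrom: str = "X"
    marker_pos_cM: float = 35.0
    select_heterozygous: bool = True
    retry_cap: int = 10_000


# A haplotype is (breaks, alleles): segment i covers
# [breaks[i-1], breaks[i]) with allele alleles[i]; breaks[-1] == map length.
Haplotype = tuple[np.ndarray, np.ndarray]


def _pure(length: float, allele: int) -> Haplotype:
    return np.array([length]), np.array([allele], dtype=np.int8)


def _slice_segments(hap: Haplotype, a: float, b: float) -> list[tuple[float, int]]:
    """Segments of ``hap`` restricted to [a, b) as (end, allele) pairs."""
    breaks, alleles = hap
    out = []
    lo = np.searchsorted(breaks, a, side="right")
    for i in range(lo, len(breaks)):
        end = min(float(breaks[i]), b)
        if end > a:
            out.append((end, int(alleles[i])))
            a = end
        if end >= b:
            break
    return out


def _recombine(h1: Haplotype, h2: Haplotype, length: float, rng: np.random.Generator) -> Haplotype:
    """One meiotic product under the Haldane model."""
    n_xo = rng.poisson(length / 100.0)
    start = int(rng.integers(0, 2))
    if n_xo == 0:
        breaks, alleles = (h1, h2)[start]
        return breaks.copy(), alleles.copy()
    xo = np.sort(rng.uniform(0.0, length, n_xo))
    bounds = [0.0, *xo.tolist(), length]
    segs: list[tuple[float, int]] = []
    for i in range(len(bounds) - 1):
        src = (h1, h2)[(start + i) % 2]
        segs.extend(_slice_segments(src, bounds[i], bounds[i + 1]))
    # merge adjacent equal alleles
    ends, alleles = [], []
    for end, allele in segs:
        if alleles and alleles[-1] == allele:
            ends[-1] = end
        else:
            ends.append(end)
            alleles.append(allele)
    return np.array(ends), np.array(alleles, dtype=np.int8)


def _allele_at(hap: Haplotype, pos: float) -> int:
    breaks, alleles = hap
    return int(alleles[np.searchsorted(breaks, pos, side="right")])


def _allele_fraction(hap: Haplotype, allele: int) -> float:
    breaks, alleles = hap
    starts = np.concatenate([[0.0], breaks[:-1]])
    lengths = breaks - starts
    return float(lengths[alleles == allele].sum() / breaks[-1])


def _donor_tract_length(hap: Haplotype, pos: float) -> float:
    """Length of the donor segment containing ``pos`` (0 if recurrent there)."""
    breaks, alleles = hap
    i = int(np.searchsorted(breaks, pos, side="right"))
    if alleles[i] != DONOR:
        return 0.0
    start = float(breaks[i - 1]) if i > 0 else 0.0
    return float(breaks[i]) - start


def _f1_female(genome: GenomeModel) -> dict[str, tuple[Haplotype, Haplotype]]:
    return {
        chrom: (_pure(L, DONOR), _pure(L, RECURRENT))
        for chrom, L in genome.chromosome_cM.items()
    }


def _daughter_from_backcross(
    female: dict, genome: GenomeModel, scheme: BreedingScheme | None,
    rng: np.random.Generator, select: bool,
) -> dict:
    """Cross ``female`` to a recurrent male; return a daughter.

    Under marker selection only the X gamete is resampled (chromosomes
    assort independently, so conditioning on the marker leaves the
    autosomal gametes' distribution untouched).
    """
    daughter = {}
    for chrom, L in genome.chromosome_cM.items():
        gamete = _recombine(*female[chrom], L, rng)
        if (
            select
            and scheme is not None
            and chrom == scheme.marker_chrom
        ):
            tries = 1
            while _allele_at(gamete, scheme.marker_pos_cM) != DONOR:
                if tries >= scheme.retry_cap:
                    raise SelectionError(
                        f"no marker-heterozygous daughter within {scheme.retry_cap} tries"
                    )
                gamete = _recombine(*female[chrom], L, rng)
                tries += 1
        daughter[chrom] = (gamete, _pure(L, RECURRENT))
    return daughter


def simulate_backcross(
    scheme: BreedingScheme = BreedingScheme(),
    genome: GenomeModel = GenomeModel(),
    n_replicates: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate terminal-cohort males of the marker-selected backcross.

    Returns one row per replicate male with length-weighted percentages over
    autosomes + X: ``homozygous_recurrent_pct`` (hemizygous-recurrent X
    counts as homozygous), ``donor_pct``, ``x_donor_pct``, the donor tract
    length around the marker (``marker_tract_cM``) and whether the male
    carries the donor marker allele.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if scheme.marker_chrom not in genome.chromosome_cM:
        raise ValueError(f"marker chromosome {scheme.marker_chrom!r} not in genome")
    if not 0 <= scheme.marker_pos_cM <= genome.chromosome_cM[scheme.marker_chrom]:
        raise ValueError("marker position outside chromosome")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 53]))
    lengths = genome.chromosome_cM
    total = sum(lengths.values())
    rows = []
    for rep in range(n_replicates):
        female = _f1_female(genome)
        for _ in range(scheme.n_marker_backcrosses):
            female = _daughter_from_backcross(
                female, genome, scheme, rng, scheme.select_heterozygous
            )
        # Final cross: male offspring take one maternal gamete per
        # chromosome; the paternal contribution is pure recurrent (and no
        # paternal X reaches a son).
        donor_cM = 0.0
        x_gamete = None
        for chrom, L in lengths.items():
            gamete = _recombine(*female[chrom], L, rng)
            donor_cM += _allele_fraction(gamete, DONOR) * L
            if chrom == scheme.marker_chrom:
                x_gamete = gamete
        donor_pct = 100.0 * donor_cM / total
        rows.append(
            {
                "replicate": rep,
                "homozygous_recurrent_pct": 100.0 - donor_pct,
                "donor_pct": donor_pct,
                "x_donor_pct": 100.0 * _allele_fraction(x_gamete, DONOR),
                "marker_tract_cM": _donor_tract_length(x_gamete, scheme.marker_pos_cM),
                "marker_is_donor": _allele_at(x_gamete, scheme.marker_pos_cM) == DONOR,
            }
        )
    return pd.DataFrame(rows)


def simulate_unselected_backcross(
    n_generations: int,
    genome: GenomeModel = GenomeModel(),
    n_replicates: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Heterozygous genome percentage of backcross females, no selection.

    After ``g`` crosses to the recurrent parent the expected heterozygous
    (donor-carrying) fraction is ``(1/2)**g`` — the closed-form oracle the
    simulator is checked against.  ``n_generations = 0`` returns the F1
    females themselves (100% heterozygous).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 59]))
    lengths = genome.chromosome_cM
    total = sum(lengths.values())
    out = np.empty(n_replicates)
    for rep in range(n_replicates):
        female = _f1_female(genome)
        for _ in range(n_generations):
            female = _daughter_from_backcross(female, genome, None, rng, select=False)
        het_cM = sum(
            _allele_fraction(female[chrom][0], DONOR) * L
            for chrom, L in lengths.items()
        )
        out[rep] = 100.0 * het_cM / total
    return out


def summarize_backcross(result: pd.DataFrame) -> dict[str, float]:
    """Mean / SD / quantiles of the homozygous-recurrent genome fraction."""
    h = result["homozygous_recurrent_pct"]
    return {
        "n_replicates": int(len(result)),
        "mean_homozygous_recurrent_pct": float(h.mean()),
        "sd_homozygous_recurrent_pct": float(h.std(ddof=1)),
        "q05_homozygous_recurrent_pct": float(h.quantile(0.05)),
        "median_homozygous_recurrent_pct": float(h.median()),
        "q95_homozygous_recurrent_pct": float(h.quantile(0.95)),
        "mean_donor_pct": float(result["donor_pct"].mean()),
        "marker_donor_carrier_fraction": float(result["marker_is_donor"].mean()),
        "mean_marker_tract_cM_carriers": float(
            result.loc[result["marker_is_donor"], "marker_tract_cM"].mean()
        )
        if result["marker_is_donor"].any()
        else 0.0,
    }
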