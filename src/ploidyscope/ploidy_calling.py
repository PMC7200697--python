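"""Ploidy calling against the endothelial diploid standard and composition calculus.

The chain implemented here is the study's quantitative core:

1. :func:`normalize_intensities` — divide every nucleus's integrated DAPI
   intensity by the median intensity of CD31+ endothelial nuclei, so that a
   diploid nucleus sits at 1.0 by construction.
2. :func:`call_nuclear_ploidy` — window the normalized values into 2n / 4n /
   8n classes (values in the undefined gaps stay ``unassigned``).
3. :func:`summarize_sample` — per-animal nucleation and nuclear-ploidy
   composition, including the headline product
   ``diploid cells % = mononuclear % x (2n share of mononuclear nuclei) %``.
4. :func:`combine_subgroups` — weight the mononuclear / binuclear nuclear
   spectra by the nucleation split to obtain the six cell classes
   1x2n, 2x2n, 1x4n, 2x4n, 1x8n, 2x8n.
5. :func:`compare_groups` — unpaired two-tailed equal-variance Student t-test
   between animal groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_BINS",
    "DEFAULT_MIN_CELLS",
    "GroupComparison",
    "NormalizationError",
    "PloidyBins",
    "SampleComposition",
    "call_nuclear_ploidy",
    "calls_from_image_output",
    "calls_from_table",
    "combine_subgroups",
    "compare_groups",
    "diploid_cell_percentage",
    "normalize_intensities",
    "summarize_sample",
]

PLOIDY_CLASSES = ("2n", "4n", "8n")
CELL_CLASSES = ("1x2n", "1x4n", "1x8n", "2x2n", "2x4n", "2x8n", "other")

#: Minimum cells to count per animal before a composition is trusted.
DEFAULT_MIN_CELLS = {
    "cardiomyocyte": 300,
    "hepatocyte": 200,
    "marrow": 400,
    "endothelial": 0,
    "unknown": 0,
}


class NormalizationError(ValueError):
    """Too few reference nuclei to define the diploid standard."""


@dataclass(frozen=True)
class PloidyBins:
    """Normalized-intensity windows for nuclear ploidy classes.

    With the diploid standard at 1: diploid ``[0.5, 1.5)``, tetraploid
    ``[1.5, 2.5)``, octoploid ``(3, inf)``.  Values below 0.5
    (debris/apoptotic) and in the undefined gap ``[2.5, 3]`` are
    ``unassigned`` — counted, reported, never imputed.  Boundaries are
    closed-left / open-right so every value has exactly one class.
    """

    diploid_low: float = 0.5
    diploid_high: float = 1.5
    tetraploid_high: float = 2.5
    octoploid_low: float = 3.0

    def classify(self, values: np.ndarray | Sequence[float]) -> np.ndarray:
        """Vectorized window assignment; returns an object array of labels."""
        v = np.asarray(values, dtype=float)
        if (v < 0).any():
            bad = int(np.flatnonzero(v < 0)[0])
            raise ValueError(f"negative normalized intensity at index {bad}")
        out = np.full(v.shape, "unassigned", dtype=object)
        out[(v >= self.diploid_low) & (v < self.diploid_high)] = "2n"
        out[(v >= self.diploid_high) & (v < self.tetraploid_high)] = "4n"
        out[v > self.octoploid_low] = "8n"
        return out


DEFAULT_BINS = PloidyBins()


def normalize_intensities(
    intensities: Sequence[float] | np.ndarray,
    reference_intensities: Sequence[float] | np.ndarray,
    min_reference: int = 10,
) -> np.ndarray:
    """Normalize to the median of the CD31+ endothelial reference nuclei.

    The reference median is given the value 1; there is no fallback
    standard — fewer than ``min_reference`` reference nuclei is an error.
    Invariant under rescaling all raw intensities by a common factor.
    """
    ref = np.asarray(reference_intensities, dtype=float)
    if ref.size < min_reference:
        raise NormalizationError(
            f"only {ref.size} reference nuclei; need >= {min_reference} "
            "CD31+ endothelial nuclei to define the diploid standard"
        )
    median = float(np.median(ref))
    if median <= 0:
        raise NormalizationError("reference median is non-positive")
    return np.asarray(intensities, dtype=float) / median


def call_nuclear_ploidy(
    normalized: Sequence[float] | np.ndarray,
    bins: PloidyBins = DEFAULT_BINS,
    nucleus_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Window normalized intensities into ploidy classes.

    Returns one row per nucleus with ``nucleus_id, normalized_intensity,
    ploidy_class``.
    """
    v = np.asarray(normalized, dtype=float)
    if (v < 0).any():
        bad = np.flatnonzero(v < 0)[0]
        nid = nucleus_ids[bad] if nucleus_ids is not None else int(bad)
        raise ValueError(f"negative normalized intensity for nucleus {nid!r}")
    classes = bins.classify(v)
    if nucleus_ids is None:
        nucleus_ids = np.arange(v.size)
    return pd.DataFrame(
        {
            "nucleus_id": np.asarray(nucleus_ids),
            "normalized_intensity": v,
            "ploidy_class": classes,
        }
    )


def diploid_cell_percentage(mononuclear_pct: float, mono_2n_pct: float) -> float:
    """The headline product: % of all cells that are mononuclear diploid.

    ``6.6 x 66.7 / 100 -> 4.4022`` (reported to one decimal as 4.4).
    """
    if mononuclear_pct < 0 or mono_2n_pct < 0:
        raise ValueError("percentages must be nonnegative")
    return mononuclear_pct * mono_2n_pct / 100.0


@dataclass
class SampleComposition:
    """Per-animal nucleation x nuclear-ploidy composition.

    ``mono_dist`` / ``bi_dist`` are percentages over *all* nuclei of the
    subgroup including the ``unassigned`` share (each sums to 100).
    ``mono_pct2n`` / ``bi_pct2n`` are the 2n share of *assigned* nuclei —
    the quantity the study reports and the factor in the diploid-cell
    product.  ``cell_class_distribution`` covers the six nucleation x ploidy
    classes plus ``other`` (mixed-ploidy binuclear cells); cells containing
    unassigned nuclei are the remainder to 100%.
    """

    animal_id: str
    cell_type: str
    n_cells_counted: int
    mononuclear_fraction: float
    binuclear_fraction: float
    mono_dist: dict[str, float]
    bi_dist: dict[str, float]
    mono_pct2n: float
    bi_pct2n: float
    diploid_cell_fraction: float
    cell_class_distribution: dict[str, float]
    n_multi_excluded: int = 0
    below_min_cells: bool = False

    def to_row(self, decimals: int = 1) -> dict:
        """Flat reporting row with percentages to one decimal (as printed)."""
        row = {
            "animal_id": self.animal_id,
            "cell_type": self.cell_type,
            "n_cells_counted": self.n_cells_counted,
            "mononuclear_fraction": round(self.mononuclear_fraction, decimals),
            "binuclear_fraction": round(self.binuclear_fraction, decimals),
            "mono_pct2n": round(self.mono_pct2n, decimals),
            "bi_pct2n": round(self.bi_pct2n, decimals),
            "diploid_cell_fraction": round(self.diploid_cell_fraction, decimals),
            "n_multi_excluded": self.n_multi_excluded,
            "below_min_cells": self.below_min_cells,
        }
        for name, dist in (("mono", self.mono_dist), ("bi", self.bi_dist)):
            for cls, pct in dist.items():
                row[f"{name}_{cls}"] = round(pct, decimals)
        for cls, pct in self.cell_class_distribution.items():
            row[f"cells_{cls}"] = round(pct, decimals)
        return row


def _subgroup_distribution(classes: pd.Series) -> tuple[dict[str, float], float]:
    """Distribution over all nuclei (incl. unassigned) and 2n% of assigned."""
    n = len(classes)
    dist = {cls: 0.0 for cls in (*PLOIDY_CLASSES, "unassigned")}
    if n == 0:
        return dist, 0.0
    counts = classes.value_counts()
    for cls in dist:
        dist[cls] = 100.0 * counts.get(cls, 0) / n
    n_assigned = sum(counts.get(c, 0) for c in PLOIDY_CLASSES)
    pct2n = 100.0 * counts.get("2n", 0) / n_assigned if n_assigned else 0.0
    return dist, pct2n


def summarize_sample(
    cells: pd.DataFrame,
    calls: pd.DataFrame,
    cell_type: str,
    animal_id: str = "animal",
    viability_filter: bool = True,
    min_cells: int | None = None,
) -> SampleComposition:
    """Compute one animal's composition from cell records and ploidy calls.

    Only viable, QC-passing (1 or 2 detected nuclei) cells of ``cell_type``
    enter the denominators.  Counting fewer than the per-type minimum
    (300 cardiomyocytes / 200 hepatocytes / 400 marrow cells) warns and
    flags the composition; the computation still proceeds.
    """
    if min_cells is None:
        min_cells = DEFAULT_MIN_CELLS.get(cell_type, 0)
    sub = cells[cells["cell_type"] == cell_type]
    if viability_filter:
        sub = sub[sub["viable"]]
    qc = sub[sub["n_nuclei"].isin([1, 2])]
    n_multi = len(sub) - len(qc)
    n = len(qc)
    below = n < min_cells
    if below:
        warnings.warn(
            f"{animal_id}: only {n} {cell_type} cells counted "
            f"(minimum {min_cells}); composition flagged",
            stacklevel=2,
        )
    class_by_nucleus = calls.set_index("nucleus_id")["ploidy_class"]

    def nucleus_classes(cells_subset: pd.DataFrame) -> pd.Series:
        ids = [i for ids in cells_subset["nucleus_ids"] for i in ids]
        return class_by_nucleus.reindex(ids).fillna("unassigned")

    mono_cells = qc[qc["n_nuclei"] == 1]
    bi_cells = qc[qc["n_nuclei"] == 2]
    mono_frac = 100.0 * len(mono_cells) / n if n else 0.0
    bi_frac = 100.0 * len(bi_cells) / n if n else 0.0
    mono_dist, mono_pct2n = _subgroup_distribution(nucleus_classes(mono_cells))
    bi_dist, bi_pct2n = _subgroup_distribution(nucleus_classes(bi_cells))

    # Direct cell-level classification into the six nucleation x ploidy
    # classes; binuclear cells with two different assigned classes -> other;
    # any unassigned nucleus removes the cell from the classified mass.
    class_counts = {cls: 0 for cls in CELL_CLASSES}
    for _, cell in qc.iterrows():
        cls = [class_by_nucleus.get(i, "unassigned") for i in cell["nucleus_ids"]]
        if "unassigned" in cls:
            continue
        if cell["n_nuclei"] == 1:
            class_counts[f"1x{cls[0]}"] += 1
        elif cls[0] == cls[1]:
            class_counts[f"2x{cls[0]}"] += 1
        else:
            class_counts["other"] += 1
    cell_class_distribution = {
        k: (100.0 * v / n if n else 0.0) for k, v in class_counts.items()
    }

    return SampleComposition(
        animal_id=animal_id,
        cell_type=cell_type,
        n_cells_counted=n,
        mononuclear_fraction=mono_frac,
        binuclear_fraction=bi_frac,
        mono_dist=mono_dist,
        bi_dist=bi_dist,
        mono_pct2n=mono_pct2n,
        bi_pct2n=bi_pct2n,
        diploid_cell_fraction=diploid_cell_percentage(mono_frac, mono_pct2n),
        cell_class_distribution=cell_class_distribution,
        n_multi_excluded=n_multi,
        below_min_cells=below,
    )


def combine_subgroups(
    mono_dist: Mapping[str, float],
    bi_dist: Mapping[str, float],
    mono_fraction: float,
    bi_fraction: float,
) -> dict[str, float]:
    """Weight subgroup nuclear spectra by the nucleation split.

    ``class 1xk = mono_fraction x mono %k / 100`` and
    ``class 2xk = bi_fraction x bi %k / 100`` for k in {2n, 4n, 8n}.  The
    result sums to 100 minus whatever mass the inputs held as unassigned.
    """
    for name, dist in (("mono_dist", mono_dist), ("bi_dist", bi_dist)):
        if any(v < 0 for v in dist.values()):
            raise ValueError(f"{name} has negative entries")
        total = sum(dist.values())
        if not math.isclose(total, 100.0, abs_tol=1e-6):
            raise ValueError(f"{name} sums to {total}, not 100")
    if mono_fraction < 0 or bi_fraction < 0:
        raise ValueError("fractions must be nonnegative")
    if not math.isclose(mono_fraction + bi_fraction, 100.0, abs_tol=1e-6):
        raise ValueError("mono and bi fractions must sum to 100")
    out: dict[str, float] = {}
    for k in PLOIDY_CLASSES:
        out[f"1x{k}"] = mono_fraction * mono_dist.get(k, 0.0) / 100.0
        out[f"2x{k}"] = bi_fraction * bi_dist.get(k, 0.0) / 100.0
    return out


@dataclass
class GroupComparison:
    """Unpaired two-tailed equal-variance Student t-test result."""

    metric: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    df: int
    p: float
    degenerate: bool = False


def compare_groups(
    samples_a: Iterable[float], samples_b: Iterable[float], metric: str = "value"
) -> GroupComparison:
    """Pooled-variance Student t-test between two animal groups.

    Degenerate inputs are handled explicitly: zero pooled variance with
    equal means -> ``t = 0, p = 1``; with unequal means -> ``p -> 0``,
    flagged degenerate.
    """
    a = np.asarray(list(samples_a), dtype=float)
    b = np.asarray(list(samples_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    m1, m2 = a.mean(), b.mean()
    s1, s2 = a.std(ddof=1), b.std(ddof=1)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        if m1 == m2:
            return GroupComparison(metric, m1, m2, s1, s2, n1, n2, 0.0, df, 1.0)
        t = math.inf if m1 > m2 else -math.inf
        return GroupComparison(
            metric, m1, m2, s1, s2, n1, n2, t, df, 0.0, degenerate=True
        )
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(metric, m1, m2, s1, s2, n1, n2, float(t), df, float(p))


# ---------------------------------------------------------------------------
# Entry points bridging upstream outputs to (cells, calls)
# ---------------------------------------------------------------------------


def calls_from_table(
    table: pd.DataFrame,
    bins: PloidyBins = DEFAULT_BINS,
    min_reference: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Table-level entry point that bypasses imaging.

    Treats ``true_intensity`` of a ground-truth cell table as the measured
    integrated intensity, uses the endothelial nuclei as the CD31+ diploid
    standard, and returns ``(cells, calls)`` ready for
    :func:`summarize_sample`.
    """
    table = table.reset_index(drop=True)
    nucleus_ids = table.index.to_numpy()
    ref = table.loc[table["cell_type"] == "endothelial", "true_intensity"]
    normalized = normalize_intensities(
        table["true_intensity"], ref, min_reference=min_reference
    )
    calls = call_nuclear_ploidy(normalized, bins=bins, nucleus_ids=nucleus_ids)
    cells = (
        table.assign(nucleus_id=nucleus_ids)
        .groupby("cell_id", sort=True)
        .agg(
            cell_type=("cell_type", "first"),
            viable=("viable", "first"),
            nucleus_ids=("nucleus_id", tuple),
        )
        .reset_index()
    )
    cells["n_nuclei"] = cells["nucleus_ids"].map(len)
    cells["qc"] = np.where(cells["n_nuclei"] <= 2, "ok", "multi")
    return cells, calls


def calls_from_image_output(
    nuclei: pd.DataFrame,
    cells: pd.DataFrame,
    bins: PloidyBins = DEFAULT_BINS,
    min_reference: int = 10,
) -> pd.DataFrame:
    """Ploidy calls from image_quant output, CD31+ nuclei as the standard.

    Flagged (non-positive intensity) nuclei are excluded from both the
    reference set and the calls.
    """
    ok = nuclei[~nuclei["flagged"]]
    ref = ok.loc[ok["cd31_positive"], "integrated_intensity"]
    normalized = normalize_intensities(
        ok["integrated_intensity"], ref, min_reference=min_reference
    )
    return call_nuclear_ploidy(
        normalized, bins=bins, nucleus_ids=ok["nucleus_id"].to_numpy()
    )
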