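"""Synthetic cell populations, rendered fluorescence frames, and variant panels.

Everything downstream of this module (segmentation, ploidy calling,
composition calculus, variant filtering) is exercised against populations
generated here with known ground truth:

* :func:`generate_population` draws per-cell nucleation (1 or 2 nuclei) and
  per-nucleus genome copy number (2n / 4n / 8n), and gives every nucleus an
  integrated DAPI-like intensity proportional to its copy number with
  multiplicative lognormal noise.
* :func:`render_images` paints those cells into three-channel frames
  (DAPI, lineage marker, CD31 endothelial marker) with a Gaussian PSF,
  a constant background and additive pixel noise, returning a placement map
  that links every rendered nucleus back to its ground-truth record.
* :func:`generate_variant_panel` emits multi-strain variant call sets with
  planted substrain-private X-linked coding variants hidden among decoys of
  every removable class, plus ground-truth labels.

All three generators are deterministic given a single integer seed; each
uses a named substream so the generators can be re-run independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as _disk

__all__ = [
    "CELL_TYPES",
    "CHANNELS",
    "DECOY_CLASSES",
    "GenerationError",
    "ImagingSpec",
    "PackingError",
    "PlantedVariant",
    "PopulationSpec",
    "SpecValidationError",
    "STRAIN_PRESETS",
    "generate_population",
    "generate_variant_panel",
    "population_spec_for_strain",
    "read_frames",
    "read_population_csv",
    "render_images",
    "write_frames",
    "write_population_csv",
    "write_vcf",
    "write_variant_panel_vcfs",
]

CELL_TYPES = ("cardiomyocyte", "hepatocyte", "endothelial", "marrow")
CHANNELS = ("DAPI", "lineage", "CD31")
PLOIDY_COPIES = (2, 4, 8)
NUCLEATION_SUPPORT = (1, 2)

# Named substreams: one shared integer seed, independent generators.
_POPULATION_STREAM = 11
_IMAGING_STREAM = 23
_VARIANT_STREAM = 37

#: Amplitude of the (noise-free) lineage / CD31 marker channels.
MARKER_LEVEL = 100.0


class SpecValidationError(ValueError):
    """A population or imaging spec violates its invariants."""


class PackingError(ValueError):
    """Requested cells per frame cannot be placed without mask overlap."""


class GenerationError(ValueError):
    """Variant panel generation failed (e.g. colliding planted sites)."""


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# Population generator
# ---------------------------------------------------------------------------


def _check_prob_vector(name: str, probs: Mapping, support: Sequence) -> None:
    for key, p in probs.items():
        if key not in support:
            raise SpecValidationError(f"{name}: unsupported outcome {key!r}")
        if p < 0:
            raise SpecValidationError(f"{name}: negative probability for {key!r}")
    total = float(sum(probs.values()))
    if abs(total - 1.0) > 1e-9:
        raise SpecValidationError(f"{name}: probabilities sum to {total!r}, not 1")


@dataclass(frozen=True)
class PopulationSpec:
    """Ground-truth description of one animal's cell suspension.

    Parameters
    ----------
    n_cells_by_type
        Number of cells per cell type, e.g. ``{"cardiomyocyte": 1000,
        "endothelial": 150}``.
    nucleation_probs
        Per cell type, probability over nucleus counts ``{1: p1, 2: p2}``.
    nuclear_ploidy_probs
        Per cell type and nucleation class, probability over genome copies
        per nucleus, e.g. ``{"cardiomyocyte": {1: {2: .667, 4: .3, 8: .033},
        2: {...}}}``.
    intensity_cv
        Coefficient of variation of the multiplicative lognormal noise on
        integrated nuclear intensity (unitless; 0 disables noise).
    reference_intensity
        Mean integrated intensity of a single diploid nucleus (a.u.).
    viability_prob
        Probability that a cell is alive (LiveDead-positive analogue).
    seed
        Integer seed; combined with a named substream internally.

    Endothelial cells are always mononuclear diploid regardless of the
    probability tables (they serve as the diploid intensity standard).
    """

    n_cells_by_type: Mapping[str, int]
    nucleation_probs: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    nuclear_ploidy_probs: Mapping[str, Mapping[int, Mapping[int, float]]] = field(
        default_factory=dict
    )
    intensity_cv: float = 0.13
    reference_intensity: float = 5.0e4
    viability_prob: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        for ctype, n in self.n_cells_by_type.items():
            if ctype not in CELL_TYPES:
                raise SpecValidationError(f"unknown cell type {ctype!r}")
            if n < 0:
                raise SpecValidationError(f"n_cells_by_type[{ctype}] < 0")
        if self.intensity_cv < 0:
            raise SpecValidationError("intensity_cv must be >= 0")
        if self.reference_intensity <= 0:
            raise SpecValidationError("reference_intensity must be > 0")
        if not 0.0 <= self.viability_prob <= 1.0:
            raise SpecValidationError("viability_prob must be in [0, 1]")
        for ctype in self.n_cells_by_type:
            if ctype == "endothelial":
                continue
            if ctype not in self.nucleation_probs:
                raise SpecValidationError(f"nucleation_probs missing for {ctype!r}")
            _check_prob_vector(
                f"nucleation_probs[{ctype}]",
                self.nucleation_probs[ctype],
                NUCLEATION_SUPPORT,
            )
            ploidy = self.nuclear_ploidy_probs.get(ctype, {})
            for k, p in self.nucleation_probs[ctype].items():
                if p > 0 and k not in ploidy:
                    raise SpecValidationError(
                        f"nuclear_ploidy_probs[{ctype}][{k}] missing"
                    )
                if k in ploidy:
                    _check_prob_vector(
                        f"nuclear_ploidy_probs[{ctype}][{k}]",
                        ploidy[k],
                        PLOIDY_COPIES,
                    )


# Printed study parameters plus generator defaults where only the diploid
# percentage is in print: the 4n/8n split of each subgroup and the binuclear
# spectra are package defaults chosen to echo the study's qualitative pattern
# (2x2n dominates binuclear cells; the cByJ-like configuration reaches higher
# ploidy). Percentages, converted to probabilities on use.
STRAIN_PRESETS: dict[str, dict] = {
    "BALB_cJ": {
        "cardiomyocyte": dict(
            mononuclear_pct=6.6,
            mono_ploidy_pct=(66.7, 30.0, 3.3),
            bi_ploidy_pct=(90.0, 9.0, 1.0),
        ),
        "hepatocyte": dict(
            mononuclear_pct=43.7,
            mono_ploidy_pct=(31.9, 50.0, 18.1),
            bi_ploidy_pct=(55.0, 37.0, 8.0),
        ),
    },
    "BALB_cByJ": {
        "cardiomyocyte": dict(
            mononuclear_pct=14.3,
            mono_ploidy_pct=(37.6, 50.0, 12.4),
            bi_ploidy_pct=(80.0, 17.0, 3.0),
        ),
        "hepatocyte": dict(
            mononuclear_pct=42.6,
            mono_ploidy_pct=(26.8, 50.0, 23.2),
            bi_ploidy_pct=(45.0, 42.0, 13.0),
        ),
    },
    # F1 males from cByJ mothers combine the high mononuclear level with the
    # cJ-like nuclear ploidy spectrum.
    "F1_cByJ_mother_male": {
        "cardiomyocyte": dict(
            mononuclear_pct=13.1,
            mono_ploidy_pct=(69.9, 27.0, 3.1),
            bi_ploidy_pct=(90.0, 9.0, 1.0),
        ),
    },
}


def population_spec_for_strain(
    strain: str,
    cell_type: str = "cardiomyocyte",
    n_cells: int = 1000,
    n_reference: int = 150,
    intensity_cv: float = 0.13,
    viability_prob: float = 0.95,
    seed: int = 0,
) -> PopulationSpec:
    """Build a :class:`PopulationSpec` from a named strain preset.

    ``n_reference`` endothelial cells are added as the diploid standard.
    """
    try:
        preset = STRAIN_PRESETS[strain][cell_type]
    except KeyError as exc:
        raise KeyError(f"no preset for strain={strain!r}, cell_type={cell_type!r}") from exc
    mono = preset["mononuclear_pct"] / 100.0
    mono_p = [p / 100.0 for p in preset["mono_ploidy_pct"]]
    bi_p = [p / 100.0 for p in preset["bi_ploidy_pct"]]
    return PopulationSpec(
        n_cells_by_type={cell_type: n_cells, "endothelial": n_reference},
        nucleation_probs={cell_type: {1: mono, 2: 1.0 - mono}},
        nuclear_ploidy_probs={
            cell_type: {
                1: dict(zip(PLOIDY_COPIES, mono_p)),
                2: dict(zip(PLOIDY_COPIES, bi_p)),
            }
        },
        intensity_cv=intensity_cv,
        viability_prob=viability_prob,
        seed=seed,
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal factor with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a ground-truth cell table from ``spec``.

    Returns a DataFrame with one row per nucleus and columns
    ``cell_id, cell_type, viable, nucleus_index, true_copies,
    true_intensity``.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = _rng(spec.seed, _POPULATION_STREAM)
    frames: list[pd.DataFrame] = []
    next_cell = 0
    for ctype in sorted(spec.n_cells_by_type):
        n = int(spec.n_cells_by_type[ctype])
        if n == 0:
            continue
        if ctype == "endothelial":
            nucleation = {1: 1.0}
            ploidy = {1: {2: 1.0}}
        else:
            nucleation = spec.nucleation_probs[ctype]
            ploidy = spec.nuclear_ploidy_probs[ctype]
        supp = np.array(sorted(nucleation))
        p = np.array([nucleation[k] for k in supp], dtype=float)
        n_nuclei = rng.choice(supp, size=n, p=p / p.sum())
        viable = rng.random(n) < spec.viability_prob
        cell_ids = np.arange(next_cell, next_cell + n)
        next_cell += n
        for k in sorted(set(n_nuclei.tolist())):
            sel = n_nuclei == k
            total = int(sel.sum()) * k
            pk = ploidy[k]
            copies_supp = np.array(sorted(pk))
            pv = np.array([pk[c] for c in copies_supp], dtype=float)
            copies = rng.choice(copies_supp, size=total, p=pv / pv.sum())
            noise = _lognormal_noise(rng, spec.intensity_cv, total)
            intensity = spec.reference_intensity * (copies / 2.0) * noise
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": np.repeat(cell_ids[sel], k),
                        "cell_type": ctype,
                        "viable": np.repeat(viable[sel], k),
                        "nucleus_index": np.tile(np.arange(k), int(sel.sum())),
                        "true_copies": copies.astype(int),
                        "true_intensity": intensity,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=[
                "cell_id",
                "cell_type",
                "viable",
                "nucleus_index",
                "true_copies",
                "true_intensity",
            ]
        )
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["cell_id", "nucleus_index"], ignore_index=True)
    return table


def write_population_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_population_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    table["viable"] = table["viable"].astype(bool)
    return table


# ---------------------------------------------------------------------------
# Image renderer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImagingSpec:
    """Geometry and noise of the rendered three-channel frames.

    Frames are ``frame_size`` square; nuclei are uniform disks (radius drawn
    from a clipped normal) blurred by a Gaussian PSF of ``psf_sigma`` pixels.
    The DAPI channel carries ``background_level`` plus additive Gaussian
    noise of ``additive_noise_sd``; marker channels are clean binary masks at
    :data:`MARKER_LEVEL`.  Disk rendering is sum-preserving, so the
    background-subtracted integrated DAPI signal of a nucleus equals its
    ground-truth intensity up to PSF tails and pixel noise.
    """

    frame_size: int = 512
    nucleus_radius_mean: float = 5.0
    nucleus_radius_sd: float = 0.5
    psf_sigma: float = 1.0
    background_level: float = 20.0
    additive_noise_sd: float = 2.0
    cells_per_frame: int = 40
    channels: tuple[str, ...] = CHANNELS

    def validate(self) -> None:
        if self.frame_size <= 4 * self.nucleus_radius_mean:
            raise SpecValidationError("frame_size must exceed 4x nucleus radius")
        for name in ("nucleus_radius_sd", "psf_sigma", "background_level", "additive_noise_sd"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be >= 0")
        if self.cells_per_frame < 1:
            raise SpecValidationError("cells_per_frame must be >= 1")
        if tuple(self.channels) != CHANNELS:
            raise SpecValidationError(f"channels must be {CHANNELS}")


def _cell_geometry(img: ImagingSpec) -> tuple[int, int, float]:
    """Grid layout: (cells per row, slot size px, cell marker radius px)."""
    r_max = img.nucleus_radius_mean + 3.0 * img.nucleus_radius_sd
    cell_radius = 3.2 * r_max + 2.0  # holds two nuclei at +/- 2 radii offset
    per_row = math.ceil(math.sqrt(img.cells_per_frame))
    slot = img.frame_size // per_row
    needed = 2.0 * (cell_radius + 4.0)
    if slot < needed:
        raise PackingError(
            f"cells_per_frame={img.cells_per_frame} needs slots of {needed:.0f}px "
            f"but frame_size={img.frame_size} gives {slot}px"
        )
    return per_row, slot, cell_radius


def render_images(
    table: pd.DataFrame, img: ImagingSpec, seed: int = 0
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render viable cells of ``table`` into frames.

    Returns ``(frames, placement)`` where each frame is a float32 array of
    shape ``(3, H, W)`` in :data:`CHANNELS` order and ``placement`` links
    every rendered nucleus to its ground-truth record (frame index, pixel
    coordinates, radius, true copies / intensity).

    Dead cells are not rendered: they mirror the LiveDead-excluded cells
    that the microscopy counting ignores.
    """
    if table.empty:
        raise ValueError("cannot render an empty cell table")
    img.validate()
    rng = _rng(seed, _IMAGING_STREAM)
    per_row, slot, cell_radius = _cell_geometry(img)
    jitter_max = max(0.0, (slot - 2.0 * (cell_radius + 4.0)) / 2.0 - 1.0)

    cells = [
        (cid, grp)
        for cid, grp in table[table["viable"]].groupby("cell_id", sort=True)
    ]
    n_frames = math.ceil(len(cells) / img.cells_per_frame)
    frames: list[np.ndarray] = []
    placement_rows: list[dict] = []
    size = img.frame_size
    for f in range(n_frames):
        chunk = cells[f * img.cells_per_frame : (f + 1) * img.cells_per_frame]
        dapi = np.zeros((size, size), dtype=np.float64)
        lineage = np.zeros_like(dapi)
        cd31 = np.zeros_like(dapi)
        for slot_idx, (cid, grp) in enumerate(chunk):
            gr, gc = divmod(slot_idx, per_row)
            jitter = rng.uniform(-jitter_max, jitter_max, size=2)
            cy = (gr + 0.5) * slot + jitter[0]
            cx = (gc + 0.5) * slot + jitter[1]
            ctype = grp["cell_type"].iloc[0]
            marker = cd31 if ctype == "endothelial" else lineage
            rr, cc = _disk((cy, cx), cell_radius, shape=dapi.shape)
            marker[rr, cc] = MARKER_LEVEL

            nuclei = grp.sort_values("nucleus_index")
            n_nuc = len(nuclei)
            radii = np.clip(
                rng.normal(img.nucleus_radius_mean, img.nucleus_radius_sd, n_nuc),
                2.5,
                None,
            )
            if n_nuc == 1:
                centers = [(cy, cx)]
            else:
                # Nuclei of a binuclear cell sit on opposite sides of the
                # cell centre, far enough apart that thresholding never
                # bridges them.
                theta = rng.uniform(0, 2 * math.pi)
                off = 2.0 * float(radii.max())
                centers = [
                    (cy + off * math.sin(theta), cx + off * math.cos(theta)),
                    (cy - off * math.sin(theta), cx - off * math.cos(theta)),
                ]
            for (ny, nx), radius, (_, nuc) in zip(centers, radii, nuclei.iterrows()):
                rr, cc = _disk((ny, nx), float(radius), shape=dapi.shape)
                if rr.size == 0:
                    continue
                blob = float(nuc["true_intensity"]) / rr.size
                dapi[rr, cc] += blob
                placement_rows.append(
                    {
                        "frame": f,
                        "cell_id": cid,
                        "cell_type": ctype,
                        "nucleus_index": int(nuc["nucleus_index"]),
                        "row": ny,
                        "col": nx,
                        "radius": float(radius),
                        "cell_row": cy,
                        "cell_col": cx,
                        "true_copies": int(nuc["true_copies"]),
                        "true_intensity": float(nuc["true_intensity"]),
                    }
                )
        if img.psf_sigma > 0:
            dapi = gaussian_filter(dapi, img.psf_sigma, mode="reflect")
        dapi += img.background_level
        if img.additive_noise_sd > 0:
            dapi += rng.normal(0.0, img.additive_noise_sd, dapi.shape)
        frames.append(np.stack([dapi, lineage, cd31]).astype(np.float32))
    placement = pd.DataFrame(placement_rows)
    return frames, placement


def write_frames(frames: Sequence[np.ndarray], out_dir: str | Path) -> list[Path]:
    """Write frames as multi-page TIFFs (one page per channel)."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        path = out / f"frame_{i:04d}.tif"
        tifffile.imwrite(path, frame, photometric="minisblack")
        paths.append(path)
    return paths


def read_frames(in_dir: str | Path) -> list[np.ndarray]:
    import tifffile

    paths = sorted(Path(in_dir).glob("frame_*.tif"))
    return [tifffile.imread(p) for p in paths]


# ---------------------------------------------------------------------------
# Variant panel generator
# ---------------------------------------------------------------------------

DECOY_CLASSES = (
    "rsid",
    "low_qual",
    "het",
    "autosomal",
    "shared_comparator",
    "shared_panel",
)

FUNCTIONAL_CONSEQUENCES = (
    "nonsynonymous",
    "stop_gained",
    "splice_donor",
    "splice_acceptor",
)

# Approximate chromosome sizes (bp) for position sampling and VCF contigs.
CHROM_SIZES: dict[str, int] = {
    **{str(i): int(2.0e8 - 6.5e6 * i) for i in range(1, 20)},
    "X": 171_031_299,
}
_CHROM_ORDER = {c: i for i, c in enumerate(list(map(str, range(1, 20))) + ["X"])}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedVariant:
    """A ground-truth private variant planted in the focal strain."""

    chrom: str = "X"
    pos: int = 0
    ref: str = "C"
    alt: str = "T"
    consequence: str = "nonsynonymous"
    gene: str | None = None


#: The two substrain-private X-linked coding variants of the study.
DEFAULT_PLANTED = (
    PlantedVariant("X", 74_309_969, "C", "T", "nonsynonymous", "Gdi1"),
    PlantedVariant("X", 141_723_152, "G", "A", "nonsynonymous", "Irs4"),
)


def _random_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def generate_variant_panel(
    n_strains: int = 8,
    planted_private: Sequence[PlantedVariant] = DEFAULT_PLANTED,
    decoy_counts: Mapping[str, int] | None = None,
    n_decoys: int | None = None,
    seed: int = 0,
    focal_strain: str = "BALB_cByJ",
    comparator_strain: str = "BALB_cJ",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a multi-strain call set with planted private variants.

    Parameters
    ----------
    n_strains
        Total strains: focal, comparator, and ``n_strains - 2`` panel strains.
    planted_private
        Variants present only in the focal strain: X-linked, homozygous-alt,
        novel (no rsID), high quality, functional consequence.
    decoy_counts
        Count per decoy class (:data:`DECOY_CLASSES`).  Each decoy is a
        candidate-like focal call that fails exactly one filter rule.
    n_decoys
        Convenience alternative: total decoys split as evenly as possible
        across all six classes.

    Returns
    -------
    calls, truth
        ``calls``: one row per (strain, site) with columns ``strain, chrom,
        pos, ref, alt, qual, genotype, rsid, consequence``.  ``truth``: one
        row per distinct site with its ground-truth label (``planted`` or a
        decoy class).
    """
    if n_strains < 2:
        raise GenerationError("need at least focal and comparator strains")
    if decoy_counts is not None and n_decoys is not None:
        raise GenerationError("pass decoy_counts or n_decoys, not both")
    if decoy_counts is None:
        total = 0 if n_decoys is None else int(n_decoys)
        base, extra = divmod(total, len(DECOY_CLASSES))
        decoy_counts = {
            cls: base + (1 if i < extra else 0)
            for i, cls in enumerate(DECOY_CLASSES)
        }
    unknown = set(decoy_counts) - set(DECOY_CLASSES)
    if unknown:
        raise GenerationError(f"unknown decoy classes: {sorted(unknown)}")

    planted_keys = {(v.chrom, v.pos) for v in planted_private}
    if len(planted_keys) != len(planted_private):
        raise GenerationError("planted sites collide")

    rng = _rng(seed, _VARIANT_STREAM)
    panel_strains = [f"panel_{i:02d}" for i in range(n_strains - 2)]
    strains = [focal_strain, comparator_strain, *panel_strains]

    used_positions: set[tuple[str, int]] = set(planted_keys)

    def fresh_position(chrom: str) -> int:
        for _ in range(10_000):
            pos = int(rng.integers(1, CHROM_SIZES[chrom]))
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                return pos
        raise GenerationError(f"could not place a unique decoy on {chrom}")

    calls: list[dict] = []
    truth: list[dict] = []

    def add_call(strain, chrom, pos, ref, alt, qual, genotype, rsid, consequence):
        calls.append(
            dict(
                strain=strain,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                qual=round(float(qual), 1),
                genotype=genotype,
                rsid=rsid,
                consequence=consequence,
            )
        )

    for v in planted_private:
        if v.chrom != "X":
            raise GenerationError("planted private variants must be X-linked")
        add_call(
            focal_strain, v.chrom, v.pos, v.ref, v.alt,
            rng.uniform(90, 400), "hom_alt", None, v.consequence,
        )
        truth.append(dict(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, label="planted"))

    for cls in DECOY_CLASSES:
        for _ in range(int(decoy_counts.get(cls, 0))):
            chrom = str(rng.integers(1, 20)) if cls == "autosomal" else "X"
            pos = fresh_position(chrom)
            ref, alt = _random_alleles(rng)
            qual = rng.uniform(5, 69.9) if cls == "low_qual" else rng.uniform(70, 300)
            genotype = "het" if cls == "het" else "hom_alt"
            rsid = f"rs{int(rng.integers(1_000_000, 999_999_999))}" if cls == "rsid" else None
            consequence = str(rng.choice(FUNCTIONAL_CONSEQUENCES))
            add_call(focal_strain, chrom, pos, ref, alt, qual, genotype, rsid, consequence)
            if cls == "shared_comparator":
                add_call(
                    comparator_strain, chrom, pos, ref, alt,
                    rng.uniform(70, 300), "hom_alt", None, consequence,
                )
            if cls == "shared_panel":
                if not panel_strains:
                    raise GenerationError("shared_panel decoys need panel strains")
                n_carriers = int(rng.integers(1, len(panel_strains) + 1))
                carriers = rng.choice(panel_strains, size=n_carriers, replace=False)
                for carrier in carriers:
                    add_call(
                        str(carrier), chrom, pos, ref, alt,
                        rng.uniform(70, 300), "hom_alt", None, consequence,
                    )
            truth.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt, label=cls))

    calls_df = pd.DataFrame(
        calls,
        columns=[
            "strain", "chrom", "pos", "ref", "alt",
            "qual", "genotype", "rsid", "consequence",
        ],
    )
    calls_df["_order"] = calls_df["chrom"].map(_CHROM_ORDER)
    calls_df = (
        calls_df.sort_values(["strain", "_order", "pos"], ignore_index=True)
        .drop(columns="_order")
    )
    truth_df = pd.DataFrame(truth, columns=["chrom", "pos", "ref", "alt", "label"])
    truth_df["_order"] = truth_df["chrom"].map(_CHROM_ORDER)
    truth_df = (
        truth_df.sort_values(["_order", "pos"], ignore_index=True).drop(columns="_order")
    )
    calls_df.attrs["strains"] = strains
    return calls_df, truth_df


_GT_STRINGS = {"hom_alt": "1/1", "het": "0/1", "hom_ref": "0/0"}


def write_vcf(calls: pd.DataFrame, path: str | Path, strain: str) -> Path:
    """Write one strain's calls as an uncompressed VCFv4.2 file.

    Dialect: ``ID`` carries the rsID or ``.``; the consequence annotation is
    the INFO key ``CSQ``; genotypes are in FORMAT ``GT`` for a single sample
    column named after the strain.
    """
    path = Path(path)
    sub = calls[calls["strain"] == strain].copy()
    sub["_order"] = sub["chrom"].map(_CHROM_ORDER)
    sub = sub.sort_values(["_order", "pos"])
    lines = ["##fileformat=VCFv4.2", f"##source=ploidyscope-synthetic ({strain})"]
    for chrom in _CHROM_ORDER:
        lines.append(f"##contig=<ID={chrom},length={CHROM_SIZES[chrom]}>")
    lines.append(
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Predicted consequence">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + strain
    )
    for _, row in sub.iterrows():
        rsid = row["rsid"] if isinstance(row["rsid"], str) and row["rsid"] else "."
        lines.append(
            "\t".join(
                [
                    str(row["chrom"]),
                    str(int(row["pos"])),
                    rsid,
                    row["ref"],
                    row["alt"],
                    f"{row['qual']:.1f}",
                    ".",
                    f"CSQ={row['consequence']}",
                    "GT",
                    _GT_STRINGS[row["genotype"]],
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_variant_panel_vcfs(
    calls: pd.DataFrame, out_dir: str | Path, strains: Sequence[str] | None = None
) -> dict[str, Path]:
    """Write one VCF per strain (header-only files for call-free strains)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if strains is None:
        strains = calls.attrs.get("strains") or sorted(calls["strain"].unique())
    return {s: write_vcf(calls, out / f"{s}.vcf", s) for s in strains}
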