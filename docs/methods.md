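# Methods

This note documents the models implemented in `ploidyscope`, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions used at boundaries and in degenerate
cases.

## Ploidy typing from integrated DAPI intensity

Total DNA content scales with genome copy number, so ploidy is read from
the *integrated* (summed) background-subtracted DAPI intensity of a
nucleus, not its mean: concentration varies with chromatin compaction but
the sum tracks copy number. The diploid standard is the **median**
integrated intensity of CD31⁺ endothelial nuclei in the same preparation
(endothelial cells are uniformly mononuclear diploid outside mitosis);
normalization requires at least 10 reference nuclei and has no fallback —
without a credible diploid anchor the calls would be meaningless.
Normalization is invariant under any global rescaling of raw intensities
(exposure, gain), which is verified by property test.

Normalized values are windowed:

| window       | class      |
|--------------|------------|
| [0, 0.5)     | unassigned (sub-diploid debris/apoptotic) |
| [0.5, 1.5)   | 2n         |
| [1.5, 2.5)   | 4n         |
| [2.5, 3.0]   | unassigned (undefined gap) |
| (3.0, ∞)     | 8n         |

Boundaries are closed-left/open-right so every value has exactly one
class; the published window descriptions overlap at their endpoints and
this convention resolves them deterministically with measure-zero effect.
The (2.5, 3.0] interval has no defined class; values there are counted and
reported, never imputed, because silently widening a window would bias the
4n/8n split. Sub-diploid values are likewise excluded from denominators
rather than being forced into 2n.

## Segmentation and cell grouping

Nuclei are connected components of the DAPI channel at or above a single
threshold applied to *every* frame of a study (the uniform-threshold
contract; per-frame thresholds would let exposure drift masquerade as
ploidy differences). The default threshold is Otsu computed on the pooled
**log-intensity** histogram: with a sparse foreground (nuclei cover a few
percent of pixels) linear-domain Otsu drifts into the dim end of the
nucleus intensity range and clips large dim nuclei, whereas the
background/foreground split in log space is stable. An absolute threshold
can be supplied instead.

Background is the per-frame median of sub-threshold pixels. Integrated
intensity is summed over the component grown by 3 px (growth never crosses
into a neighbouring nucleus) to capture PSF tails; background × area is
subtracted. Components smaller than 15 px² are discarded; records whose
background subtraction overshoots to ≤ 0 are flagged, never dropped.
Touching nuclei are not split (no watershed): the synthetic placement
guarantees separation, and in real data clumps surface as area outliers
and as cells flagged `multi`. Cells with ≥ 3 detected nuclei are excluded
from the mono/binuclear calculus (only those two categories are
quantified); their count is reported.

Nuclei are grouped into cells by the lineage-marker mask component their
centroid falls in; CD31-mask nuclei are endothelial; nuclei in neither
mask are `unknown` and excluded from typed denominators. A nucleus claimed
by both masks is typed by the stronger marker at its centroid and the
collision is logged.

## Composition calculus

Per animal, over viable QC-passing cells of the requested type:
mononuclear and binuclear fractions; per-subgroup nuclear class spectra
(reported two ways: over all nuclei including the unassigned share, which
sums to 100, and the 2n share of *assigned* nuclei, which is the quantity
that enters products); the six cell classes 1×2n … 2×8n (binuclear cells
with discordant assigned classes fall in `other`; cells containing an
unassigned nucleus are the remainder to 100%); and

```
diploid_cell_fraction = mononuclear_fraction × mono %2n / 100.
```

Percentages are reported to one decimal. The product uses the
assigned-nuclei 2n share because measured spectra are conditioned on a
nucleus receiving a class; with the default noise level the unassigned
mass is ~1–2% and the distinction is negligible. The mononuclear spectrum
is measured within the mononuclear subset (not per-cell across the whole
heart) because mononuclear nuclei are deliberately oversampled relative to
their frequency; the weighting back to cell classes is exactly the
`combine_subgroups` product above.

Minimum counts per animal — 300 cardiomyocytes, 200 hepatocytes, 400
marrow cells — trigger a warning and a `below_min_cells` flag rather than
an error; the flag propagates into reports.

Group comparisons use the unpaired two-tailed pooled-variance Student
t-test with df = n₁+n₂−2. Zero pooled variance is handled explicitly:
equal means → t = 0, p = 1; unequal means → p → 0, flagged degenerate.
Per-animal compositions are first-class; group summaries are means ± SD
across animals.

## Synthetic data

`PopulationSpec` draws, per cell: nucleation ∈ {1, 2} (no ≥3-nucleate
classes — only mono- and binuclear categories are quantified downstream),
then per-nucleus copies ∈ {2n, 4n, 8n}, then integrated intensity
`reference × copies/2 × LogNormal(mean 1, cv)`. Endothelial cells are
forced mononuclear diploid. Defaults are the study conditions: mononuclear
6.6%/14.3% with mono-2n 66.7%/37.6% for the two cardiomyocyte
configurations (43.7%/42.6% and 31.9%/26.8% for hepatocytes); the 4n/8n
splits of each subgroup and the binuclear spectra are not printed anywhere
and were fixed once at values echoing the qualitative pattern (2×2n
dominates binuclear cells; the cByJ-like configuration reaches higher
ploidy). Multiplicative lognormal intensity noise with cv = 0.13 is a
typical integrated-intensity spread for widefield DAPI quantification and
keeps the 2n/4n windows separated by ~3.3 cv units; cv = 0 makes the
copies→intensity map exact, which the linearity tests exploit. Viability
is Bernoulli(0.95).

Rendering paints nuclei as sum-preserving uniform disks (radius
N(5, 0.5²) px, clipped ≥ 2.5) blurred by a Gaussian PSF (σ = 1 px) into
512² frames on a jittered grid, with binuclear nuclei offset ±2 radii from
the cell centre — far enough that thresholding never bridges them. The
DAPI channel carries a constant background (20 a.u.) plus additive
Gaussian noise (σ = 2); marker channels are clean masks, so marker
detection is not the quantity under test. A placement map links every
rendered nucleus to its ground-truth record, making segmentation accuracy
measurable without manual annotation. Dead cells are not rendered,
mirroring viability-gated counting.

What the generator does **not** emulate: clumped or touching nuclei,
illumination-field inhomogeneity, saturation, photobleaching, marker
bleed-through, ≥3-nucleate cells, mitotic endothelial reference nuclei, or
flow-cytometry-style continuous DNA-content distributions. Passing
end-to-end tests therefore demonstrate that the measurement chain is
unbiased under the stated imaging model, not that segmentation is robust
to pathological real-world micrographs.

The three generators (population, images, variants) draw from named
substreams of one integer seed and are individually deterministic.

## Inheritance inference

Phenotypes are categorical (low/high/intermediate); the quantitative trait
is thresholded upstream at the midpoint of the parental means, which
matches how the cross pattern is actually read. The hypothesis space is
the full cross product — linkage {X, autosomal} × high-allele origin ×
dominance × autonomy × maternal effect × imprinting {none, maternal,
paternal} — 96 models, filtered by exact match of predicted against
observed cells; missing cells constrain nothing and an empty survivor set
is a reportable outcome.

Prediction conventions where the genetics is degenerate: a
maternal-effect trait takes the mother's own homozygous phenotype;
imprinting silences the allele from the imprinted parent only when the
offspring carries two copies (hemizygous and homozygous genotypes are
unaffected); X-linked males are hemizygous for the maternal allele;
X-inactivation mosaicism in heterozygous females is modeled as a
deterministic `intermediate` for cell-autonomous X-linked traits rather
than a stochastic mosaic fraction — the inference consumes only the
category. Autonomy is unidentifiable for autosomal loci, so autosomal
survivors always come in autonomy pairs. Two-locus and epistatic models
are out of scope; the engine reports single-locus consistency only.

## Backcross simulation

Chromosomes follow a Haldane model: Poisson(L/100) crossovers per meiosis,
uniform positions, no interference, no sex-specific map. The default map
(19 autosomes spanning 39–98 cM, X = 80 cM) loosely follows the mouse
linkage map and is config-overridable; absolute homozygosity fractions
shift by well under a percentage point for plausible alternative maps
because they are dominated by the (1/2)^g halving. Selection keeps
daughters whose maternal X gamete carries the donor allele at the marker
(default 35 cM, the approximate map position of the proximal selected
gene); because chromosomes assort independently, only the X gamete is
resampled under selection, leaving autosomal transmissions unconditioned.
Terminal males score hemizygous-recurrent X as homozygous-recurrent, since
there is no second allele to differ. The unselected simulator is checked
against the closed form E[het] = (1/2)^g, and linkage drag is verified to
shrink with backcross number.

## Variant filter

A call survives iff it has no rsID, QUAL ≥ 70 (exactly 70 is kept: the
removal rule is QUAL < 70), is homozygous-alt (hemizygous male X `1` calls
count as homozygous-alt), lies on a whitelisted chromosome (default {X}),
and has a protein-altering consequence (nonsynonymous, stop gained, splice
donor/acceptor). Survivors shared with the comparator strain at the same
(chrom, pos, ref, alt) key, or present in more than
`max_shared_panel_strains` panel strains (default 0 — the strictest
reading of "shared with several other strains", configurable because
"several" is undefined), are removed. Rules commute; only the waterfall
tally depends on the fixed rule order. Consequence annotations are
consumed from INFO `CSQ`, never computed — consequence prediction and
damage scoring (PolyPhen-style) are pass-through annotations, out of
scope. Multi-allelic records are split per ALT before filtering; duplicate
keys within a strain are deduplicated with a warning.

## Problem sizes and seeds

Default study sizes — 5 animals/group, 1,000 cells + 150 reference cells
per animal for imaging recovery; 1,000 replicates for the backcross; 100
random panels for filter soundness — were chosen so that 3-SD binomial /
Monte-Carlo bounds are decisively informative for every recovered
parameter while a full run of the suite and drivers completes in minutes.
All stochastic tests run under fixed seeds; every public simulation
function takes an explicit seed and is deterministic given it.

## Known limitations

* No watershed splitting: heavily clumped real micrographs will
  under-count nuclei (flagged via area outliers and `multi` cells, not
  corrected).
* The endothelial-standard assumption fails if the reference population
  contains many mitotic (4n) nuclei; the median is robust to a minority.
* The undefined (2.5, 3.0] normalized-intensity interval is inherited
  from the window definitions; cells there are reported unassigned.
* Single-locus inference only; an interacting autosomal × X-linked
  architecture would not be distinguished.
* The genetic map is approximate and crossover interference is ignored;
  fine-scale drag-tract lengths are therefore indicative, not exact.
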