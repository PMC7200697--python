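"""Exome candidate filter for substrain-private X-linked coding variants.

Mirrors the informatics chain used to nominate candidate genes between two
very closely related inbred substrains: starting from one strain's annotated
calls, remove previously catalogued variants (rsID-bearing), low-quality
calls (QUAL < 70), heterozygous calls, autosomal calls and non-functional
consequences; then subtract calls shared with the comparator substrain or
with any strain of a wider inbred panel.  What survives is the candidate
list of novel, homozygous, functional X-linked variants private to the
focal strain.

Rules commute — the survivor set is independent of rule order; only the
per-rule removal tally depends on the (fixed) order
``rsID -> qual -> zygosity -> chromosome -> consequence``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FilterConfig",
    "RULE_ORDER",
    "VariantCall",
    "filter_focal_strain",
    "pipeline_report",
    "read_strain_vcf",
    "report_to_text",
    "subtract_shared",
    "calls_from_dataframe",
]

RULE_ORDER = ("rsid", "qual", "zygosity", "chromosome", "consequence")

_CHROM_ORDER = {c: i for i, c in enumerate([str(i) for i in range(1, 20)] + ["X", "Y"])}


@dataclass(frozen=True)
class VariantCall:
    """One strain/site call (1-based VCF coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    genotype: str | None  # "hom_ref" | "het" | "hom_alt" | None (malformed)
    rsid: str | None = None
    consequence: str = "other"
    strain: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (VCF convention)")
        if self.alt == self.ref:
            raise ValueError("alt must differ from ref")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """The filter's thresholds; defaults are the study's rules.

    ``max_shared_panel_strains = 0`` is the strictest reading of removing
    variants "shared with several other strains": any panel occurrence
    removes a candidate.  QUAL exactly 70 is kept (the removal rule is
    QUAL < 70).
    """

    min_qual: float = 70.0
    require_hom_alt: bool = True
    drop_rsid: bool = True
    chromosome_whitelist: tuple[str, ...] = ("X",)
    allowed_consequences: tuple[str, ...] = (
        "nonsynonymous",
        "stop_gained",
        "splice_donor",
        "splice_acceptor",
    )
    max_shared_panel_strains: int = 0
    drop_shared_with_comparator: bool = True

    def __post_init__(self):
        if self.min_qual < 0 or self.max_shared_panel_strains < 0:
            raise ValueError("thresholds must be nonnegative")
        if not self.chromosome_whitelist:
            raise ValueError("chromosome whitelist must be non-empty")


def _failed_rule(call: VariantCall, cfg: FilterConfig) -> str | None:
    """First rule (in RULE_ORDER) the call fails, or None if it survives."""
    if cfg.drop_rsid and call.rsid:
        return "rsid"
    if call.qual < cfg.min_qual:
        return "qual"
    if cfg.require_hom_alt and call.genotype != "hom_alt":
        return "zygosity"
    if call.chrom not in cfg.chromosome_whitelist:
        return "chromosome"
    if call.consequence not in cfg.allowed_consequences:
        return "consequence"
    return None


def filter_focal_strain(
    calls: Iterable[VariantCall], cfg: FilterConfig = FilterConfig()
) -> tuple[list[VariantCall], dict[str, int]]:
    """Apply the per-call rules to one strain's calls.

    Returns ``(survivors, tally)`` where ``tally`` counts removals per rule
    in fixed order plus ``malformed`` (calls with no parseable genotype).
    """
    tally = {"malformed": 0, **{rule: 0 for rule in RULE_ORDER}}
    survivors = []
    for call in calls:
        if call.genotype is None:
            tally["malformed"] += 1
            continue
        rule = _failed_rule(call, cfg)
        if rule is None:
            survivors.append(call)
        else:
            tally[rule] += 1
    return survivors, tally


def _dedupe(calls: Iterable[VariantCall], label: str) -> dict[tuple, VariantCall]:
    out: dict[tuple, VariantCall] = {}
    dupes = 0
    for call in calls:
        if call.key in out:
            dupes += 1
        else:
            out[call.key] = call
    if dupes:
        warnings.warn(f"{label}: {dupes} duplicate site keys deduplicated")
    return out


def subtract_shared(
    focal_survivors: Sequence[VariantCall],
    comparator_calls: Iterable[VariantCall],
    panel_calls_by_strain: Mapping[str, Iterable[VariantCall]],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[VariantCall], dict[str, int]]:
    """Remove survivors present in the comparator or too many panel strains.

    Sharing is keyed on ``(chrom, pos, ref, alt)``; all inputs must use the
    1-based VCF convention.  Returns candidates sorted by (chrom, pos) and
    a tally with ``shared_comparator`` / ``shared_panel`` counts.
    """
    focal = _dedupe(focal_survivors, "focal survivors")
    comparator_keys = set(_dedupe(comparator_calls, "comparator"))
    panel_counts: dict[tuple, int] = {}
    for strain, calls in panel_calls_by_strain.items():
        for key in _dedupe(calls, f"panel[{strain}]"):
            panel_counts[key] = panel_counts.get(key, 0) + 1

    tally = {"shared_comparator": 0, "shared_panel": 0}
    candidates = []
    for key, call in focal.items():
        if cfg.drop_shared_with_comparator and key in comparator_keys:
            tally["shared_comparator"] += 1
            continue
        if panel_counts.get(key, 0) > cfg.max_shared_panel_strains:
            tally["shared_panel"] += 1
            continue
        candidates.append(call)
    candidates.sort(key=lambda c: (_CHROM_ORDER.get(c.chrom, 99), c.pos))
    return candidates, tally


def pipeline_report(
    candidates: Sequence[VariantCall],
    tallies: Mapping[str, int],
    n_input: int | None = None,
) -> dict:
    """Machine-readable waterfall report of the whole filter run."""
    order = ["malformed", *RULE_ORDER, "shared_comparator", "shared_panel"]
    removed_total = sum(tallies.get(rule, 0) for rule in order)
    if n_input is None:
        n_input = removed_total + len(candidates)
    waterfall = []
    remaining = n_input
    for rule in order:
        removed = int(tallies.get(rule, 0))
        remaining -= removed
        waterfall.append({"rule": rule, "removed": removed, "remaining": remaining})
    return {
        "n_input": int(n_input),
        "n_candidates": len(candidates),
        "waterfall": waterfall,
        "candidates": [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "qual": c.qual,
                "genotype": c.genotype,
                "rsid": c.rsid,
                "consequence": c.consequence,
                "strain": c.strain,
            }
            for c in candidates
        ],
    }


def report_to_text(report: Mapping) -> str:
    lines = [f"input calls: {report['n_input']}"]
    for step in report["waterfall"]:
        lines.append(
            f"  - {step['rule']:<18} removed {step['removed']:>6}  remaining {step['remaining']:>6}"
        )
    lines.append(f"candidates: {report['n_candidates']}")
    for c in report["candidates"]:
        lines.append(
            f"  {c['chrom']}:{c['pos']} {c['ref']}>{c['alt']} "
            f"QUAL={c['qual']:.1f} {c['consequence']}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Input adapters
# ---------------------------------------------------------------------------


def _parse_gt(alleles: Sequence[int], alt_index: int) -> str | None:
    """Genotype class for one ALT allele of a (possibly split) record.

    Accepts unphased/phased diploid calls and single-allele hemizygous male
    X calls (``1`` is homozygous-alt).  Missing alleles -> None (malformed).
    """
    if len(alleles) == 0 or any(a < 0 for a in alleles):
        return None
    carries = [a == alt_index for a in alleles]
    if all(carries):
        return "hom_alt"
    if any(carries):
        return "het"
    return "hom_ref"


def read_strain_vcf(path: str | Path, strain: str | None = None) -> list[VariantCall]:
    """Read one single-sample VCF into :class:`VariantCall` records.

    Multi-allelic records are split into per-ALT calls; the consequence is
    taken from INFO ``CSQ`` (``other`` when absent); the ID column carries
    the rsID or ``.``.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    if strain is None:
        strain = vcf.samples[0] if vcf.samples else Path(path).stem
    calls: list[VariantCall] = []
    for record in vcf:
        rsid = record.ID if record.ID not in (None, ".") else None
        csq = record.INFO.get("CSQ") or "other"
        genotypes = record.genotypes[0][:-1] if len(record.genotypes) else []
        for alt_index, alt in enumerate(record.ALT, start=1):
            calls.append(
                VariantCall(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    qual=float(record.QUAL) if record.QUAL is not None else 0.0,
                    genotype=_parse_gt(genotypes, alt_index),
                    rsid=rsid,
                    consequence=str(csq),
                    strain=strain,
                )
            )
    vcf.close()
    return calls


def calls_from_dataframe(calls_df, strain: str) -> list[VariantCall]:
    """Adapter from the synthetic generator's call table."""
    sub = calls_df[calls_df["strain"] == strain]
    return [
        VariantCall(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            qual=float(row.qual),
            genotype=row.genotype,
            rsid=row.rsid if isinstance(row.rsid, str) and row.rsid else None,
            consequence=row.consequence,
            strain=strain,
        )
        for row in sub.itertuples()
    ]


def write_candidates_tsv(candidates: Sequence[VariantCall], path: str | Path) -> None:
    lines = ["chrom\tpos\tref\talt\tqual\tgenotype\trsid\tconsequence\tstrain"]
    for c in candidates:
        lines.append(
            "\t".join(
                [
                    c.chrom, str(c.pos), c.ref, c.alt, f"{c.qual:.1f}",
                    str(c.genotype), c.rsid or ".", c.consequence, c.strain,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_report_json(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
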