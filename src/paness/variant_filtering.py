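"""Standard variant screening: allele frequency, effect class, score thresholds,
and Mendelian trio inheritance patterns.

The screening philosophy is deliberately liberal: a variant is never excluded
because an annotation is *absent* (a missing conservation score, or a variant
unseen in the population reference, carries no evidence of being common or
benign). Population frequency can come from an INFO field of an annotated VCF
or from an external lookup table (chrom, pos, ref, alt, af).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import pandas as pd

from .errors import AnnotationError, ConfigurationError
from .variant_io import Genotype, VariantRecord

log = logging.getLogger(__name__)

_COMPARATORS = {
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "eq": lambda a, b: a == b,
}

INHERITANCE_MODELS = ("autosomal_recessive", "autosomal_dominant_de_novo", "none")


@dataclass
class FrequencySource:
    """Where minor-allele frequencies come from.

    ``mode`` is ``info_field`` (read ``info_key`` off each variant's INFO map)
    or ``table`` (an in-memory (chrom,pos,ref,alt) -> AF lookup). An absent
    frequency is always represented as None, never as 0.
    """

    mode: str = "info_field"
    info_key: str = "AF"
    table: dict[tuple[str, int, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("info_field", "table"):
            raise ConfigurationError(f"unknown frequency mode {self.mode!r}")
        for key, af in self.table.items():
            if not 0.0 <= af <= 1.0:
                raise ConfigurationError(f"frequency {af} for {key} outside [0,1]")

    @classmethod
    def from_table(cls, source: Union[str, Path, TextIO]) -> "FrequencySource":
        """Load a TSV with columns chrom, pos, ref, alt, af (header optional)."""
        df = pd.read_csv(source, sep="\t", comment="#", dtype={0: str})
        if list(df.columns[:5]) != ["chrom", "pos", "ref", "alt", "af"]:
            df.columns = ["chrom", "pos", "ref", "alt", "af"] + list(df.columns[5:])
        table = {
            (str(r.chrom), int(r.pos), str(r.ref).upper(), str(r.alt).upper()): float(r.af)
            for r in df.itertuples(index=False)
        }
        return cls(mode="table", table=table)

    def lookup(self, variant: VariantRecord) -> Optional[float]:
        if self.mode == "table":
            return self.table.get(variant.key)
        raw = variant.info.get(self.info_key)
        if raw is None or raw == "":
            return None
        try:
            af = float(raw)
        except ValueError as exc:
            raise AnnotationError(
                f"unparseable {self.info_key}={raw!r} on variant "
                f"{variant.chrom}:{variant.pos}{variant.ref_allele}>{variant.alt_allele}"
            ) from exc
        if not 0.0 <= af <= 1.0:
            raise AnnotationError(
                f"{self.info_key}={af} outside [0,1] on variant {variant.chrom}:{variant.pos}"
            )
        return af


@dataclass
class FilterConfig:
    """Settings for the standard screen.

    ``maf_threshold`` defaults to 0.001 (the low-frequency gate of the splice
    screen); ``maf_comparator`` defaults to ``le`` so a variant exactly at the
    threshold passes. ``maf_missing_passes`` keeps variants that are absent
    from the frequency source — an allele never observed in the reference
    population is rarer than any threshold in use.
    """

    maf_threshold: float = 0.001
    maf_comparator: str = "le"
    maf_missing_passes: bool = True
    inheritance_model: str = "none"
    effect_classes_kept: frozenset[str] = frozenset()
    effect_key: str = "EFFECT"
    score_thresholds: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold < 1.0:
            raise ConfigurationError("maf_threshold must be in (0,1)")
        if self.maf_comparator not in _COMPARATORS:
            raise ConfigurationError(f"unknown comparator {self.maf_comparator!r}")
        if self.inheritance_model not in INHERITANCE_MODELS:
            raise ConfigurationError(f"unknown inheritance model {self.inheritance_model!r}")
        for key, (cmp_name, _value) in self.score_thresholds.items():
            if cmp_name not in _COMPARATORS:
                raise ConfigurationError(f"score threshold {key}: unknown comparator {cmp_name!r}")
        self.effect_classes_kept = frozenset(self.effect_classes_kept)


def annotate_maf(variant: VariantRecord, source: FrequencySource) -> VariantRecord:
    """Return the variant with its minor allele frequency attached (None if unseen)."""
    return variant.with_maf(source.lookup(variant))


def filter_by_maf(variants: Iterable[VariantRecord], config: FilterConfig) -> list[VariantRecord]:
    """Keep low-frequency variants (maf <= threshold by default).

    Variants with ``maf is None`` are kept iff ``config.maf_missing_passes``;
    they are counted separately in the log so unseen alleles remain auditable.
    """
    cmp = _COMPARATORS[config.maf_comparator]
    kept, n_missing = [], 0
    for v in variants:
        if v.maf is None:
            if config.maf_missing_passes:
                kept.append(v)
                n_missing += 1
            continue
        if cmp(v.maf, config.maf_threshold):
            kept.append(v)
    if n_missing:
        log.info("filter_by_maf: kept %d variant(s) with no frequency record", n_missing)
    return kept


def classify_inheritance(
    variant: VariantRecord,
    roles: dict[str, str],
    model: str,
    strict: bool = False,
) -> bool:
    """Does the trio genotype pattern match the inheritance model?

    ``roles`` maps role name (proband/mother/father) to sample id. Autosomal
    recessive requires a homozygous-alternate proband with two heterozygous
    carrier parents; the dominant de novo model requires a variant-carrying
    proband with two homozygous-reference parents. With ``strict=False``
    (default) any missing genotype fails the pattern; with ``strict=True`` it
    raises instead.
    """
    if model == "none":
        return True
    if model not in INHERITANCE_MODELS:
        raise ConfigurationError(f"unknown inheritance model {model!r}")
    needed = ("proband", "mother", "father")
    for role in needed:
        if role not in roles:
            raise ConfigurationError(f"role {role!r} not configured")
        if roles[role] not in variant.sample_genotypes:
            raise ConfigurationError(
                f"sample {roles[role]!r} (role {role}) absent from variant genotypes"
            )
    gt = {role: variant.sample_genotypes[roles[role]] for role in needed}
    if any(g == Genotype.MISSING for g in gt.values()):
        if strict:
            raise ConfigurationError(
                f"missing genotype in trio at {variant.chrom}:{variant.pos}"
            )
        return False
    if model == "autosomal_recessive":
        return (
            gt["proband"] == Genotype.HOM_ALT
            and gt["mother"] == Genotype.HET
            and gt["father"] == Genotype.HET
        )
    # autosomal_dominant_de_novo
    return (
        gt["proband"] in (Genotype.HET, Genotype.HOM_ALT)
        and gt["mother"] == Genotype.HOM_REF
        and gt["father"] == Genotype.HOM_REF
    )


def apply_standard_filters(
    variants: Iterable[VariantRecord], config: FilterConfig
) -> list[VariantRecord]:
    """Conjunction of effect-class membership and per-annotation score thresholds.

    Absent annotations never exclude a variant (liberal screening): a variant
    with no effect annotation, or missing a thresholded score, is kept. An
    empty config is the identity.
    """
    kept = []
    for v in variants:
        if config.effect_classes_kept:
            effect = v.info.get(config.effect_key)
            if effect is not None and effect != "" and effect not in config.effect_classes_kept:
                continue
        ok = True
        for key, (cmp_name, threshold) in config.score_thresholds.items():
            raw = v.info.get(key)
            if raw is None or raw == "":
                continue
            try:
                value = float(raw)
            except ValueError as exc:
                raise AnnotationError(
                    f"unparseable score {key}={raw!r} on variant {v.chrom}:{v.pos}"
                ) from exc
            if not _COMPARATORS[cmp_name](value, threshold):
                ok = False
                break
        if ok:
            kept.append(v)
    return kept
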