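"""Post-annotation somatic filter cascade with per-criterion accounting.

Raw annotated somatic calls (MAF-style tables) are reduced to
high-confidence, functionally relevant mutations by six ordered criteria:

1. ``vaf``          -- tumor VAF >= sample-type threshold (tissue 0.05,
                       plasma 0.001; inclusive)
2. ``filter_status``-- caller hard-filter status equals the required value
                       (default ``PASS``)
3. ``pon``          -- not flagged by the panel of normals
4. ``popfreq``      -- every present gnomAD exome/genome AF strictly below
                       the population-frequency cutoff (default 0.001)
5. ``clinvar``      -- not excluded by the ClinVar significance / germline
                       origin rule (combination mode configurable)
6. ``noncoding``    -- variant classification is coding, or in the retained
                       noncoding set (splice regions, promoters)

Removals are attributed to the *first* failing criterion in this order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "AnnotatedVariant",
    "FilterConfig",
    "FilterReport",
    "CRITERIA",
    "passes_filters",
    "apply_filter_cascade",
    "read_variant_table",
    "write_variant_table",
    "vcf_to_maf_alleles",
    "VariantTableError",
]

CRITERIA = ("vaf", "filter_status", "pon", "popfreq", "clinvar", "noncoding")

#: logical column names of the MAF-style dialect consumed by
#: :func:`read_variant_table`; a column-name mapping may rename them.
REQUIRED_COLUMNS = (
    "patient_id",
    "sample_type",
    "chrom",
    "start",
    "end",
    "ref_allele",
    "alt_allele",
    "gene",
    "variant_classification",
    "hgvs_c",
    "tumor_vaf",
    "filter_status",
    "pon_flag",
    "gnomad_exome_af",
    "gnomad_genome_af",
    "clinvar_significance",
    "clinvar_origin",
)


class VariantTableError(ValueError):
    """Raised for malformed variant tables (missing columns, bad rows)."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated somatic mutation call (MAF-style, 1-based inclusive)."""

    chrom: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    gene: str
    variant_classification: str
    hgvs_c: str
    tumor_vaf: float
    filter_status: str
    pon_flag: bool
    gnomad_exome_af: Optional[float] = None
    gnomad_genome_af: Optional[float] = None
    clinvar_significance: Optional[str] = None
    clinvar_origin: Optional[str] = None
    sample_type: str = "tissue"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for {self.chrom}:{self.start}-{self.end}")
        if not 0.0 <= self.tumor_vaf <= 1.0:
            raise ValueError(f"tumor_vaf out of [0,1]: {self.tumor_vaf}")
        if self.sample_type not in ("tissue", "plasma"):
            raise ValueError(f"unknown sample_type {self.sample_type!r}")


#: classification labels counted as coding (lower-cased comparison)
DEFAULT_CODING_CLASSES = frozenset(
    {
        "missense",
        "missense_mutation",
        "nonsense",
        "nonsense_mutation",
        "frameshift_indel",
        "frame_shift_del",
        "frame_shift_ins",
        "in_frame_del",
        "in_frame_ins",
        "inframe_indel",
        "nonstop_mutation",
        "translation_start_site",
        "start_lost",
        "silent",
    }
)

DEFAULT_RETAINED_NONCODING = frozenset(
    {"splice_site", "splice_region", "promoter", "splice_site_mutation"}
)

DEFAULT_EXCLUDED_CLINVAR = frozenset(
    {"benign", "not_provided", "uncertain_significance"}
)

DEFAULT_GERMLINE_ORIGINS = frozenset({"germline"})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade; defaults match the published criteria."""

    tissue_vaf_min: float = 0.05
    plasma_vaf_min: float = 0.001
    required_filter_status: str = "PASS"
    popfreq_max: float = 0.001  # strict <
    excluded_clinvar: frozenset[str] = DEFAULT_EXCLUDED_CLINVAR
    germline_origin_labels: frozenset[str] = DEFAULT_GERMLINE_ORIGINS
    clinvar_combination: str = "or"  # "or": exclude if either condition holds
    retained_noncoding: frozenset[str] = DEFAULT_RETAINED_NONCODING
    coding_classes: frozenset[str] = DEFAULT_CODING_CLASSES

    def __post_init__(self) -> None:
        for name in ("tissue_vaf_min", "plasma_vaf_min", "popfreq_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if self.clinvar_combination not in ("or", "and"):
            raise ValueError(
                f"clinvar_combination must be 'or' or 'and', got {self.clinvar_combination!r}"
            )
        # allow plain sets in construction
        for name in ("excluded_clinvar", "germline_origin_labels",
                     "retained_noncoding", "coding_classes"):
            v = getattr(self, name)
            if not isinstance(v, frozenset):
                object.__setattr__(self, name, frozenset(s.lower() for s in v))

    def relaxed(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)


@dataclass
class FilterReport:
    """Outcome of a cascade run: retained calls plus removal accounting."""

    input_count: int
    retained_count: int
    removed_by_criterion: dict[str, int]
    retained: list[AnnotatedVariant]

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "retained_count": self.retained_count,
            "removed_by_criterion": dict(self.removed_by_criterion),
        }


def _vaf_threshold(sample_type: str, cfg: FilterConfig) -> float:
    if sample_type == "tissue":
        return cfg.tissue_vaf_min
    if sample_type == "plasma":
        return cfg.plasma_vaf_min
    raise ValueError(f"unknown sample_type {sample_type!r}")


def passes_filters(
    v: AnnotatedVariant, cfg: FilterConfig
) -> tuple[bool, Optional[str]]:
    """Evaluate all six criteria; return (passed, first-failed label or None)."""
    # 1. sample-type VAF threshold (inclusive >=)
    if v.tumor_vaf < _vaf_threshold(v.sample_type, cfg):
        return False, "vaf"
    # 2. caller hard-filter status
    if v.filter_status != cfg.required_filter_status:
        return False, "filter_status"
    # 3. panel of normals
    if v.pon_flag:
        return False, "pon"
    # 4. population frequency, strict <; missing AF passes
    for af in (v.gnomad_exome_af, v.gnomad_genome_af):
        if af is not None and not af < cfg.popfreq_max:
            return False, "popfreq"
    # 5. ClinVar significance / germline origin
    sig = (v.clinvar_significance or "").lower()
    origin = (v.clinvar_origin or "").lower()
    sig_hit = sig in cfg.excluded_clinvar
    germ_hit = origin in cfg.germline_origin_labels
    excluded = (sig_hit or germ_hit) if cfg.clinvar_combination == "or" else (
        sig_hit and germ_hit
    )
    if excluded:
        return False, "clinvar"
    # 6. noncoding removal with retained exceptions
    cls = v.variant_classification.lower()
    if cls not in cfg.coding_classes and cls not in cfg.retained_noncoding:
        return False, "noncoding"
    return True, None


def apply_filter_cascade(
    variants: Iterable[AnnotatedVariant], cfg: FilterConfig | None = None
) -> FilterReport:
    """Run the cascade over ``variants`` preserving input order.

    Each removal is attributed to the first failing criterion; the report
    satisfies ``retained_count + sum(tallies) == input_count``.
    """
    cfg = cfg or FilterConfig()
    tallies = {c: 0 for c in CRITERIA}
    retained: list[AnnotatedVariant] = []
    n = 0
    for v in variants:
        n += 1
        ok, failed = passes_filters(v, cfg)
        if ok:
            retained.append(v)
        else:
            tallies[failed] += 1
    for crit, count in tallies.items():
        if count:
            log.info("filter criterion %-14s removed %d calls", crit, count)
    log.info("retained %d / %d calls", len(retained), n)
    return FilterReport(
        input_count=n,
        retained_count=len(retained),
        removed_by_criterion=tallies,
        retained=retained,
    )


_MISSING = {"", ".", "na", "n/a", "nan", "none"}


def _opt_float(cell, row_no: int, col: str) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    s = str(cell).strip()
    if s.lower() in _MISSING:
        return None
    try:
        return float(s)
    except ValueError:
        raise VariantTableError(
            f"row {row_no}: cannot parse {col}={cell!r} as a number"
        ) from None


def _opt_str(cell) -> Optional[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    s = str(cell).strip()
    return None if s.lower() in _MISSING else s


def read_variant_table(
    path: str | Path, column_map: Optional[Mapping[str, str]] = None
) -> list[AnnotatedVariant]:
    """Read a MAF-style tab-separated variant table.

    ``column_map`` maps logical names (see ``REQUIRED_COLUMNS``) to actual
    file column names.  Missing annotation cells become ``None`` (never a
    silent zero).  Lines starting with ``#`` are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    colmap = {c: c for c in REQUIRED_COLUMNS}
    if column_map:
        colmap.update(column_map)
    missing = [logical for logical, actual in colmap.items() if actual not in df.columns]
    if missing:
        raise VariantTableError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    out: list[AnnotatedVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        rec = {logical: getattr(row, actual) for logical, actual in colmap.items()}
        vaf = _opt_float(rec["tumor_vaf"], i, "tumor_vaf")
        if vaf is None:
            raise VariantTableError(f"row {i}: tumor_vaf is missing")
        pon = str(rec["pon_flag"]).strip().lower() in {"true", "1", "yes", "y"}
        try:
            out.append(
                AnnotatedVariant(
                    chrom=str(rec["chrom"]),
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    ref_allele=str(rec["ref_allele"]),
                    alt_allele=str(rec["alt_allele"]),
                    gene=str(rec["gene"]),
                    variant_classification=str(rec["variant_classification"]),
                    hgvs_c=str(rec["hgvs_c"]),
                    tumor_vaf=vaf,
                    filter_status=str(rec["filter_status"]),
                    pon_flag=pon,
                    gnomad_exome_af=_opt_float(rec["gnomad_exome_af"], i, "gnomad_exome_af"),
                    gnomad_genome_af=_opt_float(rec["gnomad_genome_af"], i, "gnomad_genome_af"),
                    clinvar_significance=_opt_str(rec["clinvar_significance"]),
                    clinvar_origin=_opt_str(rec["clinvar_origin"]),
                    sample_type=str(rec["sample_type"]),
                    patient_id=str(rec["patient_id"]),
                )
            )
        except ValueError as exc:
            raise VariantTableError(f"row {i}: {exc}") from exc
    return out


def write_variant_table(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write variants as a tab-separated table in the dialect read back by
    :func:`read_variant_table`."""
    rows = []
    for v in variants:
        rows.append(
            {
                "patient_id": v.patient_id,
                "sample_type": v.sample_type,
                "chrom": v.chrom,
                "start": v.start,
                "end": v.end,
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "gene": v.gene,
                "variant_classification": v.variant_classification,
                "hgvs_c": v.hgvs_c,
                "tumor_vaf": v.tumor_vaf,
                "filter_status": v.filter_status,
                "pon_flag": v.pon_flag,
                "gnomad_exome_af": "" if v.gnomad_exome_af is None else v.gnomad_exome_af,
                "gnomad_genome_af": "" if v.gnomad_genome_af is None else v.gnomad_genome_af,
                "clinvar_significance": v.clinvar_significance or "",
                "clinvar_origin": v.clinvar_origin or "",
            }
        )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, sep="\t", index=False)


def vcf_to_maf_alleles(pos: int, ref: str, alt: str) -> tuple[int, int, str, str]:
    """Normalize a VCF-style (POS, REF, ALT) record to MAF-style coordinates.

    Returns ``(start, end, ref_allele, alt_allele)`` with 1-based inclusive
    coordinates and ``-`` for the empty side of an indel.
    """
    if len(ref) == len(alt) == 1:
        return pos, pos, ref, alt
    if len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
        # deletion: deleted bases start after the anchor
        deleted = ref[1:]
        return pos + 1, pos + len(deleted), deleted, "-"
    if len(alt) > 1 and len(ref) == 1 and alt[0] == ref[0]:
        # insertion between pos and pos+1
        return pos, pos + 1, "-", alt[1:]
    # block substitution; keep as-is
    return pos, pos + len(ref) - 1, ref, alt
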