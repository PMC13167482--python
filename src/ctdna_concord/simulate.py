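"""Seeded synthetic inputs for every downstream stage.

Three generators, all deterministic for a given config + seed:

- :func:`simulate_read_pairs` -- proper-pair alignments around a single
  variant locus with a configurable mutant-allele fraction and
  allele-specific fragment-size distributions (two-component truncated
  normal mixture: mono-nucleosome plus an offset di-nucleosome component).
- :func:`simulate_variant_table` -- annotated variant tables with exact
  per-filter-criterion strata.
- :func:`simulate_cohort` -- paired tissue/plasma call sets with a known
  per-mutation plasma detection probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .concordance import MutationCall
from .filtering import AnnotatedVariant

__all__ = [
    "VariantSpec",
    "SimConfig",
    "CohortSimSpec",
    "SimConfigError",
    "generate_reference",
    "simulate_read_pairs",
    "simulate_variant_table",
    "simulate_cohort",
    "write_fasta",
    "write_sam",
    "sam_header",
    "STRATA",
]

BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class VariantSpec:
    """A single variant locus in anchored (VCF-like) representation.

    SNV: both alleles length 1.  Insertion: ref is the anchor base, alt is
    anchor + inserted bases.  Deletion: alt is the anchor base, ref is
    anchor + deleted bases.  ``pos`` is the 1-based anchor position.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SimConfigError(f"variant pos must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise SimConfigError("alleles must be nonempty")
        if len(self.ref_allele) > 1 and len(self.alt_allele) > 1:
            raise SimConfigError(
                "block substitutions are not supported; use anchored SNV/ins/del"
            )

    @property
    def kind(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNV"
        if len(self.alt_allele) > 1:
            return "insertion"
        return "deletion"

    @property
    def event_length(self) -> int:
        """Inserted or deleted base count (0 for SNV)."""
        return abs(len(self.alt_allele) - len(self.ref_allele))

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "pos": self.pos,
            "ref_allele": self.ref_allele,
            "alt_allele": self.alt_allele,
            "kind": self.kind,
        }


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the read-pair simulator."""

    seed: int = 0
    reference_length: int = 4000
    variant: VariantSpec = field(
        default_factory=lambda: VariantSpec("chrS", 2000, "C", "T")
    )
    n_fragments: int = 1000
    mutant_fraction: float = 0.1
    mutant_size_mean: float = 153.0
    mutant_size_sd: float = 20.0
    nonmutant_size_mean: float = 162.0
    nonmutant_size_sd: float = 20.0
    dinucleosome_weight: float = 0.15
    dinucleosome_offset: float = 150.0
    read_length: int = 60
    min_size: int = 60
    max_size: int = 450
    background_fraction: float = 0.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mutant_fraction", "dinucleosome_weight",
                     "background_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} out of [0,1]: {v}")
        if self.reference_length < 2000:
            raise SimConfigError(
                f"reference_length must be >= 2000, got {self.reference_length}"
            )
        if self.min_size > self.max_size:
            raise SimConfigError("min_size > max_size")
        if self.min_size < self.read_length:
            raise SimConfigError(
                "min_size must be >= read_length (mates may not overhang the fragment)"
            )
        if self.max_size > self.reference_length - 200:
            raise SimConfigError(
                "max_size must leave a 200 bp placement margin inside the reference"
            )
        if self.read_length < self.variant.event_length + 4:
            raise SimConfigError(
                "read_length too short to span the variant event with anchors"
            )
        margin = self.max_size + 10
        if not margin <= self.variant.pos <= self.reference_length - margin:
            raise SimConfigError(
                "variant pos must sit at least max_size + 10 bases from both ends"
            )


def generate_reference(seed: int, length: int) -> str:
    """Deterministic random A/C/G/T reference sequence."""
    if length < 2000:
        raise SimConfigError(f"reference length must be >= 2000, got {length}")
    rng = np.random.default_rng(seed)
    return "".join(BASES[rng.integers(0, 4, size=length)])


def write_fasta(name: str, sequence: str, path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def sam_header(chrom: str, length: int) -> list[str]:
    return ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{length}"]


def write_sam(
    records: Sequence[dict], chrom: str, ref_length: int, path: Union[str, Path]
) -> None:
    """Write simulated alignment records as SAM text (mandatory 11 columns)."""
    with open(path, "w") as fh:
        for line in sam_header(chrom, ref_length):
            fh.write(line + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r["qname"], r["flag"], r["chrom"], r["pos"], r["mapq"],
                        r["cigar"], "=", r["pnext"], r["tlen"], r["seq"], "*",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# haplotype geometry


def _mutant_haplotype(reference: str, v: VariantSpec) -> str:
    a0 = v.pos - 1
    if reference[a0] != v.ref_allele[0]:
        # force the reference to carry the declared ref anchor base
        reference = reference[:a0] + v.ref_allele[0] + reference[a0 + 1 :]
    if v.kind == "SNV":
        return reference[:a0] + v.alt_allele + reference[a0 + 1 :]
    if v.kind == "insertion":
        return reference[: a0 + 1] + v.alt_allele[1:] + reference[a0 + 1 :]
    d = v.event_length
    return reference[: a0 + 1] + reference[a0 + 1 + d :]


def _normalize_reference(reference: str, v: VariantSpec) -> str:
    """Force the reference to match the variant's declared ref allele bases."""
    a0 = v.pos - 1
    return reference[:a0] + v.ref_allele + reference[a0 + len(v.ref_allele) :]


def _covering_range(v: VariantSpec, mutant: bool, rl: int) -> tuple[int, int]:
    """Inclusive range of haplotype read starts that span the event with
    >= 1 aligned anchor base on each side (enables an informative call)."""
    a0 = v.pos - 1  # 0-based anchor index in both haplotypes
    if v.kind == "SNV":
        return a0 - rl + 2, a0 - 1
    if v.kind == "insertion":
        ki = v.event_length if mutant else 0
        return a0 + ki + 2 - rl, a0
    # deletion
    d = 0 if mutant else v.event_length
    return a0 + d + 2 - rl, a0


def _placement_constraint(v: VariantSpec, mutant: bool) -> Optional[tuple[int, int]]:
    """Haplotype interval a read must fully span (with anchors) or avoid.

    Only mutant insertion haplotypes have one: a read starting or ending
    inside the inserted bases has no plain-CIGAR representation here (real
    aligners would soft-clip it).  Everything else is always representable.
    """
    if v.kind == "insertion" and mutant:
        a0 = v.pos - 1
        return a0 + 1, a0 + v.event_length
    return None


def _read_alignment(
    hap: str, s: int, rl: int, v: VariantSpec, mutant: bool
) -> tuple[int, str, str]:
    """Map a read at haplotype offset ``s`` to (1-based ref pos, CIGAR, seq)."""
    seq = hap[s : s + rl]
    a0 = v.pos - 1
    if not mutant or v.kind == "SNV":
        return s + 1, f"{rl}M", seq
    if v.kind == "insertion":
        ki = v.event_length
        ins_lo, ins_hi = a0 + 1, a0 + ki  # inserted hap indices
        if s + rl - 1 < ins_lo:
            return s + 1, f"{rl}M", seq
        if s > ins_hi:
            return s - ki + 1, f"{rl}M", seq
        a = a0 + 1 - s
        b = rl - a - ki
        if a < 1 or b < 1:
            raise SimConfigError("read partially overlaps insertion (placement bug)")
        return s + 1, f"{a}M{ki}I{b}M", seq
    # deletion
    d = v.event_length
    if s + rl - 1 <= a0:
        return s + 1, f"{rl}M", seq
    if s >= a0 + 1:
        return s + d + 1, f"{rl}M", seq
    a = a0 + 1 - s
    b = rl - a
    return s + 1, f"{a}M{d}D{b}M", seq


def _ref_span(cigar: str, rl: int, v: VariantSpec) -> int:
    if "I" in cigar:
        return rl - v.event_length
    if "D" in cigar:
        return rl + v.event_length
    return rl


def _draw_size(rng: np.random.Generator, cfg: SimConfig, mutant: bool) -> int:
    mean = cfg.mutant_size_mean if mutant else cfg.nonmutant_size_mean
    sd = cfg.mutant_size_sd if mutant else cfg.nonmutant_size_sd
    if rng.random() < cfg.dinucleosome_weight:
        mean += cfg.dinucleosome_offset
    for _ in range(10_000):
        f = int(round(rng.normal(mean, sd)))
        if cfg.min_size <= f <= cfg.max_size:
            return f
    raise SimConfigError(
        f"truncated size support [{cfg.min_size}, {cfg.max_size}] is effectively "
        f"empty for N({mean}, {sd})"
    )


def _sample_from_intervals(
    rng: np.random.Generator, intervals: list[tuple[int, int]]
) -> int:
    """Uniform integer draw from a union of inclusive intervals."""
    merged = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    sizes = [hi - lo + 1 for lo, hi in merged]
    total = sum(sizes)
    if total <= 0:
        raise SimConfigError("no valid fragment placement exists")
    r = int(rng.integers(0, total))
    for (lo, hi), sz in zip(merged, sizes):
        if r < sz:
            return lo + r
        r -= sz
    raise AssertionError("unreachable")


def _mate_valid(s: int, rl: int, event: Optional[tuple[int, int]]) -> bool:
    """A mate must avoid the constrained interval or span it with anchors."""
    if event is None:
        return True
    e_lo, e_hi = event
    if s + rl - 1 < e_lo or s > e_hi:
        return True
    return s <= e_lo - 1 and s + rl - 1 >= e_hi + 1


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def simulate_read_pairs(cfg: SimConfig) -> tuple[list[dict], pd.DataFrame, str]:
    """Simulate proper read pairs around the configured variant locus.

    Returns ``(records, truth, reference)``.  ``records`` is a list of SAM
    field dicts (two mates per fragment, flags 99/147 or 163/83);
    ``truth`` has one row per fragment with the generator's allele label,
    the molecule size and the reference-span size that |TLEN| reports
    (they differ by the indel length for indel-spanning fragments).
    """
    rng = np.random.default_rng(cfg.seed)
    v = cfg.variant
    reference = _normalize_reference(
        generate_reference(cfg.seed, cfg.reference_length), v
    )
    haps = {False: reference, True: _mutant_haplotype(reference, v)}
    rl = cfg.read_length

    records: list[dict] = []
    truth_rows: list[dict] = []
    n_digits = max(6, len(str(cfg.n_fragments)))
    for i in range(cfg.n_fragments):
        mutant = bool(rng.random() < cfg.mutant_fraction)
        background = bool(rng.random() < cfg.background_fraction)
        hap = haps[mutant]
        hap_len = len(hap)
        f = _draw_size(rng, cfg, mutant)
        event = _placement_constraint(v, mutant)

        cov_lo, cov_hi = _covering_range(v, mutant, rl)
        m1 = (max(0, cov_lo), min(hap_len - f, cov_hi))
        m2 = (max(0, cov_lo - f + rl), min(hap_len - f, cov_hi - f + rl))
        covering = [iv for iv in (m1, m2) if iv[0] <= iv[1]]

        s = None
        for _ in range(1000):
            if background:
                cand = int(rng.integers(0, hap_len - f + 1))
                if _mate_covers_none(cand, f, rl, cov_lo, cov_hi, event):
                    s = cand
                    break
            else:
                if not covering:
                    raise SimConfigError(
                        "fragment cannot be placed to cover the locus; "
                        "check min_size/read_length vs the event length"
                    )
                cand = _sample_from_intervals(rng, covering)
                if _mate_valid(cand, rl, event) and _mate_valid(
                    cand + f - rl, rl, event
                ):
                    s = cand
                    break
        if s is None:
            raise SimConfigError("failed to place fragment after 1000 attempts")

        qname = f"frag_{i:0{n_digits}d}"
        pos1, cig1, seq1 = _read_alignment(hap, s, rl, v, mutant)
        pos2, cig2, seq2 = _read_alignment(hap, s + f - rl, rl, v, mutant)
        end2 = pos2 + _ref_span(cig2, rl, v)  # exclusive
        tlen = end2 - pos1
        seq1 = _apply_errors(rng, seq1, cfg.error_rate)
        seq2 = _apply_errors(rng, seq2, cfg.error_rate)
        # leftmost mate is read1 half the time (99/147), read2 otherwise (163/83)
        first_is_left = bool(rng.random() < 0.5)
        flag_left, flag_right = (99, 147) if first_is_left else (163, 83)
        records.append(
            {"qname": qname, "flag": flag_left, "chrom": v.chrom, "pos": pos1,
             "mapq": 60, "cigar": cig1, "pnext": pos2, "tlen": tlen, "seq": seq1}
        )
        records.append(
            {"qname": qname, "flag": flag_right, "chrom": v.chrom, "pos": pos2,
             "mapq": 60, "cigar": cig2, "pnext": pos1, "tlen": -tlen, "seq": seq2}
        )
        truth_rows.append(
            {
                "fragment": qname,
                "allele": "mutant" if mutant else "non_mutant",
                "molecule_size": f,
                "tlen_size": tlen,
                "hap_start": s,
                "covers_locus": not background,
            }
        )

    truth = pd.DataFrame(truth_rows)
    return records, truth, reference


def _mate_covers_none(
    s: int, f: int, rl: int, cov_lo: int, cov_hi: int, event: tuple[int, int]
) -> bool:
    for ms in (s, s + f - rl):
        if cov_lo <= ms <= cov_hi:
            return False
        if not _mate_valid(ms, rl, event):
            return False
    return True


# ---------------------------------------------------------------------------
# filter-cascade strata

STRATA = (
    "pass_all",
    "fail_vaf",
    "fail_status",
    "fail_pon",
    "fail_popfreq",
    "fail_clinvar",
    "fail_noncoding",
)

_CODING_POOL = ("missense", "nonsense", "frameshift_indel", "silent")
_NONCODING_POOL = ("intron", "3'utr", "5'utr", "igr")
_FAIL_STATUS_POOL = ("base_quality", "weak_evidence", "panel_of_normals")
_EXCLUDED_CLINVAR_POOL = ("benign", "not_provided", "uncertain_significance")
_GENES = ("APC", "KRAS", "TP53", "PIK3CA", "BRAF", "EGFR", "SMAD4", "ATM")


def simulate_variant_table(
    seed: int, stratum_counts: dict[str, int], sample_type: str = "tissue"
) -> tuple[list[AnnotatedVariant], int]:
    """Generate an annotated variant table with exact per-criterion strata.

    Each ``fail_*`` stratum fails exactly that one cascade criterion (under
    the default :class:`~ctdna_concord.filtering.FilterConfig`); ``pass_all``
    rows pass every criterion.  Returns ``(variants, expected_pass_count)``
    with rows in seeded shuffled order.
    """
    unknown = set(stratum_counts) - set(STRATA)
    if unknown:
        raise SimConfigError(f"unknown strata: {sorted(unknown)}")
    if any(c < 0 for c in stratum_counts.values()):
        raise SimConfigError("stratum counts must be nonnegative")
    rng = np.random.default_rng(seed)
    vaf_min = 0.05 if sample_type == "tissue" else 0.001

    variants: list[AnnotatedVariant] = []
    for stratum in STRATA:
        for _ in range(stratum_counts.get(stratum, 0)):
            pos = int(rng.integers(1_000_000, 2_000_000))
            fields = {
                "chrom": f"chr{int(rng.integers(1, 23))}",
                "start": pos,
                "end": pos,
                "ref_allele": str(rng.choice(list("ACGT"))),
                "alt_allele": str(rng.choice(list("ACGT"))),
                "gene": str(rng.choice(_GENES)),
                "variant_classification": str(rng.choice(_CODING_POOL)),
                "hgvs_c": f"c.{int(rng.integers(1, 5000))}A>G",
                "tumor_vaf": float(rng.uniform(vaf_min, 0.9)),
                "filter_status": "PASS",
                "pon_flag": False,
                "gnomad_exome_af": None if rng.random() < 0.5 else float(rng.uniform(0, 0.0009)),
                "gnomad_genome_af": None,
                "clinvar_significance": None if rng.random() < 0.5 else "pathogenic",
                "clinvar_origin": None if rng.random() < 0.5 else "somatic",
                "sample_type": sample_type,
                "patient_id": "sim",
            }
            if stratum == "fail_vaf":
                fields["tumor_vaf"] = float(rng.uniform(0, vaf_min * 0.98))
            elif stratum == "fail_status":
                fields["filter_status"] = str(rng.choice(_FAIL_STATUS_POOL))
            elif stratum == "fail_pon":
                fields["pon_flag"] = True
            elif stratum == "fail_popfreq":
                fields["gnomad_exome_af"] = float(rng.uniform(0.001, 0.5))
            elif stratum == "fail_clinvar":
                fields["clinvar_significance"] = str(rng.choice(_EXCLUDED_CLINVAR_POOL))
                fields["clinvar_origin"] = "somatic"
            elif stratum == "fail_noncoding":
                fields["variant_classification"] = str(rng.choice(_NONCODING_POOL))
            variants.append(AnnotatedVariant(**fields))

    order = rng.permutation(len(variants))
    variants = [variants[i] for i in order]
    return variants, stratum_counts.get("pass_all", 0)


# ---------------------------------------------------------------------------
# paired tissue/plasma cohorts


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameterization of the paired tissue/plasma cohort generator."""

    seed: int = 0
    n_patients: int = 16
    mutations_per_patient: Union[int, tuple[int, int]] = 20
    plasma_detection_prob: float = 0.734
    plasma_only_rate: float = 0.0
    tissue_vaf_range: tuple[float, float] = (0.05, 0.9)
    plasma_vaf_range: tuple[float, float] = (0.001, 0.5)

    def __post_init__(self) -> None:
        for name in ("plasma_detection_prob", "plasma_only_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} out of [0,1]: {v}")
        if self.n_patients < 1:
            raise SimConfigError("n_patients must be >= 1")


def simulate_cohort(
    spec: CohortSimSpec,
) -> tuple[list[MutationCall], list[MutationCall], pd.DataFrame]:
    """Generate paired tissue/plasma call sets.

    Every tissue mutation independently appears in plasma with
    ``plasma_detection_prob`` (sharing its coordinate identity key); extra
    plasma-exclusive calls are added per ``plasma_only_rate``.  Returns
    ``(tissue_calls, plasma_calls, truth)`` where ``truth`` has one row per
    patient with matched/total counts.
    """
    rng = np.random.default_rng(spec.seed)
    mpp = spec.mutations_per_patient
    tissue: list[MutationCall] = []
    plasma: list[MutationCall] = []
    truth_rows = []
    locus = 0
    for p in range(spec.n_patients):
        pid = f"P{p + 1:03d}"
        n_mut = mpp if isinstance(mpp, int) else int(rng.integers(mpp[0], mpp[1] + 1))
        matched = 0
        for _ in range(n_mut):
            locus += 1
            gene = str(rng.choice(_GENES))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            call = dict(
                patient_id=pid,
                gene=gene,
                chrom=f"chr{int(rng.integers(1, 23))}",
                start=1_000_000 + locus,  # unique per mutation
                ref_allele=str(ref),
                alt_allele=str(alt),
                hgvs_c=f"c.{locus}{ref}>{alt}",
            )
            tissue.append(
                MutationCall(sample_type="tissue",
                             vaf=float(rng.uniform(*spec.tissue_vaf_range)), **call)
            )
            if rng.random() < spec.plasma_detection_prob:
                matched += 1
                plasma.append(
                    MutationCall(sample_type="plasma",
                                 vaf=float(rng.uniform(*spec.plasma_vaf_range)), **call)
                )
        n_extra = int(rng.binomial(n_mut, spec.plasma_only_rate))
        for _ in range(n_extra):
            locus += 1
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            plasma.append(
                MutationCall(
                    patient_id=pid,
                    gene=str(rng.choice(_GENES)),
                    sample_type="plasma",
                    chrom=f"chr{int(rng.integers(1, 23))}",
                    start=5_000_000 + locus,
                    ref_allele=str(ref),
                    alt_allele=str(alt),
                    hgvs_c=f"c.{locus + 900000}{ref}>{alt}",
                    vaf=float(rng.uniform(*spec.plasma_vaf_range)),
                )
            )
        truth_rows.append(
            {"patient_id": pid, "tissue_mutations": n_mut,
             "matched_in_plasma": matched, "plasma_only": n_extra}
        )
    return tissue, plasma, pd.DataFrame(truth_rows)
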