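"""Tissue-plasma concordance metrics.

Implements mutation-level tumor-mutation detection rates with score-based
confidence intervals, patient-level per-gene positive detection rates,
reference-material panel evaluation, and the expected-VAF mixing arithmetic
used to construct diluted reference standards.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .stats import binomial_interval, round_half_away

__all__ = [
    "MutationCall",
    "MatchResult",
    "DetectionRateResult",
    "RefMatPanelRow",
    "match_variants",
    "detection_rate",
    "gene_positive_rate",
    "refmat_detection_rate",
    "expected_mix_vaf",
    "cohort_detection_rates",
]

KEY_MODES = ("hgvs", "coordinate")
GENE_RATE_MODES = ("plasma_given_tissue", "tissue_only", "plasma_only", "combined")


@dataclass(frozen=True)
class MutationCall:
    """One mutation call in one sample of one patient.

    Identity for matching is either ``(gene, hgvs_c)`` string equality
    ("hgvs" mode; no HGVS normalization is attempted) or the
    ``(chrom, start, ref, alt)`` tuple ("coordinate" mode).
    """

    patient_id: str
    gene: str
    sample_type: str  # tissue | plasma
    hgvs_c: str = ""
    chrom: Optional[str] = None
    start: Optional[int] = None
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None
    vaf: Optional[float] = None

    def key(self, key_mode: str) -> tuple:
        if key_mode == "hgvs":
            return (self.patient_id, self.gene, self.hgvs_c)
        if key_mode == "coordinate":
            return (self.patient_id, self.chrom, self.start, self.ref_allele, self.alt_allele)
        raise ValueError(f"unknown key_mode {key_mode!r}; choose from {KEY_MODES}")


@dataclass
class MatchResult:
    matched: list[MutationCall]      # tissue calls also seen in plasma
    tissue_only: list[MutationCall]
    plasma_only: list[MutationCall]


@dataclass
class DetectionRateResult:
    """A detection-rate claim: counts, rounded percentage, and 95% CI."""

    numerator: int
    denominator: int
    rate_percent: Optional[float]  # rounded half-away-from-zero
    ci_low: Optional[float]
    ci_high: Optional[float]
    undefined: bool = False

    @property
    def rate_str(self) -> str:
        if self.undefined:
            return "NA"
        return f"{self.rate_percent}% ({self.numerator}/{self.denominator})"

    def to_dict(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "rate_percent": self.rate_percent,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "undefined": self.undefined,
        }


@dataclass(frozen=True)
class RefMatPanelRow:
    """One variant of the multiplexed reference panel with per-arm observed VAFs."""

    gene: str
    cosmic_id: str
    theoretical_af: Optional[float]          # percent, None = not tested
    observed_af: dict[str, Optional[float]]  # arm name -> percent or None (not detected)


def _check_no_duplicates(calls: Sequence[MutationCall], key_mode: str, label: str) -> None:
    counts = Counter(c.key(key_mode) for c in calls)
    dups = [k for k, n in counts.items() if n > 1]
    if dups:
        raise ValueError(
            f"duplicate {key_mode} keys within {label} calls: {dups[:5]}"
            " (deduplicate upstream)"
        )


def match_variants(
    tissue_calls: Sequence[MutationCall],
    plasma_calls: Sequence[MutationCall],
    key_mode: str = "hgvs",
) -> MatchResult:
    """Partition calls into matched / tissue-only / plasma-only, within patient.

    ``|matched| + |tissue_only| == |tissue_calls|`` always holds; plasma-only
    calls never enter any detection-rate denominator.
    """
    _check_no_duplicates(tissue_calls, key_mode, "tissue")
    _check_no_duplicates(plasma_calls, key_mode, "plasma")
    plasma_keys = {c.key(key_mode) for c in plasma_calls}
    tissue_keys = {c.key(key_mode) for c in tissue_calls}
    matched = [c for c in tissue_calls if c.key(key_mode) in plasma_keys]
    tissue_only = [c for c in tissue_calls if c.key(key_mode) not in plasma_keys]
    plasma_only = [c for c in plasma_calls if c.key(key_mode) not in tissue_keys]
    return MatchResult(matched=matched, tissue_only=tissue_only, plasma_only=plasma_only)


def detection_rate(
    matched_count: int,
    tissue_count: int,
    conf: float = 0.95,
    method: str = "wilson",
    places: int = 1,
) -> DetectionRateResult:
    """Mutation-level detection rate with a score-based CI (Wilson default)."""
    if not 0 <= matched_count <= tissue_count:
        raise ValueError(
            f"need 0 <= matched <= tissue_count, got {matched_count}/{tissue_count}"
        )
    if tissue_count == 0:
        return DetectionRateResult(0, 0, None, None, None, undefined=True)
    low, high = binomial_interval(matched_count, tissue_count, conf, method)
    pct = round_half_away(100.0 * matched_count / tissue_count, places)
    return DetectionRateResult(matched_count, tissue_count, pct, low, high)


def gene_positive_rate(
    cohort_calls: Iterable[MutationCall],
    gene: str,
    mode: str,
    n_patients: Optional[int] = None,
    key_mode: str = "hgvs",
    conf: float = 0.95,
    places: int = 1,
) -> DetectionRateResult:
    """Patient-level positive detection rate for one gene.

    Modes
    -----
    ``plasma_given_tissue``
        denominator = patients with >=1 tissue mutation in ``gene``;
        numerator = those whose plasma contains >=1 *identical* mutation
        in ``gene`` (same identity key).
    ``tissue_only`` / ``plasma_only`` / ``combined``
        denominator = ``n_patients`` (the full cohort size, required);
        numerator = patients with >=1 call in that sample type (or either,
        for ``combined``).

    A patient counts once regardless of mutation multiplicity.
    """
    if mode not in GENE_RATE_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {GENE_RATE_MODES}")
    calls = [c for c in cohort_calls if c.gene == gene]
    tissue = [c for c in calls if c.sample_type == "tissue"]
    plasma = [c for c in calls if c.sample_type == "plasma"]

    if mode == "plasma_given_tissue":
        tissue_patients = {c.patient_id for c in tissue}
        plasma_keys = {c.key(key_mode) for c in plasma}
        hit = {c.patient_id for c in tissue if c.key(key_mode) in plasma_keys}
        k, n = len(hit), len(tissue_patients)
        if n == 0:
            return DetectionRateResult(0, 0, None, None, None, undefined=True)
        return detection_rate(k, n, conf=conf, places=places)

    if n_patients is None:
        raise ValueError(f"mode {mode!r} requires n_patients (cohort size)")
    if mode == "tissue_only":
        positive = {c.patient_id for c in tissue}
    elif mode == "plasma_only":
        positive = {c.patient_id for c in plasma}
    else:  # combined
        positive = {c.patient_id for c in tissue} | {c.patient_id for c in plasma}
    return detection_rate(len(positive), n_patients, conf=conf, places=places)


def refmat_detection_rate(
    panel: Sequence[RefMatPanelRow], arm: str, places: int = 1
) -> DetectionRateResult:
    """Detection rate of a reference-material panel for one extraction arm.

    numerator = rows with an observed VAF in that arm; denominator = panel size.
    """
    if not panel:
        raise ValueError("empty reference panel")
    for row in panel:
        if arm not in row.observed_af:
            raise ValueError(f"arm {arm!r} missing for panel row {row.cosmic_id}")
    detected = sum(1 for row in panel if row.observed_af[arm] is not None)
    return detection_rate(detected, len(panel), places=places)


def expected_mix_vaf(
    af_a: float, af_b: float, ratio_a: float = 1.0, ratio_b: float = 1.0
) -> float:
    """Expected VAF of mixing two materials at a volume ratio.

    Assumes equal amplifiable DNA content per unit volume, so the expected
    VAF is the ratio-weighted mean ``(ra*af_a + rb*af_b) / (ra + rb)``.
    """
    if min(af_a, af_b, ratio_a, ratio_b) < 0:
        raise ValueError("inputs must be nonnegative")
    if ratio_a + ratio_b == 0:
        raise ValueError("ratios must not both be zero")
    return (ratio_a * af_a + ratio_b * af_b) / (ratio_a + ratio_b)


def cohort_detection_rates(
    tissue_calls: Sequence[MutationCall],
    plasma_calls: Sequence[MutationCall],
    key_mode: str = "hgvs",
    conf: float = 0.95,
    places: int = 1,
) -> dict:
    """Per-patient and overall mutation-level detection rates for a cohort.

    The overall rate pools per-patient numerators and denominators, so it
    always equals sum(matched_i) / sum(tissue_i).
    """
    result = match_variants(tissue_calls, plasma_calls, key_mode)
    per_patient: dict[str, DetectionRateResult] = {}
    patients = sorted({c.patient_id for c in tissue_calls})
    for pid in patients:
        k = sum(1 for c in result.matched if c.patient_id == pid)
        n = sum(1 for c in tissue_calls if c.patient_id == pid)
        per_patient[pid] = detection_rate(k, n, conf=conf, places=places)
    overall = detection_rate(
        len(result.matched), len(tissue_calls), conf=conf, places=places
    )
    return {
        "per_patient": per_patient,
        "overall": overall,
        "plasma_only_count": len(result.plasma_only),
    }
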