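"""Packaged fixture tables and typed loaders.

Registry names
--------------
- ``table2_refmat``        -- 38-variant reference-material VAF panel,
  observed VAF per extraction arm
- ``table3_tissue_plasma`` -- APC/KRAS/TP53 calls in matched tissue and
  plasma across the 16-patient cohort (long format)
- ``table4_detection``     -- per-patient tumor mutation counts and the
  number also detected in plasma
- ``table5_actionable``    -- actionable-gene (BRAF/PIK3CA/EGFR) calls per
  patient, tissue and plasma columns
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .concordance import MutationCall, RefMatPanelRow

__all__ = [
    "FIXTURES",
    "load_fixture",
    "table2_panel",
    "table3_calls",
    "table4_counts",
    "table5_calls",
    "COHORT_SIZE",
]

FIXTURES = {
    "table2_refmat": "table2_refmat.tsv",
    "table3_tissue_plasma": "table3_tissue_plasma.tsv",
    "table4_detection": "table4_detection.tsv",
    "table5_actionable": "table5_actionable.tsv",
}

#: number of patients in the paired tissue/plasma cohort
COHORT_SIZE = 16

#: arms of the reference-material comparison
REFMAT_ARMS = ("liquid_liquid", "solid_phase")


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by registry name."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        )
    ref = resources.files("ctdna_concord") / "data" / FIXTURES[name]
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def table2_panel() -> list[RefMatPanelRow]:
    """The reference-material panel as typed rows (VAFs in percent)."""
    df = load_fixture("table2_refmat")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            RefMatPanelRow(
                gene=rec.gene,
                cosmic_id=rec.cosmic_id,
                theoretical_af=(
                    None if rec.theoretical_af == "not_tested" else float(rec.theoretical_af)
                ),
                observed_af={
                    "solid_phase": None if rec.solid_phase_af == "NA" else float(rec.solid_phase_af),
                    "liquid_liquid": None if rec.liquid_liquid_af == "NA" else float(rec.liquid_liquid_af),
                },
            )
        )
    return rows


def table3_calls() -> list[MutationCall]:
    """Matched tissue/plasma calls for APC/KRAS/TP53 (HGVS identity keys)."""
    df = load_fixture("table3_tissue_plasma")
    return [
        MutationCall(
            patient_id=rec.patient_id,
            sample_type=rec.sample_type,
            gene=rec.gene,
            hgvs_c=rec.hgvs_c,
            vaf=float(rec.vaf_percent) / 100.0,
        )
        for rec in df.itertuples(index=False)
    ]


def table4_counts() -> pd.DataFrame:
    """Per-patient (tissue_mutations, detected_in_plasma) counts as integers."""
    df = load_fixture("table4_detection")
    return df.astype({"tissue_mutations": int, "detected_in_plasma": int})


def table5_calls() -> list[MutationCall]:
    """Actionable-gene calls parsed from the per-patient wide fixture."""
    df = load_fixture("table5_actionable")
    calls: list[MutationCall] = []
    for rec in df.itertuples(index=False):
        for sample_type in ("tissue", "plasma"):
            cell = getattr(rec, sample_type)
            if cell == ".":
                continue
            for entry in cell.split(";"):
                gene, hgvs, vaf = entry.split("|")
                calls.append(
                    MutationCall(
                        patient_id=rec.patient_id,
                        sample_type=sample_type,
                        gene=gene,
                        hgvs_c=hgvs,
                        vaf=float(vaf) / 100.0,
                    )
                )
    return calls
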