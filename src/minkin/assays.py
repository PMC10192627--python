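"""Soil assay arithmetic: plate counts, extractability, cyclodextrin dosing.

Small exactly-specified calculations that accompany a mineralization
study: viable degrader counts from serial-dilution plating (CFU per gram
of soil), the percentage of the spiked compound recovered in an aqueous
extract, and the mass of 2-hydroxypropyl-β-cyclodextrin (HPBCD) needed to
dose a soil at a chosen molar ratio to the contaminant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DilutionCount",
    "ExtractionRecord",
    "cfu_per_gram",
    "percent_extracted",
    "hpbcd_dose",
    "read_extractions_csv",
    "MW_PHENANTHRENE",
    "MW_HPBCD",
]

MW_PHENANTHRENE = 178.23  # g/mol
MW_HPBCD = 1380.0  # g/mol, typical substitution grade

EXTRACTANTS = ("water", "NS", "NS_HPBCD")


@dataclass(frozen=True)
class DilutionCount:
    """Colonies on one plate from a 1:10 serial dilution series.

    Defaults mirror the usual protocol: 1 g soil suspended in 5 mL medium,
    100 µL plated from the 10^-d dilution.
    """

    colonies: int
    dilution_exponent: int
    plated_volume: float = 0.1  # mL
    suspension_volume: float = 5.0  # mL
    soil_mass: float = 1.0  # g

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")
        if self.dilution_exponent < 0:
            raise ValueError("dilution_exponent must be >= 0")
        if min(self.plated_volume, self.suspension_volume, self.soil_mass) <= 0:
            raise ValueError("volumes and soil mass must be > 0")


@dataclass(frozen=True)
class ExtractionRecord:
    """Aqueous extraction of a spiked soil (defaults: 1 g soil, 50 mg/kg)."""

    soil: str
    extractant: str
    extract_conc: float  # mg/L in the extract
    extract_volume: float = 5.0  # mL
    applied_mass: float = 0.05  # mg in the extracted soil portion

    def __post_init__(self) -> None:
        if self.extractant not in EXTRACTANTS:
            raise ValueError(f"extractant must be one of {EXTRACTANTS}")
        if self.extract_conc < 0:
            raise ValueError("extract_conc must be >= 0")
        if self.extract_volume <= 0:
            raise ValueError("extract_volume must be > 0")


def cfu_per_gram(c: DilutionCount) -> float:
    """Viable count per gram of soil from one plate.

    ``(colonies / plated_volume) * 10^d * suspension_volume / soil_mass``.
    The suspension/soil normalization factor is explicit so alternative
    counting conventions can be reproduced by overriding the defaults.
    """
    return (
        c.colonies
        / c.plated_volume
        * 10.0**c.dilution_exponent
        * c.suspension_volume
        / c.soil_mass
    )


def percent_extracted(r: ExtractionRecord) -> float:
    """Percent of the applied mass recovered in the extract.

    ``conc (mg/L) * volume (mL) / 1000 / applied (mg) * 100`` — raises on a
    mass-balance violation (>100%) or zero applied mass.
    """
    if r.applied_mass <= 0:
        raise ValueError("applied_mass must be > 0")
    pct = r.extract_conc * (r.extract_volume / 1000.0) / r.applied_mass * 100.0
    if pct > 100.0:
        raise ValueError(
            f"extracted {pct:.1f}% exceeds the applied mass (mass balance violated)"
        )
    return pct


def hpbcd_dose(
    applied_conc: float,
    soil_mass: float,
    molar_ratio: float = 10.0,
    mw_phe: float = MW_PHENANTHRENE,
    mw_hpbcd: float = MW_HPBCD,
) -> float:
    """Mass of HPBCD (mg) dosing a soil at ``molar_ratio`` × the contaminant.

    ``applied_conc`` is the contaminant concentration in mg per kg of soil
    and ``soil_mass`` the treated soil in grams.  The cyclodextrin molar
    mass depends on the substitution grade, so it is a parameter.
    """
    if applied_conc < 0 or soil_mass <= 0 or molar_ratio < 0:
        raise ValueError("inputs must be positive (molar_ratio may be 0)")
    if mw_phe <= 0 or mw_hpbcd <= 0:
        raise ValueError("molar masses must be > 0")
    applied_mg = applied_conc * soil_mass / 1000.0
    return applied_mg / mw_phe * molar_ratio * mw_hpbcd


def read_extractions_csv(path) -> list[ExtractionRecord]:
    """Load extraction records (columns soil,extractant,conc_mg_L[,volume_mL])."""
    df = pd.read_csv(path)
    required = {"soil", "extractant", "conc_mg_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        if "volume_mL" in df.columns:
            kwargs["extract_volume"] = float(row["volume_mL"])
        records.append(
            ExtractionRecord(
                soil=str(row["soil"]),
                extractant=str(row["extractant"]),
                extract_conc=float(row["conc_mg_L"]),
                **kwargs,
            )
        )
    return records
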