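"""Leaf functional traits and nutrient resorption metrics.

Resorption efficiency (RE) is the proportion of a green-leaf nutrient
withdrawn before abscission, corrected for the dry-mass loss that
accompanies senescence:

    RE = (1 - senesced/green * MLCF) * 100 %

where MLCF (mass loss correction factor) is the senesced-to-green leaf
dry-mass ratio.  Without the correction (MLCF = 1) RE is underestimated,
because nutrient per remaining mass overstates nutrient per original leaf.
Negative RE means net accumulation during senescence (typical of Na in
Na-compartmentalising euhalophytes).  Resorption proficiency (RP) is simply
the terminal concentration in senesced leaves; lower RP = higher
proficiency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ELEMENTS, LeafSample, ResorptionRecord, samples_to_frame

logger = logging.getLogger(__name__)

#: leaf water mass per area (g m-2) above which a leaf counts as succulent
SUCCULENCE_THRESHOLD = 500.0


@dataclass
class FunctionalTraits:
    SLA: float  # specific leaf area, cm2 g-1
    LDMC: float  # leaf dry matter content, dry/saturated mass
    succulence: float  # leaf water per area, g m-2
    K_Na_ratio: float | None
    is_succulent: bool


def mlcf(green_dry_mass: float, senesced_dry_mass: float) -> float:
    """Mass loss correction factor: senesced/green leaf dry mass (typically <= 1)."""
    if not (green_dry_mass > 0 and senesced_dry_mass > 0):
        raise ValueError("dry masses must be positive")
    return senesced_dry_mass / green_dry_mass


def resorption_efficiency(green_conc, senesced_conc, mlcf: float = 1.0):
    """Mass-loss-corrected resorption efficiency in percent.

    ``(1 - senesced/green * mlcf) * 100``; negative values signal
    accumulation and are not capped.  Accepts scalars or arrays.
    """
    green = np.asarray(green_conc, dtype=float)
    senesced = np.asarray(senesced_conc, dtype=float)
    if np.any(green <= 0):
        raise ValueError("green concentration must be positive (RE undefined at 0)")
    if np.any(senesced < 0):
        raise ValueError("senesced concentration must be non-negative")
    if not mlcf > 0:
        raise ValueError("mlcf must be positive")
    out = (1.0 - senesced / green * mlcf) * 100.0
    return float(out) if out.ndim == 0 else out


def resorption_proficiency(senesced_conc: float) -> float:
    """Terminal nutrient concentration in senesced leaves (mg g-1).

    Identity on its input; the convention is that LOWER values mean HIGHER
    proficiency (more complete withdrawal).
    """
    if senesced_conc < 0:
        raise ValueError("senesced concentration must be non-negative")
    return float(senesced_conc)


def functional_traits(
    area: float,
    dry_mass: float,
    saturated_mass: float,
    green_K: float | None = None,
    green_Na: float | None = None,
) -> FunctionalTraits:
    """SLA, LDMC, succulence and K/Na from one (green) leaf observation.

    Succulence is leaf water mass per leaf area in g m-2 so that the
    conventional 500 g m-2 succulence threshold applies directly.
    """
    if not (area > 0 and dry_mass > 0 and saturated_mass > 0):
        raise ValueError("area and masses must be positive")
    if dry_mass > saturated_mass:
        raise ValueError("dry mass cannot exceed saturated mass")
    sla = area / dry_mass
    ldmc = dry_mass / saturated_mass
    succulence = (saturated_mass - dry_mass) / (area / 1e4)  # cm2 -> m2
    k_na = None
    if green_K is not None and green_Na is not None:
        if green_Na > 0:
            k_na = green_K / green_Na
        else:
            logger.warning("green Na is 0; K/Na ratio undefined, returned as missing")
    return FunctionalTraits(
        SLA=sla,
        LDMC=ldmc,
        succulence=succulence,
        K_Na_ratio=k_na,
        is_succulent=succulence > SUCCULENCE_THRESHOLD,
    )


# ---------------------------------------------------------------------- #
# table-level aggregation
# ---------------------------------------------------------------------- #


def species_summaries(samples: list[LeafSample] | pd.DataFrame) -> pd.DataFrame:
    """Per-species trait summary table.

    Functional traits (SLA, LDMC, succulence, K/Na) come from green leaves;
    MLCF is the ratio of species-mean senesced to species-mean green dry
    mass.  Element means are reported per status.
    """
    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    rows = []
    for species, sub in df.groupby("species", sort=True):
        green = sub[sub["status"] == "green"]
        senesced = sub[sub["status"] == "senesced"]
        if green.empty or senesced.empty:
            logger.warning("species %s lacks a green/senesced pair; skipped", species)
            continue
        ft = functional_traits(
            area=green["leaf_area"].mean(),
            dry_mass=green["dry_mass"].mean(),
            saturated_mass=green["saturated_mass"].mean(),
            green_K=green["K"].mean(),
            green_Na=green["Na"].mean(),
        )
        row = {
            "species": species,
            "family": sub["family"].iloc[0],
            "group": sub["group"].iloc[0],
            "MLCF": mlcf(green["dry_mass"].mean(), senesced["dry_mass"].mean()),
            "SLA": ft.SLA,
            "LDMC": ft.LDMC,
            "succulence": ft.succulence,
            "is_succulent": ft.is_succulent,
            "K_Na_green": ft.K_Na_ratio,
            "n_green": len(green),
            "n_senesced": len(senesced),
        }
        sen_na = senesced["Na"].mean()
        row["K_Na_senesced"] = senesced["K"].mean() / sen_na if sen_na > 0 else math.nan
        for el in ELEMENTS:
            row[f"{el}_green"] = green[el].mean()
            row[f"{el}_senesced"] = senesced[el].mean()
        row["N_P_green"] = row["N_green"] / row["P_green"] if row["P_green"] > 0 else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def resorption_table(
    samples: list[LeafSample] | pd.DataFrame,
    level: str = "species",
) -> pd.DataFrame:
    """RE (%) and RP (mg g-1) per unit and element.

    ``level='species'`` (default) computes RE from species-mean green and
    senesced concentrations with the species MLCF; ``level='individual'``
    pairs the green and senesced rows of each tagged individual.  The
    (Se, Na) combination carries a caveat flag: salt secretion makes the RE
    arithmetic uninterpretable as resorption for sodium in secretohalophytes.
    """
    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    if level not in ("species", "individual"):
        raise ValueError(f"unknown level {level!r}")
    summ = species_summaries(df)
    mlcf_of = summ.set_index("species")["MLCF"]
    records = []
    if level == "species":
        for _, row in summ.iterrows():
            for el in ELEMENTS:
                re = resorption_efficiency(
                    row[f"{el}_green"], row[f"{el}_senesced"], row["MLCF"]
                )
                records.append(
                    {
                        "unit": row["species"],
                        "group": row["group"],
                        "element": el,
                        "RE_percent": re,
                        "RP": resorption_proficiency(row[f"{el}_senesced"]),
                        "caveat": "Na-secretion" if (row["group"], el) == ("Se", "Na") else "",
                    }
                )
    else:
        for (species, individual), sub in df.groupby(["species", "individual"], sort=True):
            green = sub[sub["status"] == "green"]
            senesced = sub[sub["status"] == "senesced"]
            if green.empty or senesced.empty or species not in mlcf_of.index:
                continue
            group = sub["group"].iloc[0]
            for el in ELEMENTS:
                re = resorption_efficiency(
                    green[el].mean(), senesced[el].mean(), mlcf_of[species]
                )
                records.append(
                    {
                        "unit": f"{species}/{individual}",
                        "group": group,
                        "element": el,
                        "RE_percent": re,
                        "RP": resorption_proficiency(senesced[el].mean()),
                        "caveat": "Na-secretion" if (group, el) == ("Se", "Na") else "",
                    }
                )
    return pd.DataFrame(records)


def records_from_table(table: pd.DataFrame) -> list[ResorptionRecord]:
    return [
        ResorptionRecord(
            unit=r["unit"], element=r["element"], RE_percent=r["RE_percent"],
            RP=r["RP"], caveat=r.get("caveat", ""),
        )
        for r in table.to_dict("records")
    ]
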