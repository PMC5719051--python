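"""Core data types and file I/O for the resorption pipeline.

The trait table is a long-format CSV with one row per leaf sample:
``species, family, group, site, individual, status`` plus the six element
concentrations (mg g-1), ``leaf_area`` (cm2), ``dry_mass`` and
``saturated_mass`` (g).  Trees travel as Newick, results as plain CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .tree import Phylogeny

logger = logging.getLogger(__name__)

ELEMENTS = ["N", "P", "K", "Na", "Ca", "Mg"]
GROUPS = ["Eu", "Se", "Ps", "Gl"]
STATUSES = ["green", "senesced"]

TRAIT_COLUMNS = (
    ["species", "family", "group", "site", "individual", "status"]
    + ELEMENTS
    + ["leaf_area", "dry_mass", "saturated_mass"]
)


class TraitTableFormatError(ValueError):
    """Raised when a trait CSV is structurally unusable (missing columns)."""


@dataclass
class LeafSample:
    """One leaf observation (element concentrations in mg g-1, masses in g,
    area in cm2)."""

    species: str
    family: str
    group: str  # Eu | Se | Ps | Gl
    site: str
    individual: str
    status: str  # green | senesced
    conc: dict[str, float]
    leaf_area: float
    dry_mass: float
    saturated_mass: float

    def check(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.status not in STATUSES:
            problems.append(f"unknown status {self.status!r}")
        for el in ELEMENTS:
            v = self.conc.get(el)
            if v is None or pd.isna(v):
                problems.append(f"missing {el} concentration")
            elif v < 0:
                problems.append(f"negative {el} concentration ({v})")
        if not self.dry_mass > 0:
            problems.append(f"non-positive dry_mass ({self.dry_mass})")
        if self.dry_mass > self.saturated_mass:
            problems.append(
                f"dry_mass {self.dry_mass} exceeds saturated_mass {self.saturated_mass}"
            )
        if not self.leaf_area > 0:
            problems.append(f"non-positive leaf_area ({self.leaf_area})")
        return problems


@dataclass
class SpeciesTraitSummary:
    """Per-species trait summary: per-status element means plus functional
    traits and the mass loss correction factor (MLCF)."""

    species: str
    group: str
    mean_conc: dict[str, dict[str, float]]  # status -> element -> mg g-1
    SLA: float  # cm2 g-1
    LDMC: float  # dry/saturated mass, in (0, 1]
    succulence: float  # g water m-2
    MLCF: float  # senesced/green dry mass
    K_Na_ratio: float | None


@dataclass
class ResorptionRecord:
    """Resorption efficiency (%) and proficiency (mg g-1) for one unit
    (species or individual) and element.  Negative RE = net accumulation;
    lower RP = higher proficiency."""

    unit: str
    element: str
    RE_percent: float
    RP: float
    caveat: str = ""


@dataclass
class TraitTableReport:
    n_accepted: int
    n_rejected: int
    diagnostics: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------- #
# readers
# ---------------------------------------------------------------------- #


def read_trait_table(path) -> tuple[list[LeafSample], TraitTableReport]:
    """Read a long-format leaf-trait CSV.

    Rows violating :class:`LeafSample` invariants are rejected with
    row-numbered diagnostics; an unknown group label anywhere aborts with a
    ``ValueError`` naming the label, a missing mandatory column with a
    :class:`TraitTableFormatError`.
    """
    df = pd.read_csv(path, dtype={c: str for c in TRAIT_COLUMNS[:6]})
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableFormatError(f"missing mandatory column(s): {missing}")
    bad_groups = sorted(set(df["group"]) - set(GROUPS))
    if bad_groups:
        raise ValueError(f"unknown group label(s): {bad_groups}")

    samples: list[LeafSample] = []
    diagnostics: list[str] = []
    for idx, row in df.iterrows():
        sample = LeafSample(
            species=row["species"],
            family=row["family"],
            group=row["group"],
            site=row["site"],
            individual=row["individual"],
            status=row["status"],
            conc={el: float(row[el]) for el in ELEMENTS},
            leaf_area=float(row["leaf_area"]),
            dry_mass=float(row["dry_mass"]),
            saturated_mass=float(row["saturated_mass"]),
        )
        problems = sample.check()
        if problems:
            diagnostics.append(f"row {idx + 2}: " + "; ".join(problems))
        else:
            samples.append(sample)
    report = TraitTableReport(len(samples), len(diagnostics), diagnostics)
    if report.n_rejected:
        logger.warning("rejected %d trait rows: %s", report.n_rejected, diagnostics)
    return samples, report


def samples_to_frame(samples: list[LeafSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        d = asdict(s)
        conc = d.pop("conc")
        d.update(conc)
        rows.append(d)
    return pd.DataFrame(rows, columns=TRAIT_COLUMNS)


def write_trait_table(samples: list[LeafSample] | pd.DataFrame, path) -> None:
    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    df.to_csv(path, index=False)


def read_newick(path, default_branch_length: float = 1.0) -> Phylogeny:
    """Read a Newick tree; absent branch lengths default to unit length
    (logged) and polytomies are resolved with zero-length branches."""
    return Phylogeny.read(path, default_branch_length=default_branch_length)


# ---------------------------------------------------------------------- #
# writers
# ---------------------------------------------------------------------- #


def write_results(tables: dict[str, pd.DataFrame], outdir, metadata: dict | None = None):
    """Write one CSV per named result table plus ``run_metadata.json``.

    Numeric values keep full precision (Python repr), so re-running with
    the same seed and configuration gives byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        if table.empty:
            logger.warning("result table %r is empty; writing header only", name)
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    if metadata is not None:
        meta_path = outdir / "run_metadata.json"
        with open(meta_path, "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(meta_path)
    return written
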