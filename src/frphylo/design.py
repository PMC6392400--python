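"""Experimental-design data model, trial/control CSV I/O, and the
control-based net-consumption correction.

The study layout is a split-plot feeding experiment: heated tanks are the
whole plots (one temperature each), and boxes within a tank — one plant
species at one initial biomass, with a single snail — are the subplots.
A matching no-herbivore control experiment measures each species' natural
weight change (imbibition / air-drying) over the trial, which is subtracted
from gross consumption to obtain net consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SpeciesInfo",
    "ExperimentalDesign",
    "ConsumptionRecord",
    "ControlVariation",
    "InvalidDesignError",
    "enumerate_units",
    "enumerate_control_units",
    "correct_consumption",
    "read_trials",
    "write_trials",
    "read_controls",
    "write_controls",
    "records_to_frame",
    "frame_to_records",
]

TRIAL_COLUMNS = ["block", "temperature_C", "species", "N_initial_g", "final_g"]
OPTIONAL_TRIAL_COLUMNS = ["gross_g", "net_g", "clamped"]
CONTROL_COLUMNS = ["replicate", "species", "N_initial_g", "final_g"]


class InvalidDesignError(ValueError):
    """Raised when an experimental design is internally inconsistent."""


@dataclass(frozen=True)
class SpeciesInfo:
    """One host plant: identity, biogeographic origin, and habitat.

    ``familiarity`` is "familiar" when the plant shares the herbivore's
    region of origin (South America) and "novel" otherwise.
    """

    name: str
    common_name: str
    origin_region: str
    habitat: str  # "aquatic" | "semiaquatic"

    @property
    def familiarity(self) -> str:
        return "familiar" if self.origin_region == "South America" else "novel"


@dataclass(frozen=True)
class ExperimentalDesign:
    """Factor levels of the split-plot feeding experiment.

    Parameters
    ----------
    n_blocks
        Number of temporal blocks (study: 3).
    temperatures_C
        Whole-plot (tank) temperatures in degrees Celsius (study: 26-34).
    species
        Host plants (study: 10, five familiar and five novel).
    biomass_levels_g
        Initial wet weights offered, in grams (study: 1,2,4,6,8,10,12).
    duration_hr
        Trial length T in hours (study: 60).
    """

    n_blocks: int = 3
    temperatures_C: tuple[float, ...] = (26.0, 28.0, 30.0, 32.0, 34.0)
    species: tuple[SpeciesInfo, ...] = ()
    biomass_levels_g: tuple[float, ...] = (1, 2, 4, 6, 8, 10, 12)
    duration_hr: float = 60.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise InvalidDesignError("n_blocks must be >= 1")
        if not self.temperatures_C or not self.biomass_levels_g or not self.species:
            raise InvalidDesignError("all factor lists must be non-empty")
        if self.duration_hr <= 0:
            raise InvalidDesignError("duration_hr must be positive")
        levels = tuple(self.biomass_levels_g)
        if any(b <= 0 for b in levels):
            raise InvalidDesignError("biomass levels must be strictly positive")
        if any(b2 <= b1 for b1, b2 in zip(levels, levels[1:])):
            raise InvalidDesignError("biomass levels must be strictly increasing")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise InvalidDesignError("duplicate species names in design")

    @property
    def n_units(self) -> int:
        return (
            self.n_blocks
            * len(self.temperatures_C)
            * len(self.species)
            * len(self.biomass_levels_g)
        )

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def familiarity_of(self, name: str) -> str:
        for s in self.species:
            if s.name == name:
                return s.familiarity
        raise KeyError(f"species not in design: {name!r}")


@dataclass
class ConsumptionRecord:
    """One feeding-trial unit, optionally control-corrected.

    ``gross_g`` is initial minus final weight; ``net_g`` is gross minus the
    species' mean natural weight change, clamped into [0, N_initial_g]
    (``clamped`` records whether clamping changed the value).
    """

    block: int
    temperature_C: float
    species: str
    N_initial_g: float
    final_g: float
    net_g: float | None = None
    clamped: bool = False

    @property
    def gross_g(self) -> float:
        return self.N_initial_g - self.final_g


@dataclass(frozen=True)
class ControlVariation:
    """Per-species mean and SD of natural weight change over the trial."""

    values: Mapping[str, tuple[float, float]]  # species -> (mean_g, sd_g)

    def __post_init__(self) -> None:
        for name, (_, sd) in self.values.items():
            if sd < 0:
                raise ValueError(f"negative control SD for {name!r}")

    def mean_g(self, species: str) -> float:
        try:
            return self.values[species][0]
        except KeyError:
            raise KeyError(f"species not in control table: {species!r}") from None

    def sd_g(self, species: str) -> float:
        try:
            return self.values[species][1]
        except KeyError:
            raise KeyError(f"species not in control table: {species!r}") from None

    def species_names(self) -> list[str]:
        return list(self.values)


def enumerate_units(design: ExperimentalDesign) -> list[tuple[int, float, str, float]]:
    """Full factorial crossing of the trial design.

    Returns ``(block, temperature_C, species_name, biomass_g)`` tuples in a
    fixed block-major order (block, then temperature, species, biomass) so
    that seeded simulations are reproducible.
    """
    return [
        (block, temp, sp.name, b)
        for block in range(1, design.n_blocks + 1)
        for temp in design.temperatures_C
        for sp in design.species
        for b in design.biomass_levels_g
    ]


def enumerate_control_units(
    design: ExperimentalDesign, n_replicates: int
) -> list[tuple[int, str, float]]:
    """Units of the no-herbivore control: (replicate, species, biomass)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [
        (rep, sp.name, b)
        for rep in range(1, n_replicates + 1)
        for sp in design.species
        for b in design.biomass_levels_g
    ]


def correct_consumption(
    gross_g: float,
    species: str,
    control: ControlVariation,
    N_initial_g: float,
) -> tuple[float, bool]:
    """Net consumption = gross − species control mean, clamped to [0, N].

    Clamping enforces the domain of Rogers' equation (0 ≤ Ne ≤ N); the
    returned flag reports whether the raw corrected value fell outside it.
    """
    if N_initial_g <= 0:
        raise ValueError("N_initial_g must be positive")
    net = gross_g - control.mean_g(species)
    clamped_net = min(max(net, 0.0), N_initial_g)
    return clamped_net, clamped_net != net


def apply_correction(
    records: Iterable[ConsumptionRecord], control: ControlVariation
) -> list[ConsumptionRecord]:
    """Control-correct every record in place-order, returning new records."""
    out = []
    for r in records:
        net, was_clamped = correct_consumption(
            r.gross_g, r.species, control, r.N_initial_g
        )
        out.append(replace(r, net_g=net, clamped=was_clamped))
    return out


# ---------------------------------------------------------------------------
# CSV I/O


def records_to_frame(records: Sequence[ConsumptionRecord]) -> pd.DataFrame:
    rows = [
        {
            "block": r.block,
            "temperature_C": r.temperature_C,
            "species": r.species,
            "N_initial_g": r.N_initial_g,
            "final_g": r.final_g,
            "gross_g": r.gross_g,
            "net_g": r.net_g,
            "clamped": r.clamped,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS + OPTIONAL_TRIAL_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[ConsumptionRecord]:
    _validate_trial_frame(df)
    records = []
    for i, row in df.iterrows():
        records.append(
            ConsumptionRecord(
                block=int(row["block"]),
                temperature_C=float(row["temperature_C"]),
                species=str(row["species"]),
                N_initial_g=float(row["N_initial_g"]),
                final_g=float(row["final_g"]),
                net_g=float(row["net_g"]) if "net_g" in df.columns and pd.notna(row["net_g"]) else None,
                clamped=bool(row["clamped"]) if "clamped" in df.columns and pd.notna(row["clamped"]) else False,
            )
        )
    return records


def _validate_trial_frame(df: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials table missing column(s): {missing}")
    for col in ("N_initial_g", "final_g", "temperature_C"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int((df[col].isna() | bad).idxmax())
            raise ValueError(f"non-numeric or missing {col!r} at row {row}")
    neg = df.index[pd.to_numeric(df["N_initial_g"]) <= 0]
    if len(neg):
        raise ValueError(f"non-positive N_initial_g at row {int(neg[0])}")


def read_trials(path) -> list[ConsumptionRecord]:
    """Read trial records from CSV (columns: block,temperature_C,species,
    N_initial_g,final_g[,gross_g,net_g,clamped])."""
    return frame_to_records(pd.read_csv(path))


def write_trials(records: Sequence[ConsumptionRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_controls(path) -> pd.DataFrame:
    """Read no-herbivore control records (replicate,species,N_initial_g,final_g)."""
    df = pd.read_csv(path)
    missing = [c for c in CONTROL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"control table missing column(s): {missing}")
    return df


def write_controls(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def estimate_control_variation(controls: pd.DataFrame) -> ControlVariation:
    """Per-species mean/SD of (initial − final) weight change in the controls."""
    change = controls["N_initial_g"] - controls["final_g"]
    grouped = change.groupby(controls["species"])
    return ControlVariation(
        {
            name: (float(g.mean()), float(g.std(ddof=1)) if len(g) > 1 else 0.0)
            for name, g in grouped
        }
    )
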