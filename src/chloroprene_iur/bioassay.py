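"""Individual-animal time-to-tumor bioassay data and fixed constant tables.

The central record is one animal from a chronic rodent inhalation bioassay:
its dose group (external air concentration in ppm and the PBPK-derived
internal dose, µmole chloroprene metabolized per gram lung per day), the
week of the study at which the animal died or was sacrificed, whether the
tumor of interest was present at necropsy, and the tumor *context* — how
the tumor relates to death:

``incidental``
    the tumor was observed at death but did not cause it (the likelihood
    uses onset prevalence at the death time);
``fatal``
    the tumor caused death (the likelihood uses the onset density);
``unknown``
    tumor status could not be determined (missing/autolyzed tissue).

CSV layout (UTF-8, '.' decimal separator)::

    animal_id,group,conc_ppm,internal_dose,time_weeks,tumor,context

with ``context`` coded ``I``/``F``/``U``, mirroring BMDS-style
time-to-tumor input files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "TumorContext",
    "AnimalRecord",
    "DoseGroupSummary",
    "ConstantsTable",
    "TumorPairMarginals",
    "read_animal_records",
    "write_animal_records",
    "ntp_female_mouse_fixture",
    "ntp_female_mouse_tumor_pairs",
    "DEFAULT_TERMINAL_WEEKS",
]

#: Terminal sacrifice time for a standard 2-year chronic study, in weeks.
DEFAULT_TERMINAL_WEEKS = 104.0

CSV_COLUMNS = [
    "animal_id",
    "group",
    "conc_ppm",
    "internal_dose",
    "time_weeks",
    "tumor",
    "context",
]


class TumorContext(enum.Enum):
    """How an observed tumor relates to the animal's death."""

    INCIDENTAL = "I"
    FATAL = "F"
    UNKNOWN = "U"


@dataclass(frozen=True)
class AnimalRecord:
    """One animal's dose, death time and tumor observation."""

    animal_id: str
    group_label: str
    external_conc: float  # ppm
    internal_dose: float  # µmole/g-lung/day
    death_time: float  # study weeks
    tumor_present: bool
    context: TumorContext

    def __post_init__(self) -> None:
        if self.external_conc < 0:
            raise ValueError(f"external_conc must be >= 0, got {self.external_conc}")
        if self.internal_dose < 0:
            raise ValueError(f"internal_dose must be >= 0, got {self.internal_dose}")
        if self.death_time <= 0:
            raise ValueError(f"death_time must be > 0, got {self.death_time}")
        if self.context is TumorContext.FATAL and not self.tumor_present:
            raise ValueError(
                f"animal {self.animal_id}: fatal context requires tumor_present=True"
            )


@dataclass(frozen=True)
class DoseGroupSummary:
    """Marginal tumor incidence for one dose group."""

    external_conc: float  # ppm
    internal_dose: float  # µmole/g-lung/day
    n_animals: int
    n_tumor: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_tumor <= self.n_animals:
            raise ValueError(
                f"n_tumor ({self.n_tumor}) must lie in [0, n_animals={self.n_animals}]"
            )


@dataclass(frozen=True)
class ConstantsTable:
    """Published conversion constants used throughout the pipeline.

    ``human_conversion_factor`` is the PBPK-derived relationship between a
    continuous human exposure in ppm and the internal lung dose metric
    (µmole metabolized/g-lung/day per ppm).  ``internal_dose_map`` holds the
    female-mouse bioassay concentrations and their PBPK internal doses.
    ``epa_2010_iur`` is the 2010 EPA multi-tumor unit risk (per µg/m³),
    carried only as a comparison constant.
    """

    human_conversion_factor: float = 0.0106
    ppm_to_ugm3: float = 3620.0
    internal_dose_map: tuple[tuple[float, float], ...] = (
        (12.8, 0.74),
        (32.0, 1.19),
        (80.0, 1.58),
    )
    epa_2010_iur: float = 5e-4

    def __post_init__(self) -> None:
        if self.human_conversion_factor <= 0 or self.ppm_to_ugm3 <= 0:
            raise ValueError("conversion constants must be strictly positive")
        if self.epa_2010_iur <= 0:
            raise ValueError("epa_2010_iur must be strictly positive")
        ppm = [p for p, _ in self.internal_dose_map]
        dose = [d for _, d in self.internal_dose_map]
        if any(x <= 0 for x in ppm + dose):
            raise ValueError("internal_dose_map entries must be strictly positive")
        if sorted(ppm) != ppm or sorted(dose) != dose or len(set(ppm)) != len(ppm):
            raise ValueError("internal_dose_map must be strictly increasing")


@dataclass(frozen=True)
class TumorPairMarginals:
    """Marginals for one tumor type against the lung-tumor margin."""

    label: str
    n_total: int
    n_with_type: int  # animals bearing this tumor type
    n_with_lung: int  # animals bearing a lung tumor
    n_both: int  # animals bearing both


def _parse_row(row: pd.Series, line_no: int) -> AnimalRecord:
    try:
        context = TumorContext(str(row["context"]).strip().upper())
    except ValueError:
        raise ValueError(
            f"row {line_no}: invalid tumor context {row['context']!r} "
            f"(expected one of I, F, U)"
        ) from None
    try:
        conc = float(row["conc_ppm"])
        dose = float(row["internal_dose"])
        time = float(row["time_weeks"])
        tumor = int(row["tumor"])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {line_no}: non-numeric field ({exc})") from None
    if tumor not in (0, 1):
        raise ValueError(f"row {line_no}: tumor must be 0 or 1, got {tumor}")
    try:
        return AnimalRecord(
            animal_id=str(row["animal_id"]),
            group_label=str(row["group"]),
            external_conc=conc,
            internal_dose=dose,
            death_time=time,
            tumor_present=bool(tumor),
            context=context,
        )
    except ValueError as exc:
        raise ValueError(f"row {line_no}: {exc}") from None


def read_animal_records(path: str | Path) -> list[AnimalRecord]:
    """Read individual-animal records from the documented CSV layout.

    Errors (missing column, non-numeric time, negative dose, invalid
    context code) are hard failures naming the offending data row
    (1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = [_parse_row(row, i + 1) for i, (_, row) in enumerate(frame.iterrows())]
    records.sort(key=lambda r: (r.group_label, r.animal_id))
    return records


def write_animal_records(records: list[AnimalRecord], path: str | Path) -> None:
    """Write records in the same CSV layout ``read_animal_records`` consumes."""
    frame = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "group": [r.group_label for r in records],
            "conc_ppm": [r.external_conc for r in records],
            "internal_dose": [r.internal_dose for r in records],
            "time_weeks": [r.death_time for r in records],
            "tumor": [int(r.tumor_present) for r in records],
            "context": [r.context.value for r in records],
        }
    )
    frame.to_csv(path, index=False)


def ntp_female_mouse_fixture() -> list[DoseGroupSummary]:
    """Female B6C3F1 mouse lung-tumor incidence from the 2-year NTP bioassay.

    Four groups of 50 animals at 0/12.8/32/80 ppm with combined
    alveolar/bronchiolar adenoma-or-carcinoma counts 4/28/34/42 and PBPK
    internal doses 0/0.74/1.19/1.58 µmole/g-lung/day.
    """
    return [
        DoseGroupSummary(0.0, 0.0, 50, 4),
        DoseGroupSummary(12.8, 0.74, 50, 28),
        DoseGroupSummary(32.0, 1.19, 50, 34),
        DoseGroupSummary(80.0, 1.58, 50, 42),
    ]


def ntp_female_mouse_tumor_pairs() -> list[TumorPairMarginals]:
    """Co-occurrence marginals of each female-mouse tumor type with lung tumors.

    Pooled over all 200 female mice (controls included).  108 animals bore a
    lung tumor; for each other tumor type the marginals give the number of
    animals with that type and the number bearing both.
    """
    lung = 108
    pairs = [
        ("All organs: hemangiosarcomas and/or hemangiomas", 36, 25),
        ("Mammary gland: carcinoma and/or adenoacanthoma", 32, 23),
        ("Forestomach: squamous cell papilloma and/or carcinoma", 5, 5),
        ("Liver: hepatocellular adenoma and/or carcinoma", 96, 61),
        ("Skin: sarcoma", 40, 30),
        ("Harderian gland: adenoma and/or carcinoma", 19, 12),
        ("Zymbal gland: carcinoma", 3, 3),
    ]
    return [
        TumorPairMarginals(label, 200, n_type, lung, n_both)
        for label, n_type, n_both in pairs
    ]
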