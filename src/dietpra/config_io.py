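"""Survey I/O, packaged reference tables, and descriptive summaries.

The contaminant survey is a flat table of individual rice-sample cadmium
measurements (region, year, concentration in mg/kg fresh weight, detection
flag).  Non-detects — samples below the censoring threshold — are stored as
exactly zero, and every summary statistic is computed over all values
including those zeros.  This module also packages, as plain CSV/YAML
fixtures, the per-region survey summary table, the age–gender consumption
strata, and the reference-dose constants that parameterize the risk model.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, SchemaError, ValidationError

__all__ = [
    "ConcentrationRecord",
    "ConcentrationSummary",
    "ReferenceConstants",
    "read_concentration_survey",
    "write_concentration_survey",
    "summarize_concentrations",
    "five_number_summary_by_year",
    "compliance_check",
    "load_constants",
    "load_table1_summaries",
    "load_table2_groups",
]

#: canonical survey column names
SURVEY_COLUMNS = ("region", "year", "cd_mg_per_kg", "detected")

_TRUE_TOKENS = {"1", "true", "t", "yes"}
_FALSE_TOKENS = {"0", "false", "f", "no"}


@dataclass(frozen=True)
class ConcentrationRecord:
    """One rice sample's cadmium measurement.

    ``value`` is in mg/kg fresh weight; ``detected`` is False for censored
    (non-detect) samples, whose value is stored as 0 by convention.
    """

    region: str
    year: int
    value: float
    detected: bool

    def __post_init__(self):
        if self.value < 0:
            raise ValidationError(f"negative concentration {self.value}")
        if not self.detected and self.value != 0:
            raise ValidationError("non-detect record must carry value 0")


@dataclass(frozen=True)
class ConcentrationSummary:
    """Descriptive summary of one survey stratum (a region, a year, or all).

    ``detect_rate`` may be ``None`` when unknown (e.g. a summary transcribed
    from a report that prints only moments).
    """

    region: str
    n: int
    mean: float
    sd: float
    median: float
    max: float
    detect_rate: float | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"summary needs n >= 1, got {self.n}")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")
        if not (0 <= self.median <= self.max or np.isclose(self.median, self.max)):
            raise ValidationError(
                f"median {self.median} outside [0, max={self.max}]"
            )
        if self.detect_rate is not None and not 0 <= self.detect_rate <= 1:
            raise ValidationError(f"detect_rate {self.detect_rate} outside [0,1]")


@dataclass(frozen=True)
class ReferenceConstants:
    """Health-based guidance values and regulatory limits for cadmium.

    Doses are per kg body weight: ``rfd_efsa`` in ug/kg bw/day, the weekly
    intakes in ug/kg bw/week, the EPA reference doses in mg/kg/day.
    Maximum levels (``ml_*``) are concentrations in mg/kg.
    """

    rfd_efsa: float = 0.36
    twi_efsa: float = 2.5
    ptwi_jecfa: float = 7.0
    ptmi_jecfa: float = 25.0
    rfd_epa_water: float = 0.0005
    rfd_epa_food: float = 0.001
    ml_taiwan: float = 0.4
    ml_china: float = 0.2
    loq_as_printed: float = 0.2
    censor_threshold_default: float = 0.002
    detect_rate_overall: float = 0.89

    def __post_init__(self):
        for name in (
            "rfd_efsa", "twi_efsa", "ptwi_jecfa", "ptmi_jecfa",
            "rfd_epa_water", "rfd_epa_food", "ml_taiwan", "ml_china",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if round(self.twi_efsa / 7.0, 2) != self.rfd_efsa:
            raise ValidationError("rfd_efsa must equal twi_efsa/7 to 2 decimals")


def _data_path(name: str):
    return importlib.resources.files("dietpra") / "data" / name


def load_constants(path=None) -> ReferenceConstants:
    """Load reference constants from YAML (packaged defaults if no path)."""
    if path is None:
        text = (_data_path("constants.yaml")).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return ReferenceConstants(**yaml.safe_load(text))


def _parse_detected(token, row: int) -> bool:
    s = str(token).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise ValidationError(f"unparseable detected flag {token!r}", row=row)


def read_concentration_survey(
    path, dialect: Mapping[str, str] | None = None
) -> list[ConcentrationRecord]:
    """Read a survey CSV into records.

    ``dialect`` maps canonical column names (``region``, ``year``,
    ``cd_mg_per_kg``, ``detected``) to the names used in the file.  Rows
    flagged as non-detect get value 0 regardless of any reported trace
    value, matching the censoring convention used throughout.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path)
    cols = {}
    for canon in SURVEY_COLUMNS:
        name = dialect.get(canon, canon)
        if name not in df.columns:
            raise SchemaError(name, path=str(path))
        cols[canon] = df[name]
    records: list[ConcentrationRecord] = []
    for i in range(len(df)):
        value = float(cols["cd_mg_per_kg"].iloc[i])
        if value < 0:
            raise ValidationError(f"negative concentration {value}", row=i)
        detected = _parse_detected(cols["detected"].iloc[i], i)
        records.append(
            ConcentrationRecord(
                region=str(cols["region"].iloc[i]),
                year=int(cols["year"].iloc[i]),
                value=value if detected else 0.0,
                detected=detected,
            )
        )
    return records


def write_concentration_survey(records: Iterable[ConcentrationRecord], path) -> None:
    """Write records to the canonical survey CSV layout."""
    df = records_to_frame(records)
    df.to_csv(path, index=False)


def records_to_frame(records: Iterable[ConcentrationRecord]) -> pd.DataFrame:
    rows = [(r.region, r.year, r.value, int(r.detected)) for r in records]
    return pd.DataFrame(rows, columns=list(SURVEY_COLUMNS))


def _summary_from_values(
    label: str, values: np.ndarray, detected: np.ndarray
) -> ConcentrationSummary:
    n = values.size
    return ConcentrationSummary(
        region=label,
        n=int(n),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if n > 1 else 0.0,
        median=float(np.median(values)),
        max=float(values.max()),
        detect_rate=float(detected.sum()) / n,
    )


def summarize_concentrations(
    records: Sequence[ConcentrationRecord], group_by: str = "none"
) -> list[ConcentrationSummary]:
    """Descriptive summaries with non-detect zeros included in every moment.

    ``group_by`` is ``"region"``, ``"year"`` or ``"none"`` (one pooled row
    labelled ``"Total"``).  SD is the n-1 sample standard deviation.
    """
    if not records:
        raise EmptyInputError("no records to summarize")
    if group_by not in ("region", "year", "none"):
        raise ValueError(f"unknown group_by {group_by!r}")
    values = np.array([r.value for r in records], dtype=float)
    detected = np.array([r.detected for r in records], dtype=bool)
    if group_by == "none":
        return [_summary_from_values("Total", values, detected)]
    keys = np.array([getattr(r, group_by) for r in records])
    out = []
    for key in sorted(set(keys.tolist())):
        mask = keys == key
        out.append(_summary_from_values(str(key), values[mask], detected[mask]))
    return out


def five_number_summary_by_year(
    records: Sequence[ConcentrationRecord],
) -> dict[int, tuple[float, float, float, float, float]]:
    """Per-year (min, Q1, median, Q3, max) with the linear quantile rule."""
    if not records:
        raise EmptyInputError("no records")
    years = np.array([r.year for r in records])
    values = np.array([r.value for r in records], dtype=float)
    out = {}
    for year in sorted(set(years.tolist())):
        v = values[years == year]
        q = np.percentile(v, [0, 25, 50, 75, 100])
        out[int(year)] = tuple(float(x) for x in q)
    return out


def compliance_check(
    records: Sequence[ConcentrationRecord], max_level: float
) -> dict[str, float]:
    """Count samples exceeding a regulatory maximum level (strictly above)."""
    if max_level <= 0:
        raise ValueError("max_level must be positive")
    n = len(records)
    n_exceeding = sum(1 for r in records if r.value > max_level)
    return {
        "n_total": n,
        "n_exceeding": n_exceeding,
        "fraction_exceeding": (n_exceeding / n) if n else 0.0,
    }


def load_table1_summaries(
    path=None, detect_rate: float | None = None
) -> list[ConcentrationSummary]:
    """Load the packaged per-region survey summary table (17 regions + Total).

    The printed table carries no per-region detection rates, so all rows get
    the overall rate (0.89 by default) unless ``detect_rate`` overrides it.
    """
    if detect_rate is None:
        detect_rate = load_constants().detect_rate_overall
    if path is None:
        with _data_path("table1_summaries.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return [
        ConcentrationSummary(
            region=row.region,
            n=int(row.n),
            mean=float(row.mean),
            sd=float(row.sd),
            median=float(row.median),
            max=float(row.max),
            detect_rate=detect_rate,
        )
        for row in df.itertuples(index=False)
    ]


def load_table2_groups(path=None) -> pd.DataFrame:
    """Load the age–gender consumption strata table as a DataFrame.

    Columns: group label, arithmetic mean/SD of daily rice intake (g/day),
    the surveyed intake range (g/day) used as truncation bounds, and
    arithmetic mean/SD of body weight (kg).
    """
    if path is None:
        with _data_path("table2_groups.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)
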