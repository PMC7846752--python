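"""Domain types, validation, and IO for enamel-carbonate isotope datasets.

A dataset is a flat table of individual tooth measurements (one tooth per
individual) plus a site registry describing the funerary communities the
samples come from: site code, period, an optional modern reference
drinking-water range for the locality, and an optional pooling group that
marks sites suitable for merging into one statistical population.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

PERIODS = ("neolithic", "copper_age")

#: canonical CSV column order for sample tables
SAMPLE_COLUMNS = [
    "sample_id",
    "site_code",
    "period",
    "tooth_element",
    "tooth_generation",
    "d18O_ca_vpdb",
    "d13C_ca_vpdb",
]

ISOTOPE_BOUNDS = (-30.0, 10.0)  # plausible ‰ range for enamel carbonate values


def round_report(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as isotope results are conventionally printed.

    Python's built-in ``round`` is banker's rounding; printed per-mil values
    round ties away from zero (−6.25 → −6.3 at one decimal).
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ToothSample:
    """One individual's enamel carbonate measurement with tooth metadata."""

    sample_id: str
    site_code: str
    period: str
    tooth_element: str
    tooth_generation: str  # "deciduous" | "permanent"
    d18O_ca_vpdb: float
    d13C_ca_vpdb: Optional[float] = None
    age_class: Optional[str] = None
    notes: Optional[str] = None

    def __post_init__(self):
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}, got {self.period!r}")
        if self.tooth_generation not in ("deciduous", "permanent"):
            raise ValueError(f"bad tooth_generation {self.tooth_generation!r}")


@dataclass
class SiteGroup:
    """A funerary community: its samples plus locality metadata."""

    code: str
    name: str
    period: str
    reference_water_range: Optional[tuple[float, float]] = None
    pooling_group: Optional[str] = None
    samples: list[ToothSample] = field(default_factory=list)
    member_codes: Optional[list[str]] = None  # provenance when pooled
    synthetic: Optional[dict] = None  # generative parameters for the bundled scenario

    def __post_init__(self):
        if self.reference_water_range is not None:
            lo, hi = self.reference_water_range
            # ranges are normalized on load so reversed input is not an error
            self.reference_water_range = (min(lo, hi), max(lo, hi))

    @property
    def n(self) -> int:
        return len(self.samples)

    def d18O_vpdb(self) -> list[float]:
        return [s.d18O_ca_vpdb for s in self.samples]

    def d13C(self) -> list[float]:
        return [s.d13C_ca_vpdb for s in self.samples if s.d13C_ca_vpdb is not None]


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    min: float
    max: float
    mean: float
    sd: float  # n−1 denominator; NaN for n = 1
    median: float
    q1: float
    q3: float

    @property
    def range(self) -> float:
        return self.max - self.min


@dataclass(frozen=True)
class SpreadMeasures:
    """Robust spread set used to build locality windows.

    ``mad_raw`` is the median absolute deviation from the median; ``mad_norm``
    its normal-consistent scaling (×1.4826); ``mad_q3`` the 75th percentile of
    the absolute deviations, a skew-tolerant alternative for non-normal sites;
    ``iqr`` the interquartile range.
    """

    mad_raw: float
    mad_norm: float
    mad_q3: float
    iqr: float


@dataclass(frozen=True)
class NormalityResult:
    W: float
    p: float
    n: int


@dataclass(frozen=True)
class LocalityWindow:
    """The interval of values compatible with local origin under one criterion."""

    method: str  # two_sd | three_mad_norm | three_mad_q3 | tukey_iqr | two_permil
    center: float
    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        """Closed-interval membership; only strictly-outside values are outliers."""
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class SampleFlags:
    sample_id: str
    value: float
    flags: Mapping[str, bool]  # method → outside window
    boundary: Mapping[str, bool]  # method → within one reporting unit of a bound
    consensus_count: int
    is_consensus_outlier: bool


@dataclass
class OutlierReport:
    site_code: str
    methods: list[str]
    windows: dict[str, LocalityWindow]
    rows: list[SampleFlags]

    def consensus_outliers(self) -> list[SampleFlags]:
        return [r for r in self.rows if r.is_consensus_outlier]

    def flagged_by(self, method: str) -> list[SampleFlags]:
        return [r for r in self.rows if r.flags.get(method, False)]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec = {"sample_id": r.sample_id, "value": r.value}
            for m in self.methods:
                rec[m] = r.flags[m]
            rec["consensus_count"] = r.consensus_count
            rec["is_consensus_outlier"] = r.is_consensus_outlier
            records.append(rec)
        return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class PoolingReport:
    test: str  # "t_test" | "kruskal_wallis"
    statistic: float
    p: float
    groups: list[str]
    pooled: bool


@dataclass
class DrinkingWaterEstimate:
    site_code: str
    per_sample_dw: dict[str, float]  # sample_id → δ¹⁸Odw ‰ V-SMOW
    mean_dw: float
    sd_dw: float


@dataclass
class ValidationFinding:
    kind: str  # unknown_site | out_of_range | duplicate_id | missing_d18O | missing_d13C
    sample_id: Optional[str]
    message: str
    severity: str = "error"  # "error" | "warning"


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __len__(self) -> int:
        return len(self.findings)


# ---------------------------------------------------------------------------
# readers / writers


def infer_tooth_generation(tooth_element: str, explicit: Optional[str] = None) -> str:
    """Resolve deciduous vs permanent.

    Order: explicit column value, then the lowercase-"d" element-name prefix
    convention ("dm2" is a deciduous second molar), else permanent.
    """
    if explicit:
        e = explicit.strip().lower()
        if e in ("deciduous", "permanent"):
            return e
        raise ValueError(f"bad tooth_generation value {explicit!r}")
    if tooth_element and tooth_element[:1] == "d":
        return "deciduous"
    return "permanent"


def read_samples(
    path: str | Path,
    *,
    sep: str = ",",
    column_map: Optional[Mapping[str, str]] = None,
) -> list[ToothSample]:
    """Read a delimited sample table into :class:`ToothSample` records.

    ``column_map`` maps canonical names to the file's header names when they
    differ. Values are kept at full precision; rounding happens only at
    reporting time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = ["sample_id", "site_code", "period", "tooth_element", "d18O_ca_vpdb"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample table is missing required column(s): {', '.join(missing)}")

    samples: list[ToothSample] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid in seen:
            raise ValueError(f"duplicate sample_id {sid!r} at row {idx}")
        seen.add(sid)
        try:
            d18O = float(row["d18O_ca_vpdb"])
        except ValueError as exc:
            raise ValueError(f"row {idx} ({sid}): unparseable d18O_ca_vpdb "
                             f"{row['d18O_ca_vpdb']!r}") from exc
        d13C_text = str(row.get("d13C_ca_vpdb", "")).strip()
        if d13C_text in ("", "NA", "nan", "-"):
            d13C = None
        else:
            try:
                d13C = float(d13C_text)
            except ValueError as exc:
                raise ValueError(f"row {idx} ({sid}): unparseable d13C_ca_vpdb "
                                 f"{d13C_text!r}") from exc
        generation = infer_tooth_generation(
            row["tooth_element"].strip(),
            explicit=str(row.get("tooth_generation", "")).strip() or None,
        )
        samples.append(
            ToothSample(
                sample_id=sid,
                site_code=row["site_code"].strip(),
                period=row["period"].strip(),
                tooth_element=row["tooth_element"].strip(),
                tooth_generation=generation,
                d18O_ca_vpdb=d18O,
                d13C_ca_vpdb=d13C,
                age_class=str(row.get("age_class", "")).strip() or None,
                notes=str(row.get("notes", "")).strip() or None,
            )
        )
    return samples


def write_samples(samples: Sequence[ToothSample], path: str | Path, *, sep: str = ",") -> None:
    """Write samples back to the canonical CSV schema (repr precision)."""
    records = []
    for s in samples:
        records.append(
            {
                "sample_id": s.sample_id,
                "site_code": s.site_code,
                "period": s.period,
                "tooth_element": s.tooth_element,
                "tooth_generation": s.tooth_generation,
                "d18O_ca_vpdb": repr(s.d18O_ca_vpdb),
                "d13C_ca_vpdb": "" if s.d13C_ca_vpdb is None else repr(s.d13C_ca_vpdb),
            }
        )
    pd.DataFrame.from_records(records, columns=SAMPLE_COLUMNS).to_csv(path, sep=sep, index=False)


def _site_from_mapping(entry: Mapping) -> SiteGroup:
    rng = entry.get("reference_water_range")
    if rng is not None:
        if len(rng) != 2:
            raise ValueError(f"site {entry.get('code')}: reference_water_range must be a pair")
        rng = (float(rng[0]), float(rng[1]))
    return SiteGroup(
        code=str(entry["code"]),
        name=str(entry.get("name", entry["code"])),
        period=str(entry.get("period", "copper_age")),
        reference_water_range=rng,
        pooling_group=entry.get("pooling_group"),
        synthetic=entry.get("synthetic"),
    )


def read_site_config(path: str | Path) -> dict[str, SiteGroup]:
    """Load a YAML/JSON site registry keyed by site code."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    entries = raw["sites"] if isinstance(raw, Mapping) and "sites" in raw else raw
    registry: dict[str, SiteGroup] = {}
    for entry in entries:
        site = _site_from_mapping(entry)
        if site.code in registry:
            raise ValueError(f"duplicate site code {site.code!r} in {path}")
        registry[site.code] = site
    return registry


def default_site_registry() -> dict[str, SiteGroup]:
    """The bundled ten-site registry (codes MC, PA, GN, CE, FR, SS, CM, TC, OC, PB)."""
    return read_site_config(Path(__file__).parent / "data" / "sites.yaml")


def attach_samples(
    samples: Iterable[ToothSample], registry: Mapping[str, SiteGroup]
) -> dict[str, SiteGroup]:
    """Return a copy of the registry with each site's sample list populated."""
    out = {code: replace(site, samples=[]) for code, site in registry.items()}
    for s in samples:
        if s.site_code in out:
            out[s.site_code].samples.append(s)
    return out


def validate_dataset(
    samples: Sequence[ToothSample], registry: Mapping[str, SiteGroup]
) -> ValidationReport:
    """Check a dataset against the type invariants; purely reporting."""
    report = ValidationReport()
    lo, hi = ISOTOPE_BOUNDS
    seen: set[str] = set()
    for s in samples:
        if s.sample_id in seen:
            report.findings.append(
                ValidationFinding("duplicate_id", s.sample_id, f"duplicate sample_id {s.sample_id!r}")
            )
        seen.add(s.sample_id)
        if s.site_code not in registry:
            report.findings.append(
                ValidationFinding("unknown_site", s.sample_id,
                                  f"site code {s.site_code!r} not in registry")
            )
        if s.d18O_ca_vpdb is None or math.isnan(s.d18O_ca_vpdb):
            report.findings.append(
                ValidationFinding("missing_d18O", s.sample_id, "missing δ¹⁸O value")
            )
        elif not (lo <= s.d18O_ca_vpdb <= hi):
            report.findings.append(
                ValidationFinding("out_of_range", s.sample_id,
                                  f"δ¹⁸O {s.d18O_ca_vpdb} outside [{lo}, {hi}] ‰ V-PDB")
            )
        if s.d13C_ca_vpdb is None:
            report.findings.append(
                ValidationFinding("missing_d13C", s.sample_id, "missing δ¹³C value",
                                  severity="warning")
            )
        elif not (lo <= s.d13C_ca_vpdb <= hi):
            report.findings.append(
                ValidationFinding("out_of_range", s.sample_id,
                                  f"δ¹³C {s.d13C_ca_vpdb} outside [{lo}, {hi}] ‰ V-PDB")
            )
    return report
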