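"""Event-record datasets and study-specific data-handling rules.

The unit of fitting and simulation is a :class:`StudyDataset`: subjects
with oral dose events, observations on up to four analyte streams
(enalaprilat concentration, ANG I, ANG II, and the dimensionless
ANG II/ANG I ratio), covariates, and the assay quantification limits
that drive censoring.

Datasets round-trip through a NONMEM/Monolix-style event CSV dialect
(columns ID, TIME, EVID, AMT, DVID, DV, CENS, LIMIT, SUBST, EXCL plus
covariates; missing numeric fields written as ".").  A value flagged
CENS=1 is interval-censored: DV holds the LLOQ and LIMIT the lower bound
of the interval (zero throughout this package).

Two rule sets mirror how the two studies prepared their analysis sets:

* adults (single-dose rich sampling): predose PK samples are dropped
  (drug-naive subjects have no expected concentration), ratio
  observations later than 24 h post dose are dropped (the ratio rises
  back above baseline and the maximal clinical dosing interval is 24 h),
  and PK values below the 0.70 µg/L LLOQ become interval-censored;
* paediatrics (sparse repeated dosing): tagged records (ANG I above
  calibration, therapy stopped, unclear stop time, both angiotensins
  below LLOQ, other) and records more than 24 h after the last dose are
  excluded, and the survivors are classified as predose-first-dose,
  post-first-dose, or post-repeated-dose.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "PAED_EXCLUSION_TAGS",
    "AssayLimits",
    "AssayConfig",
    "ADULT_ASSAY",
    "PAEDIATRIC_ASSAY",
    "DoseEvent",
    "Observation",
    "SubjectRecord",
    "StudyDataset",
    "RatioResult",
    "read_dataset",
    "write_dataset",
    "compute_ratio",
    "apply_adult_inclusion_rules",
    "apply_paediatric_exclusion_rules",
    "time_since_last_dose",
]

ANALYTES = ("ENALAPRILAT", "RATIO", "ANGI", "ANGII")
_DVID_TO_ANALYTE = {1: "ENALAPRILAT", 2: "RATIO", 3: "ANGI", 4: "ANGII"}
_ANALYTE_TO_DVID = {v: k for k, v in _DVID_TO_ANALYTE.items()}

#: §3.2 exclusion categories for the paediatric analysis set.
PAED_EXCLUSION_TAGS = ("ANGI_ULOQ", "THERAPY_STOPPED", "STOP_UNCLEAR",
                       "BOTH_BLQ", "GT24H", "OTHER")

_COVARIATE_COLUMNS = ("AGE", "WT", "BMI", "SEX", "ROSS", "AETIOL")
_COLUMN_KEY = {"AGE": "age", "WT": "weight", "BMI": "bmi", "SEX": "sex",
               "ROSS": "ross", "AETIOL": "aetiology"}


class DatasetError(ValueError):
    """Raised for schema or validation failures on event datasets."""


@dataclass(frozen=True)
class AssayLimits:
    """Quantification limits of one analyte: [lloq, uloq] in ``units``."""

    lloq: float
    uloq: float | None
    units: str

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise DatasetError("LLOQ must be positive")
        if self.uloq is not None and not self.lloq < self.uloq:
            raise DatasetError("LLOQ must lie below the upper limit")


@dataclass(frozen=True)
class AssayConfig:
    """Per-analyte assay limits for one study population."""

    population: str
    limits: Mapping[str, AssayLimits]

    def __post_init__(self) -> None:
        object.__setattr__(self, "limits", dict(self.limits))
        for analyte in self.limits:
            if analyte not in ANALYTES:
                raise DatasetError(f"unknown analyte {analyte!r}")

    def lloq(self, analyte: str, units: str = "pg/mL") -> float:
        lim = self.limits[analyte]
        return _convert_units(lim.lloq, lim.units, units) \
            if analyte in ("ANGI", "ANGII") else lim.lloq


def _convert_units(value, from_units: str, to_units: str):
    """Angiotensin unit harmonisation (1 µg/L = 1000 pg/mL)."""
    norm = {"ug/l": "ug/L", "µg/l": "ug/L", "pg/ml": "pg/mL"}
    f = norm.get(from_units.lower())
    t = norm.get(to_units.lower())
    if f is None or t is None:
        raise DatasetError(f"unknown units {from_units!r} / {to_units!r}")
    if f == t:
        return value
    return value * 1000.0 if (f, t) == ("ug/L", "pg/mL") else value / 1000.0


#: Adult study assay: enalaprilat LLOQ 0.70 µg/L; ANG I calibrated
#: 0.2-30 µg/L, ANG II 1-125 pg/mL.
ADULT_ASSAY = AssayConfig("adult", {
    "ENALAPRILAT": AssayLimits(0.70, None, "ug/L"),
    "ANGI": AssayLimits(0.2, 30.0, "ug/L"),
    "ANGII": AssayLimits(1.0, 125.0, "pg/mL"),
})

#: Paediatric study assay: enalaprilat calibrated 0.18-180 µg/L;
#: ANG I 25.4-1594.2 pg/mL, ANG II 22.3-1395.8 pg/mL.
PAEDIATRIC_ASSAY = AssayConfig("paediatric", {
    "ENALAPRILAT": AssayLimits(0.18, 180.0, "ug/L"),
    "ANGI": AssayLimits(25.4, 1594.2, "pg/mL"),
    "ANGII": AssayLimits(22.3, 1395.8, "pg/mL"),
})


@dataclass(frozen=True)
class DoseEvent:
    """Oral dose of enalapril maleate (µg) at ``time`` h since first dose."""

    subject_id: str
    time: float
    amount: float
    route: str = "oral"

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise DatasetError("dose amount must be positive")
        if self.time < 0:
            raise DatasetError("dose time must be non-negative")
        if self.route != "oral":
            raise DatasetError("only oral dosing is supported")


@dataclass(frozen=True)
class Observation:
    """One measured value of one analyte stream.

    ``censored`` observations carry the applicable LLOQ in ``value`` and
    are interval-censored on [``lower``, ``value``].  ``substituted``
    marks an ANG II value replaced by LLOQ/2 before ratio computation;
    ``excluded`` carries an exclusion-category tag.
    """

    subject_id: str
    time: float
    analyte: str
    value: float
    censored: bool = False
    lower: float = 0.0
    excluded: str | None = None
    substituted: bool = False

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise DatasetError(f"unknown analyte {self.analyte!r}")
        if self.time < 0:
            raise DatasetError("observation time must be non-negative")
        if not self.censored and self.value < 0:
            raise DatasetError("observed value must be non-negative")
        if self.censored and not self.value > self.lower:
            raise DatasetError("censoring LLOQ must exceed the lower bound")

    @property
    def lloq(self) -> float | None:
        return self.value if self.censored else None


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: covariates, dosing diary, observations."""

    id: str
    covariates: Mapping[str, float | str]
    doses: tuple[DoseEvent, ...] = ()
    observations: tuple[Observation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", dict(self.covariates))
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))
        times = [d.time for d in self.doses]
        if any(b < a for a, b in zip(times, times[1:])):
            raise DatasetError(f"doses of subject {self.id} not sorted")
        for ev in self.doses:
            if ev.subject_id != self.id:
                raise DatasetError("dose subject_id mismatch")
        for ob in self.observations:
            if ob.subject_id != self.id:
                raise DatasetError("observation subject_id mismatch")


@dataclass(frozen=True)
class StudyDataset:
    """A complete study: population label, subjects, assay limits."""

    population: str
    subjects: tuple[SubjectRecord, ...]
    assay: AssayConfig

    def __post_init__(self) -> None:
        if self.population not in ("adult", "paediatric"):
            raise DatasetError("population must be 'adult' or 'paediatric'")
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DatasetError("subject ids must be unique")

    def observations(self, analyte: str | None = None) -> list[Observation]:
        return [ob for s in self.subjects for ob in s.observations
                if analyte is None or ob.analyte == analyte]

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise KeyError(subject_id)


def dataset_fingerprint(ds: StudyDataset) -> str:
    """Stable digest of a dataset's identity (subjects + observations)."""
    h = hashlib.sha256()
    for s in ds.subjects:
        h.update(s.id.encode())
        for d in s.doses:
            h.update(f"{d.time:.10g},{d.amount:.10g};".encode())
        for ob in s.observations:
            h.update(f"{ob.time:.10g},{ob.analyte},{ob.value:.12g},"
                     f"{int(ob.censored)};".encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# CSV dialect


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "."
    if isinstance(x, (float, np.floating)):
        x = float(x)  # builtin repr round-trips the double exactly
        return repr(x) if x != int(x) else str(int(x))
    if isinstance(x, np.integer):
        return str(int(x))
    return str(x)


def write_dataset(ds: StudyDataset, path) -> None:
    """Write the event CSV dialect (missing fields as '.')."""
    cols = ["ID", "TIME", "EVID", "AMT", "DVID", "DV", "CENS", "LIMIT",
            "SUBST", "EXCL", *_COVARIATE_COLUMNS]
    rows = []
    for s in ds.subjects:
        cov = {c: s.covariates.get(_COLUMN_KEY[c])
               for c in _COVARIATE_COLUMNS}
        events = [(d.time, 0, d) for d in s.doses] \
            + [(o.time, 1, o) for o in s.observations]
        for t, _, ev in sorted(events, key=lambda e: (e[0], e[1])):
            row = dict.fromkeys(cols)
            row.update({"ID": s.id, "TIME": t})
            row.update({c: cov[c] for c in _COVARIATE_COLUMNS})
            if isinstance(ev, DoseEvent):
                row.update(EVID=1, AMT=ev.amount)
            else:
                row.update(EVID=0, DVID=_ANALYTE_TO_DVID[ev.analyte],
                           DV=ev.value, CENS=int(ev.censored),
                           LIMIT=ev.lower if ev.censored else None,
                           SUBST=int(ev.substituted), EXCL=ev.excluded)
            rows.append(row)
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        fh.write(f"# population={ds.population}\n")
        for row in rows:
            fh.write(",".join(_fmt(row[c]) for c in cols) + "\n")


def read_dataset(path, population: str | None = None,
                 assay: AssayConfig | None = None) -> StudyDataset:
    """Read the event CSV dialect into a validated :class:`StudyDataset`.

    Dose rows (EVID=1) become :class:`DoseEvent`; observation rows
    (EVID=0) become :class:`Observation`; CENS=1 rows become
    interval-censored observations on [LIMIT, DV].
    """
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        second = fh.readline()
        meta = {}
        body = [second] if not second.startswith("#") else []
        if second.startswith("#"):
            for kv in second[1:].strip().split():
                k, _, v = kv.partition("=")
                meta[k] = v
        body += fh.readlines()
    population = population or meta.get("population")
    if population is None:
        raise DatasetError("population not given and absent from the file")
    if assay is None:
        assay = ADULT_ASSAY if population == "adult" else PAEDIATRIC_ASSAY
    df = pd.read_csv(
        pd.io.common.StringIO(",".join(header) + "\n" + "".join(body)),
        na_values=".", dtype={"ID": str, "EXCL": str},
        float_precision="round_trip")
    for col in ("ID", "TIME", "EVID"):
        if col not in df.columns:
            raise DatasetError(f"required column {col!r} missing")
    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        doses, obs = [], []
        cov = {}
        for c in _COVARIATE_COLUMNS:
            if c in grp.columns:
                vals = grp[c].dropna()
                if len(vals):
                    v = vals.iloc[0]
                    cov[_COLUMN_KEY[c]] = v if isinstance(v, str) \
                        else float(v)
        for _, row in grp.iterrows():
            t = float(row["TIME"])
            if t < 0:
                raise DatasetError(f"negative time for subject {sid}")
            if int(row["EVID"]) == 1:
                doses.append(DoseEvent(str(sid), t, float(row["AMT"])))
                continue
            dvid = row.get("DVID")
            if pd.isna(dvid) or int(dvid) not in _DVID_TO_ANALYTE:
                raise DatasetError(
                    f"unknown DVID {dvid!r} for subject {sid}")
            cens = bool(int(row["CENS"])) if "CENS" in row and \
                not pd.isna(row["CENS"]) else False
            if cens and ("LIMIT" not in grp.columns
                         or pd.isna(row["LIMIT"])):
                raise DatasetError(
                    "censored row requires the LIMIT column (lower bound "
                    "of the censoring interval)")
            obs.append(Observation(
                str(sid), t, _DVID_TO_ANALYTE[int(dvid)],
                float(row["DV"]), censored=cens,
                lower=float(row["LIMIT"]) if cens else 0.0,
                excluded=None if pd.isna(row.get("EXCL")) else row["EXCL"],
                substituted=bool(int(row["SUBST"])) if "SUBST" in row and
                not pd.isna(row["SUBST"]) else False))
        subjects.append(SubjectRecord(str(sid), cov, tuple(doses),
                                      tuple(obs)))
    return StudyDataset(population, tuple(subjects), assay)


# ---------------------------------------------------------------------------
# ratio computation and inclusion/exclusion rules


@dataclass(frozen=True)
class RatioResult:
    """Outcome of an ANG II/ANG I ratio computation."""

    value: float | None
    substituted: bool = False
    excluded: bool = False


def compute_ratio(ang2: float, ang1: float, assay: AssayConfig, *,
                  ang1_units: str = "pg/mL", ang2_units: str = "pg/mL",
                  ang2_blq: bool | None = None,
                  ang1_blq: bool | None = None) -> RatioResult:
    """ANG II/ANG I ratio with the below-LLOQ substitution rules.

    Both analytes are harmonised to pg/mL.  An ANG II value below its
    LLOQ is replaced by LLOQ/2 (flagged ``substituted``); if both
    analytes are below their LLOQs the record is excluded and no ratio
    is emitted.  BLQ status defaults to a strict ``value < LLOQ``
    comparison against the assay config.
    """
    ang2_pg = _convert_units(float(ang2), ang2_units, "pg/mL")
    ang1_pg = _convert_units(float(ang1), ang1_units, "pg/mL")
    lloq2 = assay.lloq("ANGII", "pg/mL")
    lloq1 = assay.lloq("ANGI", "pg/mL")
    blq2 = ang2_pg < lloq2 if ang2_blq is None else bool(ang2_blq)
    blq1 = ang1_pg < lloq1 if ang1_blq is None else bool(ang1_blq)
    if blq1 and blq2:
        return RatioResult(None, excluded=True)
    if ang1_pg == 0:
        raise DatasetError("ANG I is zero but not flagged below LLOQ: "
                           "ratio undefined")
    if blq2:
        return RatioResult(lloq2 / 2.0 / ang1_pg, substituted=True)
    return RatioResult(ang2_pg / ang1_pg)


def time_since_last_dose(subject: SubjectRecord, t: float) -> float:
    """Hours between ``t`` and the latest dose at or before ``t``."""
    prior = [d.time for d in subject.doses if d.time <= t]
    if not prior:
        raise DatasetError(
            f"subject {subject.id} has no dose at or before t={t}")
    return t - max(prior)


def _audit(**counts) -> dict:
    return {k: int(v) for k, v in counts.items()}


def apply_adult_inclusion_rules(ds: StudyDataset
                                ) -> tuple[StudyDataset, dict]:
    """Adult analysis-set rules; returns the filtered set + audit counts.

    Removes predose PK samples and ratio observations more than 24 h
    post dose, and interval-censors PK values below the LLOQ on
    [0, LLOQ].  Idempotent.
    """
    if ds.population != "adult":
        raise DatasetError("adult rules applied to a non-adult dataset")
    lloq = ds.assay.limits["ENALAPRILAT"].lloq
    n_predose = n_late = n_blq = 0
    n_pk = n_ratio = 0
    subjects = []
    for s in ds.subjects:
        kept = []
        for ob in s.observations:
            if ob.analyte == "ENALAPRILAT":
                if not s.doses or ob.time <= s.doses[0].time:
                    n_predose += 1
                    continue
                if not ob.censored and ob.value < lloq:
                    ob = replace(ob, value=lloq, censored=True, lower=0.0)
                    n_blq += 1
                elif ob.censored:
                    n_blq += 1
                n_pk += 1
            elif ob.analyte == "RATIO":
                tsld = time_since_last_dose(s, ob.time) if s.doses and \
                    ob.time >= s.doses[0].time else 0.0
                if tsld > 24.0:
                    n_late += 1
                    continue
                n_ratio += 1
            kept.append(ob)
        subjects.append(replace(s, observations=tuple(kept)))
    out = StudyDataset(ds.population, tuple(subjects), ds.assay)
    return out, _audit(included_pk=n_pk, included_ratio=n_ratio,
                       excluded_predose_pk=n_predose,
                       excluded_ratio_gt24h=n_late, censored_blq_pk=n_blq)


def _classify_record(subject: SubjectRecord, t: float) -> str:
    """Predose-first / post-first / post-repeated classification.

    A sample drawn exactly at a dose time counts as taken before that
    dose (trough convention), so the first-dose predose sample at t = 0
    is "predose_first".
    """
    prior = [d.time for d in subject.doses if d.time < t]
    if not prior:
        return "predose_first"
    return "post_first" if len(prior) == 1 else "post_repeated"


def apply_paediatric_exclusion_rules(ds: StudyDataset
                                     ) -> tuple[StudyDataset, dict]:
    """Paediatric analysis-set rules; returns filtered set + audit counts.

    A record is the set of simultaneous observations of one subject at
    one time.  Tagged records are removed by category, records more
    than 24 h after the last dose are removed, and survivors are
    classified as predose-first / post-first / post-repeated dose.
    """
    if ds.population != "paediatric":
        raise DatasetError(
            "paediatric rules applied to a non-paediatric dataset")
    counts = dict.fromkeys(PAED_EXCLUSION_TAGS, 0)
    classes = {"predose_first": 0, "post_first": 0, "post_repeated": 0}
    n_included = 0
    subjects = []
    for s in ds.subjects:
        by_time: dict[float, list[Observation]] = {}
        for ob in s.observations:
            by_time.setdefault(ob.time, []).append(ob)
        kept: list[Observation] = []
        for t in sorted(by_time):
            group = by_time[t]
            tags = {ob.excluded for ob in group if ob.excluded}
            unknown = tags - set(PAED_EXCLUSION_TAGS)
            if unknown:
                raise DatasetError(
                    f"unknown exclusion tag(s) {sorted(unknown)}")
            if tags:
                counts[sorted(tags)[0]] += 1
                continue
            tsld_gt24 = bool(s.doses) and s.doses[0].time <= t and \
                time_since_last_dose(s, t) > 24.0
            if tsld_gt24:
                counts["GT24H"] += 1
                continue
            classes[_classify_record(s, t)] += 1
            n_included += 1
            kept.extend(group)
        subjects.append(replace(s, observations=tuple(kept)))
    out = StudyDataset(ds.population, tuple(subjects), ds.assay)
    audit = _audit(included=n_included, **counts, **classes)
    return out, audit
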