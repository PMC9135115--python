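"""Synthetic FHIR benchmark data: planted cohorts plus background load.

The performance design plants cohorts of exactly known sizes — each
member carries one matching Patient attribute (administrative gender),
one Condition, one Procedure, and one Observation, with codes unique to
its cohort — so every benchmark query has an exactly predictable answer.
Two of the built-in profiles add *background* resources: data that no
benchmark query targets but that loads the server's indexes the way a
real hospital's data would.  Background totals are spread over a stated
number of unique codes as evenly as possible (the real hospital
code-frequency distribution behind the stated totals is not public), and
background codes never collide with cohort codes.

Built-in profiles::

    small     cohorts 1 000 / 10 000 / 100 000, no background
    bg-small  same cohorts + background (413 375 conditions over 8 593
              codes, 270 505 procedures over 6 429 codes, 4 907 600
              observations over 1 798 codes)
    bg-large  cohorts 1 000 / 10 000 / 100 000 / 1 000 000 + the same
              background

Everything is deterministic given a seed, streams resource-by-resource
(profiles reach millions of resources), and scales down by an exact
rational factor for fast test runs — a profile at scale 1/1000 yields
1/1000 of every count and every planted query answer.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
import random
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

from feasquery.query_model import Criterion, StructuredQuery, TermCode
from feasquery.store import ResourceStore
from feasquery.terminology import MappingEntry, MappingTable, TermTree, TermTreeNode

__all__ = [
    "BackgroundSpec",
    "DatasetProfile",
    "PlantedCohort",
    "ScaleError",
    "PROFILES",
    "get_profile",
    "plan_cohorts",
    "iter_dataset",
    "iter_background",
    "generate",
    "terminology_for",
    "benchmark_queries",
    "write_dataset",
]

ICD10_SYSTEM = "http://fhir.de/CodeSystem/bfarm/icd-10-gm"
OPS_SYSTEM = "http://fhir.de/CodeSystem/bfarm/ops"
LOINC_SYSTEM = "http://loinc.org"
GENDER_SYSTEM = "http://hl7.org/fhir/administrative-gender"
UCUM_SYSTEM = "http://unitsofmeasure.org"

# 5-year window from which all clinical dates are drawn
_WINDOW_START = datetime.date(2018, 1, 1)
_WINDOW_DAYS = 1826  # through 2022-12-31
_DATES = [
    (_WINDOW_START + datetime.timedelta(days=d)).isoformat() for d in range(_WINDOW_DAYS)
]


class ScaleError(ValueError):
    """A scale factor makes some configured count non-integral."""


@dataclass(frozen=True)
class BackgroundSpec:
    """Background resource totals and their unique-code counts."""

    conditions: int
    condition_codes: int
    procedures: int
    procedure_codes: int
    observations: int
    observation_codes: int


@dataclass(frozen=True)
class DatasetProfile:
    name: str
    cohort_sizes: tuple[int, ...]
    background: Optional[BackgroundSpec] = None
    scale: Fraction = Fraction(1)

    def scaled(self, scale: Union[Fraction, float, str, int]) -> "DatasetProfile":
        if not isinstance(scale, Fraction):
            scale = Fraction(str(scale))
        if scale <= 0:
            raise ScaleError(f"scale must be positive, got {scale}")
        return dataclasses.replace(self, scale=scale)


_BACKGROUND = BackgroundSpec(
    conditions=413_375,
    condition_codes=8_593,
    procedures=270_505,
    procedure_codes=6_429,
    observations=4_907_600,
    observation_codes=1_798,
)

PROFILES: dict[str, DatasetProfile] = {
    "small": DatasetProfile("small", (1_000, 10_000, 100_000)),
    "bg-small": DatasetProfile("bg-small", (1_000, 10_000, 100_000), _BACKGROUND),
    "bg-large": DatasetProfile("bg-large", (1_000, 10_000, 100_000, 1_000_000), _BACKGROUND),
}


def get_profile(name: str, scale: Union[Fraction, float, str, int] = Fraction(1)) -> DatasetProfile:
    if name not in PROFILES:
        raise KeyError(f"unknown profile {name!r}; built-in: {', '.join(PROFILES)}")
    return PROFILES[name].scaled(scale)


@dataclass(frozen=True)
class PlantedCohort:
    """One cohort of exactly known size; every member satisfies all 4 criteria."""

    label: str  # unscaled size, used in benchmark-query labels
    size: int  # scaled member count
    gender: str
    condition_code: TermCode
    procedure_code: TermCode
    observation_code: TermCode
    observation_value: Decimal


def _scaled_int(count: int, scale: Fraction, what: str) -> int:
    value = count * scale
    if value.denominator != 1:
        raise ScaleError(f"{what} {count} × scale {scale} is not an integer")
    return int(value)


_GENDER_POOL = ("male", "other", "unknown")  # female is reserved for the 100k cohort


def plan_cohorts(profile: DatasetProfile) -> list[PlantedCohort]:
    """Assign each cohort its distinguishing gender, codes, and value.

    The 100 000 cohort carries the canonical worked-example criteria
    (female / ICD-10 C50.1 / OPS 5-787.ex / LOINC 55782-7); other cohorts
    get clearly synthetic per-cohort codes.  At most four cohorts are
    supported, one per administrative-gender value.
    """
    if not profile.cohort_sizes:
        raise ValueError(f"profile {profile.name!r} has no cohorts")
    if len(profile.cohort_sizes) > 4:
        raise ValueError(
            "at most 4 planted cohorts are supported (one per administrative-gender value)"
        )
    cohorts = []
    pool = iter(_GENDER_POOL if 100_000 in profile.cohort_sizes else ("female",) + _GENDER_POOL)
    for i, size in enumerate(profile.cohort_sizes):
        if size == 100_000:
            gender = "female"
            cond = TermCode(system=ICD10_SYSTEM, code="C50.1", display="Malignant neoplasm of breast, central portion")
            proc = TermCode(system=OPS_SYSTEM, code="5-787.ex", display="Removal of osteosynthesis material")
            obs = TermCode(system=LOINC_SYSTEM, code="55782-7", display="Beta-2-Microglobulin")
        else:
            gender = next(pool)
            cond = TermCode(system=ICD10_SYSTEM, code=f"COH{i}-COND", display=f"Planted condition, cohort {size}")
            proc = TermCode(system=OPS_SYSTEM, code=f"COH{i}-PROC", display=f"Planted procedure, cohort {size}")
            obs = TermCode(system=LOINC_SYSTEM, code=f"COH{i}-OBS", display=f"Planted observation, cohort {size}")
        cohorts.append(
            PlantedCohort(
                label=str(size),
                size=_scaled_int(size, profile.scale, f"cohort size {size}"),
                gender=gender,
                condition_code=cond,
                procedure_code=proc,
                observation_code=obs,
                observation_value=Decimal(i * 10 + 7) / Decimal(2),
            )
        )
    return cohorts


def _nomatch_gender(cohorts: Sequence[PlantedCohort]) -> str:
    used = {c.gender for c in cohorts}
    for g in ("unknown", "other", "male", "female"):
        if g not in used:
            return g
    return "nomatch"  # all four real values are planted; any token absent from data works


# -- resource streaming -----------------------------------------------------


def _rng(seed: int, label: str) -> random.Random:
    return random.Random(f"{seed}:{label}")


def iter_patients(profile: DatasetProfile, seed: int) -> Iterator[dict]:
    rng = _rng(seed, "patients")
    lo = datetime.date(1930, 1, 1).toordinal()
    hi = datetime.date(2005, 12, 31).toordinal()
    n = 0
    for cohort in plan_cohorts(profile):
        for _ in range(cohort.size):
            yield {
                "resourceType": "Patient",
                "id": f"p{n}",
                "gender": cohort.gender,
                "birthDate": datetime.date.fromordinal(rng.randrange(lo, hi + 1)).isoformat(),
            }
            n += 1


def iter_cohort_resources(profile: DatasetProfile, seed: int, resource_type: str) -> Iterator[dict]:
    """The planted clinical resources of one type: exactly one per cohort member."""
    rng = _rng(seed, f"cohort-{resource_type}")
    n = 0
    for cohort in plan_cohorts(profile):
        for _ in range(cohort.size):
            date = _DATES[rng.randrange(_WINDOW_DAYS)]
            subject = {"reference": f"Patient/p{n}"}
            if resource_type == "Condition":
                yield {
                    "resourceType": "Condition",
                    "id": f"c{n}",
                    "code": {"coding": [{"system": cohort.condition_code.system, "code": cohort.condition_code.code}]},
                    "subject": subject,
                    "recordedDate": date,
                }
            elif resource_type == "Procedure":
                yield {
                    "resourceType": "Procedure",
                    "id": f"pr{n}",
                    "code": {"coding": [{"system": cohort.procedure_code.system, "code": cohort.procedure_code.code}]},
                    "subject": subject,
                    "performedDateTime": date,
                }
            elif resource_type == "Observation":
                yield {
                    "resourceType": "Observation",
                    "id": f"o{n}",
                    "code": {"coding": [{"system": cohort.observation_code.system, "code": cohort.observation_code.code}]},
                    "subject": subject,
                    "valueQuantity": {
                        "value": float(cohort.observation_value),
                        "unit": "mg/dL",
                        "system": UCUM_SYSTEM,
                    },
                    "effectiveDateTime": date,
                }
            else:
                raise ValueError(f"unknown cohort resource type {resource_type!r}")
            n += 1


def _scaled_background(spec: BackgroundSpec, scale: Fraction) -> BackgroundSpec:
    def codes(n_codes: int, total: int) -> int:
        if total == 0:
            return 0
        # code diversity is shape, not size: shrink proportionally but keep >= 1
        return min(total, max(1, math.ceil(n_codes * scale)))

    conditions = _scaled_int(spec.conditions, scale, "background condition count")
    procedures = _scaled_int(spec.procedures, scale, "background procedure count")
    observations = _scaled_int(spec.observations, scale, "background observation count")
    return BackgroundSpec(
        conditions=conditions,
        condition_codes=codes(spec.condition_codes, conditions),
        procedures=procedures,
        procedure_codes=codes(spec.procedure_codes, procedures),
        observations=observations,
        observation_codes=codes(spec.observation_codes, observations),
    )


def iter_background(
    spec: BackgroundSpec,
    n_patients: int,
    seed: int,
    resource_type: Optional[str] = None,
) -> Iterator[dict]:
    """Stream background resources (optionally one type only).

    The total per type is split over its unique codes as evenly as
    possible (the first ``total mod codes`` codes receive one extra), and
    resources are attached round-robin to the existing patients — no new
    patients are created for background data.
    """
    if n_patients <= 0:
        raise ValueError("background data needs at least one existing patient")
    plans = {
        "Condition": (spec.conditions, spec.condition_codes, "BG-C", ICD10_SYSTEM),
        "Procedure": (spec.procedures, spec.procedure_codes, "BG-P", OPS_SYSTEM),
        "Observation": (spec.observations, spec.observation_codes, "BG-O", LOINC_SYSTEM),
    }
    types = [resource_type] if resource_type is not None else list(plans)
    for rtype in types:
        total, n_codes, prefix, system = plans[rtype]
        if total == 0:
            continue
        rng = _rng(seed, f"background-{rtype}")
        base, extra = divmod(total, n_codes)
        j = 0
        for k in range(n_codes):
            code = f"{prefix}{k}"
            coding = {"coding": [{"system": system, "code": code}]}
            for _ in range(base + (1 if k < extra else 0)):
                pid = f"p{j % n_patients}"
                date = _DATES[rng.randrange(_WINDOW_DAYS)]
                if rtype == "Condition":
                    yield {
                        "resourceType": "Condition",
                        "id": f"bgc{j}",
                        "code": coding,
                        "subject": {"reference": f"Patient/{pid}"},
                        "recordedDate": date,
                    }
                elif rtype == "Procedure":
                    yield {
                        "resourceType": "Procedure",
                        "id": f"bgp{j}",
                        "code": coding,
                        "subject": {"reference": f"Patient/{pid}"},
                        "performedDateTime": date,
                    }
                else:
                    yield {
                        "resourceType": "Observation",
                        "id": f"bgo{j}",
                        "code": coding,
                        "subject": {"reference": f"Patient/{pid}"},
                        "valueQuantity": {
                            "value": round(rng.uniform(0.1, 500.0), 1),
                            "unit": "mg/dL",
                            "system": UCUM_SYSTEM,
                        },
                        "effectiveDateTime": date,
                    }
                j += 1


def iter_dataset(profile: DatasetProfile, seed: int) -> Iterator[dict]:
    """Stream the complete data set: patients, planted resources, background."""
    yield from iter_patients(profile, seed)
    for rtype in ("Condition", "Procedure", "Observation"):
        yield from iter_cohort_resources(profile, seed, rtype)
    if profile.background is not None:
        n_patients = sum(c.size for c in plan_cohorts(profile))
        yield from iter_background(_scaled_background(profile.background, profile.scale), n_patients, seed)


def generate(profile: DatasetProfile, seed: int) -> ResourceStore:
    """Materialize the profile as an indexed in-memory store."""
    return ResourceStore.from_resources(iter_dataset(profile, seed))


def expected_counts(profile: DatasetProfile) -> dict[str, int]:
    """Closed-form per-type counts implied by the profile (for manifests and checks)."""
    patients = sum(c.size for c in plan_cohorts(profile))
    counts = {"Patient": patients, "Condition": patients, "Procedure": patients, "Observation": patients}
    if profile.background is not None:
        bg = _scaled_background(profile.background, profile.scale)
        counts["Condition"] += bg.conditions
        counts["Procedure"] += bg.procedures
        counts["Observation"] += bg.observations
    counts["total"] = sum(v for k, v in counts.items() if k != "total")
    return counts


# -- terminology and benchmark queries --------------------------------------


def terminology_for(profile: DatasetProfile) -> tuple[TermTree, MappingTable]:
    """Terminology tree and mapping covering every code the benchmark queries use.

    All planted codes are tree leaves (the benchmark plants exact codes, not
    hierarchies), and the no-match codes are mapped but deliberately absent
    from the data.
    """
    cohorts = plan_cohorts(profile)
    roots: list[TermTreeNode] = []
    entries: list[MappingEntry] = []

    def add(code: TermCode, rtype: str, **kwargs) -> None:
        roots.append(TermTreeNode(term_code=code))
        entries.append(MappingEntry(key=code, fhir_resource_type=rtype, **kwargs))

    genders = {c.gender for c in cohorts} | {_nomatch_gender(cohorts)}
    for gender in sorted(genders):
        add(
            TermCode(system=GENDER_SYSTEM, code=gender, display=gender.capitalize()),
            "Patient",
            term_code_search_parameter="gender",
            token_form="code",
        )
    for c in cohorts:
        add(c.condition_code, "Condition", term_code_search_parameter="code",
            time_restriction_parameter="recorded-date")
        add(c.procedure_code, "Procedure", term_code_search_parameter="code",
            time_restriction_parameter="date")
        add(c.observation_code, "Observation", term_code_search_parameter="code",
            value_search_parameter="value-quantity", time_restriction_parameter="date")
    add(TermCode(system=ICD10_SYSTEM, code="NOMATCH-COND", display="No-match condition"),
        "Condition", term_code_search_parameter="code", time_restriction_parameter="recorded-date")
    add(TermCode(system=OPS_SYSTEM, code="NOMATCH-PROC", display="No-match procedure"),
        "Procedure", term_code_search_parameter="code", time_restriction_parameter="date")
    add(TermCode(system=LOINC_SYSTEM, code="NOMATCH-OBS", display="No-match observation"),
        "Observation", term_code_search_parameter="code",
        value_search_parameter="value-quantity", time_restriction_parameter="date")
    return TermTree(roots), MappingTable(entries)


def _single(code: TermCode) -> Criterion:
    return Criterion(term_codes=[code])


def benchmark_queries(profile: DatasetProfile) -> list[tuple[str, StructuredQuery]]:
    """The benchmark suite: per cohort a single-condition query ``<N>-1`` and a
    4-criterion AND query ``<N>-all`` (patient ∧ condition ∧ procedure ∧
    observation, each its own inclusion group), plus the no-match query ``0``.

    The AND queries are a deliberate worst case: each criterion matches
    exactly the cohort, so no sub-query can be skipped and the executor
    processes exactly 4 × N resources for a cohort of size N.
    """
    cohorts = plan_cohorts(profile)
    queries: list[tuple[str, StructuredQuery]] = [
        (
            "0",
            StructuredQuery(
                inclusion_criteria=[
                    [_single(TermCode(system=GENDER_SYSTEM, code=_nomatch_gender(cohorts)))],
                    [_single(TermCode(system=ICD10_SYSTEM, code="NOMATCH-COND"))],
                    [_single(TermCode(system=OPS_SYSTEM, code="NOMATCH-PROC"))],
                    [_single(TermCode(system=LOINC_SYSTEM, code="NOMATCH-OBS"))],
                ]
            ),
        )
    ]
    for c in cohorts:
        queries.append((f"{c.label}-1", StructuredQuery(inclusion_criteria=[[_single(c.condition_code)]])))
        queries.append(
            (
                f"{c.label}-all",
                StructuredQuery(
                    inclusion_criteria=[
                        [_single(TermCode(system=GENDER_SYSTEM, code=c.gender))],
                        [_single(c.condition_code)],
                        [_single(c.procedure_code)],
                        [_single(c.observation_code)],
                    ]
                ),
            )
        )
    return queries


# -- file output -------------------------------------------------------------


def write_dataset(profile: DatasetProfile, seed: int, out_dir: Union[str, Path]) -> dict:
    """Write the data set as one NDJSON file per resource type, plus the
    terminology tree, mapping, benchmark queries, and a manifest with the
    realized counts and cohort code assignments.  Returns the manifest.
    """
    from feasquery.query_model import serialize_structured_query

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {"Patient": 0, "Condition": 0, "Procedure": 0, "Observation": 0}

    def dump(path: Path, resources: Iterator[dict]) -> None:
        with path.open("w", encoding="utf-8") as fh:
            for r in resources:
                counts[r["resourceType"]] += 1
                fh.write(json.dumps(r, ensure_ascii=False, sort_keys=True))
                fh.write("\n")

    dump(out / "Patient.ndjson", iter_patients(profile, seed))
    n_patients = counts["Patient"]
    bg = _scaled_background(profile.background, profile.scale) if profile.background else None
    for rtype in ("Condition", "Procedure", "Observation"):
        path = out / f"{rtype}.ndjson"
        with path.open("w", encoding="utf-8") as fh:
            for r in iter_cohort_resources(profile, seed, rtype):
                counts[rtype] += 1
                fh.write(json.dumps(r, ensure_ascii=False, sort_keys=True) + "\n")
            if bg is not None:
                for r in iter_background(bg, n_patients, seed, resource_type=rtype):
                    counts[rtype] += 1
                    fh.write(json.dumps(r, ensure_ascii=False, sort_keys=True) + "\n")

    tree, mapping = terminology_for(profile)
    tree.save(out / "term-tree.json")
    mapping.save(out / "mapping.json")
    queries_dir = out / "queries"
    queries_dir.mkdir(exist_ok=True)
    labels = []
    for label, q in benchmark_queries(profile):
        (queries_dir / f"{label}.json").write_text(serialize_structured_query(q), encoding="utf-8")
        labels.append(label)

    manifest = {
        "profile": profile.name,
        "scale": str(profile.scale),
        "seed": seed,
        "counts": {**counts, "total": sum(counts.values())},
        "cohorts": [
            {
                "label": c.label,
                "size": c.size,
                "gender": c.gender,
                "conditionCode": f"{c.condition_code.system}|{c.condition_code.code}",
                "procedureCode": f"{c.procedure_code.system}|{c.procedure_code.code}",
                "observationCode": f"{c.observation_code.system}|{c.observation_code.code}",
                "observationValue": str(c.observation_value),
            }
            for c in plan_cohorts(profile)
        ],
        "queries": labels,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
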