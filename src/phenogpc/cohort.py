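"""Phenopacket-style cohort I/O.

Reads a directory of GA4GH Phenopacket Schema v2 JSON case records (the
supported subset: subject, phenotypic features with observed/excluded state
and onset, measurements, diseases, and variant interpretations), optionally
merges a variant functional-annotation sidecar TSV, and builds a validated
in-memory :class:`Cohort`.  Missing data are never imputed: absent fields
stay absent or UNKNOWN and the statistics downstream omit such data points.
"""

from __future__ import annotations

import enum
import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .ontology import TermId

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """A case record or sidecar violates the supported-subset contract."""


class Sex(enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


class VitalStatus(enum.Enum):
    ALIVE = "ALIVE"
    DECEASED = "DECEASED"
    UNKNOWN = "UNKNOWN"


# ISO-8601 durations restricted to date components: P[nY][nM][nW][nD]
_ISO_DURATION_RE = re.compile(
    r"^P(?:(?P<Y>\d+(?:\.\d+)?)Y)?(?:(?P<M>\d+(?:\.\d+)?)M)?"
    r"(?:(?P<W>\d+(?:\.\d+)?)W)?(?:(?P<D>\d+(?:\.\d+)?)D)?$"
)

DAYS_PER_YEAR = 365.25


def parse_iso8601_age(text: str) -> float:
    """Convert an ISO-8601 duration like ``P3Y6M`` to age in years.

    Months count as 1/12 year and days as 1/365.25 year, fixed constants for
    reproducibility.  Time-of-day and gestational components are rejected.
    """
    if not isinstance(text, str):
        raise ValidationError(f"age duration must be a string, got {text!r}")
    m = _ISO_DURATION_RE.match(text)
    if not m or text == "P":
        raise ValidationError(f"malformed ISO-8601 age duration: {text!r}")
    y = float(m.group("Y") or 0)
    mo = float(m.group("M") or 0)
    w = float(m.group("W") or 0)
    d = float(m.group("D") or 0)
    return y + mo / 12.0 + (w * 7.0 + d) / DAYS_PER_YEAR


def format_iso8601_age(years: float) -> str:
    """Inverse of :func:`parse_iso8601_age` to day resolution (round trip safe)."""
    if years < 0 or not math.isfinite(years):
        raise ValidationError(f"age must be a finite non-negative value: {years}")
    whole = int(years)
    days = round((years - whole) * DAYS_PER_YEAR)
    if days == 0:
        return f"P{whole}Y" if whole else "P0D"
    return f"P{whole}Y{days}D" if whole else f"P{days}D"


@dataclass(frozen=True)
class PhenotypicFeatureRecord:
    term: TermId
    excluded: bool = False
    onset: float | None = None  # age in years


@dataclass(frozen=True)
class MeasurementRecord:
    assay_id: str  # e.g. a LOINC code
    value: float
    unit: str = ""  # e.g. a UCUM code

    def __post_init__(self) -> None:
        if not self.assay_id:
            raise ValidationError("measurement assay_id must be non-empty")
        if not math.isfinite(self.value):
            raise ValidationError(
                f"measurement value must be finite: {self.assay_id}={self.value}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One allele's functional annotation plus this individual's dose.

    ``change_length`` is ``len(alt) - len(ref)`` and only defined for
    sequence variants; imprecise structural events carry ``structural_kind``
    and may omit all coordinates.
    """

    key: str
    gene: str = ""
    transcript: str = ""
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    consequences: frozenset[str] = frozenset()
    affected_exons: frozenset[int] = frozenset()
    protein_span: tuple[int, int] | None = None  # 1-based inclusive residues
    change_length: int | None = None
    structural_kind: str | None = None  # DEL | DUP | INV | chromosomal...
    allele_count: int = 1

    def __post_init__(self) -> None:
        if self.allele_count not in (1, 2):
            raise ValidationError(
                f"allele_count must be 1 or 2, got {self.allele_count} for {self.key}"
            )
        if self.protein_span is not None and self.protein_span[0] > self.protein_span[1]:
            raise ValidationError(f"inverted protein span for {self.key}")


@dataclass(frozen=True)
class DiseaseRecord:
    disease_id: str
    label: str = ""
    onset: float | None = None  # age in years


@dataclass
class Individual:
    """One case: sex, ages, phenotype features, measurements, diseases, variants."""

    id: str
    sex: Sex = Sex.UNKNOWN
    age_last_encounter: float | None = None
    vital: VitalStatus = VitalStatus.UNKNOWN
    age_at_death: float | None = None
    features: list[PhenotypicFeatureRecord] = field(default_factory=list)
    measurements: list[MeasurementRecord] = field(default_factory=list)
    diseases: list[DiseaseRecord] = field(default_factory=list)
    variants: list[VariantRecord] = field(default_factory=list)
    genotype_unknown: bool = False  # allelic state unparseable -> omit from classifiers

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("individual id must be non-empty")
        if self.age_at_death is not None and self.vital is not VitalStatus.DECEASED:
            raise ValidationError(
                f"{self.id}: age_at_death present but vital status is {self.vital.value}"
            )
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValidationError(f"{self.id}: duplicate variant key")
        per_gene: dict[str, int] = {}
        for v in self.variants:
            per_gene[v.gene] = per_gene.get(v.gene, 0) + v.allele_count
        for gene, total in per_gene.items():
            if total > 2:
                raise ValidationError(
                    f"{self.id}: more than two alleles annotated in gene {gene or '?'}"
                )

    def observed_terms(self) -> set[TermId]:
        return {f.term for f in self.features if not f.excluded}

    def excluded_terms(self) -> set[TermId]:
        return {f.term for f in self.features if f.excluded}


@dataclass
class Cohort:
    individuals: list[Individual]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.individuals:
            raise ValidationError("cohort must be non-empty")
        ids = [i.id for i in self.individuals]
        dupes = {x for x in ids if ids.count(x) > 1}
        if dupes:
            raise ValidationError(f"duplicate subject ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)


# ---------------------------------------------------------------------------
# Phenopacket JSON <-> Individual
# ---------------------------------------------------------------------------

_SEX_MAP = {"MALE": Sex.MALE, "FEMALE": Sex.FEMALE}
_ALLELIC_STATE = {
    # GENO ontology labels as used in variationDescriptor.allelicState
    "heterozygous": 1,
    "hemizygous": 1,
    "homozygous": 2,
}


def _age_from(node: dict | None) -> float | None:
    if not node:
        return None
    age = node.get("age") or {}
    iso = age.get("iso8601duration")
    if iso is None:
        if "gestationalAge" in node:
            raise ValidationError("gestational ages are not supported")
        return None
    return parse_iso8601_age(iso)


def parse_phenopacket(doc: dict) -> Individual:
    """Map one phenopacket JSON document to an :class:`Individual`.

    All present fields of the supported subset are mapped; anything absent
    stays UNKNOWN/absent and is never imputed.
    """
    subject = doc.get("subject") or {}
    subject_id = subject.get("id")
    if not subject_id:
        raise ValidationError("phenopacket has no subject.id")
    sex = _SEX_MAP.get(subject.get("sex", ""), Sex.UNKNOWN)
    age_last = _age_from(subject.get("timeAtLastEncounter"))

    vital = VitalStatus.UNKNOWN
    age_at_death = None
    vs = subject.get("vitalStatus") or {}
    status = vs.get("status")
    if status in ("ALIVE", "DECEASED"):
        vital = VitalStatus[status]
    if vital is VitalStatus.DECEASED:
        age_at_death = _age_from({"age": (vs.get("timeOfDeath") or {}).get("age", {})})

    features = []
    for pf in doc.get("phenotypicFeatures", []):
        term = (pf.get("type") or {}).get("id")
        if not term:
            raise ValidationError(f"{subject_id}: phenotypic feature without type.id")
        features.append(
            PhenotypicFeatureRecord(
                term=term,
                excluded=bool(pf.get("excluded", False)),
                onset=_age_from(pf.get("onset")),
            )
        )

    measurements = []
    for meas in doc.get("measurements", []):
        assay = (meas.get("assay") or {}).get("id")
        quantity = ((meas.get("value") or {}).get("quantity")) or {}
        if assay is None or "value" not in quantity:
            raise ValidationError(f"{subject_id}: incomplete measurement element")
        measurements.append(
            MeasurementRecord(
                assay_id=assay,
                value=float(quantity["value"]),
                unit=(quantity.get("unit") or {}).get("id", ""),
            )
        )

    diseases = []
    for dis in doc.get("diseases", []):
        term = dis.get("term") or {}
        if not term.get("id"):
            raise ValidationError(f"{subject_id}: disease without term.id")
        diseases.append(
            DiseaseRecord(
                disease_id=term["id"],
                label=term.get("label", ""),
                onset=_age_from(dis.get("onset")),
            )
        )

    variants, genotype_unknown = _parse_interpretations(doc, subject_id)

    return Individual(
        id=subject_id,
        sex=sex,
        age_last_encounter=age_last,
        vital=vital,
        age_at_death=age_at_death,
        features=features,
        measurements=measurements,
        diseases=diseases,
        variants=variants,
        genotype_unknown=genotype_unknown,
    )


def _parse_interpretations(doc: dict, subject_id: str) -> tuple[list[VariantRecord], bool]:
    variants: list[VariantRecord] = []
    seen: set[str] = set()
    genotype_unknown = False
    for interp in doc.get("interpretations", []):
        for gi in (interp.get("diagnosis") or {}).get("genomicInterpretations", []):
            vd = ((gi.get("variantInterpretation") or {}).get("variationDescriptor")) or {}
            key = vd.get("id")
            if not key:
                continue
            if key in seen:
                raise ValidationError(f"{subject_id}: duplicate variant key {key}")
            seen.add(key)
            state = ((vd.get("allelicState") or {}).get("label", "")).lower()
            if state not in _ALLELIC_STATE:
                genotype_unknown = True
                allele_count = 1
            else:
                allele_count = _ALLELIC_STATE[state]
            hgvs_c = hgvs_p = None
            for expr in vd.get("expressions", []):
                if expr.get("syntax") == "hgvs.c":
                    hgvs_c = expr.get("value")
                elif expr.get("syntax") == "hgvs.p":
                    hgvs_p = expr.get("value")
            variants.append(
                VariantRecord(
                    key=key,
                    gene=((vd.get("geneContext") or {}).get("symbol", "")),
                    hgvs_c=hgvs_c,
                    hgvs_p=hgvs_p,
                    structural_kind=(vd.get("structuralType") or {}).get("label"),
                    allele_count=allele_count,
                )
            )
    return variants, genotype_unknown


def write_phenopacket(individual: Individual) -> dict:
    """Serialize an :class:`Individual` back to the supported phenopacket subset."""
    subject: dict = {"id": individual.id}
    if individual.sex is not Sex.UNKNOWN:
        subject["sex"] = individual.sex.value
    if individual.age_last_encounter is not None:
        subject["timeAtLastEncounter"] = {
            "age": {"iso8601duration": format_iso8601_age(individual.age_last_encounter)}
        }
    if individual.vital is not VitalStatus.UNKNOWN:
        vs: dict = {"status": individual.vital.value}
        if individual.age_at_death is not None:
            vs["timeOfDeath"] = {
                "age": {"iso8601duration": format_iso8601_age(individual.age_at_death)}
            }
        subject["vitalStatus"] = vs

    doc: dict = {"subject": subject}
    if individual.features:
        doc["phenotypicFeatures"] = [
            {
                "type": {"id": f.term},
                **({"excluded": True} if f.excluded else {}),
                **(
                    {"onset": {"age": {"iso8601duration": format_iso8601_age(f.onset)}}}
                    if f.onset is not None
                    else {}
                ),
            }
            for f in individual.features
        ]
    if individual.measurements:
        doc["measurements"] = [
            {
                "assay": {"id": m.assay_id},
                "value": {"quantity": {"value": m.value, "unit": {"id": m.unit}}},
            }
            for m in individual.measurements
        ]
    if individual.diseases:
        doc["diseases"] = [
            {
                "term": {"id": d.disease_id, "label": d.label},
                **(
                    {"onset": {"age": {"iso8601duration": format_iso8601_age(d.onset)}}}
                    if d.onset is not None
                    else {}
                ),
            }
            for d in individual.diseases
        ]
    if individual.variants:
        state = {1: "heterozygous", 2: "homozygous"}
        doc["interpretations"] = [
            {
                "id": f"{individual.id}-interpretation",
                "diagnosis": {
                    "genomicInterpretations": [
                        {
                            "subjectOrBiosampleId": individual.id,
                            "variantInterpretation": {
                                "variationDescriptor": {
                                    "id": v.key,
                                    **(
                                        {"geneContext": {"symbol": v.gene}}
                                        if v.gene
                                        else {}
                                    ),
                                    **(
                                        {
                                            "structuralType": {
                                                "label": v.structural_kind
                                            }
                                        }
                                        if v.structural_kind
                                        else {}
                                    ),
                                    "allelicState": {
                                        "label": state[v.allele_count]
                                    },
                                }
                            },
                        }
                        for v in individual.variants
                    ]
                },
            }
        ]
    return doc


# ---------------------------------------------------------------------------
# Variant-annotation sidecar TSV
# ---------------------------------------------------------------------------

_SIDECAR_COLUMNS = [
    "key",
    "gene",
    "transcript",
    "consequences",
    "exons",
    "protein_start",
    "protein_end",
    "change_length",
    "structural_kind",
]


def load_variant_annotations(path) -> dict[str, dict]:
    """Read the functional-annotation sidecar TSV keyed by variant key.

    The sidecar replaces live consequence annotation (e.g. VEP) so analyses
    stay hermetic.  Consequence labels are ';'-separated, exons ','-separated;
    empty numeric fields stay absent.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = set(_SIDECAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"sidecar TSV missing columns: {sorted(missing)}")
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        key = row["key"]
        if key in out:
            raise ValidationError(f"duplicate variant key in sidecar: {key}")
        ann: dict = {
            "gene": row["gene"],
            "transcript": row["transcript"],
            "consequences": frozenset(
                c for c in row["consequences"].split(";") if c
            ),
            "affected_exons": frozenset(
                int(e) for e in row["exons"].split(",") if e
            ),
        }
        if row["protein_start"] and row["protein_end"]:
            ann["protein_span"] = (int(row["protein_start"]), int(row["protein_end"]))
        if row["change_length"] != "":
            ann["change_length"] = int(row["change_length"])
        if row["structural_kind"]:
            ann["structural_kind"] = row["structural_kind"]
        out[key] = ann
    return out


def apply_variant_annotations(
    individual: Individual, annotations: dict[str, dict]
) -> Individual:
    """Merge sidecar annotation fields into an individual's variant records."""
    merged = []
    unannotated = []
    for v in individual.variants:
        ann = annotations.get(v.key)
        if ann is None:
            unannotated.append(v.key)
            continue
        updates = dict(ann)
        if not updates.get("gene"):
            updates.pop("gene", None)
        merged.append(replace(v, **updates))
    if unannotated:
        raise ValidationError(
            f"{individual.id}: variant keys without sidecar annotation: {unannotated}"
        )
    individual.variants = merged
    return individual


# ---------------------------------------------------------------------------
# Cohort loading & summary
# ---------------------------------------------------------------------------


def load_cohort(directory, annotations=None, strict: bool = True) -> Cohort:
    """Load all phenopacket JSON files in *directory* into a :class:`Cohort`.

    In strict mode (default) any unparseable file aborts the load; in lenient
    mode failures are logged and skipped.  When *annotations* names a sidecar
    TSV, its functional annotations are merged into every variant record.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.json"))
    if not paths:
        raise ValidationError(f"no phenopacket JSON files found in {directory}")
    ann = load_variant_annotations(annotations) if annotations else None
    individuals = []
    for path in paths:
        try:
            with open(path) as fh:
                doc = json.load(fh)
            ind = parse_phenopacket(doc)
            if ann is not None:
                ind = apply_variant_annotations(ind, ann)
            individuals.append(ind)
        except (ValidationError, json.JSONDecodeError, OSError) as exc:
            if strict:
                raise ValidationError(f"{path.name}: {exc}") from exc
            logger.warning("skipping %s: %s", path.name, exc)
    if not individuals:
        raise ValidationError(f"no parseable phenopackets in {directory}")
    return Cohort(individuals=individuals, provenance=[str(directory)])


def cohort_summary(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Descriptive statistics: counts, sex, top terms, diseases, variant classes."""
    sex = pd.Series([i.sex.value for i in cohort]).value_counts()
    terms = pd.Series(
        [f.term for i in cohort for f in i.features if not f.excluded]
    ).value_counts()
    diseases = pd.Series(
        [d.disease_id for i in cohort for d in i.diseases]
    ).value_counts()
    variant_keys = pd.Series(
        [v.key for i in cohort for v in i.variants]
    ).value_counts()
    consequences = pd.Series(
        [c for i in cohort for v in i.variants for c in sorted(v.consequences)]
    ).value_counts()
    return {
        "individuals": pd.DataFrame({"n": [len(cohort)]}),
        "sex": sex.rename_axis("sex").to_frame("n"),
        "top_terms": terms.rename_axis("term").to_frame("n"),
        "diseases": diseases.rename_axis("disease").to_frame("n"),
        "variants": variant_keys.rename_axis("variant").to_frame("n"),
        "consequences": consequences.rename_axis("consequence").to_frame("n"),
    }
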