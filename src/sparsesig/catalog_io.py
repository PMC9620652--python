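"""Reading and writing mutation catalogs and signature matrices.

Mutation tables are MAF-like TSVs (one somatic SNV per row, 1-based
coordinates); signature catalogs follow the COSMIC SBS96 text layout
(channel label column plus one column per signature, columns summing to 1).
Cohort-level filters live here too: rows that are not single-nucleotide
substitutions are dropped on read, and patients with multiple samples are
reduced to the most recent sample (greatest participant age).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import BASES, CHANNELS, N_CHANNELS

logger = logging.getLogger(__name__)

CANCER_GROUPS: frozenset[str] = frozenset(
    {"BLCA", "GI", "HEME", "HNSC", "SARC", "SKIN", "OTHER"}
)

#: default column names in mutation TSVs; a config mapping can rename them
DEFAULT_COLUMNS: dict[str, str] = {
    "sample_id": "sample_id",
    "patient_id": "patient_id",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "cancer_group": "cancer_group",
    "age": "age",
    "context": "context",
}

_REQUIRED = ("sample_id", "patient_id", "chrom", "pos", "ref", "alt", "cancer_group")
_OPTIONAL = ("age", "context")


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant with sample-level metadata.

    ``pos`` is 1-based (MAF/VCF convention); internal interval logic converts
    to 0-based half-open at the point of use. ``context`` is the optional
    3-base reference sequence centred on ``pos``.
    """

    sample_id: str
    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    cancer_group: str
    age: float | None = None
    context: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or self.ref not in BASES:
            raise ValueError(f"ref must be one of ACGT, got {self.ref!r}")
        if len(self.alt) != 1 or self.alt not in BASES:
            raise ValueError(f"alt must be one of ACGT, got {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.cancer_group not in CANCER_GROUPS:
            raise ValueError(f"unknown cancer group {self.cancer_group!r}")
        if self.age is not None and not (self.age >= 0):
            raise ValueError(f"age must be non-negative, got {self.age}")
        if self.context is not None:
            ctx = self.context.upper()
            if len(ctx) != 3:
                raise ValueError(f"context must be 3 bases, got {self.context!r}")
            if ctx[1] != self.ref:
                raise ValueError(
                    f"context middle base {ctx[1]!r} does not match ref {self.ref!r}"
                )
            object.__setattr__(self, "context", ctx)


class SignatureCatalog:
    """A 96 x K column-stochastic matrix of named mutational signatures.

    Rows are the canonical SBS96 channels (COSMIC order, pyrimidine strand);
    each column is one signature and sums to 1.
    """

    def __init__(self, names: Sequence[str], probs: np.ndarray) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (N_CHANNELS, len(names)):
            raise ValueError(
                f"probs must be 96 x {len(names)}, got shape {probs.shape}"
            )
        if len(set(names)) != len(names):
            raise ValueError("duplicate signature names")
        if np.any(probs < 0):
            raise ValueError("signature probabilities must be non-negative")
        sums = probs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            bad = [n for n, s in zip(names, sums) if abs(s - 1.0) > 1e-8]
            raise ValueError(f"signature columns must sum to 1: {bad}")
        self.names: tuple[str, ...] = tuple(str(n) for n in names)
        self.channels: tuple[str, ...] = CHANNELS
        self.probs: np.ndarray = probs

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"signature {name!r} not in catalog") from None

    def column(self, name: str) -> np.ndarray:
        return self.probs[:, self.index(name)]

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        idx = [self.index(n) for n in names]
        probs = self.probs[:, idx]
        return SignatureCatalog(names, probs / probs.sum(axis=0, keepdims=True))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(CHANNELS), columns=list(self.names))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SignatureCatalog)
            and self.names == other.names
            and np.array_equal(self.probs, other.probs)
        )


def read_signature_catalog(path) -> SignatureCatalog:
    """Read a COSMIC SBS96-layout signature catalog from a TSV file.

    The first column holds channel labels; remaining columns are signatures.
    Rows may appear in any order and are reordered canonically. Columns whose
    sum deviates from 1 by less than 1e-4 are renormalized; larger deviations
    are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != N_CHANNELS:
        raise FormatError(f"expected {N_CHANNELS} channel rows, got {df.shape[0]}")
    labels = [str(x) for x in df.index]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise FormatError(f"duplicate channel labels: {dupes}")
    unknown = sorted(set(labels) - set(CHANNELS))
    if unknown:
        raise FormatError(f"unrecognized channel labels: {unknown[:5]}")
    df.index = labels
    df = df.loc[list(CHANNELS)]
    probs = df.to_numpy(dtype=float)
    sums = probs.sum(axis=0)
    bad = [c for c, s in zip(df.columns, sums) if abs(s - 1.0) >= 1e-4]
    if bad:
        raise FormatError(f"signature columns do not sum to 1 (tolerance 1e-4): {bad}")
    probs = probs / sums
    return SignatureCatalog([str(c) for c in df.columns], probs)


def write_signature_catalog(catalog: SignatureCatalog, path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index_label="Type", float_format="%.6g")


def read_mutation_table(
    path, columns: Mapping[str, str] | None = None
) -> list[MutationRecord]:
    """Read a MAF-like TSV of somatic SNVs.

    ``columns`` maps the canonical field names (sample_id, patient_id, chrom,
    pos, ref, alt, cancer_group, age, context) to the file's column names;
    unmapped fields use the canonical name directly. Rows whose ref or alt is
    not a single ACGT base (indels, dinucleotides, ambiguous calls) are
    dropped and the drop count logged.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype={colmap["chrom"]: str})
    if df.shape[0] == 0:
        raise FormatError(f"mutation table {path} contains no rows")
    for field in _REQUIRED:
        if colmap[field] not in df.columns:
            raise FormatError(f"missing required column {colmap[field]!r} ({field})")
    has_age = colmap["age"] in df.columns
    has_context = colmap["context"] in df.columns

    ref = df[colmap["ref"]].astype(str).str.upper()
    alt = df[colmap["alt"]].astype(str).str.upper()
    snv = ref.isin(list(BASES)) & alt.isin(list(BASES)) & (ref != alt)
    n_dropped = int((~snv).sum())
    if n_dropped:
        logger.info("dropped %d non-SNV rows from %s", n_dropped, path)
    df = df[snv]

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        age = None
        if has_age:
            raw = d[colmap["age"]]
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                age = float(raw)
        context = None
        if has_context:
            raw = d[colmap["context"]]
            if isinstance(raw, str) and raw.strip():
                context = raw.strip()
        records.append(
            MutationRecord(
                sample_id=str(d[colmap["sample_id"]]),
                patient_id=str(d[colmap["patient_id"]]),
                chrom=str(d[colmap["chrom"]]),
                pos=int(d[colmap["pos"]]),
                ref=str(d[colmap["ref"]]).upper(),
                alt=str(d[colmap["alt"]]).upper(),
                cancer_group=str(d[colmap["cancer_group"]]),
                age=age,
                context=context,
            )
        )
    return records


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "cancer_group": r.cancer_group,
            "age": r.age,
            "context": r.context,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "patient_id",
            "chrom",
            "pos",
            "ref",
            "alt",
            "cancer_group",
            "age",
            "context",
        ],
    )


def write_mutation_table(records: Iterable[MutationRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.6g")


def dedup_latest_sample(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Keep, per patient, only the mutations of the most recent sample.

    Recency is indicated by participant age at sampling: the sample with the
    greatest age wins. Samples with missing age are never preferred over a
    dated sample (missing age compares as -inf). Ties — including patients
    whose samples all lack age — are broken by lexicographically smallest
    sample_id, and such patients are logged.
    """
    sample_age: dict[tuple[str, str], float] = {}
    for r in records:
        key = (r.patient_id, r.sample_id)
        age = -math.inf if r.age is None else r.age
        sample_age[key] = max(sample_age.get(key, -math.inf), age)

    per_patient: dict[str, list[tuple[str, float]]] = {}
    for (patient, sample), age in sample_age.items():
        per_patient.setdefault(patient, []).append((sample, age))

    keep: set[tuple[str, str]] = set()
    for patient, samples in per_patient.items():
        best = min(samples, key=lambda sa: (-sa[1], sa[0]))
        if len(samples) > 1 and not math.isfinite(best[1]):
            logger.info(
                "patient %s deduplicated without age metadata; kept %s",
                patient,
                best[0],
            )
        keep.add((patient, best[0]))

    return [r for r in records if (r.patient_id, r.sample_id) in keep]
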