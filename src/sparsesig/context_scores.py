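"""Replication-strand asymmetry and driver-hotspot accessibility.

Ganciclovir-associated C>A mutations show replication strand asymmetry —
more C>A on the leading strand (equivalently G>T on the lagging strand).
Given an annotation of replication direction, each pyrimidine-strand C>A
event is classified leading/lagging and the bias tested with an exact
binomial test.

Hotspot accessibility asks how readily a signature can create a recurrent
driver mutation: it is the probability mass the signature places on the
exact trinucleotide substitution channel the hotspot requires. Gene-level
accessibility sums over a gene's retained hotspots. Candidate genes are the
50 with the highest variance of mutation counts across positions (TP53
excluded — its sheer volume of hotspot sites dominates), keeping hotspots
with at least 100 recorded occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog_io import MutationRecord
from .channels import channel_for

REPLICATION_CLASSES = ("leading", "lagging", "unknown")


@dataclass(frozen=True)
class StrandAnnotatedMutation:
    """A mutation record plus its replication-strand class.

    Only pyrimidine-strand C>A events (ref C alt A, or ref G alt T on the
    other strand) receive a leading/lagging class; everything else is
    ``unknown``.
    """

    record: MutationRecord
    replication_class: str

    def __post_init__(self) -> None:
        if self.replication_class not in REPLICATION_CLASSES:
            raise ValueError(f"bad replication class {self.replication_class!r}")


@dataclass(frozen=True)
class HotspotRecord:
    """One recurrent driver mutation from a COSMIC-census-style export."""

    gene: str
    label: str
    context: str
    alt: str
    occurrences: int
    position: int | None = None

    def __post_init__(self) -> None:
        if self.occurrences < 0:
            raise ValueError("occurrences must be non-negative")
        ctx = self.context.upper()
        if len(ctx) != 3:
            raise ValueError(f"context must be 3 bases, got {self.context!r}")
        if ctx[1] == self.alt.upper():
            raise ValueError("alt equals the context middle (reference) base")
        object.__setattr__(self, "context", ctx)
        object.__setattr__(self, "alt", self.alt.upper())


class ReplicationAnnotation:
    """Non-overlapping genomic intervals labelled by replication direction.

    Intervals are 0-based half-open with direction ``left`` or ``right``
    (the direction the replication fork travels through the locus).
    """

    def __init__(self, intervals: pd.DataFrame) -> None:
        required = {"chrom", "start", "end", "direction"}
        missing = required - set(intervals.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        bad = set(intervals["direction"]) - {"left", "right"}
        if bad:
            raise ValueError(f"directions must be left/right, got {sorted(bad)}")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in intervals.groupby("chrom"):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=int)
            ends = sub["end"].to_numpy(dtype=int)
            if np.any(ends <= starts):
                raise ValueError(f"empty or inverted interval on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            self._by_chrom[str(chrom)] = (
                starts,
                ends,
                sub["direction"].to_numpy(),
            )

    @classmethod
    def from_bed(cls, path) -> "ReplicationAnnotation":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "direction"],
            dtype={"chrom": str},
        )
        return cls(df)

    def direction_at(self, chrom: str, pos0: int) -> str | None:
        """Fork direction at a 0-based position, or None outside intervals."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, directions = entry
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i >= 0 and pos0 < ends[i]:
            return str(directions[i])
        return None


def classify_replication_strand(
    records: Iterable[MutationRecord], annotation: ReplicationAnnotation
) -> list[StrandAnnotatedMutation]:
    """Assign leading/lagging classes to C>A-class mutations.

    Convention: a C>A event whose pyrimidine sits on the reference (plus)
    strand, in a region where the fork travels rightward, is ``leading``;
    the G>T representation of the same event at the same locus gets the
    opposite class, so the classification is strand-symmetric. Loci outside
    the annotation, and non-C>A mutations, are ``unknown``.
    """
    out = []
    for r in records:
        cls = "unknown"
        is_plus_ca = r.ref == "C" and r.alt == "A"
        is_minus_ca = r.ref == "G" and r.alt == "T"
        if is_plus_ca or is_minus_ca:
            direction = annotation.direction_at(r.chrom, r.pos - 1)
            if direction is not None:
                pyrimidine_on_plus = is_plus_ca
                if (direction == "right") == pyrimidine_on_plus:
                    cls = "leading"
                else:
                    cls = "lagging"
        out.append(StrandAnnotatedMutation(record=r, replication_class=cls))
    return out


def strand_asymmetry_test(
    annotated: Sequence[StrandAnnotatedMutation],
) -> tuple[int, int, float, float]:
    """Leading/lagging counts, log2 ratio, and two-sided exact binomial p.

    The ratio uses a 0.5 pseudo-count per arm so it is finite at zero
    counts; the test is exact binomial at rate 0.5 on the raw counts.
    """
    leading = sum(1 for a in annotated if a.replication_class == "leading")
    lagging = sum(1 for a in annotated if a.replication_class == "lagging")
    total = leading + lagging
    if total == 0:
        raise ValueError("no classified C>A mutations")
    log2_ratio = float(np.log2((leading + 0.5) / (lagging + 0.5)))
    p = float(stats.binomtest(leading, total, 0.5).pvalue)
    return leading, lagging, log2_ratio, p


def select_hotspot_genes(
    counts: pd.DataFrame,
    *,
    top_n: int = 50,
    min_occurrences: int = 100,
    exclude: Sequence[str] = ("TP53",),
) -> tuple[list[str], pd.DataFrame]:
    """Rank genes by positional count variance and filter hotspots.

    ``counts`` has columns gene, position, occurrences (one row per
    annotated position with at least one occurrence). Returns the selected
    gene list (variance descending, excluded genes removed, top ``top_n``)
    and the hotspot rows of selected genes with occurrences >=
    ``min_occurrences``. Single-position genes have variance 0.
    """
    required = {"gene", "position", "occurrences"}
    if counts.empty:
        raise ValueError("empty hotspot table")
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"hotspot table missing columns {sorted(missing)}")
    variances = (
        counts.groupby("gene")["occurrences"].var(ddof=1).fillna(0.0)
    )
    variances = variances.drop(index=[g for g in exclude if g in variances.index])
    ranked = variances.sort_values(ascending=False, kind="mergesort")
    genes = list(ranked.index[:top_n])
    kept = counts[
        counts["gene"].isin(genes) & (counts["occurrences"] >= min_occurrences)
    ].copy()
    return genes, kept


def hotspot_accessibility(hotspot: HotspotRecord, signature: np.ndarray) -> float:
    """Signature probability mass on the hotspot's substitution channel.

    Purine-centred contexts are reverse-complemented before lookup, so the
    score is invariant to the strand the hotspot is reported on.
    """
    signature = np.asarray(signature, dtype=float)
    return float(signature[channel_for(hotspot.context, hotspot.alt)])


def gene_accessibility(
    hotspots: Sequence[HotspotRecord], signature: np.ndarray
) -> float:
    """Sum of hotspot accessibilities for one gene."""
    genes = {h.gene for h in hotspots}
    if len(genes) > 1:
        raise ValueError(f"hotspots span multiple genes: {sorted(genes)}")
    return float(sum(hotspot_accessibility(h, signature) for h in hotspots))


def rank_gene_accessibility(
    hotspots: Sequence[HotspotRecord], signature: np.ndarray
) -> pd.DataFrame:
    """Per-gene accessibility table, descending (most accessible first)."""
    per_gene: dict[str, float] = {}
    for h in hotspots:
        per_gene[h.gene] = per_gene.get(h.gene, 0.0) + hotspot_accessibility(
            h, signature
        )
    df = pd.DataFrame(
        sorted(per_gene.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "accessibility"],
    )
    return df
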