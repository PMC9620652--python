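"""96-channel trinucleotide spectra and CA>AA summaries.

A sample's catalog of SNVs is reduced to a :class:`Spectrum96` — counts over
the 96 pyrimidine-strand trinucleotide substitution channels. The CA>AA
fraction (C>A substitutions with a 3' adenine) is the scalar summary that
tracks ganciclovir mutagenesis; treatment-comparison statistics on those
fractions (Fisher's exact test on counts, the ratio t-test on paired
contribution scores) live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .catalog_io import MutationRecord
from .channels import CA_AA_CHANNELS, CHANNELS, N_CHANNELS, channel_for

logger = logging.getLogger(__name__)


@dataclass
class Spectrum96:
    """Counts over the 96 canonical SBS channels."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros(N_CHANNELS, dtype=np.int64)
    )

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (N_CHANNELS,):
            raise ValueError(f"counts must have shape (96,), got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty spectrum has no frequencies")
        return self.counts / self.total


@dataclass(frozen=True)
class CaAaSummary:
    """Count and fraction of CA>AA mutations in a spectrum.

    ``defined`` is False for empty spectra, where the fraction is reported
    as 0 by convention.
    """

    ca_aa_count: int
    total: int
    fraction: float
    defined: bool = True


def open_reference(path):
    """Open an indexed FASTA file for context lookup in :func:`build_spectrum`."""
    from pyfaidx import Fasta

    return Fasta(str(path))


def _context_of(record: MutationRecord, reference) -> str | None:
    if record.context is not None:
        return record.context
    if reference is None:
        return None
    chrom = reference[record.chrom]
    # record.pos is 1-based; slice is 0-based half-open around it
    seq = chrom[record.pos - 2 : record.pos + 1]
    return str(seq).upper()


def build_spectrum(
    records: Iterable[MutationRecord], reference=None
) -> Spectrum96:
    """Build a 96-channel spectrum from SNV records.

    Contexts come from each record's ``context`` field, or are looked up in
    ``reference`` (a mapping of chromosome name to sequence, e.g. a
    ``pyfaidx.Fasta``). Purine-reference mutations are reverse-complemented
    onto the pyrimidine strand. Records whose context middle base disagrees
    with the reference allele are rejected (logged with their position);
    contexts containing N are dropped.
    """
    counts = np.zeros(N_CHANNELS, dtype=np.int64)
    n_rejected = n_ambiguous = 0
    for record in records:
        context = _context_of(record, reference)
        if context is None:
            raise ValueError(
                f"no context for {record.chrom}:{record.pos} and no reference given"
            )
        if "N" in context:
            n_ambiguous += 1
            continue
        if context[1] != record.ref:
            n_rejected += 1
            logger.warning(
                "context %s at %s:%d does not match ref %s; record rejected",
                context,
                record.chrom,
                record.pos,
                record.ref,
            )
            continue
        counts[channel_for(context, record.alt)] += 1
    if n_ambiguous:
        logger.info("dropped %d records with ambiguous (N) context", n_ambiguous)
    if n_rejected:
        logger.info("rejected %d records with mismatching context", n_rejected)
    return Spectrum96(counts)


def ca_aa_fraction(spectrum: Spectrum96) -> CaAaSummary:
    """Fraction of mutations in the four C>A channels with 3' adenine."""
    total = spectrum.total
    ca_aa = int(spectrum.counts[list(CA_AA_CHANNELS)].sum())
    if total == 0:
        return CaAaSummary(ca_aa_count=0, total=0, fraction=0.0, defined=False)
    return CaAaSummary(ca_aa_count=ca_aa, total=total, fraction=ca_aa / total)


def cohort_average_spectrum(spectra: Sequence[Spectrum96]) -> np.ndarray:
    """Pooled channel frequencies across a cohort (sums to 1).

    This is the mutation-weighted average: channel counts are summed over
    samples and normalized by the grand total.
    """
    if not spectra:
        raise ValueError("empty cohort")
    pooled = np.zeros(N_CHANNELS, dtype=np.int64)
    for s in spectra:
        pooled += s.counts
    grand = pooled.sum()
    if grand == 0:
        raise ValueError("cohort contains no mutations")
    return pooled / grand


def compare_ca_fractions(a: CaAaSummary, b: CaAaSummary) -> float:
    """Two-sided Fisher's exact p-value comparing two CA>AA fractions.

    The 2x2 table is [[a.ca_aa, a.other], [b.ca_aa, b.other]]; the two-sided
    p sums hypergeometric probabilities no larger than the observed table's.
    """
    if a.total == 0 or b.total == 0:
        raise ValueError("both summaries must have positive totals")
    table = [
        [a.ca_aa_count, a.total - a.ca_aa_count],
        [b.ca_aa_count, b.total - b.ca_aa_count],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def ratio_t_test(paired_scores: Sequence[tuple[float, float]]) -> float:
    """Two-sided ratio-paired t-test p-value.

    Tests whether paired positive scores differ multiplicatively: a
    one-sample t-test of log(score_b / score_a) against zero mean. Degenerate
    all-equal pairs (zero variance of the log-ratio) give p = 1 when the mean
    log-ratio is 0 and p = 0 otherwise.
    """
    if len(paired_scores) < 2:
        raise ValueError("need at least 2 pairs")
    a = np.array([p[0] for p in paired_scores], dtype=float)
    b = np.array([p[1] for p in paired_scores], dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("all scores must be positive")
    logs = np.log(b / a)
    if np.std(logs, ddof=1) == 0:
        return 1.0 if np.mean(logs) == 0 else 0.0
    return float(stats.ttest_1samp(logs, 0.0).pvalue)


def spectrum_to_series(spectrum: Spectrum96):
    import pandas as pd

    return pd.Series(spectrum.counts, index=list(CHANNELS), name="count")


def write_spectrum(spectrum: Spectrum96, path) -> None:
    spectrum_to_series(spectrum).to_csv(path, sep="\t", index_label="Type")


def read_spectrum(path) -> Spectrum96:
    import pandas as pd

    s = pd.read_csv(path, sep="\t", index_col=0)["count"]
    if list(s.index) != list(CHANNELS):
        s = s.loc[list(CHANNELS)]
    return Spectrum96(s.to_numpy())
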