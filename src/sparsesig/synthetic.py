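"""Synthetic data generators emulating panel-sequencing cohorts.

The real cohorts behind this pipeline (pan-cancer targeted panels with
per-sample mutation counts averaging ~8, heavy-tailed up to thousands) are
access-controlled, so every input the pipeline needs can be generated here
with the statistical structure the analysis assumes: signature catalogs
containing SBS5/SBS18/SBS38 and a CA>AA-dominated focal signature, cohorts
of multinomial samples from signature mixtures with controlled focal
spike-ins, replication-direction annotations, COSMIC-census-style hotspot
tables, and small reference sequences. All generators are pure functions of
their spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog_io import SignatureCatalog
from .channels import (
    BASES,
    CA_AA_CHANNELS,
    CHANNELS,
    N_CHANNELS,
    channel_context_alt,
)

CATALOG_SIGNATURES = ("SBS5", "SBS18", "SBS38", "GCVsig")

_C_TO_A = [i for i, c in enumerate(CHANNELS) if "[C>A]" in c]
_C_TO_T = [i for i, c in enumerate(CHANNELS) if "[C>T]" in c]
_T_TO_C = [i for i, c in enumerate(CHANNELS) if "[T>C]" in c]


def _dirichlet_on(rng, indices, mass, conc=2.0, out=None):
    if out is None:
        out = np.zeros(N_CHANNELS)
    out[indices] += mass * rng.dirichlet(np.full(len(indices), conc))
    return out


def make_signature_catalog(
    style: str = "cosmic_like", rng: np.random.Generator | None = None
) -> SignatureCatalog:
    """Build a 4-signature catalog (SBS5, SBS18, SBS38, GCVsig).

    Styles
    ------
    disjoint
        Each signature is uniform over its own block of 24 channels
        (pairwise-orthogonal supports), giving closed-form refits. GCVsig
        owns the C>A block, SBS18 the C>G/C>T block.
    overlapping
        Dense Dirichlet draws over all 96 channels for every signature.
    cosmic_like
        Shapes mimicking the real processes: the focal signature puts most
        of its mass (~0.75) on the four CA>AA channels; SBS18 and SBS38 are
        C>A-rich (hence confusable with the focal signature); SBS5 is a
        flat-ish clock-like background weighted to C>T/T>C.
    """
    rng = rng or np.random.default_rng(0)
    cols = {}
    if style == "disjoint":
        for k, name in enumerate(CATALOG_SIGNATURES):
            col = np.zeros(N_CHANNELS)
            # block order: SBS5, SBS18, SBS38, GCVsig -> reorder so GCVsig
            # covers the C>A block (channels 0..23) for CA>AA realism
            block = {"GCVsig": 0, "SBS18": 1, "SBS38": 2, "SBS5": 3}[name]
            col[block * 24 : (block + 1) * 24] = 1 / 24
            cols[name] = col
    elif style == "overlapping":
        for name in CATALOG_SIGNATURES:
            cols[name] = rng.dirichlet(np.full(N_CHANNELS, 0.5))
    elif style == "cosmic_like":
        gcv = np.zeros(N_CHANNELS)
        _dirichlet_on(rng, list(CA_AA_CHANNELS), 0.75, conc=5.0, out=gcv)
        other_ca = [i for i in _C_TO_A if i not in CA_AA_CHANNELS]
        _dirichlet_on(rng, other_ca, 0.20, conc=2.0, out=gcv)
        rest = [i for i in range(N_CHANNELS) if i not in _C_TO_A]
        _dirichlet_on(rng, rest, 0.05, conc=0.5, out=gcv)
        cols["GCVsig"] = gcv

        sbs18 = np.zeros(N_CHANNELS)
        _dirichlet_on(rng, _C_TO_A, 0.80, conc=2.0, out=sbs18)
        _dirichlet_on(rng, rest, 0.20, conc=1.0, out=sbs18)
        cols["SBS18"] = sbs18

        sbs38 = np.zeros(N_CHANNELS)
        _dirichlet_on(rng, _C_TO_A, 0.70, conc=2.0, out=sbs38)
        _dirichlet_on(rng, _C_TO_T, 0.20, conc=2.0, out=sbs38)
        leftover = [i for i in range(N_CHANNELS) if i not in _C_TO_A + _C_TO_T]
        _dirichlet_on(rng, leftover, 0.10, conc=1.0, out=sbs38)
        cols["SBS38"] = sbs38

        sbs5 = np.zeros(N_CHANNELS)
        _dirichlet_on(rng, _C_TO_T, 0.40, conc=5.0, out=sbs5)
        _dirichlet_on(rng, _T_TO_C, 0.40, conc=5.0, out=sbs5)
        leftover5 = [i for i in range(N_CHANNELS) if i not in _C_TO_T + _T_TO_C]
        _dirichlet_on(rng, leftover5, 0.20, conc=5.0, out=sbs5)
        cols["SBS5"] = sbs5
    else:
        raise ValueError(f"unknown catalog style {style!r}")
    probs = np.column_stack([cols[name] for name in CATALOG_SIGNATURES])
    probs = probs / probs.sum(axis=0, keepdims=True)
    return SignatureCatalog(CATALOG_SIGNATURES, probs)


@dataclass
class CohortSimSpec:
    """Specification of a synthetic panel cohort.

    Defaults emulate a GENIE-like cohort: lognormal per-sample mutation
    counts with mean ~7.9 truncated at 10,000, a background of clock-like /
    SBS18 mixtures, and a controlled fraction of focal-signature spike-ins
    whose counts are forced to at least ``spike_in_min_count`` so the spike
    is detectable at all. The number of spike-ins is deterministic:
    round(spike_in_fraction * n_samples).
    """

    n_samples: int = 500
    count_distribution: dict = field(
        default_factory=lambda: {
            "kind": "lognormal",
            "mean": 7.9,
            "sigma": 1.3,
            "max": 10_000,
        }
    )
    background_mixtures: list = field(
        default_factory=lambda: [
            ({"SBS5": 1.0}, 0.4),
            ({"SBS5": 0.6, "SBS18": 0.4}, 0.4),
            ({"SBS5": 0.3, "SBS18": 0.7}, 0.2),
        ]
    )
    spike_in_fraction: float = 0.0
    spike_in_exposure: float = 0.8
    spike_in_min_count: int = 50
    skin_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("spike_in_fraction", self.spike_in_fraction),
            ("skin_fraction", self.skin_fraction),
        ):
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not 0 < self.spike_in_exposure <= 1:
            raise ValueError("spike_in_exposure must lie in (0, 1]")


_NON_SKIN_GROUPS = ("BLCA", "GI", "HEME", "HNSC", "SARC", "OTHER")


def _draw_count(rng, dist: dict) -> int:
    if dist.get("kind", "lognormal") != "lognormal":
        raise ValueError(f"unknown count distribution {dist!r}")
    sigma = dist.get("sigma", 1.3)
    mu = np.log(dist["mean"]) - sigma**2 / 2
    n = int(np.rint(rng.lognormal(mu, sigma)))
    return min(max(n, 0), int(dist.get("max", 10_000)))


def make_cohort(
    spec: CohortSimSpec, catalog: SignatureCatalog
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a mutation table and its ground-truth table.

    The mutation table is MAF-like (one row per SNV, context emitted
    directly in the ``context`` column); the truth table records each
    sample's count, mixture, spike flag and cancer group. One sample per
    patient. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_samples
    n_spikes = int(round(spec.spike_in_fraction * m))
    spike_idx = set(rng.choice(m, size=n_spikes, replace=False).tolist())

    bg_weights = np.array([w for _, w in spec.background_mixtures], dtype=float)
    bg_weights = bg_weights / bg_weights.sum()

    mut_rows = []
    truth_rows = []
    pos_counter = 1
    for i in range(m):
        sample_id = f"S{i:04d}"
        patient_id = f"P{i:04d}"
        age = float(rng.integers(30, 86))
        skin = rng.random() < spec.skin_fraction
        group = "SKIN" if skin else _NON_SKIN_GROUPS[rng.integers(len(_NON_SKIN_GROUPS))]
        n = _draw_count(rng, spec.count_distribution)
        spiked = i in spike_idx
        if spiked:
            for _ in range(1000):
                if n >= spec.spike_in_min_count:
                    break
                n = _draw_count(rng, spec.count_distribution)
            n = max(n, spec.spike_in_min_count)

        base_mixture, _ = spec.background_mixtures[
            rng.choice(len(spec.background_mixtures), p=bg_weights)
        ]
        mixture = {k: float(v) for k, v in base_mixture.items()}
        if spiked:
            e = spec.spike_in_exposure
            mixture = {k: v * (1 - e) for k, v in mixture.items()}
            mixture["GCVsig"] = mixture.get("GCVsig", 0.0) + e

        p = np.zeros(N_CHANNELS)
        for name, w in mixture.items():
            p += w * catalog.column(name)
        channel_counts = rng.multinomial(n, p) if n > 0 else np.zeros(N_CHANNELS, int)
        for ch in np.nonzero(channel_counts)[0]:
            context, alt = channel_context_alt(int(ch))
            for _ in range(int(channel_counts[ch])):
                mut_rows.append(
                    {
                        "sample_id": sample_id,
                        "patient_id": patient_id,
                        "chrom": "chr1",
                        "pos": pos_counter,
                        "ref": context[1],
                        "alt": alt,
                        "cancer_group": group,
                        "age": age,
                        "context": context,
                    }
                )
                pos_counter += 1
        truth_rows.append(
            {
                "sample_id": sample_id,
                "patient_id": patient_id,
                "cancer_group": group,
                "n": int(n),
                "spiked": spiked,
                "mixture": json.dumps(mixture, sort_keys=True),
            }
        )
    columns = [
        "sample_id",
        "patient_id",
        "chrom",
        "pos",
        "ref",
        "alt",
        "cancer_group",
        "age",
        "context",
    ]
    mutations = pd.DataFrame(mut_rows, columns=columns)
    truth = pd.DataFrame(truth_rows)
    return mutations, truth


def make_replication_annotation(
    sequence_length: int,
    segment_length: int,
    rng: np.random.Generator | None = None,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Alternating left/right-replicating segments tiling [0, length)."""
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    rng = rng or np.random.default_rng(0)
    first = "right" if rng.random() < 0.5 else "left"
    other = "left" if first == "right" else "right"
    rows = []
    start = 0
    i = 0
    while start < sequence_length:
        end = min(start + segment_length, sequence_length)
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "direction": first if i % 2 == 0 else other,
            }
        )
        start = end
        i += 1
    return pd.DataFrame(rows)


def make_hotspot_table(
    n_genes: int,
    hotspots_per_gene: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """COSMIC-census-style hotspot table with a dominating TP53 decoy.

    Occurrence counts straddle the 100 threshold; TP53 gets many positions
    with huge counts so its positional variance dominates (and must be
    excluded by the selection step). Contexts span all 96 channels.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = rng or np.random.default_rng(0)
    rows = []
    genes = ["TP53"] + [f"GENE{i:03d}" for i in range(1, n_genes)]
    pos = 1
    for gene in genes:
        k = hotspots_per_gene * 4 if gene == "TP53" else hotspots_per_gene
        for j in range(k):
            ch = int(rng.integers(N_CHANNELS))
            context, alt = channel_context_alt(ch)
            if gene == "TP53":
                occurrences = int(rng.integers(1000, 10_000))
            else:
                occurrences = int(rng.integers(20, 400))
            rows.append(
                {
                    "gene": gene,
                    "label": f"{context[1]}{pos}{alt}",
                    "position": pos,
                    "context": context,
                    "alt": alt,
                    "occurrences": occurrences,
                }
            )
            pos += 1
    return pd.DataFrame(rows)


def make_reference_sequence(
    length: int, rng: np.random.Generator | None = None
) -> str:
    rng = rng or np.random.default_rng(0)
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_cohort(
    spec: CohortSimSpec,
    catalog: SignatureCatalog,
    out_dir,
    *,
    reference_length: int = 10_000,
) -> dict[str, Path]:
    """Materialize a full synthetic input set in a directory.

    Writes mutations.tsv, truth.tsv, catalog.tsv, replication.bed and
    reference.fa; returns the paths.
    """
    from .catalog_io import write_signature_catalog

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    mutations, truth = make_cohort(spec, catalog)
    paths = {
        "mutations": out_dir / "mutations.tsv",
        "truth": out_dir / "truth.tsv",
        "catalog": out_dir / "catalog.tsv",
        "replication": out_dir / "replication.bed",
        "reference": out_dir / "reference.fa",
    }
    mutations.to_csv(paths["mutations"], sep="\t", index=False, float_format="%.6g")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_signature_catalog(catalog, paths["catalog"])
    annotation = make_replication_annotation(reference_length, 1000, rng)
    annotation.to_csv(paths["replication"], sep="\t", index=False, header=False)
    write_fasta({"chr1": make_reference_sequence(reference_length, rng)}, paths["reference"])
    return paths
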