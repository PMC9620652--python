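"""Canonical SBS96 channel definitions.

Single-base substitutions are reported on the pyrimidine strand: the 96
channels are the six substitution classes C>A, C>G, C>T, T>A, T>C, T>G,
each in the 16 possible trinucleotide contexts (5' and 3' flanking base).
A mutation observed with a purine reference base is reverse-complemented
(reference, alternate and both flanks) before channel lookup, so the two
strand representations of one event map to the same channel.

Channel labels follow the COSMIC convention, e.g. ``A[C>A]G``. The canonical
order iterates substitution classes in the order above, then the 5' base,
then the 3' base, each alphabetically.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

SUBSTITUTION_TYPES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(CHANNELS)}

N_CHANNELS = 96

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: indices of the four C>A channels with a 3' adenine (the "CA>AA" channels,
#: the dinucleotide change that dominates the ganciclovir signature)
CA_AA_CHANNELS: tuple[int, ...] = tuple(
    CHANNEL_INDEX[f"{five}[C>A]A"] for five in BASES
)


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_for(context: str, alt: str) -> int:
    """Map a trinucleotide reference context and alternate base to a channel index.

    ``context`` is the 3-base reference sequence centred on the mutated base;
    its middle base is the reference allele. Purine-reference events are
    reverse-complemented first, so ``channel_for("TGT", "T")`` equals
    ``channel_for("ACA", "A")``.

    Raises
    ------
    ValueError
        If the context is not 3 ACGT bases, the alternate is not a single
        ACGT base, or the alternate equals the reference.
    """
    context = context.upper()
    alt = alt.upper()
    if len(context) != 3 or any(b not in BASES for b in context):
        raise ValueError(f"context must be 3 ACGT bases, got {context!r}")
    if len(alt) != 1 or alt not in BASES:
        raise ValueError(f"alt must be a single ACGT base, got {alt!r}")
    ref = context[1]
    if ref == alt:
        raise ValueError(f"alt equals reference base {ref!r}")
    if ref in PURINES:
        context = reverse_complement(context)
        alt = complement(alt)
        ref = context[1]
    return CHANNEL_INDEX[f"{context[0]}[{ref}>{alt}]{context[2]}"]


def channel_context_alt(index: int) -> tuple[str, str]:
    """Inverse of :func:`channel_for` on the pyrimidine strand.

    Returns the (context, alt) pair of the given channel in its canonical
    pyrimidine-strand representation.
    """
    label = CHANNELS[index]
    context = label[0] + label[2] + label[6]
    return context, label[4]
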