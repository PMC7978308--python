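"""The fixed 96-channel single-base-substitution axis.

Somatic single-base substitutions are classified pyrimidine-centered: the six
substitution types C>A, C>G, C>T, T>A, T>C, T>G, each split by the 5' and 3'
flanking bases, giving 96 trinucleotide channels.  Channel order is the COSMIC
convention: substitution classes in the order above, flanks alphabetical within
each class, so channel 0 is ``A[C>A]A`` and channel 95 is ``T[T>G]T``.

The ordering is load-bearing for every catalog, signature profile and
reference-catalog comparison in this package, so it is frozen here and guarded
by a checksum.
"""

from __future__ import annotations

import hashlib

SUBSTITUTION_TYPES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
FLANK_BASES = "ACGT"

SBS96_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in FLANK_BASES
    for three in FLANK_BASES
)

#: md5 of the comma-joined channel labels; guards against silent reordering.
SBS96_CHECKSUM = "463000db3a129981977b0b23c11d167d"

_LABEL_TO_INDEX = {label: i for i, label in enumerate(SBS96_LABELS)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _verify_axis() -> None:
    digest = hashlib.md5(",".join(SBS96_LABELS).encode()).hexdigest()
    if digest != SBS96_CHECKSUM:  # pragma: no cover - corruption guard
        raise RuntimeError("SBS96 channel axis does not match its frozen checksum")


_verify_axis()


def channel_index(label: str) -> int:
    """Index of a channel label like ``"A[C>T]G"`` on the fixed axis."""
    try:
        return _LABEL_TO_INDEX[label]
    except KeyError:
        raise ValueError(f"not an SBS96 channel label: {label!r}") from None


def channel_label(index: int) -> str:
    """Label of channel ``index`` (0-95)."""
    if not 0 <= index < 96:
        raise ValueError(f"channel index out of range: {index}")
    return SBS96_LABELS[index]


def channel_of_substitution(ref: str, alt: str, context: str) -> int:
    """Map a substitution with its trinucleotide context to a channel.

    ``context`` is the reference trinucleotide centered on the mutated base.
    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand first.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref in "AG":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
        context = context.translate(_COMPLEMENT)[::-1]
    return channel_index(f"{context[0]}[{ref}>{alt}]{context[2]}")
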