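"""Expanded target sequences and the position-label coordinate system.

A CRISPR-Cas9 target site is represented as a 30-nt "expanded target":
4 nt of upstream genomic context, the 20-nt spacer-matching protospacer,
the 3-nt NGG PAM, and 3 nt of downstream context.  All features are
addressed with position labels relative to the spacer start rather than
raw string offsets: upstream context is labelled -4..-1, the spacer plus
PAM occupy labels 1..23, and the downstream context is +1..+3.  There is
no label 0.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "POSITION_LABELS",
    "LABEL_TO_OFFSET",
    "ExpandedTarget",
    "TargetError",
    "LengthError",
    "AlphabetError",
    "PamError",
    "validate_target",
]

DNA_ALPHABET = frozenset("ACGT")
TARGET_LENGTH = 30

#: Position labels for array offsets 0..29, in order.
POSITION_LABELS: tuple[str, ...] = (
    "-4", "-3", "-2", "-1",
    *[str(i) for i in range(1, 24)],
    "+1", "+2", "+3",
)

LABEL_TO_OFFSET: dict[str, int] = {lab: i for i, lab in enumerate(POSITION_LABELS)}

# Offsets of structural regions.
SPACER_SLICE = slice(4, 24)      # labels 1..20
PAM_SLICE = slice(24, 27)        # labels 21..23
PAM_GG_OFFSETS = (25, 26)        # labels 22, 23 -- must be 'GG'


class TargetError(ValueError):
    """Base class for expanded-target validation failures."""


class LengthError(TargetError):
    pass


class AlphabetError(TargetError):
    pass


class PamError(TargetError):
    pass


@dataclass(frozen=True)
class ExpandedTarget:
    """A validated 30-nt expanded target sequence.

    Attributes
    ----------
    sequence
        Uppercase 30-character DNA string.
    """

    sequence: str

    @property
    def spacer(self) -> str:
        """The 20-nt protospacer (labels 1..20)."""
        return self.sequence[SPACER_SLICE]

    @property
    def pam(self) -> str:
        """The 3-nt PAM (labels 21..23)."""
        return self.sequence[PAM_SLICE]

    @property
    def upstream(self) -> str:
        return self.sequence[:4]

    @property
    def downstream(self) -> str:
        return self.sequence[27:]

    def base(self, label: str) -> str:
        """Nucleotide at a position label (e.g. ``"-4"``, ``"20"``, ``"+1"``)."""
        return self.sequence[LABEL_TO_OFFSET[label]]

    def region(self, start_label: str, end_label: str) -> str:
        """Substring spanning two labels inclusive."""
        i, j = LABEL_TO_OFFSET[start_label], LABEL_TO_OFFSET[end_label]
        if i > j:
            raise ValueError(f"start label {start_label!r} is after end label {end_label!r}")
        return self.sequence[i : j + 1]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.sequence


def validate_target(raw: str, *, require_pam: bool = True) -> ExpandedTarget:
    """Validate and canonicalise a raw 30-mer into an :class:`ExpandedTarget`.

    Parameters
    ----------
    raw
        Candidate sequence; lowercase letters are accepted and upcased.
        ``U`` is rejected -- the expanded target is genomic DNA.
    require_pam
        When true (default) offsets 25-26 (labels 22-23) must read ``GG``
        per the SpCas9 NGG requirement.  Permissive mode is for
        exploratory featurisation of non-NGG sites.

    Raises
    ------
    LengthError
        If the input is not exactly 30 characters.
    AlphabetError
        Naming the first offending offset, if any character is outside
        ``{A,C,G,T,a,c,g,t}``.
    PamError
        If the GG of the NGG PAM is absent (unless ``require_pam=False``).
    """
    if not isinstance(raw, str):
        raise TypeError(f"expected str, got {type(raw).__name__}")
    if len(raw) != TARGET_LENGTH:
        raise LengthError(
            f"expanded target must be exactly {TARGET_LENGTH} nt, got {len(raw)}"
        )
    seq = raw.upper()
    for i, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise AlphabetError(
                f"invalid character {raw[i]!r} at offset {i} "
                f"(position label {POSITION_LABELS[i]}); alphabet is A/C/G/T"
            )
    if require_pam and (seq[25] != "G" or seq[26] != "G"):
        raise PamError(
            f"PAM positions 22-23 must be 'GG' (NGG), found {seq[24:27]!r} at labels 21-23"
        )
    return ExpandedTarget(seq)
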