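"""Shared domain types, coordinate conventions and threshold configuration.

Coordinate conventions used throughout the package:

* All positions are 0-based, half-open, on the forward strand of the amplicon.
* SpCas9 cuts bluntly between the -4 and -3 positions relative to the NGG PAM.
  ``cut_pos`` is the index of the first base 3' of the cut on the amplicon
  forward strand; for a forward-strand guide whose protospacer starts at
  ``i``, ``cut_pos = i + 17``.
* Guides on the minus strand store protospacer and PAM in their own (reverse
  complement) orientation but ``cut_pos`` stays in forward coordinates.
* Indel sizes are signed: negative = deletion, positive = insertion, in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "DNA_ALPHABET",
    "Amplicon",
    "GuideSite",
    "Thresholds",
    "IndelEvent",
    "IndelSpectrum",
    "InvalidIndelError",
    "is_frameshift",
    "is_knockout_indel",
    "revcomp",
]

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# rounding slack on percentage totals (percentage points)
PCT_EPS = 0.5


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidIndelError(ValueError):
    """Raised when an indel size of 0 is passed where an indel is required."""


@dataclass(frozen=True)
class Amplicon:
    """A sequenced target region holding a protein-coding segment.

    ``cds_start``/``cds_end`` delimit the coding sequence (0-based,
    half-open); the guide-design window (5-65% of the CDS) is measured
    against these bounds.
    """

    id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set(DNA_ALPHABET):
            bad = sorted(set(seq) - set(DNA_ALPHABET))
            raise ValueError(f"non-ACGT characters in amplicon {self.id!r}: {bad}")
        if not (0 <= self.cds_start < self.cds_end <= len(seq)):
            raise ValueError(
                f"CDS bounds [{self.cds_start}, {self.cds_end}) invalid for "
                f"sequence of length {len(seq)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]


@dataclass(frozen=True)
class GuideSite:
    """A 20-nt SpCas9 protospacer with its NGG PAM and blunt-cut coordinate."""

    guide_id: str
    protospacer: str
    pam: str
    strand: str
    cut_pos: int
    cds_fraction: float | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.cut_pos <= 0:
            raise ValueError("cut_pos must be positive")


@dataclass(frozen=True)
class Thresholds:
    """QC and scoring thresholds for the whole pipeline.

    Defaults are the study-wide analysis settings: a 30-bp decomposition
    window, per-indel significance p < 0.01, fit quality R² > 0.7, the
    ≥21-bp size-based knockout rule, the 20% dominant-indel cutoff, a
    group-size floor of 15 roots, 100-bp microhomology-strength flanks and
    the -4 insertion-template position.
    """

    max_indel: int = 30
    p_cut: float = 0.01
    r2_cut: float = 0.7
    ko_len: int = 21
    dominance_pct: float = 20.0
    min_roots: int = 15
    mh_flank: int = 100
    template_offset: int = -4

    def __post_init__(self) -> None:
        for name in ("max_indel", "p_cut", "r2_cut", "ko_len", "dominance_pct",
                     "min_roots", "mh_flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.template_offset != -4:
            raise ValueError("template_offset is fixed at -4 (fill-in of a 1-nt 5' overhang)")
        if self.max_indel < self.ko_len:
            raise ValueError("max_indel must be >= ko_len")

    def replace(self, **kwargs) -> "Thresholds":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class IndelEvent:
    """One indel allele in a root's sequence population.

    ``size`` is signed bp (negative deletion, positive insertion);
    ``inserted_bases`` is known only for synthetic ground truth (a Sanger
    mixture does not resolve inserted bases), and two insertions of equal
    size but different bases are distinct events.
    """

    size: int
    percentage: float
    inserted_bases: str | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.size == 0:
            raise InvalidIndelError("indel size must be nonzero")
        if self.percentage < 0:
            raise ValueError("percentage must be >= 0")
        if self.inserted_bases is not None:
            if self.size < 0:
                raise ValueError("deletions carry no inserted bases")
            if len(self.inserted_bases) != self.size:
                raise ValueError("inserted_bases length must equal insertion size")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")

    @property
    def key(self) -> tuple[int, str | None]:
        return (self.size, self.inserted_bases)


@dataclass
class IndelSpectrum:
    """The indel composition of one root: events plus the wild-type share."""

    events: list[IndelEvent] = field(default_factory=list)
    wt_percentage: float = 0.0

    def __post_init__(self) -> None:
        keys = [e.key for e in self.events]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate indel keys in spectrum")
        total = self.wt_percentage + sum(e.percentage for e in self.events)
        if total > 100.0 + PCT_EPS:
            raise ValueError(f"spectrum percentages sum to {total:.2f} > 100")
        if self.wt_percentage < 0:
            raise ValueError("wt_percentage must be >= 0")

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def by_size(self) -> dict[int, float]:
        """Total percentage per signed size (insertion bases pooled)."""
        out: dict[int, float] = {}
        for e in self.events:
            out[e.size] = out.get(e.size, 0.0) + e.percentage
        return out


def is_frameshift(size: int) -> bool:
    """True iff an indel of this signed size shifts the reading frame."""
    if size == 0:
        raise InvalidIndelError("indel size must be nonzero")
    return size % 3 != 0


def is_knockout_indel(size: int, ko_len: int = Thresholds.ko_len) -> bool:
    """True iff the indel likely yields a null allele.

    Frameshifts count, and so do in-frame indels of ``ko_len`` bp or more
    (large enough to disrupt the protein even without a frameshift). The
    size rule is applied to ``abs(size)`` for either sign.
    """
    return is_frameshift(size) or abs(size) >= ko_len
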