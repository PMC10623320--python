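"""Repair-outcome prediction from sequence context.

Two mechanisms are modelled. Microhomology-mediated end joining (MMEJ):
short repeated blocks flanking the cut collapse into deletions whose length
equals the offset between the two copies; each pattern is scored with an
exponential length-decay and doubled GC weight, and the out-of-frame score
is the score-weighted fraction of frame-shifting deletion patterns.
Templated insertion: fill-in of a 1-nt 5' overhang duplicates the base at
the -4 position relative to the PAM, predicting the identity of 1-bp
insertions.

The microhomology *strength* of a locus (long, GC-rich microhomologies
close to the cut) is summarised as a single value with low/average/high
classes; the value is a package-defined proxy whose class labels and
monotonicity are the contract, not its absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

__all__ = [
    "MicrohomologyPattern",
    "PredictionEntry",
    "PredictionSet",
    "enumerate_microhomologies",
    "mh_pattern_score",
    "out_of_frame_score",
    "mh_strength",
    "classify_mh_strength",
    "templated_insertion",
    "predict_spectrum",
    "top_k",
]

DEFAULT_LENGTH_WEIGHT = 20.0  # bp; exponential deletion-length decay
DEFAULT_MIN_MH_LEN = 2
DELETION_WINDOW = 30   # bp each side for deletion scoring (reporting cap)
STRENGTH_FLANK = 100   # bp each side for microhomology strength
STRENGTH_DISTANCE_TAU = 20.0  # bp; distance-to-cut decay for strength
STRENGTH_NORM = 3400.0  # scales a typical random locus to ~0.5 ("average")
STRENGTH_CLASSES = (0.3, 0.8)  # low < 0.3 <= average <= 0.8 < high


@dataclass(frozen=True)
class MicrohomologyPattern:
    """A repeated block flanking the cut whose collapse implies a deletion
    of ``deletion_length`` bp (= right_start - left_start)."""

    left_start: int
    right_start: int
    length: int
    sequence: str
    cut_pos: int

    @property
    def deletion_length(self) -> int:
        return self.right_start - self.left_start

    @property
    def gc_count(self) -> int:
        return sum(b in "GC" for b in self.sequence)

    @property
    def distance_to_cut(self) -> int:
        """Gap between the pattern copies and the cut: how far the left copy
        ends 5' of the cut plus how far the right copy starts 3' of it."""
        left_gap = self.cut_pos - (self.left_start + self.length)
        right_gap = max(self.right_start - self.cut_pos, 0)
        return max(left_gap, 0) + right_gap


@dataclass(frozen=True)
class PredictionEntry:
    size: int
    weight: float
    inserted_base: str | None = None


@dataclass(frozen=True)
class PredictionSet:
    model: str
    entries: tuple[PredictionEntry, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        if any(e.weight < 0 for e in self.entries):
            raise ValueError("prediction weights must be >= 0")
        if self.normalized and self.entries:
            total = sum(e.weight for e in self.entries)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"normalized weights sum to {total}")

    def normalize(self) -> "PredictionSet":
        total = sum(e.weight for e in self.entries)
        if total <= 0:
            raise ValueError("cannot normalize an all-zero prediction set")
        entries = tuple(
            PredictionEntry(e.size, e.weight / total, e.inserted_base)
            for e in self.entries
        )
        return PredictionSet(self.model, entries, normalized=True)


def enumerate_microhomologies(
    sequence: str,
    cut_pos: int,
    window: int = DELETION_WINDOW,
    min_mh_len: int = DEFAULT_MIN_MH_LEN,
) -> list[MicrohomologyPattern]:
    """All maximal repeated blocks of length >= min_mh_len whose left copy
    lies entirely 5' of the cut (ending at most ``window`` bp before it)
    and whose right copy lies at/3' of the cut (starting at most ``window``
    bp after it). Collapsing such a pair deletes ``right_start -
    left_start`` bp spanning the cut.

    Only maximal repeats are reported: a pair is extended as far as the
    sequences agree, and pairs that are merely shifted-in sub-blocks of a
    longer pattern implying the same deletion (not left-maximal) are
    skipped — the nested sub-patterns of a longer pattern at the same
    locus.
    """
    seq = sequence.upper()
    n = len(seq)
    kept: list[tuple[int, int, int]] = []  # (left, right, length)
    hi = min(n, cut_pos + window + 1)
    for left in range(0, cut_pos):
        for right in range(max(left + 1, cut_pos), hi):
            if seq[left] != seq[right]:
                continue
            if left > 0 and seq[left - 1] == seq[right - 1]:
                continue  # shifted-in sub-block of a longer pattern
            length = 1
            while (
                left + length < cut_pos  # left copy stays 5' of the cut
                and right + length < n
                and seq[left + length] == seq[right + length]
            ):
                length += 1
            if length < min_mh_len:
                continue
            if cut_pos - (left + length) > window:
                continue
            if right - cut_pos > window:
                continue
            kept.append((left, right, length))
    return [
        MicrohomologyPattern(
            left_start=l,
            right_start=r,
            length=ln,
            sequence=seq[l : l + ln],
            cut_pos=cut_pos,
        )
        for l, r, ln in sorted(kept)
    ]


def mh_pattern_score(
    pattern: MicrohomologyPattern, length_weight: float = DEFAULT_LENGTH_WEIGHT
) -> float:
    """Pattern weight: 100 * exp(-deletion_length / length_weight) *
    (2*GC + AT) — longer implied deletions decay exponentially, GC pairs
    count double (stronger annealing)."""
    gc = pattern.gc_count
    at = pattern.length - gc
    return 100.0 * exp(-pattern.deletion_length / length_weight) * (2 * gc + at)


def out_of_frame_score(
    patterns: list[MicrohomologyPattern],
    length_weight: float = DEFAULT_LENGTH_WEIGHT,
) -> float | None:
    """Score-weighted percentage of microhomology deletion patterns whose
    implied deletion shifts the frame; None when no patterns exist."""
    if not patterns:
        return None
    total = sum(mh_pattern_score(p, length_weight) for p in patterns)
    if total == 0:
        return None
    oof = sum(
        mh_pattern_score(p, length_weight)
        for p in patterns
        if p.deletion_length % 3 != 0
    )
    return 100.0 * oof / total


def classify_mh_strength(value: float) -> str:
    low, high = STRENGTH_CLASSES
    if value < low:
        return "low"
    if value > high:
        return "high"
    return "average"


def mh_strength(
    sequence: str,
    cut_pos: int,
    flank: int = STRENGTH_FLANK,
    min_mh_len: int = DEFAULT_MIN_MH_LEN,
) -> tuple[float, str]:
    """Microhomology strength of the flanking sequence: the normalized sum
    of pattern scores, each additionally decayed by the pattern's distance
    to the cut. Classes: low < 0.3 <= average <= 0.8 < high."""
    patterns = enumerate_microhomologies(sequence, cut_pos, flank, min_mh_len)
    value = (
        sum(
            mh_pattern_score(p) * exp(-p.distance_to_cut / STRENGTH_DISTANCE_TAU)
            for p in patterns
        )
        / STRENGTH_NORM
    )
    return value, classify_mh_strength(value)


def templated_insertion(sequence: str, cut_pos: int) -> PredictionSet:
    """Predict the 1-bp insertion templated by the -4 position: the base
    immediately 5' of the cut is duplicated during overhang fill-in."""
    if cut_pos < 1 or cut_pos > len(sequence):
        raise ValueError("cut_pos out of range for templated insertion")
    base = sequence.upper()[cut_pos - 1]
    return PredictionSet(
        model="templated_insertion",
        entries=(PredictionEntry(size=1, weight=1.0, inserted_base=base),),
        normalized=True,
    )


def predict_spectrum(
    sequence: str,
    cut_pos: int,
    *,
    insertion_mass: float = 0.25,
    window: int = DELETION_WINDOW,
    min_mh_len: int = DEFAULT_MIN_MH_LEN,
    length_weight: float = DEFAULT_LENGTH_WEIGHT,
) -> PredictionSet | None:
    """Combined predicted spectrum: microhomology deletions (weighted by
    pattern score, pooled by size) mixed with the templated +1 insertion at
    ``insertion_mass`` (default 0.25, the ~3:1 deletion:insertion
    observation). Returns None when no outcome is predictable."""
    if not (0.0 <= insertion_mass <= 1.0):
        raise ValueError("insertion_mass must be in [0, 1]")
    by_size: dict[int, float] = {}
    for p in enumerate_microhomologies(sequence, cut_pos, window, min_mh_len):
        s = -p.deletion_length
        by_size[s] = by_size.get(s, 0.0) + mh_pattern_score(p, length_weight)
    del_total = sum(by_size.values())
    entries: list[PredictionEntry] = []
    if del_total > 0 and insertion_mass < 1.0:
        scale = (1.0 - insertion_mass) / del_total
        entries.extend(
            PredictionEntry(size=s, weight=w * scale)
            for s, w in sorted(by_size.items())
        )
    if insertion_mass > 0:
        ins = templated_insertion(sequence, cut_pos).entries[0]
        entries.append(
            PredictionEntry(size=1, weight=insertion_mass, inserted_base=ins.inserted_base)
        )
    if not entries:
        return None
    return PredictionSet(
        model="mh+template", entries=tuple(entries), normalized=False
    ).normalize()


def top_k(prediction: PredictionSet, k: int = 5) -> list[PredictionEntry]:
    """The k highest-weight entries, weight-descending; ties broken by
    smaller |size|, then deletions before insertions."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not prediction.normalized:
        raise ValueError("prediction set must be normalized")
    ordered = sorted(
        prediction.entries, key=lambda e: (-e.weight, abs(e.size), e.size > 0)
    )
    return ordered[:k]
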