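"""sgRNA candidate enumeration and filtering.

Design rules: the cut site must fall in the 5-65% window of the coding
sequence (avoiding alternative downstream start codons and near-C-terminal
edits), the protospacer must start with G (the U6 promoter initiates
transcription on a guanine), the protospacer+PAM must be free of BbsI
recognition sites (GAAGAC / GTCTTC, needed for cloning), and off-target
hits with more than 4 mismatches including at least one in the PAM-proximal
seed region are dismissed as non-cleavable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core import Amplicon, GuideSite, revcomp

__all__ = [
    "BBSI_SITES",
    "GuideCandidate",
    "OffTargetHit",
    "enumerate_guides",
    "filter_guides",
    "off_target_scan",
    "rank_guides",
]

BBSI_SITES = ("GAAGAC", "GTCTTC")
CDS_WINDOW = (0.05, 0.65)
DEFAULT_SEED_LEN = 12  # PAM-proximal bases; Cas-OFFinder workflow convention

_PAM_FWD = re.compile(r"(?=[ACGT]GG)")
_PAM_REV = re.compile(r"(?=CC[ACGT])")


@dataclass(frozen=True)
class GuideCandidate:
    guide_id: str
    protospacer: str
    pam: str
    strand: str
    cut_pos: int
    cds_fraction: float | None
    in_cds_window: bool
    starts_with_g: bool
    has_bbsi: bool
    off_target_risk_count: int = 0

    def to_site(self) -> GuideSite:
        return GuideSite(
            guide_id=self.guide_id,
            protospacer=self.protospacer,
            pam=self.pam,
            strand=self.strand,
            cut_pos=self.cut_pos,
            cds_fraction=self.cds_fraction,
        )


@dataclass(frozen=True)
class OffTargetHit:
    """A PAM-adjacent 20-mer in a background sequence, compared to the
    protospacer by Hamming distance."""

    background_id: str
    position: int
    strand: str
    sequence: str
    mismatches: int
    seed_mismatch: bool
    dismissed: bool


def _candidate(amplicon: Amplicon, protospacer: str, pam: str, strand: str,
               cut_pos: int, idx: int) -> GuideCandidate:
    frac: float | None = None
    if amplicon.cds_start <= cut_pos < amplicon.cds_end:
        frac = (cut_pos - amplicon.cds_start) / (amplicon.cds_end - amplicon.cds_start)
    in_window = frac is not None and CDS_WINDOW[0] <= frac <= CDS_WINDOW[1]
    context = protospacer + pam
    return GuideCandidate(
        guide_id=f"g{idx:03d}{strand}",
        protospacer=protospacer,
        pam=pam,
        strand=strand,
        cut_pos=cut_pos,
        cds_fraction=frac,
        in_cds_window=in_window,
        starts_with_g=protospacer.startswith("G"),
        has_bbsi=any(site in context for site in BBSI_SITES),
    )


def enumerate_guides(amplicon: Amplicon) -> list[GuideCandidate]:
    """All 20-nt windows followed by an NGG PAM, on both strands.

    Forward candidates: protospacer at [i, i+20), PAM at [i+20, i+23),
    blunt cut between forward positions i+16 and i+17 (cut_pos = i+17).
    Reverse candidates: PAM (CCN on the forward strand) at [j, j+3),
    protospacer at [j+3, j+23) read on the reverse strand; cut_pos = j+6.
    """
    seq = amplicon.sequence
    out: list[GuideCandidate] = []
    idx = 0
    for m in _PAM_FWD.finditer(seq):
        pam_start = m.start()
        i = pam_start - 20
        if i < 0:
            continue
        cut = i + 17
        if not (0 < cut < len(seq)):
            continue
        out.append(
            _candidate(amplicon, seq[i : i + 20], seq[pam_start : pam_start + 3],
                       "+", cut, idx)
        )
        idx += 1
    for m in _PAM_REV.finditer(seq):
        j = m.start()
        if j + 23 > len(seq):
            continue
        cut = j + 6
        if not (0 < cut < len(seq)):
            continue
        protospacer = revcomp(seq[j + 3 : j + 23])
        pam = revcomp(seq[j : j + 3])
        out.append(_candidate(amplicon, protospacer, pam, "-", cut, idx))
        idx += 1
    return out


def filter_guides(
    candidates: list[GuideCandidate],
    cds_window: tuple[float, float] = CDS_WINDOW,
) -> list[GuideCandidate]:
    """Keep candidates whose cut falls inside the CDS window, whose
    protospacer starts with G, and which carry no BbsI site. Idempotent."""
    lo, hi = cds_window
    return [
        c
        for c in candidates
        if c.cds_fraction is not None
        and lo <= c.cds_fraction <= hi
        and c.starts_with_g
        and not c.has_bbsi
    ]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def off_target_scan(
    guide: GuideSite,
    background: dict[str, str],
    seed_len: int = DEFAULT_SEED_LEN,
) -> tuple[list[OffTargetHit], int]:
    """Scan background sequences for NGG-adjacent 20-mers and classify them.

    A hit is dismissed when it has more than 4 mismatches to the protospacer
    including at least one in the ``seed_len`` PAM-proximal bases. Returns
    (hits, risk_count) where risk_count counts non-dismissed hits; exact
    (0-mismatch) hits are treated as the on-target site and excluded from
    the count.
    """
    hits: list[OffTargetHit] = []
    risk = 0
    for bg_id, bg_seq in background.items():
        bg_seq = bg_seq.upper()
        for strand, seq in (("+", bg_seq), ("-", revcomp(bg_seq))):
            for m in _PAM_FWD.finditer(seq):
                i = m.start() - 20
                if i < 0:
                    continue
                window = seq[i : i + 20]
                mism = _hamming(window, guide.protospacer)
                seed_mm = _hamming(window[-seed_len:], guide.protospacer[-seed_len:]) > 0
                dismissed = mism > 4 and seed_mm
                pos = i if strand == "+" else len(bg_seq) - (i + 20)
                hits.append(
                    OffTargetHit(
                        background_id=bg_id,
                        position=pos,
                        strand=strand,
                        sequence=window,
                        mismatches=mism,
                        seed_mismatch=seed_mm,
                        dismissed=dismissed,
                    )
                )
                if not dismissed and mism > 0:
                    risk += 1
    return hits, risk


def rank_guides(
    candidates: list[GuideCandidate],
    efficiency_scores: dict[str, float],
) -> list[GuideCandidate]:
    """Order candidates by (fewest off-target risks, highest efficiency
    score, 5'-most cut) — the selection rule 'highest predicted efficiency,
    lowest potential off-targets'."""
    for c in candidates:
        if c.guide_id not in efficiency_scores:
            raise KeyError(f"no efficiency score for guide {c.guide_id!r}")
    return sorted(
        candidates,
        key=lambda c: (
            c.off_target_risk_count,
            -efficiency_scores[c.guide_id],
            c.cut_pos,
        ),
    )
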