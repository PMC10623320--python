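"""Synthetic cohorts: amplicons, guide sites, per-root indel spectra and
paired control/edited trace matrices.

The generator emulates the statistical structure of an edited hairy-root
cohort: each root is a (possibly chimeric) mixture of alleles carrying
1-4 dominant indels (>20% each), indel sizes follow a pooled distribution
with a ~3:1 deletion:insertion ratio anchored at 22.6% 1-bp deletions and
19.1% 1-bp insertions (deletions up to 30 bp, insertions up to 4 bp), and
+1 insertions preferentially duplicate the base at the -4 position relative
to the PAM (fill-in of a 1-nt 5' overhang).

Chromatograms are modelled as normalized per-position base-signal fractions
(a ``TraceMatrix``), which is exactly the information the decomposition
stage consumes; no AB1 binaries, quality scores or dye artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .core import (
    DNA_ALPHABET,
    Amplicon,
    GuideSite,
    IndelEvent,
    IndelSpectrum,
    revcomp,
)

__all__ = [
    "ConfigError",
    "GenerationError",
    "InvalidSpectrumError",
    "RepairSpectrumConfig",
    "TraceMatrix",
    "GroupSpec",
    "CohortRecord",
    "load_size_weights",
    "make_amplicon",
    "pick_guide",
    "template_base",
    "sample_root_spectrum",
    "synthesize_traces",
    "inject_seed_snp",
    "simulate_study",
]

_STOP_CODONS = ("TAA", "TGA", "TAG")


class ConfigError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """No valid amplicon/guide could be generated within the retry budget."""


class InvalidSpectrumError(ValueError):
    """A spectrum event cannot be realized on the given read geometry."""


def load_size_weights() -> dict[int, float]:
    """Load the shipped pooled indel-size distribution fixture."""
    text = (
        resources.files("rootedit.data")
        .joinpath("pooled_size_weights.tsv")
        .read_text()
    )
    weights: dict[int, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("size"):
            continue
        size_s, w_s = line.split("\t")
        weights[int(size_s)] = float(w_s)
    return weights


@dataclass(frozen=True)
class RepairSpectrumConfig:
    """Parameters of the per-root repair-outcome generator.

    ``size_weights`` is the pooled indel-size distribution (signed bp ->
    probability); ``template_bias`` is the probability that a +1 insertion
    duplicates the -4 template base; ``wt_fraction_range`` is the uniform
    range of the unedited (wild-type) allele fraction per root, i.e. one
    minus the root's editing level.
    """

    size_weights: dict[int, float] = field(default_factory=load_size_weights)
    dominant_count_range: tuple[int, int] = (1, 4)
    wt_fraction_range: tuple[float, float] = (0.1, 0.3)
    template_bias: float = 0.75
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.size_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"size_weights sum to {total}, expected 1")
        if any(s == 0 for s in self.size_weights):
            raise ConfigError("size_weights support must exclude 0")
        if any(w < 0 for w in self.size_weights.values()):
            raise ConfigError("size_weights must be non-negative")
        lo, hi = self.dominant_count_range
        if not (1 <= lo <= hi <= 4):
            raise ConfigError("dominant_count_range must be within [1, 4]")
        wlo, whi = self.wt_fraction_range
        if not (0.0 <= wlo <= whi <= 1.0):
            raise ConfigError("wt_fraction_range must be within [0, 1]")
        if not (0.0 <= self.template_bias <= 1.0):
            raise ConfigError("template_bias must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        # even a single dominant indel cannot exceed the whole population
        if lo * 20.0 > 100.0:
            raise ConfigError("dominance constraint unsatisfiable")

    def replace(self, **kwargs) -> "RepairSpectrumConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TraceMatrix:
    """Per-position base-signal fractions: rows = template positions,
    columns = A, C, G, T; every row sums to 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2 or vals.shape[1] != 4:
            raise ValueError("trace matrix must have shape (n, 4)")
        if (vals < 0).any():
            raise ValueError("trace fractions must be >= 0")
        sums = vals.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("every trace row must sum to 1")

    def __len__(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_sequence(cls, seq: str) -> "TraceMatrix":
        return cls(_one_hot(seq))


def _one_hot(seq: str) -> np.ndarray:
    idx = np.fromiter((DNA_ALPHABET.index(b) for b in seq), dtype=int, count=len(seq))
    mat = np.zeros((len(seq), 4))
    mat[np.arange(len(seq)), idx] = 1.0
    return mat


# ---------------------------------------------------------------------------
# amplicon and guide generation
# ---------------------------------------------------------------------------

#: minimal distance of the cut site from either read end so that the
#: decomposition window (cut + max_indel .. length - max_indel) is non-empty
#: and every +-30 bp template is realizable.
MIN_CUT_FLANK_5P = 20
MIN_CUT_FLANK_3P = 65


def make_amplicon(
    length: int,
    gc_fraction: float = 0.45,
    seed: int = 0,
    *,
    amplicon_id: str | None = None,
    max_tries: int = 200,
) -> Amplicon:
    """Generate a random amplicon with an internal in-frame CDS and at least
    one usable guide site inside the 5-65% CDS window.

    Deterministic for a fixed seed. Raises :class:`GenerationError` when no
    valid guide site is placeable within the retry budget (e.g. at
    gc_fraction=0, where no NGG PAM can occur).
    """
    from . import design  # local import: design depends only on core

    if length < 120:
        raise ValueError("amplicon length must be >= 120")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([
        (1 - gc_fraction) / 2,  # A
        gc_fraction / 2,        # C
        gc_fraction / 2,        # G
        (1 - gc_fraction) / 2,  # T
    ])
    cds_start = max(9, length // 8)
    cds_len = ((length - cds_start - length // 8) // 3) * 3
    cds_end = cds_start + cds_len
    name = amplicon_id or f"amp_{seed}"
    for _ in range(max_tries):
        bases = rng.choice(list(DNA_ALPHABET), size=length, p=p)
        seq = list("".join(bases))
        seq[cds_start : cds_start + 3] = "ATG"
        stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
        seq[cds_end - 3 : cds_end] = stop
        amp = Amplicon(name, "".join(seq), cds_start, cds_end)
        if _usable_guides(amp, design):
            return amp
    raise GenerationError(
        f"no valid guide site placeable in {max_tries} tries "
        f"(length={length}, gc={gc_fraction})"
    )


def _usable_guides(amplicon: Amplicon, design) -> list:
    cands = design.filter_guides(design.enumerate_guides(amplicon))
    return [
        c
        for c in cands
        if c.cut_pos >= MIN_CUT_FLANK_5P
        and len(amplicon) - c.cut_pos >= MIN_CUT_FLANK_3P
    ]


def pick_guide(amplicon: Amplicon, prefer_strand: str = "+") -> GuideSite:
    """Deterministically pick one filtered guide on the amplicon: prefer the
    requested strand, then the most central cut site."""
    from . import design

    cands = _usable_guides(amplicon, design)
    if not cands:
        raise GenerationError(f"no usable guide on amplicon {amplicon.id!r}")
    cands.sort(
        key=lambda c: (
            c.strand != prefer_strand,
            -min(c.cut_pos, len(amplicon) - c.cut_pos),
            c.cut_pos,
        )
    )
    c = cands[0]
    return GuideSite(
        guide_id=f"{amplicon.id}_{c.guide_id}",
        protospacer=c.protospacer,
        pam=c.pam,
        strand=c.strand,
        cut_pos=c.cut_pos,
        cds_fraction=c.cds_fraction,
    )


def template_base(site: GuideSite) -> str:
    """Forward-strand identity of the base a templated +1 insertion
    duplicates: the -4 position relative to the PAM (protospacer base 17)."""
    b = site.protospacer[16]
    return b if site.strand == "+" else revcomp(b)


# ---------------------------------------------------------------------------
# per-root spectra
# ---------------------------------------------------------------------------


def _madow_sample(sizes: np.ndarray, probs: np.ndarray, k: int, rng) -> np.ndarray:
    """Draw k distinct items with inclusion probability exactly k*p_i
    (systematic probability-proportional-to-size sampling).

    Keeps the pooled marginal frequency of each indel size equal to the
    fixture weights even though sizes within one root must be distinct.
    Falls back to sequential sampling without replacement when k*max(p) > 1.
    """
    if k > len(sizes):
        raise ConfigError("more dominant events requested than distinct sizes")
    if k * probs.max() > 1.0:
        return rng.choice(sizes, size=k, replace=False, p=probs)
    order = rng.permutation(len(sizes))
    cum = np.cumsum(k * probs[order])
    cum[-1] = float(k)  # guard against rounding
    targets = rng.uniform() + np.arange(k)
    idx = np.searchsorted(cum, targets, side="right")
    return sizes[order[idx]]


def _insertion_bases(size: int, fwd_template: str, bias: float, rng) -> str:
    if size == 1:
        if rng.uniform() < bias:
            return fwd_template
        others = [b for b in DNA_ALPHABET if b != fwd_template]
        return others[rng.integers(3)]
    return "".join(rng.choice(list(DNA_ALPHABET), size=size))


def sample_root_spectrum(
    config: RepairSpectrumConfig,
    site: GuideSite,
    root_seed: int,
    *,
    dominance_pct: float = 20.0,
) -> IndelSpectrum:
    """Sample the allele composition of one hairy root.

    The root carries k dominant indels (k uniform on
    ``dominant_count_range``, capped so that k events above the dominance
    cutoff fit into the edited fraction), with distinct sizes drawn by
    systematic PPS sampling from ``size_weights``; the wild-type fraction
    fills the remainder. Roots whose edited fraction is below the dominance
    cutoff (e.g. a mismatched guide) carry at most one minor event.
    """
    rng = np.random.default_rng(root_seed)
    wlo, whi = config.wt_fraction_range
    wt_pct = 100.0 * rng.uniform(wlo, whi)
    edited = 100.0 - wt_pct
    sizes_arr = np.array(sorted(config.size_weights))
    probs = np.array([config.size_weights[s] for s in sizes_arr], dtype=float)
    probs = probs / probs.sum()
    fwd_template = template_base(site)

    if edited <= dominance_pct + 0.5:
        if edited <= 0.5:
            return IndelSpectrum(events=[], wt_percentage=round(100.0 - edited, 4))
        size = int(rng.choice(sizes_arr, p=probs))
        bases = (
            _insertion_bases(size, fwd_template, config.template_bias, rng)
            if size > 0
            else None
        )
        ev = IndelEvent(size=size, percentage=edited, inserted_bases=bases)
        return IndelSpectrum(events=[ev], wt_percentage=wt_pct)

    klo, khi = config.dominant_count_range
    k_feasible = int(math.floor(edited / (dominance_pct + 0.5)))
    k_hi = min(khi, k_feasible)
    k_lo = min(klo, k_hi)
    k = int(rng.integers(k_lo, k_hi + 1))
    sizes = _madow_sample(sizes_arr, probs, k, rng)
    base_pct = dominance_pct + 0.25
    remainder = edited - k * base_pct
    shares = rng.dirichlet(np.ones(k)) * remainder
    events = []
    for size, share in zip(sizes, shares):
        size = int(size)
        bases = (
            _insertion_bases(size, fwd_template, config.template_bias, rng)
            if size > 0
            else None
        )
        events.append(
            IndelEvent(size=size, percentage=base_pct + share, inserted_bases=bases)
        )
    return IndelSpectrum(events=events, wt_percentage=wt_pct)


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------


def _allele_signal(ref: str, cut: int, event: IndelEvent | None) -> np.ndarray:
    """Signal matrix of a single allele read on the forward strand.

    Deletions shift the template left from the cut; insertions shift it
    right, with inserted positions contributing the inserted base (or a
    uniform 0.25 when the base identity is unknown). Positions reading past
    the template end contribute uniform signal.
    """
    n = len(ref)
    mat = np.full((n, 4), 0.25)
    mat[:cut] = _one_hot(ref[:cut])
    if event is None:  # wild type
        return _one_hot(ref)
    size = event.size
    if size < 0:
        d = -size
        for p in range(cut, n):
            if p + d < n:
                mat[p] = 0.0
                mat[p, DNA_ALPHABET.index(ref[p + d])] = 1.0
    else:
        m = size
        for j in range(m):
            p = cut + j
            if p >= n:
                break
            if event.inserted_bases is not None:
                mat[p] = 0.0
                mat[p, DNA_ALPHABET.index(event.inserted_bases[j])] = 1.0
        for p in range(cut + m, n):
            mat[p] = 0.0
            mat[p, DNA_ALPHABET.index(ref[p - m])] = 1.0
    return mat


def _add_noise(signal: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    if noise_sd > 0:
        signal = np.clip(signal + rng.normal(0.0, noise_sd, signal.shape), 0.0, None)
    sums = signal.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    signal[zero] = 0.25
    sums[zero] = 1.0
    return signal / sums


def synthesize_traces(
    amplicon: Amplicon,
    site: GuideSite,
    spectrum: IndelSpectrum,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    max_shift: int | None = None,
) -> tuple[TraceMatrix, TraceMatrix]:
    """Render a (control, edited) trace pair for one root.

    The control encodes the unedited sequence; the edited trace equals the
    control upstream of the cut and is the percentage-weighted mixture of
    the indel-shifted allele signals downstream. Independent truncated
    Gaussian noise is added to each trace, then rows are renormalized.

    ``max_shift`` bounds the largest realizable shift (default: half the
    read length); it is intentionally independent of the decomposition's
    indel-size window so that oversized deletions can be injected in stress
    scenarios.
    """
    seq, cut = amplicon.sequence, site.cut_pos
    if max_shift is None:
        max_shift = len(seq) // 2
    for ev in spectrum:
        if abs(ev.size) > max_shift:
            raise InvalidSpectrumError(
                f"event of size {ev.size} exceeds max shift {max_shift}"
            )
    rng = np.random.default_rng(seed)
    control_sig = _one_hot(seq)
    total = spectrum.wt_percentage + sum(e.percentage for e in spectrum)
    if total <= 0:
        raise InvalidSpectrumError("spectrum carries no sequence population")
    edited_sig = (spectrum.wt_percentage / total) * _allele_signal(seq, cut, None)
    for ev in spectrum:
        edited_sig += (ev.percentage / total) * _allele_signal(seq, cut, ev)
    control = _add_noise(control_sig, noise_sd, rng)
    edited = _add_noise(edited_sig, noise_sd, rng)
    return TraceMatrix(control), TraceMatrix(edited)


def inject_seed_snp(amplicon: Amplicon, site: GuideSite, seed: int = 0) -> Amplicon:
    """Return a copy of the amplicon with a single substitution at the
    PAM-proximal protospacer base (position 20), mimicking a cultivar SNP in
    the seed sequence that abolishes cleavage."""
    pos = site.cut_pos + 2 if site.strand == "+" else site.cut_pos - 3
    rng = np.random.default_rng(seed)
    original = amplicon.sequence[pos]
    choices = [b for b in DNA_ALPHABET if b != original]
    new = choices[rng.integers(3)]
    seq = amplicon.sequence[:pos] + new + amplicon.sequence[pos + 1 :]
    return Amplicon(amplicon.id + "_snp", seq, amplicon.cds_start, amplicon.cds_end)


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One guide x construct group: ``mean_indel`` is the configured true
    mean INDEL score (%) of the group; ``suppressed`` marks a group whose
    guide cannot cut (e.g. a seed SNP)."""

    guide: str
    construct: str
    n: int
    mean_indel: float = 80.0
    suppressed: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("per-group n must be >= 1")
        if not (0.0 <= self.mean_indel <= 100.0):
            raise ConfigError("mean_indel must be in [0, 100]")


@dataclass(frozen=True)
class CohortRecord:
    guide_id: str
    construct: str
    root_id: str
    amplicon: Amplicon
    site: GuideSite
    true_spectrum: IndelSpectrum
    control: TraceMatrix
    edited: TraceMatrix


def _wt_range_for_mean(mean_indel: float, half_width: float = 0.1) -> tuple[float, float]:
    center = 1.0 - mean_indel / 100.0
    return (max(0.0, center - half_width), min(1.0, center + half_width))


def simulate_study(
    groups: list[GroupSpec],
    config: RepairSpectrumConfig | None = None,
    *,
    amplicon_length: int = 300,
    gc_fraction: float = 0.45,
    seed: int = 0,
) -> list[CohortRecord]:
    """Simulate a full cohort: one amplicon/guide per guide label, n roots
    per group, each with a true spectrum and a control/edited trace pair.

    Byte-identical output for a fixed seed. Each group's configured mean
    editing level shapes the per-root wild-type fraction so that promoter
    contrasts are recoverable downstream; a suppressed group draws near-100%
    wild-type spectra.
    """
    if config is None:
        config = RepairSpectrumConfig()
    master = np.random.default_rng(seed)
    guide_labels = list(dict.fromkeys(g.guide for g in groups))
    amp_site: dict[str, tuple[Amplicon, GuideSite]] = {}
    for label in guide_labels:
        amp_seed = int(master.integers(2**31 - 1))
        amp = make_amplicon(
            amplicon_length, gc_fraction, amp_seed, amplicon_id=label
        )
        amp_site[label] = (amp, pick_guide(amp))
    records = []
    for grp in groups:
        amp, site = amp_site[grp.guide]
        if grp.suppressed:
            grp_cfg = config.replace(wt_fraction_range=(0.95, 1.0))
        else:
            grp_cfg = config.replace(wt_fraction_range=_wt_range_for_mean(grp.mean_indel))
        for i in range(grp.n):
            root_seed = int(master.integers(2**31 - 1))
            trace_seed = int(master.integers(2**31 - 1))
            spectrum = sample_root_spectrum(grp_cfg, site, root_seed)
            control, edited = synthesize_traces(
                amp, site, spectrum, noise_sd=config.noise_sd, seed=trace_seed
            )
            records.append(
                CohortRecord(
                    guide_id=grp.guide,
                    construct=grp.construct,
                    root_id=f"{grp.guide}_{grp.construct}_r{i:03d}",
                    amplicon=amp,
                    site=site,
                    true_spectrum=spectrum,
                    control=control,
                    edited=edited,
                )
            )
    return records
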