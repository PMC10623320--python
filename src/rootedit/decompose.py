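"""Indel-spectrum estimation from a paired control/edited trace by
non-negative least squares over indel-shifted templates.

The edited trace downstream of the cut is modelled as a non-negative
mixture of templates, one per indel size in {-max_indel..+max_indel}
(0 = wild type). Each template is the control trace shifted by the indel:
deletions shift it left, insertions shift it right. The fit window starts
``max_indel`` positions after the cut (so every template is fully defined
by control rows) and ends ``max_indel`` before the read end; this
deterministic rule replaces an interactively chosen window for the sake of
reproducibility.

Per-size significance is obtained by refitting the active (non-zero) NNLS
coefficients by ordinary least squares and applying a two-sided t-test of
each coefficient against zero. This is a standard, testable stand-in for
per-indel significance on constrained fits; the subtleties of inference on
the non-negativity boundary are documented, not modelled (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import IndelEvent, IndelSpectrum, Thresholds
from .simulate import TraceMatrix

__all__ = [
    "UndefinedFitError",
    "DecompositionResult",
    "QcRejection",
    "build_templates",
    "decompose",
    "filter_spectrum",
]

_COEF_TOL = 1e-9  # relative coefficient threshold for the active set


class UndefinedFitError(ValueError):
    """The fit window carries no signal variance (degenerate input)."""


@dataclass(frozen=True)
class DecompositionResult:
    """One root's fitted spectrum with fit QC.

    ``spectrum`` holds every fitted indel with its percentage and p-value
    (unfiltered); ``r_squared`` is 1 - SS_res/SS_tot over the fit window.
    """

    spectrum: IndelSpectrum
    r_squared: float
    window: tuple[int, int]

    def p_values(self) -> dict[int, float]:
        return {e.size: e.p_value for e in self.spectrum}


@dataclass(frozen=True)
class QcRejection:
    """Typed whole-root rejection (not an error): the proposed indel
    distribution did not fit the trace well enough."""

    reason: str
    r_squared: float


def build_templates(
    control: TraceMatrix, cut_pos: int, max_indel: int
) -> tuple[np.ndarray, np.ndarray]:
    """Return (sizes, templates) with templates[i] the full-length expected
    trace for indel size sizes[i].

    Deletion templates shift the control left by |size| from the cut;
    insertion templates shift right, with inserted positions set to uniform
    0.25 (inserted bases are not resolvable from a mixed trace). Positions
    reading past the template end are uniform.
    """
    ctrl = control.values
    n = ctrl.shape[0]
    if cut_pos + max_indel >= n:
        raise ValueError("read too short for the requested indel window")
    sizes = np.arange(-max_indel, max_indel + 1)
    templates = np.empty((sizes.size, n, 4))
    for i, size in enumerate(sizes):
        t = np.full((n, 4), 0.25)
        t[:cut_pos] = ctrl[:cut_pos]
        if size == 0:
            t = ctrl.copy()
        elif size < 0:
            d = -size
            avail = n - cut_pos - d
            if avail > 0:
                t[cut_pos : cut_pos + avail] = ctrl[cut_pos + d :]
        else:
            t[cut_pos + size :] = ctrl[cut_pos : n - size]
        templates[i] = t
    return sizes, templates


def _ols_p_values(X: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values of unconstrained OLS coefficients."""
    nobs, k = X.shape
    beta, *_ = np.linalg.lstsq(X, b, rcond=None)
    resid = b - X @ beta
    dfree = nobs - k
    if dfree <= 0:
        return np.ones(k)
    sigma2 = float(resid @ resid) / dfree
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(tvals), dfree)
    return np.where(np.isnan(p), 1.0, p)


def decompose(
    control: TraceMatrix,
    edited: TraceMatrix,
    cut_pos: int,
    thresholds: Thresholds | None = None,
) -> DecompositionResult:
    """Fit the edited trace as a non-negative mixture of indel templates.

    Coefficients are normalized to percentages summing to 100; per-size
    p-values come from an OLS refit of the active set; R² is computed over
    the flattened fit window.
    """
    if thresholds is None:
        thresholds = Thresholds()
    if len(control) != len(edited):
        raise ValueError("control and edited traces must have equal length")
    max_indel = thresholds.max_indel
    n = len(control)
    start = cut_pos + max_indel
    end = n - max_indel
    if end - start < 2:
        raise ValueError(
            f"fit window [{start}, {end}) too short; need a longer read"
        )
    sizes, templates = build_templates(control, cut_pos, max_indel)
    A = templates[:, start:end, :].reshape(sizes.size, -1).T
    b = edited.values[start:end].ravel()
    ss_tot = float(((b - b.mean()) ** 2).sum())
    if ss_tot == 0:
        raise UndefinedFitError("no signal variance in the fit window")
    coef, rnorm = optimize.nnls(A, b)
    total = coef.sum()
    if total <= 0:
        raise UndefinedFitError("all mixture coefficients are zero")
    pct = 100.0 * coef / total
    r2 = float(np.clip(1.0 - rnorm**2 / ss_tot, 0.0, 1.0))

    active = coef > _COEF_TOL * total
    p_by_size = {int(s): 1.0 for s in sizes}
    if active.any():
        p_active = _ols_p_values(A[:, active], b)
        for s, p in zip(sizes[active], p_active):
            p_by_size[int(s)] = float(p)

    events = [
        IndelEvent(size=int(s), percentage=float(p), p_value=p_by_size[int(s)])
        for s, p in zip(sizes, pct)
        if s != 0 and p > 1e-6
    ]
    wt = float(pct[sizes == 0][0])
    spectrum = IndelSpectrum(events=events, wt_percentage=wt)
    return DecompositionResult(spectrum=spectrum, r_squared=r2, window=(start, end))


def filter_spectrum(
    result: DecompositionResult, thresholds: Thresholds | None = None
) -> IndelSpectrum | QcRejection:
    """Apply the study QC: reject the whole root when R² <= r2_cut,
    otherwise keep only indels with p-value below p_cut."""
    if thresholds is None:
        thresholds = Thresholds()
    if result.r_squared <= thresholds.r2_cut:
        return QcRejection(reason="r_squared", r_squared=result.r_squared)
    kept = [
        e
        for e in result.spectrum
        if e.p_value is not None and e.p_value < thresholds.p_cut
    ]
    return IndelSpectrum(events=kept, wt_percentage=result.spectrum.wt_percentage)
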