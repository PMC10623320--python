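"""Prediction-vs-observation concordance: which observed dominant indels a
repair model's top-k list matched, and whether pooled 1-bp insertion bases
match the -4 template.

Matching is by signed indel size (published top-5 lists carry no base
identity; a model may predict the same size several times with different
bases, which collapses to one size here). A strict mode matching insertion
bases too is available for synthetic ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .predict import PredictionEntry

__all__ = [
    "ConcordanceRow",
    "InsertionConcordance",
    "match_indels",
    "insertion_concordance",
    "concordance_report",
]

IndelKey = tuple[int, "str | None"]


def _as_key(item) -> IndelKey:
    if isinstance(item, tuple):
        return (int(item[0]), item[1])
    return (int(item), None)


def match_indels(
    observed,
    predicted,
    *,
    strict_bases: bool = False,
) -> set:
    """Intersect observed dominant indels with a predicted top-k list.

    ``observed`` is a collection of signed sizes or (size, bases) keys;
    ``predicted`` a list of signed sizes, (size, base) pairs or
    :class:`PredictionEntry`. Predicted entries are deduplicated by signed
    size before matching; the matched set is returned on the same key type
    as ``observed``. Order-independent.
    """
    obs_keys = [_as_key(o) for o in observed]
    pred_keys = set()
    for p in predicted:
        if isinstance(p, PredictionEntry):
            pred_keys.add((p.size, p.inserted_base))
        else:
            pred_keys.add(_as_key(p))
    if strict_bases:
        matched_keys = {k for k in obs_keys if k in pred_keys}
    else:
        pred_sizes = {k[0] for k in pred_keys}
        matched_keys = {k for k in obs_keys if k[0] in pred_sizes}
    # return matches in the caller's original representation
    out = set()
    for orig, key in zip(list(observed), obs_keys):
        if key in matched_keys:
            out.add(orig)
    return out


@dataclass(frozen=True)
class InsertionConcordance:
    """Pooled 1-bp insertion bases vs the -4 template base."""

    template_base: str
    match: bool
    matching_fraction: float  # % of insertion mass on the template base


def insertion_concordance(
    observed_insertion_bases: dict[str, float], template_base: str
) -> InsertionConcordance | None:
    """Does the most frequent observed 1-bp insertion base equal the -4
    template base, and how much insertion mass sits on it? Returns None
    when no insertions were observed."""
    if not observed_insertion_bases:
        return None
    total = sum(observed_insertion_bases.values())
    if total > 100.0 + 0.5:
        raise ValueError("observed insertion percentages exceed 100")
    top = max(sorted(observed_insertion_bases), key=observed_insertion_bases.get)
    return InsertionConcordance(
        template_base=template_base,
        match=top == template_base,
        matching_fraction=observed_insertion_bases.get(template_base, 0.0),
    )


@dataclass(frozen=True)
class ConcordanceRow:
    guide_id: str
    model: str
    observed_dominant: tuple
    predicted: tuple
    matched: tuple
    matched_count: int
    insertion_match: bool | None
    insertion_matching_fraction: float | None
    note: str = ""


def concordance_report(
    observed_by_guide: dict[str, list],
    predictions_by_guide: dict[str, dict[str, list]],
    insertions_by_guide: dict[str, dict[str, float]] | None = None,
    template_by_guide: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per guide x model, ordered by guide then model.

    A guide with no prediction for a model yields a warning row rather than
    a failure. Insertion concordance is filled when pooled 1-bp insertion
    bases and template bases are supplied.
    """
    rows = []
    for guide_id in sorted(observed_by_guide):
        observed = tuple(observed_by_guide[guide_id])
        models = predictions_by_guide.get(guide_id, {})
        ins_cc = None
        if insertions_by_guide and template_by_guide and guide_id in template_by_guide:
            ins_cc = insertion_concordance(
                insertions_by_guide.get(guide_id, {}), template_by_guide[guide_id]
            )
        if not models:
            warnings.warn(f"no predictions for guide {guide_id!r}", stacklevel=2)
        for model in sorted(models) or ["(none)"]:
            predicted = tuple(models.get(model, ()))
            if model == "(none)":
                row = ConcordanceRow(
                    guide_id=guide_id, model=model, observed_dominant=observed,
                    predicted=(), matched=(), matched_count=0,
                    insertion_match=ins_cc.match if ins_cc else None,
                    insertion_matching_fraction=(
                        ins_cc.matching_fraction if ins_cc else None
                    ),
                    note="missing prediction",
                )
            else:
                matched = match_indels(observed, predicted)
                row = ConcordanceRow(
                    guide_id=guide_id, model=model, observed_dominant=observed,
                    predicted=predicted,
                    matched=tuple(sorted(matched, key=_as_key)),
                    matched_count=len(matched),
                    insertion_match=ins_cc.match if ins_cc else None,
                    insertion_matching_fraction=(
                        ins_cc.matching_fraction if ins_cc else None
                    ),
                )
            rows.append(row)
    return pd.DataFrame([r.__dict__ for r in rows])
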