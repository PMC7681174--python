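"""Two-informant trait scoring and intersubject dissimilarity models.

A cohort's callous-unemotional (CU) traits are measured with an ordinal
questionnaire (by default 24 items on a 0-3 scale, the standard ICU layout)
answered by two informants, the adolescent and a parent.  Scoring follows
the convention of taking, for every item, the highest response given by
either informant; an item one informant skipped falls back to the other
informant's answer, and an item both skipped is imputed as the mean of the
subject's remaining items.  Totals and subscale sums feed three intersubject
dissimilarity models:

``low_alike``
    Anna Karenina model in which low scorers are predicted to be mutually
    similar: d_ij = max(s_i, s_j) on max-normalized scores.
``high_alike``
    The mirror image: d_ij = 1 - min(s_i, s_j).
``nn_abs``
    Nearest-neighbors model: d_ij = |s_i - s_j|; similarity is relative,
    not anchored to either end of the scale.
``nn_euclid``
    Item-wise nearest-neighbors variant: Euclidean distance between the two
    subjects' raw combined item-response vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError, InputError

MODEL_KINDS = ("low_alike", "high_alike", "nn_abs", "nn_euclid")

#: Default subscale layout of the 24-item ICU (0-based item indices).
ICU_SUBSCALES: Mapping[str, tuple[int, ...]] = {
    "callousness": (1, 3, 6, 7, 8, 9, 10, 11, 17, 19, 20),
    "uncaring": (2, 4, 12, 14, 15, 16, 22, 23),
    "unemotional": (0, 5, 13, 18, 21),
}

DEFAULT_N_ITEMS = 24
DEFAULT_LEVELS = 4


def parse_response_cell(cell) -> frozenset[int] | None:
    """Parse one table cell into a set of marked responses.

    Blank / NaN means missing (``None``); ``"2"`` a single response;
    ``"0|1"`` a multi-marked response (the informant ticked both boxes).
    """
    if cell is None:
        return None
    if isinstance(cell, (float, np.floating)):
        if np.isnan(cell):
            return None
        cell = int(cell)
    if isinstance(cell, (int, np.integer)):
        return frozenset([int(cell)])
    s = str(cell).strip()
    if not s or s.lower() == "nan":
        return None
    try:
        return frozenset(int(float(tok)) for tok in s.split("|"))
    except ValueError as exc:
        raise InputError(f"unparseable item response {cell!r}") from exc


def _as_response_sets(vec: Sequence, levels: int) -> list[frozenset[int] | None]:
    out: list[frozenset[int] | None] = []
    for x in vec:
        if x is None or (isinstance(x, float) and np.isnan(x)):
            out.append(None)
        elif isinstance(x, (int, np.integer)):
            out.append(frozenset([int(x)]))
        elif isinstance(x, (frozenset, set, tuple, list)):
            out.append(frozenset(int(v) for v in x))
        else:
            out.append(parse_response_cell(x))
    for s in out:
        if s is not None and any(v < 0 or v >= levels for v in s):
            raise InputError(
                f"item response {sorted(s)} outside 0..{levels - 1}"
            )
    return out


def combine_informant_items(
    child: Sequence,
    parent: Sequence,
    levels: int = DEFAULT_LEVELS,
) -> tuple[np.ndarray, np.ndarray]:
    """Combine two informants' item responses by the maximum rule.

    Each entry may be an integer response, a set of marked responses, or
    missing (None/NaN/blank).  The combined response is the maximum over
    every response marked by either informant; a multi-marked entry
    contributes its highest marked box.  Items missing from both informants
    are flagged for imputation rather than dropped.

    Returns ``(combined, flagged)`` where ``combined`` is a float vector
    (NaN at flagged positions) and ``flagged`` a boolean vector.
    """
    c = _as_response_sets(child, levels)
    p = _as_response_sets(parent, levels)
    if len(c) != len(p):
        raise InputError(
            f"informant vectors differ in length ({len(c)} vs {len(p)})"
        )
    combined = np.full(len(c), np.nan)
    flagged = np.zeros(len(c), dtype=bool)
    for i, (ci, pi) in enumerate(zip(c, p)):
        marked = (ci or frozenset()) | (pi or frozenset())
        if marked:
            combined[i] = max(marked)
        else:
            flagged[i] = True
    return combined, flagged


def impute_flagged_items(
    combined: np.ndarray,
    flagged: np.ndarray | None = None,
    max_flagged_fraction: float = 0.25,
) -> np.ndarray:
    """Replace flagged items by the mean of the subject's remaining items.

    The imputed value is real-valued (not re-rounded to the ordinal scale).
    """
    combined = np.asarray(combined, dtype=float)
    if flagged is None:
        flagged = np.isnan(combined)
    flagged = np.asarray(flagged, dtype=bool)
    if flagged.all():
        raise InputError("all items flagged; nothing to impute from")
    if flagged.sum() > max_flagged_fraction * flagged.size:
        raise InputError(
            f"{int(flagged.sum())}/{flagged.size} items flagged exceeds the "
            f"allowed fraction {max_flagged_fraction}"
        )
    out = combined.copy()
    out[flagged] = combined[~flagged].mean()
    return out


@dataclass
class TraitProfile:
    """One subject's questionnaire data, combined items and scores."""

    subject_id: str
    child_items: Sequence
    parent_items: Sequence
    combined_items: np.ndarray | None = None
    total: float | None = None
    subscale_scores: dict[str, float] = field(default_factory=dict)
    age: float | None = None
    gender: int | None = None
    iq: float | None = None
    n_imputed: int = 0


def score_profile(
    profile: TraitProfile,
    subscale_map: Mapping[str, Iterable[int]] = ICU_SUBSCALES,
    levels: int = DEFAULT_LEVELS,
) -> TraitProfile:
    """Combine informants, impute, and fill total and subscale sums."""
    combined, flagged = combine_informant_items(
        profile.child_items, profile.parent_items, levels=levels
    )
    if flagged.any():
        combined = impute_flagged_items(combined, flagged)
    n_items = combined.size
    for name, idx in subscale_map.items():
        idx = tuple(idx)
        if any(i < 0 or i >= n_items for i in idx):
            raise ConfigError(
                f"subscale {name!r} references an item outside 0..{n_items - 1}"
            )
    profile.combined_items = combined
    profile.n_imputed = int(flagged.sum())
    profile.total = float(combined.sum())
    profile.subscale_scores = {
        name: float(combined[list(idx)].sum())
        for name, idx in subscale_map.items()
    }
    return profile


@dataclass
class ScoreVector:
    """Per-subject scores and their max-normalized counterpart s_i."""

    subject_order: list[str]
    values: np.ndarray
    normalized: np.ndarray
    norm_max: float


def normalize_scores(
    values: Sequence[float], subject_order: Sequence[str] | None = None
) -> ScoreVector:
    """Normalize scores relative to the in-sample maximum.

    s_i = values_i / max(values); errors on negative or all-zero input
    (the intersubject models are degenerate without score spread).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InputError("need at least 2 subjects")
    if (v < 0).any():
        raise InputError("scores must be non-negative")
    vmax = v.max()
    if vmax <= 0:
        raise DegenerateDataError("all scores are zero; cannot normalize")
    if subject_order is None:
        subject_order = [f"sub-{i:02d}" for i in range(v.size)]
    return ScoreVector(
        subject_order=list(subject_order),
        values=v,
        normalized=v / vmax,
        norm_max=float(vmax),
    )


@dataclass
class IntersubjectModel:
    """n x n symmetric trait-dissimilarity matrix with its model kind."""

    kind: str
    matrix: np.ndarray
    subject_order: list[str]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_model(
    scores: ScoreVector | np.ndarray,
    kind: str,
    subject_order: Sequence[str] | None = None,
    normalize_items: bool = False,
) -> IntersubjectModel:
    """Build an intersubject dissimilarity model matrix.

    ``low_alike``, ``high_alike`` and ``nn_abs`` take a :class:`ScoreVector`
    (normalized summary scores); ``nn_euclid`` takes a subjects x items
    matrix of raw combined responses (optionally max-normalized per item
    when ``normalize_items`` is set, for sensitivity analyses).
    """
    if kind not in MODEL_KINDS:
        raise ConfigError(f"unknown model kind {kind!r}; expected {MODEL_KINDS}")
    if kind == "nn_euclid":
        items = np.asarray(scores, dtype=float)
        if items.ndim != 2:
            raise InputError("nn_euclid requires a subjects x items matrix")
        if not np.isfinite(items).all():
            raise InputError("nn_euclid requires complete item responses")
        if normalize_items:
            colmax = items.max(axis=0)
            items = items / np.where(colmax > 0, colmax, 1.0)
        diff = items[:, None, :] - items[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        order = (
            list(subject_order)
            if subject_order is not None
            else [f"sub-{i:02d}" for i in range(items.shape[0])]
        )
        return IntersubjectModel(kind=kind, matrix=d, subject_order=order)

    if not isinstance(scores, ScoreVector):
        scores = normalize_scores(np.asarray(scores), subject_order)
    s = scores.normalized
    if kind == "low_alike":
        d = np.maximum.outer(s, s)
    elif kind == "high_alike":
        d = 1.0 - np.minimum.outer(s, s)
    else:  # nn_abs
        d = np.abs(np.subtract.outer(s, s))
    return IntersubjectModel(
        kind=kind, matrix=d, subject_order=list(scores.subject_order)
    )


def n_pairs(n: int) -> int:
    """Number of unordered subject pairs, n(n-1)/2 (30 subjects -> 435)."""
    if n < 2:
        raise InputError("need at least 2 subjects to form pairs")
    return n * (n - 1) // 2


def score_cohort(
    table: pd.DataFrame,
    subscale_map: Mapping[str, Iterable[int]] = ICU_SUBSCALES,
    n_items: int = DEFAULT_N_ITEMS,
    levels: int = DEFAULT_LEVELS,
) -> tuple[pd.DataFrame, dict]:
    """Score a long-format subject table (one row per subject x informant).

    Expected columns: ``subject_id``, ``informant`` in {child, parent},
    ``item_1`` .. ``item_K`` (blank = missing, ``a|b`` = multi-marked),
    ``age``, ``gender``, ``iq``; optional boolean exclusion-flag columns
    (any column ending in ``_excluded``) propagate to the manifest's
    accounting and drop the subject from the scored output.

    Returns the scored wide table (one row per retained subject) and a
    manifest dict with cohort accounting (recruited, excluded per reason,
    analyzed) and imputation counts.
    """
    if table.empty:
        raise InputError("empty subject table")
    item_cols = [f"item_{i}" for i in range(1, n_items + 1)]
    missing_cols = [c for c in ["subject_id", "informant", *item_cols] if c not in table.columns]
    if missing_cols:
        raise InputError(f"subject table lacks columns: {missing_cols}")

    excl_cols = [c for c in table.columns if c.endswith("_excluded")]
    records = []
    excluded: dict[str, int] = {c[: -len("_excluded")]: 0 for c in excl_cols}
    n_recruited = table["subject_id"].nunique()
    n_imputed_items = 0

    for sid, grp in table.groupby("subject_id", sort=True):
        flags = [c for c in excl_cols if bool(grp[c].any())]
        if flags:
            # first listed reason wins for the accounting, mirroring
            # sequential exclusion of a recruited cohort
            excluded[flags[0][: -len("_excluded")]] += 1
            continue
        by_inf = {str(r["informant"]): r for _, r in grp.iterrows()}
        if not {"child", "parent"} & set(by_inf):
            raise InputError(f"subject {sid!r} has no informant rows")
        blank = [None] * n_items
        child = [by_inf["child"][c] for c in item_cols] if "child" in by_inf else blank
        parent = [by_inf["parent"][c] for c in item_cols] if "parent" in by_inf else blank
        anyrow = next(iter(by_inf.values()))
        prof = TraitProfile(
            subject_id=str(sid),
            child_items=child,
            parent_items=parent,
            age=float(anyrow["age"]) if "age" in anyrow else None,
            gender=int(anyrow["gender"]) if "gender" in anyrow else None,
            iq=float(anyrow["iq"]) if "iq" in anyrow else None,
        )
        score_profile(prof, subscale_map=subscale_map, levels=levels)
        n_imputed_items += prof.n_imputed
        rec = {
            "subject_id": prof.subject_id,
            "total": prof.total,
            **{name: prof.subscale_scores[name] for name in subscale_map},
            "age": prof.age,
            "gender": prof.gender,
            "iq": prof.iq,
            "n_imputed": prof.n_imputed,
        }
        for i, v in enumerate(prof.combined_items, start=1):
            rec[f"combined_item_{i}"] = v
        records.append(rec)

    scored = pd.DataFrame.from_records(records)
    manifest = {
        "n_recruited": int(n_recruited),
        "n_excluded": {k: int(v) for k, v in excluded.items()},
        "n_analyzed": int(len(scored)),
        "n_imputed_items": int(n_imputed_items),
        "n_items": n_items,
        "levels": levels,
        "subscales": {k: list(map(int, v)) for k, v in subscale_map.items()},
    }
    return scored, manifest
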