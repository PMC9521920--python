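"""Two-stage hypothesis-representative predictor selection.

Each biological hypothesis (winter severity, spring bottleneck, maternal
carryover, predation, timber harvest) is measured by several intercorrelated
candidate predictors. Stage one screens every candidate with a univariate
regression against the response and keeps, per hypothesis, the candidate
with the greatest R². Stage two enforces |r| ≤ 0.7 between chosen
predictors: conflicting choices are replaced by the hypothesis's next-best
candidates so as to retain the maximum number of hypotheses, breaking
residual ties by total R². For realistic candidate counts the rule is made
deterministic by exhaustive search over per-hypothesis candidate choices.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    chosen: dict[str, str]              # hypothesis -> predictor
    r2_table: pd.Series                 # predictor -> univariate R²
    correlation: pd.DataFrame
    substitutions: list[str] = field(default_factory=list)
    dropped_hypotheses: list[str] = field(default_factory=list)


def univariate_r2_screen(
    response: pd.Series, predictors: pd.DataFrame, min_overlap: int = 3
) -> pd.Series:
    """Univariate OLS R² of the response on each predictor separately.

    Computed over the years where both the response and that predictor are
    present; predictors with fewer than `min_overlap` overlapping years are
    skipped with a warning.
    """
    out = {}
    for name in predictors.columns:
        joined = pd.concat([response, predictors[name]], axis=1).dropna()
        if len(joined) < min_overlap:
            log.warning("skipping %s: only %d overlapping years", name, len(joined))
            continue
        res = stats.linregress(joined.iloc[:, 1], joined.iloc[:, 0])
        out[name] = res.rvalue**2
    return pd.Series(out, name="r2")


def pairwise_correlation(predictors: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between predictors over pairwise-complete cases."""
    return predictors.corr(method="pearson")


def select_representatives(
    r2: pd.Series,
    hypotheses: dict[str, list[str]],
    corr: pd.DataFrame,
    threshold: float = 0.7,
    max_exhaustive: int = 20000,
) -> SelectionResult:
    """Pick one predictor per hypothesis with pairwise |r| ≤ threshold.

    Objective (lexicographic): most hypotheses retained, then greatest total
    R², then lexicographically smallest predictor names (deterministic
    tie-break). Candidates missing from the R² table are ignored; a
    hypothesis whose candidates are exhausted is dropped and logged.
    """
    cand_lists: dict[str, list[str]] = {}
    for hyp, cands in hypotheses.items():
        ranked = sorted(
            (c for c in cands if c in r2.index and np.isfinite(r2[c])),
            key=lambda c: (-r2[c], c),
        )
        if ranked:
            cand_lists[hyp] = ranked
        else:
            log.warning("hypothesis %r has no screenable candidates", hyp)

    hyp_names = sorted(cand_lists)
    options = [cand_lists[h] + [None] for h in hyp_names]
    n_combos = int(np.prod([len(o) for o in options]))
    if n_combos > max_exhaustive:
        raise ValueError(
            f"{n_combos} candidate combinations exceed the exhaustive-search cap"
        )

    def _ok(combo: tuple[str | None, ...]) -> bool:
        chosen = [c for c in combo if c is not None]
        for a, b in itertools.combinations(chosen, 2):
            r = corr.loc[a, b] if (a in corr.index and b in corr.columns) else np.nan
            if np.isfinite(r) and abs(r) > threshold:
                return False
        return True

    best = None
    best_key = None
    for combo in itertools.product(*options):
        if not _ok(combo):
            continue
        kept = sum(c is not None for c in combo)
        total = sum(r2[c] for c in combo if c is not None)
        names = tuple(c if c is not None else "~" for c in combo)
        key = (-kept, -total, names)
        if best_key is None or key < best_key:
            best_key = key
            best = combo

    chosen = {h: c for h, c in zip(hyp_names, best) if c is not None}
    dropped = [h for h, c in zip(hyp_names, best) if c is None]
    subs = []
    for h, c in chosen.items():
        top = cand_lists[h][0]
        if c != top:
            subs.append(
                f"{h}: replaced top candidate {top!r} (R²={r2[top]:.3f}) with "
                f"{c!r} (R²={r2[c]:.3f}) to satisfy |r| <= {threshold}"
            )
    for h in dropped:
        log.warning("hypothesis %r dropped: candidates exhausted by the "
                    "correlation constraint", h)
    for s in subs:
        log.info(s)
    return SelectionResult(chosen, r2, corr, subs, dropped)
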