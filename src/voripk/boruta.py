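"""All-relevant feature selection with shadow features (Boruta).

Each iteration appends a permuted "shadow" copy of every live feature,
fits a random-forest regressor, and records a hit for any real feature
whose importance beats the best shadow.  Hit counts are tested against
Binomial(n, 1/2) two-sided with a Bonferroni divisor equal to the number
of original candidates; significance at the corrected level confirms
(above) or rejects (below) the feature.  Rejected features leave the
design matrix (the canonical algorithm); confirmed ones stay so their
interactions keep competing.  Default run length 200 iterations at a
corrected p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestRegressor

from .structural import ConfigError, DataError

__all__ = ["BorutaResult", "shadow_augment", "boruta_run", "resolve_tentative"]


@dataclass
class BorutaResult:
    decisions: dict[str, str]  # feature -> confirmed | rejected | tentative
    hit_counts: dict[str, int]
    n_iterations_run: int
    importance_history: pd.DataFrame  # iterations x (features + 'shadow_max')

    @property
    def confirmed(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "confirmed"]

    @property
    def rejected(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "rejected"]

    @property
    def tentative(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "tentative"]

    def to_frame(self) -> pd.DataFrame:
        med = self.importance_history.median()
        return pd.DataFrame(
            {
                "feature": list(self.decisions),
                "decision": [self.decisions[f] for f in self.decisions],
                "hit_count": [self.hit_counts[f] for f in self.decisions],
                "median_importance": [med.get(f, np.nan) for f in self.decisions],
            }
        )


def shadow_augment(X: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Append one independently permuted shadow copy of every column."""
    if X.shape[1] < 1 or X.shape[0] < 5:
        raise DataError("need at least 1 feature and 5 rows")
    out = X.copy()
    for col in X.columns:
        out[f"shadow_{col}"] = rng.permutation(X[col].to_numpy())
    return out


def _decide(hits: int, n_done: int, n_bonf: int, alpha: float) -> str:
    test = binomtest(hits, n_done, 0.5, alternative="two-sided")
    if test.pvalue * n_bonf >= alpha:
        return "tentative"
    return "confirmed" if hits > n_done / 2 else "rejected"


def boruta_run(
    X: pd.DataFrame,
    y,
    n_iter: int = 200,
    alpha: float = 0.01,
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: int | None = 5,
    early_stop: bool = True,
    min_iter_before_test: int = 5,
    drop_rejected: bool = True,
) -> BorutaResult:
    """Run the shadow-feature selection loop over a candidate matrix.

    Deterministic for a given seed: per-iteration permutation and forest
    seeds are spawned from the master seed.  With ``early_stop`` the loop
    ends as soon as no feature is tentative.  The forest is depth-limited
    by default: unlimited-depth impurity importance credits spuriously
    correlated noise features at deep splits, inflating false
    confirmations; shallow trees keep the shadow contest honest.
    """
    if len(X) != len(y):
        raise DataError("X rows and y length differ")
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    y = np.asarray(y, dtype=float)
    features = list(X.columns)
    n_bonf = len(features)
    rng = np.random.default_rng(seed)

    decisions = {f: "tentative" for f in features}
    hits = {f: 0 for f in features}
    live = list(features)
    history = []
    n_done = 0

    for it in range(n_iter):
        active = [f for f in live
                  if not (drop_rejected and decisions[f] == "rejected")]
        if not active:
            break
        for attempt in range(3):
            # shadows are drawn from the full original candidate set so the
            # max-shadow bar does not drop as rejections accumulate
            aug = X[active].copy()
            for col in features:
                aug[f"shadow_{col}"] = rng.permutation(X[col].to_numpy())
            forest = RandomForestRegressor(
                n_estimators=n_estimators,
                max_depth=max_depth,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            try:
                forest.fit(aug.to_numpy(), y)
                break
            except Exception:  # pragma: no cover - retry contract
                if attempt == 2:
                    raise
        imp = pd.Series(forest.feature_importances_, index=aug.columns)
        shadow_max = imp[[c for c in aug.columns if c.startswith("shadow_")]].max()
        n_done += 1
        rec = {"iteration": it, "shadow_max": shadow_max}
        for f in active:
            rec[f] = imp[f]
            if imp[f] > shadow_max:
                hits[f] += 1
        history.append(rec)

        if n_done >= min_iter_before_test:
            for f in active:
                if decisions[f] == "tentative":
                    decisions[f] = _decide(hits[f], n_done, n_bonf, alpha)
        if early_stop and all(d != "tentative" for d in decisions.values()):
            break

    return BorutaResult(
        decisions=decisions,
        hit_counts=hits,
        n_iterations_run=n_done,
        importance_history=pd.DataFrame(history).set_index("iteration"),
    )


def resolve_tentative(result: BorutaResult, X: pd.DataFrame | None = None,
                      y=None) -> BorutaResult:
    """Resolve remaining tentative features from the importance history.

    A tentative feature whose median importance across the run exceeds the
    median of the per-iteration max-shadow importances becomes confirmed;
    otherwise rejected.  Deterministic given a fixed history.
    """
    decisions = dict(result.decisions)
    shadow_med = result.importance_history["shadow_max"].median()
    for f, d in decisions.items():
        if d != "tentative":
            continue
        if f in result.importance_history.columns:
            med = result.importance_history[f].median()
        else:  # pragma: no cover - feature never scored
            med = np.nan
        decisions[f] = "confirmed" if med > shadow_med else "rejected"
    return BorutaResult(
        decisions=decisions,
        hit_counts=dict(result.hit_counts),
        n_iterations_run=result.n_iterations_run,
        importance_history=result.importance_history,
    )
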