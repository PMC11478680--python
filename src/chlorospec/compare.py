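"""Comparative experiment: strategy x transform matrix, transform
shortlisting, water-band effect, leaf-position-aware optimal-model
selection, and the published regression equation.

The optimal-model rule is a bottleneck criterion: strategies are ranked
primarily by hold-out accuracy on the first pair of top leaves — the leaf
position that appears in every drought treatment and is hardest to
predict — and secondarily by the smallest spread of per-position accuracy
(uniformity).  The full criterion trace is returned so the decision is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ComparabilityError, GridError, ParameterError
from .model import AccuracyReport, ChlorophyllPLS, canonical_strategy
from .preprocess import LOG_INV_R, apply_transform
from .spectra import SpectraSet


@dataclass(frozen=True)
class ModelRunSpec:
    """One cell of the comparison matrix."""

    strategy: str
    transform: str | None = None
    index_names: tuple | None = None
    cv_folds: int = 5
    seed: int = 0
    holdout_fraction: float = 0.2
    n_lv: object = "auto"
    max_lv: int = 15


def run_strategy(spec: ModelRunSpec, s: SpectraSet) -> AccuracyReport:
    """Fit one strategy/transform cell and return its AccuracyReport."""
    strategy = canonical_strategy(spec.strategy)
    kwargs = dict(strategy=strategy, n_lv=spec.n_lv, max_lv=spec.max_lv,
                  cv_folds=spec.cv_folds, seed=spec.seed)
    if strategy in ("vi", "vi_l"):
        kwargs["index_names"] = spec.index_names
    else:
        kwargs["transform"] = spec.transform or "R"
    model = ChlorophyllPLS(s, **kwargs)
    return model.fit(holdout_fraction=spec.holdout_fraction).accuracy


def shortlist_transforms(results: dict) -> list:
    """Transforms whose all-band CV accuracy matches or beats the raw
    spectrum, ordered by descending r2_cv; "R" always qualifies.

    ``results`` maps transform name -> CVResult (or any object with
    ``r2_cv``).
    """
    if "R" not in results:
        raise ParameterError('shortlisting needs the raw-spectrum baseline "R"')
    baseline = results["R"].r2_cv
    keep = [(name, res.r2_cv) for name, res in results.items()
            if res.r2_cv >= baseline]
    keep.sort(key=lambda t: (-t[1], t[0]))
    return [name for name, _ in keep]


def select_optimal(reports: dict) -> dict:
    """Rank strategies by the leaf-position bottleneck criterion.

    ``reports`` maps (strategy, transform) -> AccuracyReport, every report
    covering position 1.  Per strategy the best transform is the one with
    the highest r2_cv; across strategies the ranking is by hold-out R2 at
    position 1, ties (within 1e-6) broken by the smallest R2 range across
    positions.  Returns ``{"ranking": [...], "trace": [...]}``.
    """
    by_strategy = {}
    for (strategy, transform), rep in reports.items():
        if 1 not in rep.per_position:
            raise ParameterError(
                f"report {(strategy, transform)} lacks position-1 metrics")
        cur = by_strategy.get(strategy)
        if cur is None or rep.r2_cv > cur[1].r2_cv:
            by_strategy[strategy] = (transform, rep)
    rows = []
    for strategy, (transform, rep) in by_strategy.items():
        rows.append({
            "strategy": strategy,
            "transform": transform,
            "r2_cv": rep.r2_cv,
            "r2_p": rep.r2_p,
            "r2_p_position1": rep.per_position[1]["r2_p"],
            "r2_p_range": rep.r2_p_range,
            "rmse_p_range": rep.rmse_p_range,
        })
    # bottleneck first, uniformity second; quantize the primary criterion
    # so near-ties fall through to the range
    rows.sort(key=lambda r: (-round(r["r2_p_position1"] / 1e-6) * 1e-6,
                             r["r2_p_range"]))
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank
    return {"ranking": [r["strategy"] for r in rows], "trace": rows}


def compare_water_effect(report_ca: AccuracyReport,
                         report_caw: AccuracyReport) -> dict:
    """Percentage change of each accuracy metric when water-window bands
    are added to the correlation-screened predictor set."""
    if (report_ca.cv_k, report_ca.cv_seed) != (report_caw.cv_k, report_caw.cv_seed):
        raise ComparabilityError("reports use different CV folds or seeds")

    def delta(old, new):
        return 100.0 * (new - old) / old

    return {
        "r2_cv_pct": delta(report_ca.r2_cv, report_caw.r2_cv),
        "rmse_cv_pct": delta(report_ca.rmse_cv, report_caw.rmse_cv),
        "r2_p_pct": delta(report_ca.r2_p, report_caw.r2_p),
        "rmse_p_pct": delta(report_ca.rmse_p, report_caw.rmse_p),
    }


# ---------------------------------------------------------------------------
# the published regression equation
# ---------------------------------------------------------------------------

PUBLISHED_BANDS = (547.0, 548.0, 549.0, 550.0, 551.0, 552.0,
                   1464.0, 1465.0, 1933.0, 1944.0)
PUBLISHED_COEFFICIENTS = (57.7898, 18.9012, -151.3200, -103.7400, 39.6828,
                          142.0900, 489.6450, -494.9750, -36.6924, 37.3505)
PUBLISHED_INTERCEPT = 2.1754


@dataclass(frozen=True)
class PublishedModel:
    """The reported optimal ten-band regression for chlorophyll (mg/g).

    The equation is printed in terms of band symbols; whether those stand
    for raw reflectance or the log(1/R)-transformed values is ambiguous in
    the source, so ``input_transform`` selects the interpretation
    (default log(1/R), the transform named as best for this strategy).
    """

    bands: tuple = PUBLISHED_BANDS
    coefficients: tuple = PUBLISHED_COEFFICIENTS
    intercept: float = PUBLISHED_INTERCEPT
    input_transform: str | None = LOG_INV_R

    def __post_init__(self):
        if len(self.bands) != 10 or len(self.coefficients) != 10:
            raise ParameterError("the published model has exactly ten bands")

    def predict_values(self, x) -> np.ndarray:
        """Evaluate the linear form on already-transformed band values."""
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[1] != 10:
            raise ParameterError(f"need 10 band values, got {x.shape[1]}")
        return self.intercept + x @ np.asarray(self.coefficients)


def evaluate_published_model(m: PublishedModel, s: SpectraSet) -> np.ndarray:
    """Apply the published equation to a raw SpectraSet (mg/g output)."""
    for b in m.bands:
        try:
            s.grid.index_of(b)
        except GridError as exc:
            raise GridError(f"published-model band {b:g} nm missing") from exc
    t = apply_transform(m.input_transform, s) if m.input_transform else s
    X = np.column_stack([t.band(b) for b in m.bands])
    return m.predict_values(X)
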