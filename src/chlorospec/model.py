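"""Statsmodels-style modeling surface.

:class:`ChlorophyllPLS` is built from a :class:`~chlorospec.spectra.SpectraSet`
and a predictor-construction strategy; :meth:`ChlorophyllPLS.fit` returns
an :class:`InversionResults` carrying the fitted coefficients, grouped
cross-validation accuracy, hold-out prediction accuracy overall and per
leaf position, and a ``summary()`` table.

Strategies
----------
``ab``   all 2151 transformed bands as predictors (AB-PLS)
``pca``  scores of the eigenvalue>1 principal components (PCA-PLS)
``ca``   top-10 correlation-screened bands (CA-PLS)
``caw``  6 whole-grid + 2x2 water-window bands (CA(W)-PLS)
``vi``   a table of vegetation/water indices, PLS (VI-PLS)
``vi_l`` one to a few indices, ordinary least squares (VI-L)

Every fitted statistic (MSC reference, correlation screening, PCA
rotation, latent-variable count, regression coefficients) is estimated on
training rows only, both inside each CV fold and for the hold-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bands as _bands
from . import indices as _indices
from . import pls as _pls
from .exceptions import ConfigError, EvaluationError
from .preprocess import get_transform
from .spectra import SpectraSet

LOW_N_THRESHOLD = 5

STRATEGY_NAMES = {
    "ab": "AB-PLS", "pca": "PCA-PLS", "ca": "CA-PLS", "caw": "CA(W)-PLS",
    "vi": "VI-PLS", "vi_l": "VI-L",
}
_STRATEGY_ALIASES = {v.lower(): k for k, v in STRATEGY_NAMES.items()}
_STRATEGY_ALIASES.update({"ca(w)-pls": "caw", "caw-pls": "caw", "ab-pls": "ab",
                          "pca-pls": "pca", "ca-pls": "ca", "vi-pls": "vi",
                          "vi-l": "vi_l"})


def canonical_strategy(name: str) -> str:
    key = name.lower()
    key = _STRATEGY_ALIASES.get(key, key)
    if key not in STRATEGY_NAMES:
        raise ConfigError(f"unknown strategy {name!r}")
    return key


# ---------------------------------------------------------------------------
# recipes: fit on training spectra, produce design matrices anywhere
# ---------------------------------------------------------------------------

class _Recipe:
    """One predictor-construction + regression pipeline."""

    def __init__(self, strategy: str, transform: str | None, index_names,
                 n_lv, max_lv: int, inner_folds: int, seed: int,
                 ca_k: int, caw_k_main: int, caw_k_per_window: int,
                 tvi_form: str):
        self.strategy = strategy
        self.transform = transform
        self.index_names = index_names
        self.n_lv = n_lv
        self.max_lv = max_lv
        self.inner_folds = inner_folds
        self.seed = seed
        self.ca_k = ca_k
        self.caw_k_main = caw_k_main
        self.caw_k_per_window = caw_k_per_window
        self.tvi_form = tvi_form
        # fitted state
        self.fitted_transform = None
        self.band_selection = None
        self.pca = None
        self.model = None
        self.n_lv_used = None
        self.training_rows_seen = 0  # leak instrumentation

    def clone(self) -> "_Recipe":
        return _Recipe(self.strategy, self.transform, self.index_names,
                       self.n_lv, self.max_lv, self.inner_folds, self.seed,
                       self.ca_k, self.caw_k_main, self.caw_k_per_window,
                       self.tvi_form)

    # -- design construction ----------------------------------------------
    def _design(self, s: SpectraSet) -> np.ndarray:
        if self.strategy in ("vi", "vi_l"):
            return _indices.compute_index_table(
                s, self.index_names, self.tvi_form).to_numpy(float)
        t = self.fitted_transform.apply(s)
        if self.strategy == "ab":
            return t.reflectance
        if self.strategy == "pca":
            return self.pca.project(t)
        cols = [t.grid.index_of(b) for b in self.band_selection.bands]
        return t.reflectance[:, cols]

    def fit(self, train: SpectraSet) -> "_Recipe":
        self.training_rows_seen += train.n_leaves
        y = train.chlorophyll
        groups = train.records["seedling_id"].to_numpy()
        if self.strategy not in ("vi", "vi_l"):
            self.fitted_transform = get_transform(self.transform).fit(train)
            t = self.fitted_transform.apply(train)
            if self.strategy == "ca":
                profile = _bands.correlation_profile(t, y)
                self.band_selection = _bands.select_top_k(profile, self.ca_k)
            elif self.strategy == "caw":
                profile = _bands.correlation_profile(t, y)
                self.band_selection = _bands.select_with_water(
                    profile, self.caw_k_main,
                    k_per_window=self.caw_k_per_window)
            elif self.strategy == "pca":
                self.pca = _bands.pca_reduce(t)
        X = self._design(train)
        if self.strategy == "vi_l":
            self.model = _pls.fit_linear(X, y)
            self.n_lv_used = X.shape[1]
            return self
        if self.n_lv == "auto":
            n_lv = _pls.choose_n_lv(X, y, k_folds=self.inner_folds,
                                    max_lv=self.max_lv, seed=self.seed,
                                    groups=groups)
        else:
            n_lv = int(self.n_lv)
        self.model = _pls.fit_pls1(X, y, n_lv)
        self.n_lv_used = self.model.n_lv
        return self

    def predict(self, s: SpectraSet) -> np.ndarray:
        return self.model.predict(self._design(s))


# ---------------------------------------------------------------------------
# accuracy containers
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    """Cross-validation and hold-out accuracy, overall and per leaf position."""

    strategy: str
    transform: str | None
    r2_cv: float
    rmse_cv: float
    r2_p: float
    rmse_p: float
    per_position: dict  # position -> {"r2_p", "rmse_p", "n", "low_n"}
    cv_k: int
    cv_seed: int
    split_seed: int
    n_train: int
    n_test: int

    @property
    def r2_p_range(self) -> float:
        vals = [m["r2_p"] for m in self.per_position.values()]
        return float(max(vals) - min(vals)) if vals else 0.0

    @property
    def rmse_p_range(self) -> float:
        vals = [m["rmse_p"] for m in self.per_position.values()]
        return float(max(vals) - min(vals)) if vals else 0.0


def _per_position_metrics(test: SpectraSet, preds: np.ndarray) -> dict:
    out = {}
    pos = test.records["pair_position"].to_numpy()
    y = test.chlorophyll
    for p in sorted(np.unique(pos)):
        mask = pos == p
        out[int(p)] = {
            "r2_p": _pls.r2_score(y[mask], preds[mask]),
            "rmse_p": _pls.rmse(y[mask], preds[mask]),
            "n": int(mask.sum()),
            "low_n": bool(mask.sum() < LOW_N_THRESHOLD),
        }
    return out


def holdout_split(s: SpectraSet, fraction: float = 0.2, seed: int = 0):
    """80/20 split by seedling, stratified by treatment, so every leaf
    position reaches the test set."""
    rng = np.random.default_rng(seed)
    rec = s.records
    test_groups = []
    for t in sorted(rec["treatment"].unique()):
        seedlings = rec.loc[rec["treatment"] == t, "seedling_id"].unique()
        n_test = max(1, int(round(fraction * seedlings.size)))
        test_groups.extend(rng.permutation(seedlings)[:n_test])
    is_test = rec["seedling_id"].isin(test_groups).to_numpy()
    if is_test.all() or not is_test.any():
        raise EvaluationError("degenerate hold-out split")
    return s.subset(~is_test), s.subset(is_test)


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

class ChlorophyllPLS:
    """Chlorophyll-inversion model for a leaf SpectraSet.

    Parameters
    ----------
    spectra : SpectraSet
        Raw reflectance set with chlorophyll metadata (mg/g).
    strategy : str
        Predictor construction: 'ab', 'pca', 'ca', 'caw', 'vi' or 'vi_l'
        (full names like "CA(W)-PLS" are accepted).
    transform : str
        Preprocessing transform name for the band strategies (ignored by
        the index strategies, which always use raw reflectance).
    index_names : sequence of str
        Index columns for 'vi'/'vi_l'.
    n_lv : "auto" or int
        Latent-variable count; "auto" uses inner CV with the 1-SE rule.
    """

    def __init__(self, spectra: SpectraSet, strategy: str = "caw",
                 transform: str = "log(1/R)", index_names=None,
                 n_lv="auto", max_lv: int = 15, cv_folds: int = 5,
                 inner_folds: int = 5, seed: int = 0,
                 tvi_form: str = "literal"):
        self.spectra = spectra
        self.strategy = canonical_strategy(strategy)
        if self.strategy in ("vi", "vi_l"):
            self.transform = None
            self.index_names = tuple(index_names or _indices.CHLOROPHYLL_INDICES)
        else:
            self.transform = get_transform(transform).name
            self.index_names = None
        self.n_lv = n_lv
        self.max_lv = max_lv
        self.cv_folds = cv_folds
        self.inner_folds = inner_folds
        self.seed = seed
        self.tvi_form = tvi_form

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "ChlorophyllPLS":
        """Build from a wide DataFrame (metadata columns + nm columns)."""
        from .spectra import METADATA_COLUMNS, WavelengthGrid

        band_cols = [c for c in frame.columns if c not in METADATA_COLUMNS]
        grid = WavelengthGrid(np.array([float(c) for c in band_cols]))
        s = SpectraSet(grid, frame[band_cols].to_numpy(float),
                       frame[list(METADATA_COLUMNS)].copy())
        return cls(s, **kwargs)

    def _make_recipe(self) -> _Recipe:
        return _Recipe(self.strategy, self.transform, self.index_names,
                       self.n_lv, self.max_lv, self.inner_folds, self.seed,
                       ca_k=10, caw_k_main=6, caw_k_per_window=2,
                       tvi_form=self.tvi_form)

    def fit(self, holdout_fraction: float = 0.2,
            split_seed: int | None = None) -> "InversionResults":
        """Cross-validate on the training seedlings, refit on all of them,
        and score the held-out seedlings overall and per leaf position."""
        split_seed = self.seed if split_seed is None else split_seed
        train, test = holdout_split(self.spectra, holdout_fraction, split_seed)
        if 1 not in set(test.records["pair_position"]):
            raise EvaluationError("hold-out split lost every position-1 leaf")
        cv = _pls.kfold_cv(self._make_recipe(), train, k=self.cv_folds,
                           seed=self.seed)
        final = self._make_recipe().fit(train)
        preds = final.predict(test)
        report = AccuracyReport(
            strategy=STRATEGY_NAMES[self.strategy],
            transform=self.transform,
            r2_cv=cv.r2_cv, rmse_cv=cv.rmse_cv,
            r2_p=_pls.r2_score(test.chlorophyll, preds),
            rmse_p=_pls.rmse(test.chlorophyll, preds),
            per_position=_per_position_metrics(test, preds),
            cv_k=self.cv_folds, cv_seed=self.seed, split_seed=split_seed,
            n_train=train.n_leaves, n_test=test.n_leaves,
        )
        return InversionResults(self, final, cv, report, test, preds)


class InversionResults:
    """Estimates, accuracy diagnostics and summary for a fitted model."""

    def __init__(self, model: ChlorophyllPLS, recipe: _Recipe,
                 cv: _pls.CVResult, accuracy: AccuracyReport,
                 test: SpectraSet, test_predictions: np.ndarray):
        self.model = model
        self.recipe = recipe
        self.cv = cv
        self.accuracy = accuracy
        self.test = test
        self.test_predictions = test_predictions

    @property
    def params(self) -> np.ndarray:
        return self.recipe.model.coefficients

    @property
    def intercept(self) -> float:
        return self.recipe.model.intercept

    @property
    def n_lv(self) -> int:
        return self.recipe.n_lv_used

    @property
    def band_selection(self):
        return self.recipe.band_selection

    @property
    def pca(self):
        return self.recipe.pca

    def predict(self, spectra: SpectraSet) -> np.ndarray:
        """Chlorophyll predictions (mg/g) for new raw spectra."""
        return self.recipe.predict(spectra)

    def per_position_frame(self) -> pd.DataFrame:
        rows = [
            {"pair_position": p, **m}
            for p, m in self.accuracy.per_position.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        a = self.accuracy
        lines = [
            "Chlorophyll inversion results",
            "=" * 46,
            f"strategy:        {a.strategy}",
            f"transform:       {a.transform or ', '.join(self.model.index_names)}",
            f"latent variables: {self.n_lv}",
            f"train/test leaves: {a.n_train}/{a.n_test}",
            f"R2_CV  = {a.r2_cv:.4f}   RMSE_CV = {a.rmse_cv:.4f} mg/g",
            f"R2_P   = {a.r2_p:.4f}   RMSE_P  = {a.rmse_p:.4f} mg/g",
            "per leaf position (hold-out):",
        ]
        for p, m in sorted(a.per_position.items()):
            flag = "  (low n)" if m["low_n"] else ""
            lines.append(
                f"  position {p}: R2_P = {m['r2_p']:.4f}, "
                f"RMSE_P = {m['rmse_p']:.4f}, n = {m['n']}{flag}"
            )
        lines.append(f"R2_P range across positions: {a.r2_p_range:.4f}")
        if self.band_selection is not None:
            sel = self.band_selection
            lines.append("selected bands (nm): "
                         + ", ".join(f"{b:g}" for b in sel.bands))
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Hold-out predicted vs measured chlorophyll scatter."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.test.chlorophyll
        ax.scatter(y, self.test_predictions, s=12, alpha=0.7)
        lo, hi = min(y.min(), self.test_predictions.min()), max(
            y.max(), self.test_predictions.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("measured chlorophyll (mg/g)")
        ax.set_ylabel("predicted chlorophyll (mg/g)")
        ax.set_title(f"{self.accuracy.strategy} hold-out predictions")
        return ax
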