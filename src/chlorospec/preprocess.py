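"""Registry of spectral preprocessing transforms.

Twenty-one named transforms: the identity R plus twenty compositions of
six primitive operators

    d1   first derivative (central differences on the nm grid,
         one-sided at the two endpoint bands)
    d2   second derivative (central second differences, endpoint bands
         copy the nearest interior value)
    sqrt, log10, reciprocal  elementwise maps with domain checks
    snv  per-spectrum standard normal variate (mean 0, sd 1, ddof=1)
    msc  multiplicative scatter correction against a reference spectrum

MSC (and the FD-MSC composite) is the only transform with fitted state:
its reference is the mean spectrum of the TRAINING rows, so held-out
spectra must be corrected with :meth:`TransformSpec.fit` /
:meth:`FittedTransform.apply` rather than refit on the test data.

Log base is 10 (the absorbance convention for log(1/R)); PLS predictions
are invariant to the base.  FD-SNV / FD-MSC take the derivative first.

Note the exact affine relations log(1/R) = -logR and logSqrtR = logR/2:
they make per-band correlation magnitudes, selected band sets and PLS
cross-validation accuracy identical across the three log variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import RegistryError, TransformError
from .spectra import SpectraSet

# canonical unicode names
PRIME = "′"          # ′
DPRIME = "″"         # ″
SQRT = "√"           # √

R = "R"
R1 = f"R{PRIME}"
R2 = f"R{DPRIME}"
SQRT_R = f"{SQRT}R"
D_SQRT_R = f"({SQRT}R){PRIME}"
LOG_R = "logR"
D_LOG_R = f"(logR){PRIME}"
INV_R = "1/R"
D_INV_R = f"(1/R){PRIME}"
LOG_INV_R = "log(1/R)"
D_LOG_INV_R = f"(log(1/R)){PRIME}"
LOG_SQRT_R = f"log{SQRT}R"
D_LOG_SQRT_R = f"(log{SQRT}R){PRIME}"
INV_LOG_R = "1/logR"
D_INV_LOG_R = f"(1/logR){PRIME}"
SQRT_INV_R = f"{SQRT}(1/R)"
D_SQRT_INV_R = f"({SQRT}(1/R)){PRIME}"
SNV = "SNV"
MSC = "MSC"
FD_SNV = "FD-SNV"
FD_MSC = "FD-MSC"

#: transforms whose all-band cross-validation accuracy matched or beat the
#: raw spectrum, and therefore enter the comparison shortlist
SHORTLISTED = (R1, SQRT_R, LOG_R, LOG_INV_R, LOG_SQRT_R, R)

_CHAINS = {
    R: (),
    R1: ("d1",),
    R2: ("d2",),
    SQRT_R: ("sqrt",),
    D_SQRT_R: ("sqrt", "d1"),
    LOG_R: ("log10",),
    D_LOG_R: ("log10", "d1"),
    INV_R: ("reciprocal",),
    D_INV_R: ("reciprocal", "d1"),
    LOG_INV_R: ("reciprocal", "log10"),
    D_LOG_INV_R: ("reciprocal", "log10", "d1"),
    LOG_SQRT_R: ("sqrt", "log10"),
    D_LOG_SQRT_R: ("sqrt", "log10", "d1"),
    INV_LOG_R: ("log10", "reciprocal"),
    D_INV_LOG_R: ("log10", "reciprocal", "d1"),
    SQRT_INV_R: ("reciprocal", "sqrt"),
    D_SQRT_INV_R: ("reciprocal", "sqrt", "d1"),
    SNV: ("snv",),
    MSC: ("msc",),
    FD_SNV: ("d1", "snv"),
    FD_MSC: ("d1", "msc"),
}

CANONICAL_ORDER = tuple(_CHAINS)

ASCII_ALIASES = {
    "R": R, "R1": R1, "R2": R2, "sqrtR": SQRT_R, "d_sqrtR": D_SQRT_R,
    "logR": LOG_R, "d_logR": D_LOG_R, "invR": INV_R, "d_invR": D_INV_R,
    "log_invR": LOG_INV_R, "d_log_invR": D_LOG_INV_R, "log_sqrtR": LOG_SQRT_R,
    "d_log_sqrtR": D_LOG_SQRT_R, "inv_logR": INV_LOG_R, "d_inv_logR": D_INV_LOG_R,
    "sqrt_invR": SQRT_INV_R, "d_sqrt_invR": D_SQRT_INV_R,
    "SNV": SNV, "MSC": MSC, "FD-SNV": FD_SNV, "FD-MSC": FD_MSC,
}


# ---------------------------------------------------------------------------
# primitive operators (stateless; arrays n x p, step in nm)
# ---------------------------------------------------------------------------

def _first_derivative(X: np.ndarray, step: float) -> np.ndarray:
    if X.shape[1] < 3:
        raise TransformError("first derivative needs at least 3 bands")
    return np.gradient(X, step, axis=1, edge_order=1)


def _second_derivative(X: np.ndarray, step: float) -> np.ndarray:
    if X.shape[1] < 3:
        raise TransformError("second derivative needs at least 3 bands")
    out = np.empty_like(X)
    out[:, 1:-1] = (X[:, 2:] - 2.0 * X[:, 1:-1] + X[:, :-2]) / step**2
    out[:, 0] = out[:, 1]
    out[:, -1] = out[:, -2]
    return out


def _check_domain(X: np.ndarray, ok: np.ndarray, op: str, grid_values: np.ndarray):
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise TransformError(
            f"{op}: domain violation at row {int(i)}, wavelength "
            f"{grid_values[j]:g} nm (value {X[i, j]:g})"
        )


def _sqrt(X, grid_values):
    _check_domain(X, X >= 0, "sqrt", grid_values)
    return np.sqrt(X)


def _log10(X, grid_values):
    _check_domain(X, X > 0, "log10", grid_values)
    return np.log10(X)


def _reciprocal(X, grid_values):
    _check_domain(X, X != 0, "reciprocal", grid_values)
    return 1.0 / X


def snv_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise standard normal variate (mean 0, sd 1, ddof=1)."""
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise TransformError(f"SNV: zero-variance row(s) {zero.tolist()}")
    return (X - mean) / sd


def msc_rows(X: np.ndarray, reference: np.ndarray):
    """MSC against a reference: per row fit x ~ a + b*ref by OLS, return
    (x - a)/b along with the fitted (a, b)."""
    ref = np.asarray(reference, float)
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    if denom == 0:
        raise TransformError("MSC: reference spectrum has zero variance")
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(b == 0):
        rows = np.flatnonzero(b == 0)
        raise TransformError(f"MSC: zero slope for row(s) {rows.tolist()}")
    a = X.mean(axis=1) - b * ref.mean()
    corrected = (X - a[:, None]) / b[:, None]
    return corrected, a, b


# ---------------------------------------------------------------------------
# registry objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformSpec:
    """A named, composable preprocessing recipe."""

    name: str
    chain: tuple
    shortlisted: bool = False

    def fit(self, s: SpectraSet) -> "FittedTransform":
        """Estimate any training statistics (the MSC reference) on ``s``."""
        refs = {}
        X = s.reflectance.copy()
        for idx, op in enumerate(self.chain):
            if op == "msc":
                if X.shape[0] < 2:
                    raise TransformError("MSC needs >= 2 training spectra")
                refs[idx] = X.mean(axis=0)
                X, _, _ = msc_rows(X, refs[idx])
            else:
                X = _apply_primitive(op, X, s)
        return FittedTransform(self, refs)

    def __call__(self, s: SpectraSet) -> SpectraSet:
        return self.fit(s).apply(s)


@dataclass(frozen=True)
class FittedTransform:
    """A TransformSpec bound to training statistics."""

    spec: TransformSpec
    msc_references: dict = field(default_factory=dict)

    def apply(self, s: SpectraSet) -> SpectraSet:
        X = s.reflectance.copy()
        for idx, op in enumerate(self.spec.chain):
            if op == "msc":
                X, _, _ = msc_rows(X, self.msc_references[idx])
            else:
                X = _apply_primitive(op, X, s)
        return s.with_values(X, self.spec.name)


def _apply_primitive(op: str, X: np.ndarray, s: SpectraSet) -> np.ndarray:
    gv = s.grid.values
    if op == "d1":
        return _first_derivative(X, s.grid.step_nm)
    if op == "d2":
        return _second_derivative(X, s.grid.step_nm)
    if op == "sqrt":
        return _sqrt(X, gv)
    if op == "log10":
        return _log10(X, gv)
    if op == "reciprocal":
        return _reciprocal(X, gv)
    if op == "snv":
        return snv_rows(X)
    raise RegistryError(f"unknown primitive {op!r}")


_REGISTRY = {
    name: TransformSpec(name, chain, shortlisted=name in SHORTLISTED)
    for name, chain in _CHAINS.items()
}


def get_transform(name: str) -> TransformSpec:
    """Look up a transform by canonical or ASCII-alias name."""
    key = ASCII_ALIASES.get(name, name)
    try:
        return _REGISTRY[key]
    except KeyError:
        raise RegistryError(f"unknown transform {name!r}") from None


def list_transforms() -> list[TransformSpec]:
    """All 21 registered transforms in canonical order."""
    return [_REGISTRY[name] for name in CANONICAL_ORDER]


def apply_transform(name: str, s: SpectraSet,
                    fit_context: FittedTransform | None = None) -> SpectraSet:
    """Apply a registered transform to a whole SpectraSet.

    With ``fit_context`` (a FittedTransform from training data) any MSC
    reference comes from the training rows; otherwise statistics are
    fitted on ``s`` itself.
    """
    spec = get_transform(name)
    if fit_context is not None:
        if fit_context.spec.name != spec.name:
            raise TransformError(
                f"fit_context is for {fit_context.spec.name!r}, not {spec.name!r}"
            )
        return fit_context.apply(s)
    return spec(s)


# convenience wrappers matching the primitive operations ---------------------

def first_derivative(s: SpectraSet) -> SpectraSet:
    return s.with_values(_first_derivative(s.reflectance, s.grid.step_nm),
                         f"{s.transform_tag}{PRIME}")


def second_derivative(s: SpectraSet) -> SpectraSet:
    return s.with_values(_second_derivative(s.reflectance, s.grid.step_nm),
                         f"{s.transform_tag}{DPRIME}")


def snv(s: SpectraSet) -> SpectraSet:
    return s.with_values(snv_rows(s.reflectance), SNV)


def msc(s: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    if reference is None:
        if s.n_leaves < 2:
            raise TransformError("MSC needs >= 2 spectra when no reference is given")
        reference = s.reflectance.mean(axis=0)
    corrected, _, _ = msc_rows(s.reflectance, reference)
    return s.with_values(corrected, MSC)
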