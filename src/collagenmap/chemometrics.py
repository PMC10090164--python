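"""PLS1 regression (NIPALS) with cross-validated complexity selection.

The calibration relates preprocessed NIR spectra (predictor rows) to
reference collagen percentages (single response). Model complexity — the
number of latent variables (LV) — is chosen by cross-validation over five
cancellation groups, taking the lowest root mean square error of
cross-validation (RMSECV); RMSECV has the statistical meaning of a
standard deviation in response units (% collagen). Robustness is probed
two ways: re-randomising the CV group assignment with the X/y pairing
intact (the error should stay at the model error) and permuting y against
X (the error should collapse to the response SD).

The PLS1 NIPALS loop here is non-iterative — for a single response the
weight direction is ``w ∝ Xᵀy`` exactly — and deflates X only, the
standard PLS1 scheme. Mean-centring is recomputed on each training fold
during CV so held-out samples never leak into the centres.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .preprocess import PreprocessRecipe, apply_recipe_matrix

__all__ = [
    "NipalsPLS",
    "CalibrationSample",
    "PLSModel",
    "CVResult",
    "PermutationReport",
    "rmse",
    "fit_pls",
    "cross_validate",
    "permutation_test",
    "default_max_lv",
    "build_design_matrix",
    "fit_calibration",
]


def rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Root mean square difference, in the units of the observations."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("rmse of empty input is undefined")
    if p.size != o.size:
        raise ValueError(f"length mismatch: {p.size} vs {o.size}")
    return float(np.sqrt(np.mean((p - o) ** 2)))


class NipalsPLS(RegressorMixin, BaseEstimator):
    """PLS1 regression fitted by NIPALS with X-only deflation.

    Parameters
    ----------
    n_components
        Number of latent variables. Must satisfy
        ``n_components <= min(n_samples - 1, n_features)``.

    Attributes
    ----------
    x_mean_ : ndarray of shape (n_features,)
        Column means of the training predictors.
    y_mean_ : float
        Mean of the training response.
    x_weights_ : ndarray of shape (n_features, n_components)
        NIPALS weight vectors W (unit norm).
    x_loadings_ : ndarray of shape (n_features, n_components)
        Loadings P.
    y_loadings_ : ndarray of shape (n_components,)
        Response loadings q.
    coef_ : ndarray of shape (n_features,)
        Regression vector in centred feature space,
        ``beta = W (PᵀW)⁻¹ q``.
    x_scores_ : ndarray of shape (n_samples, n_components)
        Training scores T (mutually orthogonal).
    n_components_ : int
        Components actually extracted (may stop early if the predictor
        residual is exhausted).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y) -> "NipalsPLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        n, p = X.shape
        if y.size != n:
            raise ValueError(f"X has {n} rows but y has {y.size}")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite")
        if np.std(y) == 0:
            raise ValueError("zero-variance response: nothing to regress on")
        a_max = min(n - 1, p)
        if not 1 <= self.n_components <= a_max:
            raise ValueError(
                f"n_components={self.n_components} outside [1, {a_max}] for "
                f"{n} samples x {p} features"
            )

        x_mean = X.mean(axis=0)
        y_mean = float(y.mean())
        Xc = X - x_mean
        yc = y - y_mean

        W = np.zeros((p, self.n_components))
        P = np.zeros((p, self.n_components))
        q = np.zeros(self.n_components)
        T = np.zeros((n, self.n_components))
        Xa = Xc.copy()
        a = 0
        for a in range(self.n_components):
            w = Xa.T @ yc
            wnorm = np.linalg.norm(w)
            if wnorm <= 1e-14 * max(1.0, np.linalg.norm(yc)):
                warnings.warn(
                    f"predictor residual exhausted after {a} component(s); "
                    f"stopping early",
                    stacklevel=2,
                )
                break
            w /= wnorm
            t = Xa @ w
            tt = t @ t
            if tt <= 0:
                break
            p_a = Xa.T @ t / tt
            q_a = yc @ t / tt
            Xa -= np.outer(t, p_a)
            W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
            a += 1

        self.n_components_ = a
        self.x_weights_ = W[:, :a]
        self.x_loadings_ = P[:, :a]
        self.y_loadings_ = q[:a]
        self.x_scores_ = T[:, :a]
        self.x_mean_ = x_mean
        self.y_mean_ = y_mean
        self.coef_ = self._coef_for(a)
        self.n_features_in_ = p
        return self

    def _coef_for(self, k: int) -> np.ndarray:
        """Regression vector using the first ``k`` latent variables."""
        if k == 0:
            return np.zeros(self.x_weights_.shape[0])
        Wk = self.x_weights_[:, :k]
        Pk = self.x_loadings_[:, :k]
        qk = self.y_loadings_[:k]
        return Wk @ np.linalg.solve(Pk.T @ Wk, qk)

    def coef_path(self) -> np.ndarray:
        """Regression vectors for 1..n_components_ LVs, shape (p, A)."""
        return np.column_stack(
            [self._coef_for(k) for k in range(1, self.n_components_ + 1)]
        )

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects "
                f"{self.n_features_in_}"
            )
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class CalibrationSample:
    """One bone's representative spectrum plus its reference collagen %."""

    sample_id: str
    form: str
    reference_collagen_pct: float
    profile: np.ndarray

    def __post_init__(self) -> None:
        if self.form not in ("powder", "fragment"):
            raise ValueError(f"form must be powder|fragment, got {self.form!r}")
        if not math.isfinite(self.reference_collagen_pct) or (
            self.reference_collagen_pct < 0
        ):
            raise ValueError("reference collagen % must be finite and >= 0")
        self.profile = np.asarray(self.profile, dtype=float)


@dataclass
class PLSModel:
    """A portable fitted predictor: PLS coefficients + the frozen recipe."""

    estimator: NipalsPLS
    recipe: PreprocessRecipe
    wavelengths: np.ndarray
    training_meta: dict = field(default_factory=dict)

    @property
    def n_lv(self) -> int:
        return self.estimator.n_components_

    def predict(self, x_preprocessed: np.ndarray) -> float:
        """Score one preprocessed feature vector: ŷ = ȳ + (x − x̄)ᵀβ."""
        x = np.asarray(x_preprocessed, dtype=float).ravel()
        if x.size != self.estimator.n_features_in_:
            raise ValueError(
                f"feature length {x.size}; model expects "
                f"{self.estimator.n_features_in_}"
            )
        return float(self.estimator.predict(x[None, :])[0])

    def predict_matrix(self, X_preprocessed: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X_preprocessed)

    def predict_spectrum(self, spectrum: np.ndarray) -> float:
        """Apply the frozen recipe to a raw reflectance spectrum, then score."""
        from .preprocess import apply_recipe

        feats = apply_recipe(spectrum, self.recipe, self.wavelengths)
        return self.predict(feats)

    # -- persistence (JSON metadata + .npz array payload) -------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        est = self.estimator
        meta = {
            "n_lv": self.n_lv,
            "y_mean": est.y_mean_,
            "recipe": self.recipe.to_dict(),
            "training_meta": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.training_meta.items()
            },
        }
        path.write_text(json.dumps(meta, indent=2))
        np.savez(
            path.with_suffix(".npz"),
            x_mean=est.x_mean_,
            coef=est.coef_,
            x_weights=est.x_weights_,
            x_loadings=est.x_loadings_,
            y_loadings=est.y_loadings_,
            wavelengths=self.wavelengths,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        path = Path(path)
        meta = json.loads(path.read_text())
        arrays = np.load(path.with_suffix(".npz"))
        est = NipalsPLS(n_components=meta["n_lv"])
        est.x_mean_ = arrays["x_mean"]
        est.y_mean_ = float(meta["y_mean"])
        est.coef_ = arrays["coef"]
        est.x_weights_ = arrays["x_weights"]
        est.x_loadings_ = arrays["x_loadings"]
        est.y_loadings_ = arrays["y_loadings"]
        est.n_components_ = int(meta["n_lv"])
        est.n_features_in_ = est.coef_.size
        return cls(
            estimator=est,
            recipe=PreprocessRecipe.from_dict(meta["recipe"]),
            wavelengths=arrays["wavelengths"],
            training_meta=meta.get("training_meta", {}),
        )


@dataclass
class CVResult:
    """Cross-validation summary: RMSECV per LV count and the chosen LV."""

    rmsecv_by_lv: np.ndarray  # index k-1 holds RMSECV with k LVs
    chosen_lv: int
    group_assignment: np.ndarray
    seed: int
    scheme: str = "random"
    y_pred_cv: np.ndarray | None = None  # (n, max_lv) held-out predictions

    @property
    def rmsecv(self) -> float:
        """RMSECV at the chosen number of latent variables."""
        return float(self.rmsecv_by_lv[self.chosen_lv - 1])

    def residuals(self) -> np.ndarray:
        """Held-out residuals (ŷ − y) at the chosen LV (requires y_pred_cv)."""
        if self.y_pred_cv is None or self._y is None:
            raise ValueError("held-out predictions were not retained")
        return self.y_pred_cv[:, self.chosen_lv - 1] - self._y

    _y: np.ndarray | None = None


@dataclass
class PermutationReport:
    """Intact RMSECV versus randomisation and y-permutation distributions."""

    intact_rmsecv: float
    chosen_lv: int
    randomised_rmsecv: np.ndarray
    permuted_rmsecv: np.ndarray
    sd_y: float
    seed: int


# ---------------------------------------------------------------------------
# Fitting and validation
# ---------------------------------------------------------------------------

def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> NipalsPLS:
    """Fit a PLS1 model with ``n_lv`` latent variables (thin wrapper)."""
    return NipalsPLS(n_components=n_lv).fit(X, y)


def default_max_lv(n_samples: int, n_groups: int = 5, cap: int = 15) -> int:
    """Largest LV count keeping every training fold solvable, capped."""
    worst_train = n_samples - math.ceil(n_samples / n_groups)
    return max(1, min(cap, worst_train - 1))


def _assign_groups(
    n: int, n_groups: int, seed: int, scheme: str
) -> np.ndarray:
    if scheme == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
    elif scheme == "contiguous":
        order = np.arange(n)
    elif scheme == "venetian":
        # venetian blinds: sample i -> group i mod n_groups
        return np.arange(n) % n_groups
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    groups = np.empty(n, dtype=int)
    sizes = np.full(n_groups, n // n_groups)
    sizes[: n % n_groups] += 1
    pos = 0
    for g, size in enumerate(sizes):
        groups[order[pos : pos + size]] = g
        pos += size
    return groups


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int | None = None,
    n_groups: int = 5,
    seed: int = 0,
    scheme: str = "random",
    groups: np.ndarray | None = None,
) -> CVResult:
    """RMSECV over cancellation groups for every LV count in 1..max_lv.

    Each group is held out once; the fold model (centres included) is fitted
    on the remaining samples only. The chosen LV is the smallest one whose
    RMSECV is within 1e-9 of the minimum (parsimony tie rule).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n_groups > n:
        raise ValueError(f"{n_groups} groups but only {n} samples")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    if max_lv is None:
        max_lv = min(default_max_lv(n, n_groups), X.shape[1])
    if groups is None:
        groups = _assign_groups(n, n_groups, seed, scheme)
    else:
        groups = np.asarray(groups, dtype=int)
        if groups.size != n:
            raise ValueError("group assignment length mismatch")
    counts = np.bincount(groups, minlength=n_groups)
    if np.any(counts < 1):
        raise ValueError("every cancellation group needs at least one sample")

    y_pred = np.empty((n, max_lv))
    for g in range(n_groups):
        test = groups == g
        train = ~test
        est = NipalsPLS(n_components=max_lv).fit(X[train], y[train])
        betas = est.coef_path()  # (p, A_actual)
        Xc = X[test] - est.x_mean_
        preds = est.y_mean_ + Xc @ betas
        if betas.shape[1] < max_lv:  # residual exhausted early: hold last
            pad = np.repeat(preds[:, -1:], max_lv - betas.shape[1], axis=1)
            preds = np.hstack([preds, pad])
        y_pred[test] = preds

    rmsecv_by_lv = np.sqrt(np.mean((y_pred - y[:, None]) ** 2, axis=0))
    best = rmsecv_by_lv.min()
    chosen = int(np.argmax(rmsecv_by_lv <= best + 1e-9)) + 1
    result = CVResult(
        rmsecv_by_lv=rmsecv_by_lv,
        chosen_lv=chosen,
        group_assignment=groups,
        seed=seed,
        scheme=scheme,
        y_pred_cv=y_pred,
    )
    result._y = y.copy()
    return result


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 50,
    seed: int = 0,
    n_randomisations: int | None = None,
    n_groups: int = 5,
    max_lv: int | None = None,
) -> PermutationReport:
    """Robustness tests around a calibration.

    *Randomisation*: the CV group assignment is re-drawn with the (X, y)
    pairing intact; a robust model's RMSECV barely moves. *Permutation*:
    y is permuted against X and the full CV repeated; the error should
    collapse to roughly SD(y), the no-information level. Each permuted run
    reports the RMSECV at its own chosen LV (same first-minimum rule).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if n_randomisations is None:
        n_randomisations = n_permutations
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)

    intact = cross_validate(
        X, y, max_lv=max_lv, n_groups=n_groups, seed=seed
    )

    randomised = np.empty(n_randomisations)
    for i in range(n_randomisations):
        sub = int(rng.integers(0, 2**31 - 1))
        randomised[i] = cross_validate(
            X, y, max_lv=max_lv, n_groups=n_groups, seed=sub
        ).rmsecv

    permuted = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        sub = int(rng.integers(0, 2**31 - 1))
        permuted[i] = cross_validate(
            X, y_perm, max_lv=max_lv, n_groups=n_groups, seed=sub
        ).rmsecv

    return PermutationReport(
        intact_rmsecv=intact.rmsecv,
        chosen_lv=intact.chosen_lv,
        randomised_rmsecv=randomised,
        permuted_rmsecv=permuted,
        sd_y=float(np.std(y, ddof=1)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Calibration workflow
# ---------------------------------------------------------------------------

def build_design_matrix(
    samples: Sequence[CalibrationSample],
    recipe: PreprocessRecipe,
    wavelengths: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess all profiles into (X, y); degenerate profiles are fatal."""
    profiles = np.vstack([s.profile for s in samples])
    X, valid, _ = apply_recipe_matrix(profiles, recipe, wavelengths)
    if not np.all(valid):
        bad = [samples[i].sample_id for i in np.flatnonzero(~valid)]
        raise ValueError(
            f"zero-variance profile(s) in calibration: {bad}"
        )
    y = np.array([s.reference_collagen_pct for s in samples])
    return X, y


def fit_calibration(
    samples: Sequence[CalibrationSample],
    wavelengths: np.ndarray,
    recipe: PreprocessRecipe | None = None,
    n_groups: int = 5,
    seed: int = 0,
    max_lv: int | None = None,
) -> tuple[PLSModel, CVResult]:
    """Full calibration: preprocess, cross-validate, fit at the chosen LV."""
    if recipe is None:
        recipe = PreprocessRecipe()
    X, y = build_design_matrix(samples, recipe, wavelengths)
    cv = cross_validate(
        X, y, max_lv=max_lv, n_groups=n_groups, seed=seed
    )
    est = NipalsPLS(n_components=cv.chosen_lv).fit(X, y)
    model = PLSModel(
        estimator=est,
        recipe=recipe,
        wavelengths=np.asarray(wavelengths, dtype=float),
        training_meta={
            "n_samples": len(samples),
            "rmsecv_by_lv": cv.rmsecv_by_lv,
            "chosen_lv": cv.chosen_lv,
            "rmsecv": cv.rmsecv,
            "cv_seed": seed,
            "n_groups": n_groups,
        },
    )
    return model, cv
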