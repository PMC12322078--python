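"""Behavioral partial least squares: X'Y = U S V' with resampling inference.

Brain (subjects x parcels) and behavior (subjects x measures) matrices are
column-standardized (z-scored by default), their cross-covariance is subjected
to singular value decomposition, and each latent variable (LV) — a left
singular vector, right singular vector, and singular value — captures a
maximally covarying brain/behavior pattern.  Effect size of LV k is
s_k^2 / sum(s^2).  Inference follows the standard behavioral-PLS recipe:

* **permutation**: rows of X are permuted and the null singular values
  collected per LV index (add-one p-values);
* **bootstrap**: subjects resampled with replacement; a feature's bootstrap
  ratio is its original weight over the bootstrap SE of that weight;
* **split-half cross-validation**: repeated half/half splits, test subjects
  projected on train weights, out-of-sample correlation of LV1 brain vs
  behavior scores; significance by re-running the splits on row-shuffled X.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .nulls import nonparametric_p

__all__ = ["BehavioralPLS", "fit_pls", "permute_pls", "bootstrap_pls",
           "crossval_pls"]


def _zscore_columns(A: np.ndarray, label: str) -> np.ndarray:
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance column(s) {bad.tolist()} in {label}")
    return (A - mu) / sd


def _preprocess(A: np.ndarray, policy: str, label: str) -> np.ndarray:
    if policy == "zscore":
        return _zscore_columns(A, label)
    if policy == "center":
        return A - A.mean(axis=0)
    if policy == "none":
        return A
    raise ValueError(f"unknown preprocessing {policy!r}")


def _cross_svd(Xp: np.ndarray, Yp: np.ndarray):
    U, s, Vt = np.linalg.svd(Xp.T @ Yp, full_matrices=False)
    return U, s, Vt.T


def _fix_signs(U: np.ndarray, V: np.ndarray):
    """Deterministic sign convention: largest-|element| of each U column > 0."""
    for k in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1
    return U, V


class BehavioralPLS(BaseEstimator):
    """Behavioral PLS estimator (SVD of the brain-behavior cross-covariance).

    Parameters
    ----------
    preprocessing : {"zscore", "center", "none"}
        Column preprocessing applied to both X and Y before the SVD.

    Fitted attributes
    -----------------
    U_ : (n_parcels, L) left singular vectors (brain weights)
    V_ : (n_measures, L) right singular vectors (behavior weights)
    S_ : (L,) singular values, nonincreasing
    cov_explained_ : (L,) fractions s_k^2 / sum(s^2), summing to 1
    brain_scores_, behavior_scores_ : (n_subjects, L) projections X U, Y V
    """

    def __init__(self, preprocessing: str = "zscore"):
        self.preprocessing = preprocessing

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "BehavioralPLS":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of subjects")
        if X.shape[0] < 3:
            raise ValueError("need >= 3 subjects")
        Xp = _preprocess(X, self.preprocessing, "X")
        Yp = _preprocess(Y, self.preprocessing, "Y")
        U, s, V = _cross_svd(Xp, Yp)
        U, V = _fix_signs(U, V)
        self.U_, self.S_, self.V_ = U, s, V
        self.cov_explained_ = s**2 / np.sum(s**2)
        self.brain_scores_ = Xp @ U
        self.behavior_scores_ = Yp @ V
        self._Xp, self._Yp = Xp, Yp
        return self

    # -- inference -----------------------------------------------------------
    def permutation_test(self, n_perm: int = 1000,
                         rng: np.random.Generator | None = None) -> np.ndarray:
        """Add-one permutation p-value per LV (X rows permuted)."""
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if rng is None:
            raise ValueError("rng is required")
        L = self.S_.size
        null_s = np.empty((n_perm, L))
        n = self._Xp.shape[0]
        for b in range(n_perm):
            perm = rng.permutation(n)
            null_s[b] = np.linalg.svd(self._Xp[perm].T @ self._Yp,
                                      compute_uv=False)[:L]
        self.perm_p_ = np.array([
            nonparametric_p(self.S_[k], null_s[:, k],
                            sidedness="one_sided_greater",
                            method="permutation").p_value
            for k in range(L)
        ])
        self.null_singular_values_ = null_s
        return self.perm_p_

    def bootstrap(self, n_boot: int = 1000,
                  rng: np.random.Generator | None = None,
                  max_retries: int = 50) -> dict:
        """Bootstrap ratios (weight / bootstrap SE) for brain and behavior."""
        if rng is None:
            raise ValueError("rng is required")
        n = self._Xp.shape[0]
        L = self.S_.size
        Us = np.empty((n_boot, *self.U_.shape))
        Vs = np.empty((n_boot, *self.V_.shape))
        # resample raw-scale standardized data; re-standardizing within the
        # resample mirrors the original preprocessing
        for b in range(n_boot):
            for _ in range(max_retries):
                idx = rng.integers(0, n, size=n)
                Xb, Yb = self._Xp[idx], self._Yp[idx]
                if np.all(Xb.std(axis=0) > 0) and np.all(Yb.std(axis=0) > 0):
                    break
            else:
                raise RuntimeError("could not draw a non-degenerate resample")
            Ub, sb, Vb = _cross_svd(Xb, Yb)
            # sign-align each LV to the original by correlation
            for k in range(L):
                if np.dot(Ub[:, k], self.U_[:, k]) < 0:
                    Ub[:, k] *= -1
                    Vb[:, k] *= -1
            Us[b], Vs[b] = Ub, Vb
        u_se = Us.std(axis=0, ddof=1)
        v_se = Vs.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.brain_bootstrap_ratios_ = self.U_ / u_se
            self.behavior_bootstrap_ratios_ = self.V_ / v_se
        return {
            "brain": self.brain_bootstrap_ratios_,
            "behavior": self.behavior_bootstrap_ratios_,
        }

    def cross_validate(self, X: np.ndarray, Y: np.ndarray,
                       n_splits: int = 100, n_perm: int = 100,
                       rng: np.random.Generator | None = None,
                       lv: int = 0) -> dict:
        """Split-half out-of-sample score correlation for one LV.

        Each split fits PLS on a random half and correlates the held-out
        half's projected brain and behavior scores.  The permutation null
        re-runs the split procedure on X with shuffled rows; p is the add-one
        exceedance of the median CV correlation.
        """
        if rng is None:
            raise ValueError("rng is required")
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        n = X.shape[0]
        if n < 8:
            raise ValueError("need >= 8 subjects for split-half CV")
        if n // 2 < 3 or n - n // 2 < 3:
            raise ValueError("test half smaller than 3 subjects")

        def _cv_corrs(Xd: np.ndarray, local_rng: np.random.Generator,
                      k_splits: int) -> np.ndarray:
            out = np.empty(k_splits)
            for i in range(k_splits):
                perm = local_rng.permutation(n)
                tr, te = perm[: n // 2], perm[n // 2:]
                Xtr = _preprocess(Xd[tr], self.preprocessing, "X")
                Ytr = _preprocess(Y[tr], self.preprocessing, "Y")
                mu_x, sd_x = Xd[tr].mean(0), Xd[tr].std(0, ddof=1)
                mu_y, sd_y = Y[tr].mean(0), Y[tr].std(0, ddof=1)
                U, s, V = _cross_svd(Xtr, Ytr)
                U, V = _fix_signs(U, V)
                if self.preprocessing == "zscore":
                    Xte = (Xd[te] - mu_x) / sd_x
                    Yte = (Y[te] - mu_y) / sd_y
                elif self.preprocessing == "center":
                    Xte = Xd[te] - mu_x
                    Yte = Y[te] - mu_y
                else:
                    Xte, Yte = Xd[te], Y[te]
                bs = Xte @ U[:, lv]
                hs = Yte @ V[:, lv]
                out[i] = np.corrcoef(bs, hs)[0, 1]
            return out

        cv = _cv_corrs(X, rng, n_splits)
        observed = float(np.median(cv))
        null_medians = np.empty(n_perm)
        for p in range(n_perm):
            Xs = X[rng.permutation(n)]
            null_medians[p] = np.median(_cv_corrs(Xs, rng, n_splits))
        ens = nonparametric_p(observed, null_medians,
                              sidedness="one_sided_greater",
                              method="permutation")
        self.cv_correlations_ = cv
        self.cv_p_ = ens.p_value
        return {"correlations": cv, "median": observed, "p": ens.p_value,
                "null_medians": null_medians}


# -- thin functional wrappers -------------------------------------------------

def fit_pls(X, Y, preprocessing: str = "zscore") -> BehavioralPLS:
    """Fit behavioral PLS and return the fitted estimator."""
    return BehavioralPLS(preprocessing=preprocessing).fit(X, Y)


def permute_pls(model: BehavioralPLS, n_perm: int = 1000,
                rng: np.random.Generator | None = None) -> np.ndarray:
    return model.permutation_test(n_perm=n_perm, rng=rng)


def bootstrap_pls(model: BehavioralPLS, n_boot: int = 1000,
                  rng: np.random.Generator | None = None) -> dict:
    return model.bootstrap(n_boot=n_boot, rng=rng)


def crossval_pls(X, Y, n_splits: int = 100, n_perm: int = 100,
                 rng: np.random.Generator | None = None,
                 preprocessing: str = "zscore") -> dict:
    model = BehavioralPLS(preprocessing=preprocessing).fit(X, Y)
    return model.cross_validate(X, Y, n_splits=n_splits, n_perm=n_perm,
                                rng=rng)
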