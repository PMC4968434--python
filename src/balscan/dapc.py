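"""Discriminant analysis of principal components (DAPC).

PCA on centered (optionally scaled) allele dosages, retention of k
leading PCs, then a linear discriminant analysis (pooled within-group
covariance, equal priors) on the PC scores.  k can be chosen by the
alpha-score: observed correct-reassignment proportion minus its mean
over random permutations of the group labels, which penalizes the
overfitting that comes with retaining too many PCs.

Held-out cohorts (e.g. a disease sample) are projected as supplementary
individuals: centered and scaled with the *reference* statistics and
passed through the reference loadings and discriminant coefficients,
without altering the fitted model.

The estimator follows the scikit-learn protocol (fit / transform /
predict / predict_proba, fitted attributes with trailing underscores)
and composes with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .core import MISSING_DOSAGE, GenotypeMatrix


def _as_array(G) -> np.ndarray:
    if isinstance(G, GenotypeMatrix):
        return G.data.astype(float)
    return np.asarray(G, dtype=float)


class DAPC(BaseEstimator, ClassifierMixin):
    """Discriminant analysis of principal components.

    Parameters
    ----------
    n_pcs : int or "auto"
        Number of principal components passed to the discriminant step.
        "auto" picks the k maximizing the mean alpha-score.
    scale : bool
        Divide each site by its standard deviation after centering.
        Default off: allele-dosage DAPC conventionally centers only.
    n_rand : int
        Label permutations per candidate k for the alpha-score.
    candidate_pcs : sequence of int, optional
        Candidate k values scanned when ``n_pcs="auto"``.
    random_state : int
        Seed for the alpha-score permutations.

    Attributes
    ----------
    mean_, scale_ : per-site centering/scaling vectors of the reference.
    components_ : (k, n_sites) retained PC loadings.
    n_pcs_ : retained-PC count actually used.
    coef_ : (k, g-1) discriminant coefficient matrix (all g-1 functions).
    classes_ : group labels.
    means_ : (g, g-1) group centroids in discriminant space.
    alpha_score_trace_ : dict k -> mean alpha-score (when k was "auto").
    """

    def __init__(
        self,
        n_pcs="auto",
        scale: bool = False,
        n_rand: int = 30,
        candidate_pcs=None,
        random_state: int = 0,
    ):
        self.n_pcs = n_pcs
        self.scale = scale
        self.n_rand = n_rand
        self.candidate_pcs = candidate_pcs
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = X.copy()
        miss = X == MISSING_DOSAGE
        if miss.any():
            X[miss] = np.nan
            X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
        return (X - self.mean_) / self.scale_

    @staticmethod
    def _fit_lda(scores: np.ndarray, y: np.ndarray, classes: np.ndarray):
        """Discriminant axes of the generalized eigenproblem S_B v = l S_W v."""
        k = scores.shape[1]
        overall = scores.mean(axis=0)
        Sw = np.zeros((k, k))
        Sb = np.zeros((k, k))
        means = []
        for c in classes:
            xc = scores[y == c]
            mc = xc.mean(axis=0)
            means.append(mc)
            Sw += (xc - mc).T @ (xc - mc)
            Sb += len(xc) * np.outer(mc - overall, mc - overall)
        Sw /= max(len(scores) - len(classes), 1)
        Sw += 1e-10 * np.eye(k)  # guard exact singularity
        evals, evecs = linalg.eigh(Sb, Sw)
        order = np.argsort(evals)[::-1][: len(classes) - 1]
        coef = evecs[:, order]
        # normalize so pooled within-group covariance is the identity in
        # discriminant space; posteriors are then spherical Gaussians
        within = coef.T @ Sw @ coef
        coef = coef / np.sqrt(np.diag(within))
        return coef, np.array(means) @ coef

    def _reassignment_rate(self, scores, y, classes, k) -> float:
        coef, means = self._fit_lda(scores[:, :k], y, classes)
        d = scores[:, :k] @ coef
        dist = ((d[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        pred = classes[np.argmin(dist, axis=1)]
        return float((pred == y).mean())

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X = _as_array(X)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2 or counts.min() < 2:
            raise ValueError("need >= 2 groups with >= 2 individuals each")
        Xw = X.copy()
        miss = Xw == MISSING_DOSAGE
        if miss.any():
            Xw[miss] = np.nan
            Xw = np.where(np.isnan(Xw), np.nanmean(Xw, axis=0), Xw)
        self.mean_ = Xw.mean(axis=0)
        sd = Xw.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0) if self.scale else np.ones(Xw.shape[1])
        Z = (Xw - self.mean_) / self.scale_
        # PCA by SVD of the centered matrix
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        rank = int((s > 1e-9 * s[0]).sum()) if s.size else 0
        max_k = min(rank, len(y) - 1)
        if max_k < 1:
            raise ValueError("data matrix has rank 0")
        self._full_components = Vt[:max_k]
        full_scores = Z @ self._full_components.T
        self.classes_ = classes
        if self.n_pcs == "auto":
            rng = np.random.default_rng(self.random_state)
            cands = self.candidate_pcs or sorted(
                {k for k in (1, 2, 3, 5, 8, 12, 20, 30, 50, max_k) if 1 <= k <= max_k}
            )
            self.alpha_score_trace_ = {}
            for k in cands:
                obs = self._reassignment_rate(full_scores, y, classes, k)
                rnd = np.mean(
                    [
                        self._reassignment_rate(
                            full_scores, rng.permutation(y), classes, k
                        )
                        for _ in range(self.n_rand)
                    ]
                )
                self.alpha_score_trace_[k] = obs - rnd
            self.n_pcs_ = max(self.alpha_score_trace_, key=self.alpha_score_trace_.get)
        else:
            if not 1 <= int(self.n_pcs) <= max_k:
                raise ValueError(f"n_pcs must be in [1, {max_k}]")
            self.n_pcs_ = int(self.n_pcs)
            self.alpha_score_trace_ = {}
        self.components_ = self._full_components[: self.n_pcs_]
        scores = full_scores[:, : self.n_pcs_]
        self.coef_, self.means_ = self._fit_lda(scores, y, classes)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Coordinates along the discriminant functions (supplementary
        projection: reference centering/scaling/loadings throughout)."""
        check_is_fitted(self, "coef_")
        X = _as_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} sites, model was fitted on {self.n_features_in_}"
            )
        Z = self._standardize(X)
        return (Z @ self.components_.T) @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        """Posterior group membership: spherical Gaussian likelihoods in
        discriminant space (pooled within-group covariance), equal priors."""
        d = self.transform(X)
        dist2 = ((d[:, None, :] - self.means_[None, :, :]) ** 2).sum(axis=2)
        loglik = -0.5 * dist2
        loglik -= loglik.max(axis=1, keepdims=True)
        p = np.exp(loglik)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# module-level wrappers (the functional surface of the pipeline)


def fit_dapc(G, groups, k="auto", n_rand: int = 30, seed: int = 0, scale: bool = False) -> DAPC:
    return DAPC(n_pcs=k, n_rand=n_rand, random_state=seed, scale=scale).fit(G, groups)


def posterior_membership(model: DAPC, G) -> pd.DataFrame:
    ids = G.sample_ids if isinstance(G, GenotypeMatrix) else range(len(_as_array(G)))
    return pd.DataFrame(model.predict_proba(G), index=list(ids), columns=model.classes_)


def project_supplementary(model: DAPC, G_new):
    """Discriminant scores + posteriors for held-out individuals."""
    return model.transform(G_new), posterior_membership(model, G_new)


def membership_summary(posteriors: pd.DataFrame, source_groups) -> pd.DataFrame:
    """Fraction of each source group assigned (argmax posterior) to each
    cluster — the admixture-like plot's underlying table."""
    assigned = posteriors.columns[np.argmax(posteriors.values, axis=1)]
    df = pd.DataFrame({"source": np.asarray(source_groups), "assigned": assigned})
    table = df.groupby("source")["assigned"].value_counts(normalize=True).unstack(fill_value=0.0)
    return table.reindex(columns=posteriors.columns, fill_value=0.0)
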