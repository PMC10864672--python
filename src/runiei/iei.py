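"""Implicit-explicit concordance (IEC) and discrepancy (IED) scores.

Paired implicit (G-Score) and explicit (feeling thermometer) association
values are z-standardized and decomposed by principal component analysis of
their 2x2 correlation matrix. With two indicators the two components are,
up to scaling, the sum and the difference of the standardized inputs:

* the component with same-sign loadings is the *concordance* component
  (IEC) — the shared valence of implicit and explicit associations,
* the component with opposite-sign loadings is the *discrepancy* component
  (IED) — the directed difference, oriented so that positive IED means the
  explicit association is more positive than the implicit one.

Component scores are rescaled to unit sample standard deviation, so IEC and
IED each have mean 0 and SD 1 over the analyzed sample and must be
interpreted relative to it. Closed form (used as a cross-check in the test
suite): with implicit-explicit correlation ``rho``,

    iec = (z_implicit + z_explicit) / sqrt(2 (1 + rho))
    ied = (z_explicit - z_implicit) / sqrt(2 (1 - rho))
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["zstandardize", "IEIScorer", "compute_iei"]


def zstandardize(values) -> np.ndarray:
    """z-scores with the sample (n-1) standard deviation.

    Raises for fewer than two values or zero variance.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D sequence")
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-scores undefined")
    return (values - values.mean()) / sd


class IEIScorer(TransformerMixin, BaseEstimator):
    """PCA-based scorer mapping (implicit, explicit) pairs to (IEC, IED).

    sklearn-style transformer: ``fit`` learns the standardization constants
    and the component structure from the analyzed sample; ``transform``
    returns an ``(n, 2)`` array with columns ``(iec, ied)``. On the fitted
    sample both scores have mean 0 and unit sample SD and are mutually
    uncorrelated.

    Attributes
    ----------
    mean_, scale_ : ndarray of shape (2,)
        Per-column mean and sample SD of the fitted data.
    corr_ : float
        Pearson correlation between the standardized inputs.
    components_ : ndarray of shape (2, 2)
        Rows are the (sign-oriented) unit loading vectors for IEC and IED
        on (implicit_z, explicit_z).
    score_scale_ : ndarray of shape (2,)
        Divisors (sqrt of component variances) giving unit-SD scores.
    """

    def __init__(self):
        pass

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=3)
        if X.shape[1] != 2:
            raise ValueError("expected exactly 2 columns: (implicit, explicit)")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            raise ValueError("constant input column: PCA scoring undefined")
        Z = (X - self.mean_) / self.scale_
        rho = float(np.corrcoef(Z[:, 0], Z[:, 1])[0, 1])
        if not np.isfinite(rho) or abs(rho) >= 1.0 - 1e-12:
            raise ValueError("inputs perfectly correlated: a component degenerates")
        self.corr_ = rho
        R = np.array([[1.0, rho], [rho, 1.0]])
        eigvals, eigvecs = np.linalg.eigh(R)
        # assignment by loading pattern, not eigenvalue order: same-sign
        # loadings -> concordance, opposite-sign -> discrepancy
        comps = []
        variances = []
        for j in range(2):
            v = eigvecs[:, j]
            comps.append(v)
            variances.append(eigvals[j])
        same = [j for j in range(2) if comps[j][0] * comps[j][1] > 0]
        if len(same) != 1:
            raise ValueError("degenerate loading pattern (rho == 0 boundary hit)")
        i_iec = same[0]
        i_ied = 1 - i_iec
        v_iec = comps[i_iec].copy()
        v_ied = comps[i_ied].copy()
        # orient: IEC loads positively on both; IED positively on explicit
        if v_iec[0] < 0:
            v_iec = -v_iec
        if v_ied[1] < 0:
            v_ied = -v_ied
        self.components_ = np.vstack([v_iec, v_ied])
        self.score_scale_ = np.sqrt(np.array([variances[i_iec], variances[i_ied]]))
        self.n_features_in_ = 2
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        if X.shape[1] != 2:
            raise ValueError("expected exactly 2 columns: (implicit, explicit)")
        Z = (X - self.mean_) / self.scale_
        return (Z @ self.components_.T) / self.score_scale_

    def inverse_transform(self, scores) -> np.ndarray:
        """Recover (implicit, explicit) raw values from (iec, ied) scores."""
        check_is_fitted(self, "components_")
        scores = check_array(scores, dtype=float)
        Z = (scores * self.score_scale_) @ self.components_
        return Z * self.scale_ + self.mean_


def compute_iei(implicit, explicit, participant_ids=None) -> pd.DataFrame:
    """Score a cohort: z-standardized inputs plus IEC/IED components.

    ``implicit`` and ``explicit`` must be paired sequences of equal length
    (at least 3) with nonzero variance and |correlation| < 1. Returns a
    DataFrame with columns ``participant_id, implicit_z, explicit_z, iec,
    ied``.
    """
    implicit = np.asarray(implicit, dtype=float)
    explicit = np.asarray(explicit, dtype=float)
    if implicit.shape != explicit.shape or implicit.ndim != 1:
        raise ValueError("implicit and explicit must be paired 1-D sequences")
    if np.isnan(implicit).any() or np.isnan(explicit).any():
        raise ValueError("missing values: drop excluded participants first")
    X = np.column_stack([implicit, explicit])
    scorer = IEIScorer().fit(X)
    scores = scorer.transform(X)
    if participant_ids is None:
        participant_ids = np.arange(len(implicit))
    return pd.DataFrame(
        {
            "participant_id": participant_ids,
            "implicit_z": zstandardize(implicit),
            "explicit_z": zstandardize(explicit),
            "iec": scores[:, 0],
            "ied": scores[:, 1],
        }
    )
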