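"""Scikit-learn style estimators for indicator-vector sequence analysis.

The classification path is fit/predict shaped, so it is exposed as three
composable estimators:

``SequenceEncoder``
    stateless transformer: aligned character strings -> quartet arrays.
``ConservedSiteFilter``
    transformer fitted on encoded sequences; removes columns of positions
    that are identical (and unambiguous) across the training pool.
``IndicatorVectorClassifier``
    the discriminant itself. For each group k it solves the eigenproblem of

        C_k = M_k - (1/(G-1)) * sum_{m != k} M_m,

    where ``M_m`` is the mean outer product of group m's unit-normalized
    sequence vectors. The dominant eigenvector of ``C_k`` — the group's
    *indicator vector* — maximizes the mean squared correlation with group
    k's sequences while minimizing it against all other groups (a Rayleigh
    quotient over the unit sphere, each competitor group weighted equally).
    Prediction assigns a test sequence to the indicator vector with which it
    is most highly correlated.

The three compose in a :class:`sklearn.pipeline.Pipeline`; module-level
functions in :mod:`kleevec.indicator` and :mod:`kleevec.matrices` are thin
wrappers over these classes.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg
import scipy.sparse.linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import seqspace
from .exceptions import ConservationError, DegenerateGroupError, ShapeError
from .seqspace import EncodingConvention


def _as_string_rows(X) -> list[str]:
    if isinstance(X, str):
        raise ValueError("X must be a sequence of strings, not a single string")
    return [str(x) for x in X]


class SequenceEncoder(TransformerMixin, BaseEstimator):
    """Transform aligned character strings into stacked probability quartets.

    Parameters
    ----------
    base_order : tuple of the four canonical bases
        Quartet slot order; any permutation gives identical geometry.

    Examples
    --------
    >>> SequenceEncoder().fit_transform(["ACGT"]).shape
    (1, 16)
    """

    def __init__(self, base_order: tuple = seqspace.CANONICAL_BASES):
        self.base_order = base_order

    def fit(self, X, y=None):
        self.convention_ = EncodingConvention(tuple(self.base_order))
        rows = _as_string_rows(X)
        self.n_sites_ = len(rows[0]) if rows else 0
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "convention_")
        return seqspace.encode_matrix(_as_string_rows(X), self.convention_)


class ConservedSiteFilter(TransformerMixin, BaseEstimator):
    """Remove alignment columns conserved across the fitted pool.

    Operates on encoded quartet arrays: a position is conserved iff every
    row carries the identical unit basis quartet there (``rule="strict"``);
    under ``rule="unambiguous"`` non-basis quartets are ignored and the
    basis quartets present must agree. Conserved positions inflate every
    correlation equally and carry no differential information.

    Attributes
    ----------
    mask_ : SiteMask
        Partition of 1-based positions into kept and dropped.
    """

    def __init__(self, rule: str = "strict"):
        self.rule = rule

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] % 4:
            raise ShapeError(f"expected (n, 4*sites) array, got {X.shape}")
        if X.shape[0] < 2:
            raise ValueError("need >= 2 sequences to assess conservation")
        quartets = X.reshape(X.shape[0], -1, 4)
        is_basis = np.isclose(quartets.max(axis=2), 1.0)
        same = np.all(quartets == quartets[:1], axis=(0, 2))
        if self.rule == "strict":
            conserved = same & is_basis.all(axis=0)
        elif self.rule == "unambiguous":
            n_sites = quartets.shape[1]
            conserved = np.zeros(n_sites, dtype=bool)
            for p in range(n_sites):
                rows = quartets[is_basis[:, p], p]
                conserved[p] = rows.size > 0 and bool(
                    np.all(rows == rows[0])
                )
        else:
            raise ValueError(f"unknown rule {self.rule!r}")
        dropped = (np.nonzero(conserved)[0] + 1).tolist()
        self.mask_ = seqspace.SiteMask.from_dropped(dropped, quartets.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mask_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ShapeError(
                f"X has {X.shape[1]} features, filter fitted on "
                f"{self.n_features_in_}"
            )
        return X[:, self.mask_.column_indices()]


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ShapeError("cannot unit-normalize a zero row")
    return X / norms


class IndicatorVectorClassifier(ClassifierMixin, BaseEstimator):
    """Eigenvector-discriminant classifier over encoded sequence vectors.

    Parameters
    ----------
    solver : {"dense", "matrix-free"}
        ``dense`` runs a symmetric eigendecomposition of each group's d x d
        operator (d = 4 x kept sites; trivial for barcode-scale d). The
        matrix-free variant applies the operator through the N x d data
        matrices via Lanczos iteration, for long alignments.
    compute_probabilities : bool
        Also derive each indicator's probability form (quartets rescaled to
        sum to one). Entries may be negative — the operator is a difference
        of positive semidefinite terms — and are reported signed.

    Attributes
    ----------
    classes_ : (G,) group labels, sorted.
    indicator_vectors_ : (G, d) unit-norm indicator vectors.
    eigenvalues_ : (G,) leading eigenvalues; equal to the discriminant
        criterion J evaluated at the optimum.
    prob_forms_ : (G, d) probability-normalized forms (NaN rows where the
        quartet-sum property failed), or None.
    """

    def __init__(self, solver: str = "dense",
                 compute_probabilities: bool = True):
        self.solver = solver
        self.compute_probabilities = compute_probabilities

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ShapeError(f"X must be 2-D, got shape {X.shape}")
        if X.shape[0] != y.shape[0]:
            raise ShapeError("X and y have inconsistent lengths")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        G = len(self.classes_)
        d = X.shape[1]
        U = _unit_rows(X)
        groups = [U[y_idx == g] for g in range(G)]

        if self.solver == "dense":
            total = np.zeros((d, d))
            for Ug in groups:
                total += Ug.T @ Ug / len(Ug)
            eigvals, vecs = [], []
            for g, Ug in enumerate(groups):
                M = Ug.T @ Ug / len(Ug)
                C = M if G == 1 else M * (G / (G - 1)) - total / (G - 1)
                w, V = scipy.linalg.eigh(C)
                eigvals.append(w[-1])
                vecs.append(V[:, -1])
        elif self.solver == "matrix-free":
            eigvals, vecs = [], []
            for g, Ug in enumerate(groups):
                others = [(m, Um) for m, Um in enumerate(groups) if m != g]

                def matvec(q, Ug=Ug, others=others):
                    out = Ug.T @ (Ug @ q) / len(Ug)
                    for _, Um in others:
                        out -= Um.T @ (Um @ q) / (len(Um) * max(G - 1, 1))
                    return out

                op = scipy.sparse.linalg.LinearOperator((d, d), matvec=matvec)
                v0 = np.full(d, 1.0 / np.sqrt(d))
                w, V = scipy.sparse.linalg.eigsh(op, k=1, which="LA", v0=v0)
                eigvals.append(w[0])
                vecs.append(V[:, 0])
        else:
            raise ValueError(f"unknown solver {self.solver!r}")

        for g in range(G):
            if eigvals[g] <= 0:
                raise DegenerateGroupError(
                    f"group {self.classes_[g]!r}: leading eigenvalue "
                    f"{eigvals[g]:.3g} is not positive (degenerate training data)"
                )
            # eigenvector sign is arbitrary; fix it so the group's own
            # training sequences correlate positively with their indicator
            total_corr = float(groups[g] @ vecs[g] @ np.ones(len(groups[g])))
            if total_corr < 0:
                vecs[g] = -vecs[g]
            elif total_corr == 0.0:
                nz = np.nonzero(vecs[g])[0]
                if nz.size and vecs[g][nz[0]] < 0:
                    vecs[g] = -vecs[g]

        self.indicator_vectors_ = np.array(vecs)
        self.eigenvalues_ = np.array(eigvals)
        self.criterion_values_ = self.eigenvalues_.copy()
        self.n_features_in_ = d
        self.prob_forms_ = None
        if self.compute_probabilities and d % 4 == 0:
            probs = np.full_like(self.indicator_vectors_, np.nan)
            for g in range(G):
                try:
                    probs[g] = normalize_probability(self.indicator_vectors_[g])
                except ConservationError as exc:  # pragma: no cover - guard
                    warnings.warn(
                        f"group {self.classes_[g]!r}: {exc}", stacklevel=2
                    )
            self.prob_forms_ = probs
        return self

    def decision_function(self, X) -> np.ndarray:
        """Correlations of each unit-normalized row of X with each group's
        indicator vector (rows sum to nothing in particular; argmax rules)."""
        check_is_fitted(self, "indicator_vectors_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ShapeError(
                f"X has shape {X.shape}, expected (*, {self.n_features_in_})"
            )
        return _unit_rows(X) @ self.indicator_vectors_.T

    def predict(self, X) -> np.ndarray:
        corr = self.decision_function(X)
        return self.classes_[np.argmax(corr, axis=1)]

    def tie_mask(self, X) -> np.ndarray:
        """Boolean mask of rows whose maximum correlation is attained by
        more than one group (exact ties; biologically meaningful for
        indistinguishable groups, never broken silently elsewhere)."""
        corr = self.decision_function(X)
        return (corr == corr.max(axis=1, keepdims=True)).sum(axis=1) > 1


def normalize_probability(unit_form: np.ndarray, rtol: float = 1e-6) -> np.ndarray:
    """Rescale an indicator vector so every quartet sums to exactly one.

    The quartet sums of a computed indicator vector are mutually equal (an
    inherited conservation property of the embedding); dividing by the
    common sum turns the vector into per-position quartets of (signed)
    base probabilities. Unequal sums signal a bug or degenerate input and
    raise :class:`ConservationError`.
    """
    sums = seqspace.quartet_sums(np.asarray(unit_form, dtype=float))
    scale = max(1.0, float(np.max(np.abs(sums))))
    spread = float(sums.max() - sums.min())
    if spread > rtol * scale:
        raise ConservationError(
            f"quartet sums are not mutually equal (spread {spread:.3g})"
        )
    common = float(sums.mean())
    if abs(common) < 1e-8:
        raise ConservationError(
            f"common quartet sum {common:.3g} too close to zero to rescale"
        )
    return np.asarray(unit_form, dtype=float) / common
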