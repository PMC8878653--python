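"""Fisher linear discriminant analysis, implemented from first principles.

Given labelled feature vectors x in R^d from c classes, the discriminant
seeks directions w maximizing the generalized Rayleigh quotient

    J(w) = (w' Sb w) / (w' Sw w),

where Sb is the between-class scatter, sum_i n_i (u_i - u)(u_i - u)', and
Sw the within-class scatter, sum_i sum_{x in class i} (x - u_i)(x - u_i)'.
Here u_i is the mean of class i (n_i samples) and u the grand mean over
all m training samples, so that the total scatter decomposes exactly as
St = Sb + Sw.  The maximizers are the leading eigenvectors of the
generalized eigenproblem Sb w = lambda Sw w; at most c - 1 of them carry
discriminative information because rank(Sb) <= c - 1.

Sw can be singular with few windows or correlated features, so the
eigenproblem is solved against Sw + eps*I with a deterministic,
scale-aware ridge eps = 1e-6 * trace(Sw)/d (absolute floor 1e-12).
Eigenvectors are canonicalized to unit norm with their first nonzero
component positive, making fitted models byte-reproducible.

Classification assigns a sample to the class whose projected mean is
nearest in the discriminant space (for two classes with equal priors this
is the usual midpoint threshold on the 1-D projection); ties break toward
the earlier class in label order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import DegenerateClassError
from .features import LabeledFeatureSet

RIDGE_REL = 1e-6
RIDGE_FLOOR = 1e-12


@dataclass
class LdaModel:
    """A fitted Fisher discriminant.

    ``omega`` has shape ``(d, k)`` with ``k = min(c - 1, d)`` retained
    discriminant directions, columns unit-norm and sign-canonicalized.
    """

    class_labels: list
    class_means: np.ndarray        # (c, d)
    grand_mean: np.ndarray         # (d,)
    n_per_class: np.ndarray        # (c,)
    Sb: np.ndarray                 # (d, d)
    Sw: np.ndarray                 # (d, d)
    omega: np.ndarray              # (d, k)
    projected_means: np.ndarray    # (c, k)
    ridge_eps: float
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    feature_names: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.omega.shape[0]

    @property
    def n_components(self) -> int:
        return self.omega.shape[1]

    # -- serialization ------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "class_labels": list(self.class_labels),
            "class_means": self.class_means.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "n_per_class": self.n_per_class.tolist(),
            "Sb": self.Sb.tolist(),
            "Sw": self.Sw.tolist(),
            "omega": self.omega.tolist(),
            "projected_means": self.projected_means.tolist(),
            "ridge_eps": self.ridge_eps,
            "eigenvalues": self.eigenvalues.tolist(),
            "feature_names": list(self.feature_names),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LdaModel":
        doc = json.loads(text)
        return cls(
            class_labels=list(doc["class_labels"]),
            class_means=np.asarray(doc["class_means"], dtype=float),
            grand_mean=np.asarray(doc["grand_mean"], dtype=float),
            n_per_class=np.asarray(doc["n_per_class"], dtype=int),
            Sb=np.asarray(doc["Sb"], dtype=float),
            Sw=np.asarray(doc["Sw"], dtype=float),
            omega=np.asarray(doc["omega"], dtype=float),
            projected_means=np.asarray(doc["projected_means"], dtype=float),
            ridge_eps=float(doc["ridge_eps"]),
            eigenvalues=np.asarray(doc["eigenvalues"], dtype=float),
            feature_names=list(doc["feature_names"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "LdaModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _canonicalize(vectors: np.ndarray) -> np.ndarray:
    """Unit-norm columns with first nonzero component positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        v = out[:, j]
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        v = v / norm
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if nz.size and v[nz[0]] < 0:
            v = -v
        out[:, j] = v
    return out


def scatter_matrices(X: np.ndarray, labels: np.ndarray):
    """Class means, grand mean, and the Sb/Sw scatter pair.

    Returns ``(class_labels, means, grand_mean, counts, Sb, Sw)`` with
    classes in sorted label order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels).astype(str)
    class_labels, inverse = np.unique(labels, return_inverse=True)
    c = len(class_labels)
    m, d = X.shape
    counts = np.bincount(inverse, minlength=c)
    means = np.vstack([X[inverse == i].mean(axis=0) for i in range(c)])
    grand = X.mean(axis=0)
    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    for i in range(c):
        dm = means[i] - grand
        Sb += counts[i] * np.outer(dm, dm)
        R = X[inverse == i] - means[i]
        Sw += R.T @ R
    return list(class_labels), means, grand, counts, Sb, Sw


def fit_lda(train: LabeledFeatureSet, ridge_eps: float | None = None,
            n_components: int | None = None) -> LdaModel:
    """Fit a Fisher discriminant to a labelled feature set.

    Parameters
    ----------
    train
        Feature matrix and labels; every class needs >= 2 samples.
    ridge_eps
        Regularization added to Sw's diagonal.  ``None`` selects the
        deterministic default ``1e-6 * trace(Sw)/d`` (floor 1e-12).
    n_components
        Retained discriminant directions; default ``min(c - 1, d)``.

    Raises
    ------
    DegenerateClassError
        If any class has fewer than 2 samples.
    """
    X = train.matrix
    if X.shape[1] < 1:
        raise ValueError("need at least one feature dimension")
    labels = train.labels.astype(str)
    class_labels, means, grand, counts, Sb, Sw = scatter_matrices(X, labels)
    if len(class_labels) < 2:
        raise ValueError("need at least two classes")
    thin = [cl for cl, n in zip(class_labels, counts) if n < 2]
    if thin:
        raise DegenerateClassError(
            f"classes with < 2 samples cannot be fitted: {thin}"
        )
    d = X.shape[1]
    if ridge_eps is None:
        ridge_eps = max(RIDGE_REL * np.trace(Sw) / d, RIDGE_FLOOR)
    Sw_reg = Sw + ridge_eps * np.eye(d)

    # Generalized symmetric eigenproblem Sb w = lambda (Sw + eps I) w.
    eigvals, eigvecs = linalg.eigh(Sb, Sw_reg)
    order = np.argsort(eigvals)[::-1]
    k = min(len(class_labels) - 1, d)
    if n_components is not None:
        if not 1 <= n_components <= k:
            raise ValueError(f"n_components must be in [1, {k}]")
        k = n_components
    omega = _canonicalize(eigvecs[:, order[:k]])
    return LdaModel(
        class_labels=class_labels,
        class_means=means,
        grand_mean=grand,
        n_per_class=counts,
        Sb=Sb,
        Sw=Sw,
        omega=omega,
        projected_means=means @ omega,
        ridge_eps=float(ridge_eps),
        eigenvalues=eigvals[order[:k]],
        feature_names=list(train.feature_names),
    )


def fisher_criterion(model: LdaModel, direction) -> float:
    """Rayleigh quotient J(w) = (w'Sb w)/(w'(Sw + eps I)w) at ``direction``."""
    w = np.asarray(direction, dtype=float).ravel()
    if w.shape[0] != model.n_features:
        raise ValueError("direction dimension does not match the model")
    if not np.any(w):
        raise ValueError("direction must be nonzero")
    Sw_reg = model.Sw + model.ridge_eps * np.eye(model.n_features)
    return float((w @ model.Sb @ w) / (w @ Sw_reg @ w))


def project(model: LdaModel, features) -> np.ndarray:
    """Project feature rows into the discriminant space: y = omega' x."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    return X @ model.omega


def predict(model: LdaModel, features) -> np.ndarray:
    """Assign each row to the class with the nearest projected mean.

    Ties break toward the earlier class in ``model.class_labels`` order.
    """
    Y = project(model, features)
    # (n, c) distances to projected class means
    diff = Y[:, None, :] - model.projected_means[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    idx = np.argmin(dist, axis=1)  # argmin takes the first minimum: tie rule
    labels = np.asarray(model.class_labels, dtype=object)
    return labels[idx]
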