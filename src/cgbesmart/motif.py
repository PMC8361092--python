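"""Sequence-context (motif) model: one-hot logistic regression.

Targeted Cs inside the editing window (protospacer positions 4-7) are
described by one-hot encodings of the nucleotides at relative positions
-k..-1, +1..+k around the C, and a logistic regression predicts the C-to-G
efficiency (a fraction in [0, 1]).  The fit maximizes the fractional-response
(quasi-binomial) log-likelihood — cross-entropy with fractional labels —
which is convex, so the optimum is deterministic.  A small L2 ridge keeps the
problem strictly convex: the 4 one-hot columns of each relative position sum
to the intercept column, so without the ridge the per-position weight level
is a gauge freedom (predictions identify only within-position contrasts; the
ridge selects the mean-centered representative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .io_tables import TargetSite, ValidationError

NUCLEOTIDES = ("A", "C", "G", "T")  # fixed feature ordering
_NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
WINDOW = (4, 7)
RIDGE_DEFAULT = 1e-6
GRAD_TOL = 1e-8


def relative_offsets(k: int) -> list[int]:
    """Feature offsets around the targeted C: -k..-1, +1..+k."""
    return list(range(-k, 0)) + list(range(1, k + 1))


def encode_context(site: TargetSite, c_position: int, k: int) -> np.ndarray:
    """One-hot context vector (length 8k) around a window C.

    Ordering is position-major with nucleotides A<C<G<T within each relative
    position; exactly one hot bit per relative position.
    """
    if not WINDOW[0] <= c_position <= WINDOW[1]:
        raise ValidationError(
            f"c_position {c_position} outside editing window {WINDOW[0]}-{WINDOW[1]}"
        )
    if site.base_at(c_position) != "C":
        raise ValidationError(
            f"site {site.site_id!r} position {c_position} is not a C"
        )
    x = np.zeros(8 * k)
    for j, offset in enumerate(relative_offsets(k)):
        base = site.base_at(c_position + offset)  # raises if out of sequence
        if base not in _NT_INDEX:
            raise ValidationError(f"ambiguous base {base!r} in context")
        x[4 * j + _NT_INDEX[base]] = 1.0
    return x


def design_matrix(
    sites: dict[str, TargetSite], labels: pd.DataFrame, k: int
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Feature matrix and label vector for window Cs in ``labels``.

    ``labels`` needs columns site_id, position, efficiency; rows outside the
    editing window are skipped.  Returns (X, y, kept_rows).
    """
    rows, feats, ys = [], [], []
    for row in labels.itertuples(index=False):
        if not WINDOW[0] <= row.position <= WINDOW[1]:
            continue
        site = sites[row.site_id]
        feats.append(encode_context(site, int(row.position), k))
        ys.append(float(row.efficiency))
        rows.append(row)
    if not feats:
        raise ValidationError("no window (positions 4-7) labels to encode")
    return np.array(feats), np.array(ys), pd.DataFrame(rows)


@dataclass
class MotifModel:
    """Fitted logistic motif model.

    ``weights`` has shape (2k, 4): one row per relative position (-k..-1,
    +1..+k), one column per nucleotide (A, C, G, T).
    """

    k: int
    weights: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        if self.weights is None:
            return
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (2 * self.k, 4):
            raise ValidationError(
                f"weights shape {self.weights.shape} != ({2 * self.k}, 4)"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("non-finite weights")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.weights.reshape(-1) + self.intercept)

    def weight(self, offset: int, base: str) -> float:
        offs = relative_offsets(self.k)
        return float(self.weights[offs.index(offset), _NT_INDEX[base]])


def fit_motif_model(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    ridge: float = RIDGE_DEFAULT,
    seed: int | None = None,
) -> MotifModel:
    """Fit by deterministic convex optimization (L-BFGS on the penalized
    cross-entropy); ``seed`` is accepted for interface uniformity but the fit
    is seed-independent.  Converges to gradient norm <= 1e-8."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != 8 * k:
        raise ValidationError(f"feature width {X.shape[1]} != 8k = {8 * k}")
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite labels")
    if np.any((y < 0) | (y > 1)):
        raise ValidationError("labels must lie in [0, 1]")
    if X.shape[0] < 8 * k + 1:
        raise ValidationError(f"need >= {8 * k + 1} examples, got {X.shape[0]}")

    n, d = X.shape

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w, b = theta[:d], theta[d]
        z = X @ w + b
        p = expit(z)
        # cross-entropy with fractional labels; logaddexp form is stable
        ll = np.sum(y * z - np.logaddexp(0.0, z))
        loss = -ll / n + 0.5 * ridge * np.dot(w, w)
        g_z = (p - y) / n
        grad = np.empty(d + 1)
        grad[:d] = X.T @ g_z + ridge * w
        grad[d] = g_z.sum()
        return loss, grad

    theta0 = np.zeros(d + 1)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 20000, "gtol": GRAD_TOL, "ftol": 1e-15},
    )
    if not np.all(np.isfinite(res.x)):
        raise ArithmeticError("motif fit diverged")
    weights = res.x[:d].reshape(2 * k, 4)
    return MotifModel(k=k, weights=weights, intercept=float(res.x[d]))


def weights_to_logo_matrix(model: MotifModel) -> pd.DataFrame:
    """Per-position weights mean-centered across the 4 nucleotides.

    The returned frame (2k rows, columns A/C/G/T, index = relative offset)
    is directly consumable by sequence-logo renderers.
    """
    if model.weights is None:
        raise ValidationError("model is not fitted")
    centered = model.weights - model.weights.mean(axis=1, keepdims=True)
    return pd.DataFrame(
        centered, index=relative_offsets(model.k), columns=list(NUCLEOTIDES)
    )


def write_motif_model(path, model: MotifModel) -> None:
    raw = pd.DataFrame(
        model.weights, index=relative_offsets(model.k), columns=list(NUCLEOTIDES)
    )
    raw["intercept"] = model.intercept
    raw.index.name = "offset"
    raw.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def read_motif_model(path) -> MotifModel:
    df = pd.read_csv(path, sep="\t", index_col="offset")
    intercept = float(df["intercept"].iloc[0])
    weights = df[list(NUCLEOTIDES)].to_numpy()
    return MotifModel(k=weights.shape[0] // 2, weights=weights, intercept=intercept)
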