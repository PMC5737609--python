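"""Multivariate adaptive regression splines with hinge bases of degree <= 2.

The response function has the classical MARS form used throughout this
package:

    y = c + sum c'' * h(x_i - knot)  +  sum c' * h(x_i - knot) * h(x_j - knot)

with h either max(0, x - c) or max(0, c - x) and every knot an observed value
of its column.  The forward pass greedily adds the reflected hinge pair
(parent term times the new hinge, over all eligible parents, columns and
knots) that most reduces the residual sum of squares; the backward pass
greedily deletes terms, keeping the subset along the deletion path with the
lowest generalized cross-validation score

    GCV = (RSS / n) / (1 - M_eff / n)**2,   M_eff = n_terms + penalty*(n_terms-1)/2

where ``n_terms`` counts basis functions including the intercept.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = 1e-10


@dataclass(frozen=True)
class HingeFunction:
    column: str
    knot: float
    direction: int  # +1 -> max(0, x - knot); -1 -> max(0, knot - x)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.direction > 0:
            return np.maximum(0.0, x - self.knot)
        return np.maximum(0.0, self.knot - x)

    def __str__(self) -> str:
        if self.direction > 0:
            return f"h({self.column} - {self.knot:g})"
        return f"h({self.knot:g} - {self.column})"


@dataclass
class BasisTerm:
    hinges: tuple[HingeFunction, ...]
    coefficient: float = 0.0

    @property
    def degree(self) -> int:
        return len(self.hinges)

    @property
    def columns(self) -> frozenset[str]:
        return frozenset(h.column for h in self.hinges)

    def evaluate(self, X: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(X))
        for h in self.hinges:
            out *= h.evaluate(X[h.column].to_numpy(dtype=float))
        return out

    def __str__(self) -> str:
        return " * ".join(str(h) for h in self.hinges)


@dataclass
class MarsModel:
    intercept: float
    terms: list[BasisTerm]
    gcv_: float
    n_train: int
    columns: list[str]

    @property
    def n_basis(self) -> int:
        """Number of basis functions including the intercept."""
        return 1 + len(self.terms)

    def basis_matrix(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(X))] + [t.evaluate(X) for t in self.terms]
        return np.column_stack(cols)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = {c for t in self.terms for c in t.columns} - set(X.columns)
        if missing:
            raise KeyError(f"prediction rows are missing columns: {sorted(missing)}")
        out = np.full(len(X), self.intercept)
        for t in self.terms:
            out += t.coefficient * t.evaluate(X)
        return out

    def predict_row(self, row) -> float:
        frame = pd.DataFrame([dict(row)])
        return float(self.predict(frame)[0])

    def formula(self) -> str:
        parts = [f"{self.intercept:+.4g}"]
        for t in self.terms:
            parts.append(f"{t.coefficient:+.4g} * {t}")
        return "activity = " + " ".join(parts)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "gcv": self.gcv_,
            "n_train": self.n_train,
            "columns": self.columns,
            "terms": [
                {
                    "coefficient": t.coefficient,
                    "hinges": [
                        {"column": h.column, "knot": h.knot, "direction": h.direction}
                        for h in t.hinges
                    ],
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MarsModel":
        terms = [
            BasisTerm(
                tuple(HingeFunction(h["column"], h["knot"], h["direction"])
                      for h in t["hinges"]),
                t["coefficient"],
            )
            for t in payload["terms"]
        ]
        return cls(payload["intercept"], terms, payload["gcv"],
                   payload["n_train"], list(payload["columns"]))


def gcv(rss: float, n: int, n_terms: int, penalty: float = 3.0) -> float:
    """Generalized cross-validation score; +inf when the model is inadmissible."""
    m_eff = n_terms + penalty * (n_terms - 1) / 2.0
    if m_eff >= n:
        return math.inf
    return (rss / n) / (1.0 - m_eff / n) ** 2


def _knot_candidates(x: np.ndarray, max_knots: int) -> np.ndarray:
    uniq = np.unique(x)
    if uniq.size > max_knots:
        idx = np.unique(np.linspace(0, uniq.size - 1, max_knots).round().astype(int))
        uniq = uniq[idx]
    return uniq


def _fit_coefficients(B: np.ndarray, y: np.ndarray, ridge: float) -> tuple[np.ndarray, float]:
    G = B.T @ B + ridge * np.eye(B.shape[1])
    beta = np.linalg.solve(G, B.T @ y)
    rss = float(((y - B @ beta) ** 2).sum())
    return beta, rss


def forward_pass(
    X: pd.DataFrame,
    y,
    max_terms: int = 61,
    max_degree: int = 2,
    rel_tol: float = 1e-4,
    max_knots: int = 500,
    ridge: float = 1e-8,
) -> MarsModel:
    """Greedy RSS-driven construction of the hinge basis.

    At each step the reflected pair of hinges on one (parent, column, knot)
    triple is evaluated jointly through its projection on the current basis;
    the best pair is added (degenerate halves of a pair are dropped).  The
    pass stops at ``max_terms`` basis functions or when the best step improves
    R^2 by less than ``rel_tol``.  Ties break towards the earlier parent, then
    the lower column index, then the lower knot.
    """
    if max_degree not in (1, 2):
        raise ValueError("max_degree must be 1 or 2")
    if max_terms < 3:
        raise ValueError("max_terms must be >= 3")
    columns = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xv.shape
    tss = float(((y - y.mean()) ** 2).sum())

    def finish(raw_cols: list[np.ndarray], terms: list[BasisTerm]) -> MarsModel:
        B = np.column_stack(raw_cols)
        beta, rss = _fit_coefficients(B, y, ridge)
        model = MarsModel(float(beta[0]), terms, 0.0, n, columns)
        for t, c in zip(terms, beta[1:]):
            t.coefficient = float(c)
        penalty = 3.0 if max_degree >= 2 else 2.0
        model.gcv_ = gcv(rss, n, len(raw_cols), penalty)
        return model

    if tss <= _EPS:
        model = MarsModel(float(y.mean()), [], 0.0, n, columns)
        model.gcv_ = gcv(0.0, n, 1, 3.0 if max_degree >= 2 else 2.0)
        return model

    # base hinge bank: one plus/minus pair per (column, knot)
    knot_col: list[int] = []
    knot_val: list[float] = []
    for j in range(p):
        for t in _knot_candidates(Xv[:, j], max_knots):
            knot_col.append(j)
            knot_val.append(float(t))
    knot_col_arr = np.asarray(knot_col)
    knot_val_arr = np.asarray(knot_val)
    diffs = Xv[:, knot_col_arr] - knot_val_arr[None, :]
    Hp = np.maximum(0.0, diffs)
    Hm = np.maximum(0.0, -diffs)
    Hp2, Hm2 = Hp * Hp, Hm * Hm
    m = Hp.shape[1]

    raw_cols: list[np.ndarray] = [np.ones(n)]
    terms: list[BasisTerm] = []
    term_cols: list[frozenset[str]] = [frozenset()]
    term_degree: list[int] = [0]
    Q = np.empty((n, max_terms))
    Q[:, 0] = 1.0 / math.sqrt(n)
    k = 1
    y_res = y - Q[:, :1] @ (Q[:, :1].T @ y)

    while k + 1 <= max_terms - 1:
        best_gain = 0.0
        best = None  # (parent, cand_index, use_plus, use_minus)
        for parent in range(len(raw_cols)):
            if term_degree[parent] >= max_degree:
                continue
            par = raw_cols[parent]
            par_y = par * y_res
            par2 = par * par
            P = Q[:, :k] * par[:, None]
            Gp = P.T @ Hp
            Gm = P.T @ Hm
            up = par_y @ Hp
            um = par_y @ Hm
            cc_p = par2 @ Hp2
            cc_m = par2 @ Hm2
            ap = cc_p - (Gp * Gp).sum(axis=0)
            am = cc_m - (Gm * Gm).sum(axis=0)
            d = -(Gp * Gm).sum(axis=0)
            scale_p = cc_p + _EPS
            scale_m = cc_m + _EPS
            ok_p = ap > _EPS * scale_p
            ok_m = am > _EPS * scale_m
            gain_p = np.where(ok_p, up**2 / np.where(ok_p, ap, 1.0), 0.0)
            gain_m = np.where(ok_m, um**2 / np.where(ok_m, am, 1.0), 0.0)
            det = ap * am - d * d
            ok_pair = ok_p & ok_m & (det > _EPS * scale_p * scale_m)
            gain_pair = np.where(
                ok_pair,
                (am * up**2 - 2.0 * d * up * um + ap * um**2) / np.where(ok_pair, det, 1.0),
                0.0,
            )
            gain = np.maximum(gain_pair, np.maximum(gain_p, gain_m))
            if term_cols[parent]:
                blocked = [columns.index(c) for c in term_cols[parent]]
                gain[np.isin(knot_col_arr, blocked)] = 0.0
            idx = int(np.argmax(gain))
            g = float(gain[idx])
            if g > best_gain * (1.0 + 1e-12) and g > 0.0:
                use_pair = bool(gain_pair[idx] >= max(gain_p[idx], gain_m[idx]))
                use_plus = use_pair or gain_p[idx] >= gain_m[idx]
                use_minus = use_pair or gain_m[idx] > gain_p[idx]
                best_gain = g
                best = (parent, idx, use_plus, use_minus)
        if best is None or best_gain / tss < rel_tol:
            break
        parent, ci, use_plus, use_minus = best
        j = int(knot_col_arr[ci])
        knot = float(knot_val_arr[ci])
        par = raw_cols[parent]
        parent_hinges = terms[parent - 1].hinges if parent > 0 else ()
        added = 0
        for direction, use in ((1, use_plus), (-1, use_minus)):
            if not use or k >= max_terms:
                continue
            hinge = HingeFunction(columns[j], knot, direction)
            col = par * hinge.evaluate(Xv[:, j])
            # modified Gram-Schmidt, twice for stability
            q = col.copy()
            for _ in range(2):
                q -= Q[:, :k] @ (Q[:, :k].T @ q)
            norm = float(np.sqrt(q @ q))
            if norm <= 1e-8 * (float(np.sqrt(col @ col)) + 1.0):
                continue  # numerically dependent half of the pair: drop it
            q /= norm
            Q[:, k] = q
            y_res = y_res - q * (q @ y_res)
            k += 1
            raw_cols.append(col)
            terms.append(BasisTerm(parent_hinges + (hinge,)))
            term_cols.append(term_cols[parent] | {columns[j]})
            term_degree.append(term_degree[parent] + 1)
            added += 1
        if added == 0:
            break
    return finish(raw_cols, terms)


def backward_pass(
    model: MarsModel,
    X: pd.DataFrame,
    y,
    penalty: float | None = None,
    ridge: float = 1e-8,
) -> MarsModel:
    """Greedy GCV-driven deletion; returns the best subset along the path.

    At each step the term whose removal yields the lowest GCV is deleted
    (coefficients implicitly refit through the Gram system); the final model
    is the subset over the whole deletion path with the global minimum GCV,
    preferring the smaller model on ties.
    """
    if penalty is None:
        penalty = 3.0 if any(t.degree > 1 for t in model.terms) else 2.0
    y = np.asarray(y, dtype=float)
    n = len(y)
    B = model.basis_matrix(X)
    k = B.shape[1]
    G = B.T @ B + ridge * np.eye(k)
    b = B.T @ y
    yy = float(y @ y)

    def rss_of(active: list[int]) -> float:
        idx = np.ix_(active, active)
        sol = np.linalg.solve(G[idx], b[active])
        return max(yy - float(b[active] @ sol), 0.0)

    active = list(range(k))
    path: list[tuple[list[int], float]] = [
        (list(active), gcv(rss_of(active), n, len(active), penalty))
    ]
    while len(active) > 1:
        best_subset, best_score = None, math.inf
        for t in active[1:]:  # intercept (index 0) is never deleted
            cand = [i for i in active if i != t]
            score = gcv(rss_of(cand), n, len(cand), penalty)
            if best_subset is None or score < best_score - 1e-15:
                best_subset, best_score = cand, score
        active = best_subset
        path.append((list(active), best_score))

    best_subset, best_score = path[0]
    for subset, score in path[1:]:
        if score <= best_score + 1e-12:  # ties -> the smaller model
            best_subset, best_score = subset, score
    sol = np.linalg.solve(G[np.ix_(best_subset, best_subset)], b[best_subset])
    terms = []
    for pos, i in enumerate(best_subset):
        if i == 0:
            continue
        src = model.terms[i - 1]
        terms.append(BasisTerm(src.hinges, float(sol[pos])))
    intercept = float(sol[0])
    out = MarsModel(intercept, terms, best_score, n, list(model.columns))
    return out


def fit_mars(
    X: pd.DataFrame,
    y,
    max_terms: int = 61,
    max_degree: int = 2,
    rel_tol: float = 1e-4,
    max_knots: int = 500,
    penalty: float | None = None,
    ridge: float = 1e-8,
) -> MarsModel:
    """Forward pass followed by GCV backward pruning."""
    if penalty is None:
        penalty = 3.0 if max_degree >= 2 else 2.0
    fwd = forward_pass(X, y, max_terms=max_terms, max_degree=max_degree,
                       rel_tol=rel_tol, max_knots=max_knots, ridge=ridge)
    return backward_pass(fwd, X, y, penalty=penalty, ridge=ridge)


def predict_mars(model: MarsModel, rows) -> np.ndarray | float:
    """Evaluate the response function on a DataFrame (array out) or mapping (scalar)."""
    if isinstance(rows, pd.DataFrame):
        return model.predict(rows)
    return model.predict_row(rows)
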