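"""Scheffe canonical mixture polynomials: build, fit, predict, diagnose.

Because mixture proportions sum to one, the usual polynomial intercept is
not identifiable and the canonical (Scheffe) form is used instead:

    linear         Y = sum_i  b_i X_i
    quadratic      Y = ... + sum_{i<j} b_ij X_i X_j
    special cubic  Y = ... + sum_{i<j<k} b_ijk X_i X_j X_k

For q = 3 the special cubic has 7 terms.  The linear coefficient b_i is
the predicted response at the pure-component vertex e_i.  Fitting is
ordinary least squares without an intercept; R-squared and the model
F-test are computed against the mean-only null (total sum of squares
corrected for the mean), which is the standard convention for mixture
models and the one response-surface packages report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixture_design import Composition, MixtureDesign, validate_composition

__all__ = [
    "ScheffeModel",
    "ResponseTable",
    "FitDiagnostics",
    "ModelOrder",
    "build_model_matrix",
    "term_names",
    "fit_scheffe",
    "predict",
    "anova",
    "model_to_json",
    "model_from_json",
    "response_table_to_csv",
    "response_table_from_csv",
]

ModelOrder = Literal["linear", "quadratic", "special_cubic"]

_ORDERS: tuple[str, ...] = ("linear", "quadratic", "special_cubic")


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient for the requested model order."""


class InsufficientDataError(ValueError):
    """Fewer rows than model terms."""


def term_names(labels: Sequence[str], order: ModelOrder) -> list[str]:
    """Canonical term order: linear, then pairs (lexicographic), then triples."""
    labels = list(labels)
    names = list(labels)
    if order in ("quadratic", "special_cubic"):
        names += ["*".join(p) for p in combinations(labels, 2)]
    if order == "special_cubic":
        names += ["*".join(t) for t in combinations(labels, 3)]
    return names


def n_terms(q: int, order: ModelOrder) -> int:
    from math import comb

    n = q
    if order in ("quadratic", "special_cubic"):
        n += comb(q, 2)
    if order == "special_cubic":
        n += comb(q, 3)
    return n


@dataclass(frozen=True)
class ScheffeModel:
    """Coefficients of a canonical mixture polynomial.

    ``beta_linear`` holds one coefficient per component (the vertex
    predictions), ``beta_pair`` one per unordered pair in lexicographic
    order, ``beta_triple`` one per unordered triple (special cubic only).
    ``units`` records the response units so fitted and fixture models
    are never silently mixed across scales.
    """

    q: int
    order: ModelOrder
    beta_linear: tuple[float, ...]
    beta_pair: tuple[float, ...] = ()
    beta_triple: tuple[float, ...] = ()
    labels: tuple[str, ...] = ()
    units: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        from math import comb

        labels = self.labels or tuple(f"X{i+1}" for i in range(self.q))
        object.__setattr__(self, "labels", tuple(labels))
        if self.order not in _ORDERS:
            raise ValueError(f"unknown model order {self.order!r}")
        if len(self.beta_linear) != self.q:
            raise ValueError("beta_linear length must equal q")
        want_pair = comb(self.q, 2) if self.order != "linear" else 0
        if len(self.beta_pair) != want_pair:
            raise ValueError(f"expected {want_pair} pair coefficients")
        want_tri = comb(self.q, 3) if self.order == "special_cubic" else 0
        if len(self.beta_triple) != want_tri:
            raise ValueError(f"expected {want_tri} triple coefficients")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array(
            list(self.beta_linear) + list(self.beta_pair) + list(self.beta_triple)
        )

    @property
    def terms(self) -> list[str]:
        return term_names(self.labels, self.order)


@dataclass(frozen=True)
class ResponseTable:
    """A design with one measured response per run.

    The design lists distinct points with a per-point replicate count;
    ``values`` holds one number per run, replicate-within-point order,
    so its length is ``len(design) * design.replicates``.
    """

    design: MixtureDesign
    response_name: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = len(self.design.points) * self.design.replicates
        if len(self.values) != expected:
            raise ValueError(
                f"{len(self.values)} responses for {expected} design runs "
                f"({len(self.design.points)} points x {self.design.replicates} replicates)"
            )

    def run_matrix(self) -> np.ndarray:
        """(n_runs, q) composition array with replicate rows expanded."""
        return np.repeat(self.design.as_matrix(), self.design.replicates, axis=0)

    def run_points(self) -> list[Composition]:
        return [
            pt for pt in self.design.points for _ in range(self.design.replicates)
        ]


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit summary for a fitted mixture model.

    Lack-of-fit fields are present only when the design contains
    replicated points (pure error is otherwise not estimable).
    """

    r2: float
    adj_r2: float
    model_f: float
    model_p: float
    residuals: tuple[float, ...]
    term_t: tuple[float, ...] = ()
    term_p: tuple[float, ...] = ()
    lof_f: float | None = None
    lof_p: float | None = None


def build_model_matrix(
    points: Sequence[Composition] | np.ndarray, order: ModelOrder
) -> np.ndarray:
    """Rows x terms matrix in canonical term order; no intercept column."""
    if order not in _ORDERS:
        raise ValueError(f"unknown model order {order!r}")
    X = np.array(
        [p.as_array() if isinstance(p, Composition) else np.asarray(p, float) for p in points]
    )
    q = X.shape[1]
    if order == "special_cubic" and q < 3:
        raise ValueError("special cubic model requires at least 3 components")
    cols = [X]
    if order in ("quadratic", "special_cubic"):
        cols.append(
            np.column_stack([X[:, i] * X[:, j] for i, j in combinations(range(q), 2)])
        )
    if order == "special_cubic":
        cols.append(
            np.column_stack(
                [X[:, i] * X[:, j] * X[:, k] for i, j, k in combinations(range(q), 3)]
            )
        )
    return np.hstack(cols)


def predict(model: ScheffeModel, x: Composition | Sequence[float]) -> float:
    """Evaluate the polynomial at a composition.

    The prediction at a vertex e_i equals ``beta_linear[i]`` exactly:
    every interaction monomial vanishes there and the remaining product
    is 1 * b_i with no accumulation.
    """
    if not isinstance(x, Composition):
        x = validate_composition(np.asarray(x, dtype=float))
    if x.q != model.q:
        raise ValueError(f"composition has {x.q} components, model has {model.q}")
    row = build_model_matrix([x], model.order)[0]
    return float(row @ model.coefficients)


def predict_many(model: ScheffeModel, X: np.ndarray) -> np.ndarray:
    """Vectorized polynomial evaluation on an (n, q) array of compositions."""
    return build_model_matrix(np.asarray(X, dtype=float), model.order) @ model.coefficients


def fit_scheffe(
    table: ResponseTable, order: ModelOrder = "special_cubic"
) -> tuple[ScheffeModel, FitDiagnostics]:
    """Fit a Scheffe polynomial by no-intercept OLS and run its ANOVA.

    Raises
    ------
    InsufficientDataError
        Fewer rows than terms.
    SingularDesignError
        The model matrix is rank-deficient (message names the dependent
        columns).
    """
    q = table.design.q
    y = np.asarray(table.values, dtype=float)
    X = build_model_matrix(table.run_matrix(), order)
    p = X.shape[1]
    if len(y) < p:
        raise InsufficientDataError(
            f"{len(y)} rows cannot identify {p} model terms"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify a maximal independent set by greedy QR on columns
        from scipy.linalg import qr

        names = term_names(table.design.labels, order)
        _, _, piv = qr(X, pivoting=True, mode="economic")
        dependent = sorted(names[i] for i in piv[rank:])
        raise SingularDesignError(
            f"design matrix rank {rank} < {p} terms; dependent columns: {dependent}"
        )

    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    beta = res.params

    from math import comb

    model = ScheffeModel(
        q=q,
        order=order,
        beta_linear=tuple(beta[:q]),
        beta_pair=tuple(beta[q : q + comb(q, 2)]) if order != "linear" else (),
        beta_triple=tuple(beta[q + comb(q, 2) :]) if order == "special_cubic" else (),
        labels=table.design.labels,
        units="",
        provenance=f"fit:{table.response_name}",
    )
    diag = _diagnostics(X, y, beta, res, table)
    return model, diag


def _diagnostics(X, y, beta, res, table: ResponseTable) -> FitDiagnostics:
    n, p = X.shape
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())  # corrected for the mean
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    # mixture convention: the q linear terms jointly absorb the mean, so
    # the model accounts for p - 1 df beyond it
    df_model = p - 1
    df_resid = n - p
    if sst > 0 and df_resid > 0:
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    else:
        adj_r2 = r2
    if df_resid > 0 and sse > 0:
        model_f = ((sst - sse) / df_model) / (sse / df_resid)
        model_p = float(stats.f.sf(model_f, df_model, df_resid))
    else:
        model_f, model_p = float("inf"), 0.0

    lof_f = lof_p = None
    groups: dict[tuple, list[int]] = {}
    for i, pt in enumerate(table.run_points()):
        groups.setdefault(tuple(np.round(pt.as_array(), 10)), []).append(i)
    n_distinct = len(groups)
    if n_distinct < n and n_distinct > p:
        sspe = sum(
            float(((y[idx] - y[idx].mean()) ** 2).sum())
            for idx in (np.array(g) for g in groups.values())
        )
        sslof = max(sse - sspe, 0.0)
        df_lof, df_pe = n_distinct - p, n - n_distinct
        if df_pe > 0 and sspe > 0:
            lof_f = (sslof / df_lof) / (sspe / df_pe)
            lof_p = float(stats.f.sf(lof_f, df_lof, df_pe))

    return FitDiagnostics(
        r2=r2,
        adj_r2=adj_r2,
        model_f=model_f,
        model_p=model_p,
        residuals=tuple(resid),
        term_t=tuple(np.asarray(res.tvalues)),
        term_p=tuple(np.asarray(res.pvalues)),
        lof_f=lof_f,
        lof_p=lof_p,
    )


def anova(model: ScheffeModel, table: ResponseTable) -> FitDiagnostics:
    """ANOVA of an already-specified model against a response table.

    Refits the model form to the table (OLS is deterministic, so a model
    fitted from the same table reproduces its own diagnostics) and
    reports the mean-corrected F-test plus, when the design contains
    replicated points, the lack-of-fit F-test against pure error.
    """
    _, diag = fit_scheffe(table, model.order)
    return diag


# ---------------------------------------------------------------------------
# serialization

def model_to_json(model: ScheffeModel, path: str | Path) -> None:
    payload = {
        "labels": list(model.labels),
        "order": model.order,
        "terms": [
            {"name": name, "coefficient": float(c)}
            for name, c in zip(model.terms, model.coefficients)
        ],
        "units": model.units,
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def model_from_json(path: str | Path) -> ScheffeModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    labels = tuple(payload["labels"])
    order = payload["order"]
    q = len(labels)
    want = term_names(labels, order)
    got = [t["name"] for t in payload["terms"]]
    if got != want:
        raise ValueError(f"model terms {got} do not match canonical order {want}")
    coefs = [float(t["coefficient"]) for t in payload["terms"]]
    from math import comb

    return ScheffeModel(
        q=q,
        order=order,
        beta_linear=tuple(coefs[:q]),
        beta_pair=tuple(coefs[q : q + comb(q, 2)]) if order != "linear" else (),
        beta_triple=tuple(coefs[q + comb(q, 2) :]) if order == "special_cubic" else (),
        labels=labels,
        units=payload.get("units", ""),
        provenance=payload.get("provenance", ""),
    )


def response_table_to_csv(table: ResponseTable, path: str | Path) -> None:
    """One CSV row per run, point-major (replicates of a point adjacent)."""
    df = pd.DataFrame(table.run_matrix(), columns=list(table.design.labels))
    df[table.response_name] = list(table.values)
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def response_table_from_csv(
    path: str | Path, response_name: str | None = None
) -> ResponseTable:
    """Read a per-run response CSV; repeated composition rows become replicates.

    Requires every distinct point to appear the same number of times
    (balanced replication); the last column is taken as the response
    unless ``response_name`` is given.
    """
    from .mixture_design import ValidationError

    df = pd.read_csv(path, encoding="utf-8")
    if response_name is None:
        response_name = str(df.columns[-1])
    labels = [c for c in df.columns if c != response_name]
    points: list[Composition] = []
    keys: list[tuple] = []
    grouped: dict[tuple, list[float]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        vec = np.array([getattr(row, c) for c in labels], dtype=float)
        try:
            comp = validate_composition(vec)
        except ValidationError as err:
            raise ValidationError(f"row {i + 1}: {err}") from err
        key = tuple(np.round(comp.as_array(), 10))
        if key not in grouped:
            grouped[key] = []
            keys.append(key)
            points.append(comp)
        grouped[key].append(float(getattr(row, response_name)))
    counts = {len(v) for v in grouped.values()}
    if len(counts) != 1:
        raise ValueError(
            f"unbalanced replication: per-point run counts {sorted(counts)}"
        )
    replicates = counts.pop()
    design = MixtureDesign(
        q=len(labels),
        m=0,
        points=tuple(points),
        labels=tuple(labels),
        replicates=replicates,
    )
    values = tuple(v for key in keys for v in grouped[key])
    return ResponseTable(design=design, response_name=response_name, values=values)
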